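"""Synthetic staged-expression generator with planted ground truth.

Emulates an 18-array staged-pregnancy endometrial dataset: log2-scale
intensities over 6 gestational stages × 3 replicates, with three planted
gene classes,

* **archetype genes** — follow one of eight temporal archetype curves
  (rise-then-fall, monotone decline, post-mid-gestation drop, terminal
  spike, baseline-high, and their mirror shapes) plus Gaussian noise;
* **module genes** — share a module-specific latent stage profile so that
  any two members have expected pairwise correlation equal to the target
  ``within_module_correlation``; latent profiles are mutually orthogonal
  stage contrasts, so expected cross-module correlation is zero; each
  module carries one designated hub gene with 4× lower idiosyncratic
  noise, giving it the highest expected intramodular connectivity; a
  fraction of members load negatively to exercise the signed-connectivity
  machinery;
* **null genes** — i.i.d. Gaussian noise around a constant gene baseline.

Every generated object is accompanied by a :class:`PlantedTruth` record so
downstream recovery (DEG calls, temporal clusters, network modules, hubs)
can be scored against the planted structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DEFAULT_DESIGN, ExpressionMatrix, StudyDesign

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "archetype_curves",
    "module_latent_profiles",
    "generate_expression_matrix",
    "generate_probe_level",
    "generate_qpcr_ct",
]

# Temporal archetypes on a normalised 0..1 gestation axis at 6 anchor
# points; shapes: mid-gestation peak, monotone decline, drop after
# mid-gestation, gradual rise with terminal spike, high-at-baseline,
# plus the mirrors of the 1st, 3rd and 4th.
_ANCHORS = np.linspace(0.0, 1.0, 6)
_BASE_SHAPES = np.array(
    [
        [-1.0, 0.1, 1.0, 0.8, 0.0, -1.0],   # rise then fall, mid peak
        [1.0, 0.6, 0.2, -0.2, -0.6, -1.0],  # monotone decrease
        [0.9, 0.9, 0.8, -0.8, -0.9, -1.0],  # drop after mid-gestation
        [-0.8, -0.7, -0.5, -0.2, 0.2, 2.0], # gradual rise, terminal spike
        [2.0, -0.2, -0.4, -0.4, -0.5, -0.5],# high at baseline then low
    ]
)
_SHAPES8 = np.vstack([_BASE_SHAPES, -_BASE_SHAPES[[0, 2, 3]]])


def _standardize_rows(m: np.ndarray) -> np.ndarray:
    m = m - m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant profile cannot be standardized")
    return m / sd


def archetype_curves(n_stages: int = 6, n_archetypes: int = 8) -> np.ndarray:
    """Archetype stage curves, each standardized to mean 0 / sd 1.

    Curves are defined at 6 anchor points and linearly interpolated onto
    ``n_stages`` equally spaced stage positions. At most 8 archetypes are
    available.
    """
    if not 1 <= n_archetypes <= len(_SHAPES8):
        raise ValueError(f"n_archetypes must be in 1..{len(_SHAPES8)}")
    t = np.linspace(0.0, 1.0, n_stages)
    curves = np.array([np.interp(t, _ANCHORS, s) for s in _SHAPES8[:n_archetypes]])
    return _standardize_rows(curves)


def module_latent_profiles(n_modules: int, n_stages: int) -> np.ndarray:
    """Mutually orthogonal, mean-zero latent stage profiles (unit sd rows).

    Uses Helmert-style contrasts; a stage axis of S points supports at most
    S−1 orthogonal mean-zero profiles.
    """
    if n_modules > n_stages - 1:
        raise ValueError(
            f"{n_stages} stages support at most {n_stages - 1} orthogonal "
            f"mean-zero module profiles (requested {n_modules})"
        )
    rows = []
    for k in range(1, n_modules + 1):
        v = np.zeros(n_stages)
        v[:k] = 1.0
        v[k] = -float(k)
        rows.append(v)
    return _standardize_rows(np.array(rows))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults define the standard study conditions.

    ``module_sizes`` sums over planted co-expression modules; together with
    ``frac_null`` it determines how many genes remain for the temporal
    archetypes. ``effect_size`` is the log2-scale amplitude of planted
    temporal signal, ``noise_sd`` the residual log2 sd for archetype and
    null genes. Module-gene noise is instead calibrated from
    ``within_module_correlation`` so that expected pairwise |r| within a
    module matches the target.
    """

    n_genes: int = 1000
    frac_null: float = 0.5
    n_archetypes: int = 8
    n_modules: int = 5
    module_sizes: tuple[int, ...] = (130, 110, 90, 70, 50)
    within_module_correlation: float = 0.8
    effect_size: float = 1.0
    noise_sd: float = 0.25
    neg_fraction: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.frac_null <= 1.0:
            raise ValueError("frac_null must lie in [0, 1]")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("each module needs at least 2 genes")
        avail = int(round(self.n_genes * (1.0 - self.frac_null)))
        if sum(self.module_sizes) > avail:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes)} but only "
                f"{avail} non-null genes are available"
            )
        if self.n_modules > 0 and not 0.0 < self.within_module_correlation < 1.0:
            raise ValueError("within_module_correlation must lie strictly in (0, 1)")
        if not 0.0 <= self.neg_fraction < 1.0:
            raise ValueError("neg_fraction must lie in [0, 1)")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("noise_sd and effect_size must be non-negative")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def scaled_to(cls, n_genes: int, seed: int = 0, **kw) -> "SyntheticConfig":
        """Default conditions rescaled to ``n_genes`` total genes.

        Module sizes keep the default proportions of the gene count so the
        planted structure survives at smaller problem sizes.
        """
        base = cls()
        factor = n_genes / base.n_genes
        sizes = tuple(max(4, round(s * factor)) for s in base.module_sizes)
        avail = int(round(n_genes * (1.0 - base.frac_null)))
        while sum(sizes) > avail and len(sizes) > 1:
            sizes = sizes[:-1]
        return cls(n_genes=n_genes, module_sizes=sizes, n_modules=len(sizes),
                   seed=seed, **kw)


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator.

    ``archetype_of_gene`` maps each gene to an archetype index, the string
    ``"module"`` for co-expression module members, or ``"null"``.
    ``deg_flags`` is a genes × non-baseline-stages boolean table of true
    differential expression vs the baseline stage.
    """

    archetype_of_gene: dict[str, object]
    module_of_gene: dict[str, str]
    hub_flags: frozenset[str]
    deg_flags: pd.DataFrame

    def __post_init__(self) -> None:
        for g in self.hub_flags:
            if self.module_of_gene.get(g, "background") == "background":
                raise ValueError(f"hub gene {g} not in a module")
        for g, a in self.archetype_of_gene.items():
            if a == "null" and bool(self.deg_flags.loc[g].any()):
                raise ValueError(f"null gene {g} has a true DEG flag")

    def module_labels(self, genes) -> list[str]:
        return [self.module_of_gene.get(g, "background") for g in genes]


_HUB_NOISE_FACTOR = 0.25  # hubs: 4x lower idiosyncratic noise than members


def generate_expression_matrix(
    design: StudyDesign = DEFAULT_DESIGN,
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Generate a log2 expression matrix plus its planted truth.

    Gene order: module genes (module by module, hub first), then archetype
    genes (archetypes assigned round-robin), then null genes.
    """
    rng = np.random.default_rng(config.seed)
    stages = list(design.stage_labels)
    n_stages = len(stages)
    reps = design.replicates_per_stage
    samples = design.sample_ids()
    n_samples = len(samples)
    stage_idx = np.repeat(np.arange(n_stages), reps)

    n = config.n_genes
    n_null = int(round(n * config.frac_null))
    n_module = sum(config.module_sizes)
    n_arch = n - n_null - n_module
    if n_arch < 0:  # guarded by config validation; defensive
        raise ValueError("module sizes exceed available non-null genes")

    width = max(4, len(str(n)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, n + 1)]
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    values = np.empty((n, n_samples))
    archetype_of: dict[str, object] = {}
    module_of: dict[str, str] = {}
    hubs: set[str] = set()
    planted_profile = np.zeros((n, n_stages))  # stage-mean shift per gene

    row = 0
    if config.n_modules > 0:
        latents = module_latent_profiles(config.n_modules, n_stages)
        rho = config.within_module_correlation
        for mi, size in enumerate(config.module_sizes):
            mod_name = f"M{mi + 1}"
            lat = latents[mi][stage_idx]  # broadcast to samples
            n_neg = int(round(size * config.neg_fraction))
            for j in range(size):
                g = gene_ids[row]
                loading = -1.0 if j >= size - n_neg else 1.0
                noise_factor = _HUB_NOISE_FACTOR if j == 0 else 1.0
                eps = rng.normal(0.0, 1.0, n_samples)
                sig = loading * np.sqrt(rho) * lat + noise_factor * np.sqrt(1 - rho) * eps
                values[row] = baselines[row] + config.effect_size * sig
                module_of[g] = mod_name
                archetype_of[g] = "module"
                planted_profile[row] = loading * np.sqrt(rho) * config.effect_size * latents[mi]
                if j == 0:
                    hubs.add(g)
                row += 1

    if n_arch > 0:
        curves = archetype_curves(n_stages, config.n_archetypes)
        for j in range(n_arch):
            g = gene_ids[row]
            a = j % config.n_archetypes
            shift = config.effect_size * curves[a]
            values[row] = (
                baselines[row]
                + shift[stage_idx]
                + rng.normal(0.0, config.noise_sd, n_samples)
            )
            archetype_of[g] = a
            planted_profile[row] = shift
            row += 1

    for _ in range(n_null):
        g = gene_ids[row]
        values[row] = baselines[row] + rng.normal(0.0, config.noise_sd, n_samples)
        archetype_of[g] = "null"
        row += 1

    base_col = stages.index(design.baseline_stage)
    later = [s for s in stages if s != design.baseline_stage]
    later_cols = [stages.index(s) for s in later]
    deg = np.abs(planted_profile[:, later_cols] - planted_profile[:, [base_col]]) > 1e-9
    deg_flags = pd.DataFrame(deg, index=gene_ids, columns=later)

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=samples),
        design.stage_of_sample(),
    )
    truth = PlantedTruth(archetype_of, module_of, frozenset(hubs), deg_flags)
    return expr, truth


def generate_probe_level(
    expr: ExpressionMatrix,
    probes_per_gene: int,
    probe_effect_sd: float,
    seed: int,
    measurement_noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Expand each gene into probe rows: gene value + fixed probe offset + noise.

    Per-probe offsets are drawn once per probe and median-centred within
    each gene (they model deviations around the gene-level signal), so
    median-polish summarization recovers the gene row exactly when
    measurement noise is zero, and a single-probe gene reproduces the gene
    row unchanged.

    Returns the probes × samples matrix and the probe → gene map.
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    if probe_effect_sd < 0 or measurement_noise_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    n_samples = len(expr.sample_ids)
    rows, ids, probe_to_gene = [], [], {}
    for g in expr.gene_ids:
        offsets = rng.normal(0.0, probe_effect_sd, probes_per_gene)
        offsets -= np.median(offsets)  # median polish recovers the gene row
        base = expr.values.loc[g].to_numpy(dtype=float)
        for p in range(probes_per_gene):
            pid = f"{g}_p{p + 1:02d}"
            noise = rng.normal(0.0, measurement_noise_sd, n_samples)
            rows.append(base + offsets[p] + noise)
            ids.append(pid)
            probe_to_gene[pid] = g
    probe_df = pd.DataFrame(np.array(rows), index=ids, columns=expr.sample_ids)
    return probe_df, probe_to_gene


def generate_qpcr_ct(
    expr_subset: ExpressionMatrix,
    reference_genes: list[str],
    ct_noise_sd: float,
    seed: int,
    ct_offset: float = 30.0,
    reference_level: float = 10.0,
) -> pd.DataFrame:
    """Simulate a CT table for target genes plus constant reference genes.

    CT is on the PCR cycle scale: one log2 unit more transcript means one
    cycle fewer, so ``CT = ct_offset − expression + noise``. Reference
    genes are constant in expectation across all samples at
    ``reference_level`` log2 units.
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    overlap = set(reference_genes) & set(expr_subset.gene_ids)
    if overlap:
        raise ValueError(f"reference genes overlap targets: {sorted(overlap)}")
    rng = np.random.default_rng(seed)
    samples = expr_subset.sample_ids
    ct = ct_offset - expr_subset.values.to_numpy(dtype=float)
    ct = ct + rng.normal(0.0, ct_noise_sd, ct.shape)
    rows = pd.DataFrame(ct, index=expr_subset.gene_ids, columns=samples)
    ref = pd.DataFrame(
        ct_offset
        - reference_level
        + rng.normal(0.0, ct_noise_sd, (len(reference_genes), len(samples))),
        index=list(reference_genes),
        columns=samples,
    )
    return pd.concat([rows, ref])
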