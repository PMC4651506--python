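"""Stage-versus-baseline differential expression.

Each later stage is compared to the baseline stage with an unpaired Welch
t-test per gene; p-values are Benjamini–Hochberg adjusted within each
comparison and genes with adjusted p below ``alpha`` are called
differentially expressed, with direction taken from the sign of the
log2 fold change (difference of stage-mean log2 values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionMatrix

__all__ = [
    "welch_t_test",
    "bh_adjust",
    "log2_fold_change",
    "call_degs",
    "partition_degs",
    "DEGPartition",
]

DEG_COLUMNS = [
    "gene_id",
    "later_stage",
    "baseline_stage",
    "log2_fold_change",
    "t_statistic",
    "welch_df",
    "p_value",
    "fdr_adjusted_p",
    "direction",
]


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Unpaired Welch t-test; returns ``(t, df, two-sided p)``.

    The degenerate both-variances-zero case is resolved explicitly:
    equal means give ``t=0, p=1`` (no evidence against the null),
    unequal means give an infinite t and ``p=0``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        df = float(a.size + b.size - 2)
        diff = a.mean() - b.mean()
        if diff == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(diff)) * np.inf, df, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(
    expr: ExpressionMatrix, gene: str, later_stage: str, baseline_stage: str
) -> float:
    """Difference of stage-mean log2 expression, later − baseline."""
    row = expr.values.loc[gene]
    later = row[expr.samples_of_stage(later_stage)].mean()
    base = row[expr.samples_of_stage(baseline_stage)].mean()
    return float(later - base)


def _vector_welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch test for genes × replicates blocks a and b."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    pooled_df = float(na + nb - 2)
    zero = se2 == 0.0
    with np.errstate(invalid="ignore"):
        t = np.where(zero, np.where(diff == 0.0, 0.0, np.sign(diff) * np.inf), t)
    df = np.where(zero, pooled_df, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero & (diff == 0.0), 1.0, p)
    p = np.where(np.isinf(t), 0.0, p)
    return t, df, np.clip(p, 0.0, 1.0)


def call_degs(
    expr: ExpressionMatrix, baseline_stage: str | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Call DEGs for every later stage versus the baseline.

    Per comparison: gene-wise Welch test, BH adjustment within that
    comparison, records retained where adjusted p < ``alpha``. Returns a
    table with one row per (gene, comparison) call.
    """
    if baseline_stage is None:
        baseline_stage = expr.stages[0]
    if baseline_stage not in expr.stages:
        raise ValueError(f"baseline stage {baseline_stage!r} absent from matrix")
    base_cols = expr.samples_of_stage(baseline_stage)
    if len(base_cols) < 2:
        raise ValueError("need at least 2 replicates per stage")
    base = expr.values[base_cols].to_numpy(dtype=float)
    frames = []
    for stage in expr.stages:
        if stage == baseline_stage:
            continue
        cols = expr.samples_of_stage(stage)
        if len(cols) < 2:
            raise ValueError("need at least 2 replicates per stage")
        later = expr.values[cols].to_numpy(dtype=float)
        t, df, p = _vector_welch(later, base)
        padj = bh_adjust(p)
        lfc = later.mean(axis=1) - base.mean(axis=1)
        keep = padj < alpha
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": np.asarray(expr.gene_ids)[keep],
                    "later_stage": stage,
                    "baseline_stage": baseline_stage,
                    "log2_fold_change": lfc[keep],
                    "t_statistic": t[keep],
                    "welch_df": df[keep],
                    "p_value": p[keep],
                    "fdr_adjusted_p": padj[keep],
                    "direction": np.where(lfc[keep] > 0, "up", "down"),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=DEG_COLUMNS)
    return pd.concat(frames, ignore_index=True)[DEG_COLUMNS]


@dataclass
class DEGPartition:
    """Stage-specific up/down DEG sets plus the multi-stage shared set."""

    stage_specific: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    shared: set[str] = field(default_factory=set)
    total_unique: int = 0


def partition_degs(records: pd.DataFrame) -> DEGPartition:
    """Partition DEG calls into stage-specific and shared sets.

    A gene significant in exactly one comparison goes to that stage's up or
    down set; a gene significant in two or more comparisons goes to the
    shared set. ``total_unique`` counts distinct genes across all calls.
    """
    part = DEGPartition()
    if records.empty:
        return part
    if records["baseline_stage"].nunique() > 1:
        raise ValueError("records mix baselines; partition one baseline at a time")
    counts = records.groupby("gene_id")["later_stage"].nunique()
    part.shared = set(counts[counts >= 2].index)
    single = counts[counts == 1].index
    once = records[records["gene_id"].isin(single)]
    for (stage, direction), grp in once.groupby(["later_stage", "direction"]):
        part.stage_specific[(stage, direction)] = set(grp["gene_id"])
    part.total_unique = int(records["gene_id"].nunique())
    return part
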