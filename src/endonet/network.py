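"""Weighted gene co-expression network construction and module detection.

The network is built from the absolute Pearson correlation between all
gene pairs, soft-thresholded with a power function (``|r²|^β``, i.e.
``|r|^(2β)``; a conventional ``|r|^β`` dialect is available), with the
power β chosen by the scale-free topology criterion: the smallest
candidate for which the regression of log10 p(k) on log10 k across
connectivity bins reaches the target R² with negative slope.

Modules are branches of the average-linkage dendrogram on topological-
overlap dissimilarity (1 − TOM) below a static height cut (default 0.94),
subject to a minimum size; they are labelled by colour in decreasing size
order. Hub genes are called from signed intramodular connectivity: the sum
of adjacency to positively / negatively correlated partners, scaled by the
within-module maximum, with a hub requiring |scaled K| > 0.9 and more than
10 connected partners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "pearson_adjacency",
    "connectivity",
    "scale_free_fit",
    "pick_soft_threshold",
    "ScaleFreeFit",
    "tom",
    "detect_modules",
    "signed_scaled_connectivity",
    "CoexpressionNetwork",
    "MODULE_COLORS",
]

# canonical module colour sequence, assigned in decreasing module size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)

BACKGROUND = "background"


def _drop_constant(values: np.ndarray, gene_ids: list[str]):
    keep = values.std(axis=1) > 0
    if not keep.all():
        dropped = [g for g, k in zip(gene_ids, keep) if not k]
        warnings.warn(
            f"excluding {len(dropped)} constant gene(s) from the network: "
            f"{dropped[:5]}",
            stacklevel=3,
        )
    return values[keep], [g for g, k in zip(gene_ids, keep) if k]


def _power_adjacency(r: np.ndarray, beta: float, dialect: str) -> np.ndarray:
    if dialect == "r2":
        a = np.abs(r**2) ** beta  # the printed power law: |r²|^β = |r|^(2β)
    elif dialect == "abs":
        a = np.abs(r) ** beta
    else:
        raise ValueError("adjacency dialect must be 'r2' or 'abs'")
    np.fill_diagonal(a, 0.0)
    return a


def pearson_adjacency(
    matrix: pd.DataFrame, beta: float, dialect: str = "r2"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation and soft-thresholded adjacency for genes × samples data.

    Returns ``(r, a)`` where ``a_ij = |r_ij²|^β`` (or ``|r_ij|^β`` in the
    ``abs`` dialect) off-diagonal and ``a_ii = 0`` so connectivity sums
    exclude self-edges. Constant genes have undefined correlation and are
    excluded with a warning.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    values, genes = _drop_constant(matrix.to_numpy(dtype=float), list(matrix.index))
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    a = _power_adjacency(r, beta, dialect)
    return (
        pd.DataFrame(r, index=genes, columns=genes),
        pd.DataFrame(a, index=genes, columns=genes),
    )


def connectivity(a: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity k_i = Σ_{j≠i} a_ij (row sums)."""
    values = a.to_numpy(dtype=float).copy()
    np.fill_diagonal(values, 0.0)
    return pd.Series(values.sum(axis=1), index=a.index, name="k")


def scale_free_fit(k, n_bins: int = 10) -> tuple[float, float]:
    """Goodness of scale-free topology fit from a connectivity vector.

    Bins k into ``n_bins`` equal-width bins, estimates p(k) as the
    fraction of genes per bin, and regresses log10 p(k) on log10 of the
    bin-mean k over non-empty bins. Returns ``(R², slope)``.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("connectivity values must be positive for the log fit")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        raise ValueError(
            f"only {len(xs)} non-empty connectivity bin(s); the scale-free "
            "fit needs at least 3"
        )
    slope, intercept = np.polyfit(xs, ys, 1)
    yhat = slope * np.asarray(xs) + intercept
    ss_res = float(np.sum((np.asarray(ys) - yhat) ** 2))
    ss_tot = float(np.sum((np.asarray(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(np.clip(r2, 0.0, 1.0)), float(slope)


@dataclass
class ScaleFreeFit:
    """Per-candidate scale-free diagnostics and the chosen power."""

    beta_candidates: list[float]
    r_squared: list[float]
    slope: list[float]
    mean_connectivity: list[float]
    chosen_beta: float
    criterion_met: bool = True
    r2_target: float = 0.8


def pick_soft_threshold(
    matrix: pd.DataFrame,
    beta_candidates=tuple(range(1, 7)),
    r2_target: float = 0.8,
    n_bins: int = 10,
    dialect: str = "r2",
) -> ScaleFreeFit:
    """Choose the soft-threshold power by the scale-free topology criterion.

    The chosen β is the smallest candidate whose log p(k) / log k
    regression reaches ``r2_target`` with a negative slope; if none
    qualifies the candidate maximizing R² is returned with a warning.
    """
    candidates = list(beta_candidates)
    if not candidates:
        raise ValueError("beta_candidates must be non-empty")
    values, _ = _drop_constant(matrix.to_numpy(dtype=float), list(matrix.index))
    r = np.clip(np.corrcoef(values), -1.0, 1.0)
    r2s, slopes, mean_k = [], [], []
    for beta in candidates:
        a = _power_adjacency(r, beta, dialect)
        k = a.sum(axis=1)
        mean_k.append(float(k.mean()))
        try:
            r2, slope = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            r2, slope = 0.0, 0.0
        r2s.append(r2)
        slopes.append(slope)
    chosen, met = None, True
    for beta, r2, slope in zip(candidates, r2s, slopes):
        if r2 >= r2_target and slope < 0:
            chosen = beta
            break
    if chosen is None:
        met = False
        chosen = candidates[int(np.argmax(r2s))]
        warnings.warn(
            f"no candidate power reached R² ≥ {r2_target}; falling back to "
            f"the best fit (beta={chosen}, R²={max(r2s):.3f})",
            stacklevel=2,
        )
    return ScaleFreeFit(candidates, r2s, slopes, mean_k, float(chosen), met, r2_target)


def tom(a: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap ω_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 − a_ij).

    ``l_ij = Σ_u a_iu a_uj`` counts shared-neighbour strength; the diagonal
    is 1 by convention and 1 − ω is the clustering dissimilarity.
    """
    A = a.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    if A.min() < 0 or A.max() > 1 or not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric with entries in [0, 1]")
    L = A @ A
    k = A.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - A
    omega = (L + A) / denom
    np.fill_diagonal(omega, 1.0)
    omega = np.clip(omega, 0.0, 1.0)
    return pd.DataFrame(omega, index=a.index, columns=a.columns)


def detect_modules(
    omega: pd.DataFrame,
    cut_height: float = 0.94,
    min_module_size: int = 30,
) -> tuple[pd.Series, np.ndarray]:
    """Average-linkage modules from TOM with a static height cut.

    Branches of the dendrogram below ``cut_height`` (on 1 − TOM
    dissimilarity) containing at least ``min_module_size`` genes become
    modules, labelled by colour in decreasing size order (size ties broken
    by the lexicographically smallest member id); all other genes are
    labelled ``background``. Returns the gene → label series and the
    scipy linkage matrix.
    """
    genes = list(omega.index)
    d = 1.0 - omega.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    # branches merge strictly below the cut; a cut at 0 keeps all singletons
    raw = fcluster(z, t=np.nextafter(cut_height, -np.inf), criterion="distance")
    labels = pd.Series(BACKGROUND, index=genes, dtype=object, name="module")
    groups = []
    for cl in np.unique(raw):
        members = [g for g, c in zip(genes, raw) if c == cl]
        if len(members) >= min_module_size:
            groups.append(members)
    if not groups:
        warnings.warn("no branch met the minimum module size; all background",
                      stacklevel=2)
    groups.sort(key=lambda ms: (-len(ms), min(ms)))
    for i, members in enumerate(groups):
        color = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
        labels.loc[members] = color
    return labels, z


def signed_scaled_connectivity(
    a: pd.DataFrame,
    r: pd.DataFrame,
    modules: pd.Series,
    edge_threshold: float = 0.02,
    hub_scaled_k: float = 0.9,
    hub_min_nodes: int = 10,
) -> pd.DataFrame:
    """Signed, within-module-scaled connectivity and hub calls per gene.

    ``k_positive`` sums a gene's adjacency to partners it is positively
    correlated with (network-wide), ``k_negative`` to negatively
    correlated partners; each is scaled by its maximum within the gene's
    module, so every module's most-connected gene shows scaled K = 1 for
    that sign. ``connected_nodes`` counts partners with adjacency at or
    above ``edge_threshold``. A gene is a hub when
    ``max(scaled_k_positive, scaled_k_negative) > hub_scaled_k`` and
    ``connected_nodes > hub_min_nodes``; background genes are never hubs.
    """
    genes = list(a.index)
    A = a.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    R = r.loc[genes, genes].to_numpy(dtype=float)
    k_pos = np.where(R > 0, A, 0.0).sum(axis=1)
    k_neg = np.where(R < 0, A, 0.0).sum(axis=1)
    n_conn = (A >= edge_threshold).sum(axis=1)
    table = pd.DataFrame(
        {
            "module": modules.loc[genes].to_numpy(),
            "k_positive": k_pos,
            "k_negative": k_neg,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    scaled_pos = np.zeros(len(genes))
    scaled_neg = np.zeros(len(genes))
    for mod, grp in table.groupby("module"):
        loc = table.index.get_indexer(grp.index)
        for col, out in (("k_positive", scaled_pos), ("k_negative", scaled_neg)):
            mx = grp[col].max()
            out[loc] = grp[col].to_numpy() / mx if mx > 0 else 0.0
    table["scaled_k_positive"] = scaled_pos
    table["scaled_k_negative"] = scaled_neg
    table["connected_nodes"] = n_conn
    table["is_hub"] = (
        (np.maximum(scaled_pos, scaled_neg) > hub_scaled_k)
        & (n_conn > hub_min_nodes)
        & (table["module"] != BACKGROUND)
    )
    return table


@dataclass
class _NetworkParams:
    beta: object = "auto"
    beta_candidates: tuple = tuple(range(1, 7))
    r2_target: float = 0.8
    n_bins: int = 10
    adjacency_dialect: str = "r2"
    cut_height: float = 0.94
    min_module_size: int = 30
    edge_threshold: float = 0.02
    hub_scaled_k: float = 0.9
    hub_min_nodes: int = 10


class CoexpressionNetwork(ClusterMixin, BaseEstimator):
    """End-to-end weighted co-expression network estimator.

    ``fit(X)`` takes samples × genes data (a DataFrame's columns provide
    gene ids) and computes, in order: Pearson correlation, the scale-free-
    selected soft threshold (unless ``beta`` is fixed), the power
    adjacency, TOM and its average-linkage dendrogram, the static-cut
    module assignment, and the signed scaled-connectivity hub table.

    Fitted attributes: ``beta_``, ``scale_free_``, ``correlation_``,
    ``adjacency_``, ``connectivity_``, ``tom_``, ``linkage_``,
    ``modules_``, ``labels_`` (integer codes, −1 for background),
    ``hub_table_``.
    """

    def __init__(
        self,
        beta="auto",
        beta_candidates=tuple(range(1, 7)),
        r2_target: float = 0.8,
        n_bins: int = 10,
        adjacency_dialect: str = "r2",
        cut_height: float = 0.94,
        min_module_size: int = 30,
        edge_threshold: float = 0.02,
        hub_scaled_k: float = 0.9,
        hub_min_nodes: int = 10,
    ):
        self.beta = beta
        self.beta_candidates = beta_candidates
        self.r2_target = r2_target
        self.n_bins = n_bins
        self.adjacency_dialect = adjacency_dialect
        self.cut_height = cut_height
        self.min_module_size = min_module_size
        self.edge_threshold = edge_threshold
        self.hub_scaled_k = hub_scaled_k
        self.hub_min_nodes = hub_min_nodes

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            genes = [str(c) for c in X.columns]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2:
                raise ValueError("X must be 2-dimensional (samples × genes)")
            genes = [f"g{i}" for i in range(values.shape[1])]
        matrix = pd.DataFrame(values.T, index=genes)  # genes × samples
        if self.beta == "auto":
            self.scale_free_ = pick_soft_threshold(
                matrix,
                beta_candidates=self.beta_candidates,
                r2_target=self.r2_target,
                n_bins=self.n_bins,
                dialect=self.adjacency_dialect,
            )
            self.beta_ = self.scale_free_.chosen_beta
        else:
            self.beta_ = float(self.beta)
            self.scale_free_ = None
        self.correlation_, self.adjacency_ = pearson_adjacency(
            matrix, self.beta_, dialect=self.adjacency_dialect
        )
        self.connectivity_ = connectivity(self.adjacency_)
        self.tom_ = tom(self.adjacency_)
        self.modules_, self.linkage_ = detect_modules(
            self.tom_, cut_height=self.cut_height, min_module_size=self.min_module_size
        )
        self.hub_table_ = signed_scaled_connectivity(
            self.adjacency_,
            self.correlation_,
            self.modules_,
            edge_threshold=self.edge_threshold,
            hub_scaled_k=self.hub_scaled_k,
            hub_min_nodes=self.hub_min_nodes,
        )
        colors = [m for m in self.modules_.unique() if m != BACKGROUND]
        code = {m: i for i, m in enumerate(colors)}
        code[BACKGROUND] = -1
        self.labels_ = np.array([code[m] for m in self.modules_])
        self.n_features_in_ = len(genes)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    @property
    def module_sizes_(self) -> pd.Series:
        check_is_fitted(self, "modules_")
        sizes = self.modules_[self.modules_ != BACKGROUND].value_counts()
        return sizes

    def edge_list(self, min_adjacency: float | None = None) -> pd.DataFrame:
        """Weighted undirected edge list (each unordered pair once)."""
        check_is_fitted(self, "adjacency_")
        thr = self.edge_threshold if min_adjacency is None else min_adjacency
        a = self.adjacency_.to_numpy()
        r = self.correlation_.to_numpy()
        genes = list(self.adjacency_.index)
        iu = np.triu_indices(len(genes), k=1)
        keep = a[iu] >= thr
        return pd.DataFrame(
            {
                "gene_a": np.asarray(genes)[iu[0][keep]],
                "gene_b": np.asarray(genes)[iu[1][keep]],
                "adjacency": a[iu][keep],
                "sign": np.where(r[iu][keep] >= 0, "positive", "negative"),
            }
        )
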