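"""Normalization of raw intensities into the log2 expression matrix.

The chain mirrors standard single-channel microarray processing:
quantile normalization across arrays, Tukey median-polish summarization of
probe blocks into one value per gene, and a log2 transform. Background
correction is deliberately a no-op: inputs are assumed background-free.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "quantile_normalize",
    "QuantileNormalizer",
    "median_polish",
    "median_polish_summarize",
    "log2_transform",
]


def _qn_column(col: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map one column onto the reference distribution, averaging the
    reference over tied rank spans."""
    order = np.argsort(col, kind="mergesort")
    out = np.empty_like(reference)
    sorted_col = col[order]
    # tie groups in the sorted column share the mean reference value
    boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
    start = 0
    for stop in [*boundaries, len(col)]:
        out[order[start:stop]] = reference[start:stop].mean()
        start = stop
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column (sample) to the common reference distribution.

    The reference is the across-column mean of the column-sorted values;
    the value at rank r in each column becomes the reference value at rank
    r, with ties averaged over their rank span.
    """
    if matrix.isna().any().any():
        raise ValueError("missing values are not allowed (no imputation)")
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.column_stack(
        [_qn_column(values[:, j], reference) for j in range(values.shape[1])]
    )
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style quantile normalizer over rows of X (samples × genes).

    ``fit`` learns the reference distribution (rank-wise mean of the
    row-sorted training samples); ``transform`` maps each sample's values
    onto it. ``fit_transform`` on the full study is equivalent to
    :func:`quantile_normalize` on its transpose.
    """

    def fit(self, X, y=None):
        X = self._validate(X)
        self.reference_distribution_ = np.sort(X, axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_distribution_")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        return np.vstack([_qn_column(row, self.reference_distribution_) for row in X])

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if np.isnan(X).any():
            raise ValueError("missing values are not allowed (no imputation)")
        return X


def median_polish(
    block: np.ndarray, tol: float = 1e-6, max_iter: int = 10
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Tukey median polish of a probes × samples block.

    Alternating row/column median sweeps until the residual matrix changes
    by less than ``tol`` (max absolute change) or ``max_iter`` sweeps.
    Returns ``(overall, row_effects, col_effects, residuals, converged)``.
    """
    z = np.asarray(block, dtype=float).copy()
    if z.ndim != 2 or z.size == 0:
        raise ValueError("median polish needs a non-empty 2-D block")
    overall = 0.0
    row = np.zeros(z.shape[0])
    col = np.zeros(z.shape[1])
    converged = False
    for _ in range(max_iter):
        previous = z.copy()
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        delta = np.median(col)
        col -= delta
        overall += delta
        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        delta = np.median(row)
        row -= delta
        overall += delta
        if np.max(np.abs(z - previous)) < tol:
            converged = True
            break
    return overall, row, col, z, converged


def median_polish_summarize(
    probe_matrix: pd.DataFrame,
    probe_to_gene: dict[str, str],
    tol: float = 1e-6,
    max_iter: int = 10,
) -> pd.DataFrame:
    """Summarize probes into one expression value per gene and sample.

    For each gene the probes × samples block is median-polished and the
    per-sample summary is ``overall + column effect`` — invariant to
    per-probe additive offsets, which are absorbed by the row effects.
    Gene order follows first appearance of each gene among the probe rows.
    """
    unmapped = [p for p in probe_matrix.index if p not in probe_to_gene]
    if unmapped:
        raise ValueError(f"probes without a gene mapping: {unmapped[:5]}")
    genes: list[str] = []
    for p in probe_matrix.index:
        g = probe_to_gene[p]
        if g not in genes:
            genes.append(g)
    summaries = []
    for g in genes:
        probes = [p for p in probe_matrix.index if probe_to_gene[p] == g]
        if not probes:  # unreachable through the public path; defensive
            raise ValueError(f"gene {g} has no probe rows")
        block = probe_matrix.loc[probes].to_numpy(dtype=float)
        overall, _, colfx, _, _ = median_polish(block, tol=tol, max_iter=max_iter)
        summaries.append(overall + colfx)
    return pd.DataFrame(np.array(summaries), index=genes, columns=probe_matrix.columns)


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise base-2 logarithm; rejects non-positive entries by name."""
    values = matrix.to_numpy(dtype=float)
    bad = np.argwhere(~(values > 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive value {values[i, j]!r} at gene "
            f"{matrix.index[i]!r}, sample {matrix.columns[j]!r}"
        )
    return pd.DataFrame(np.log2(values), index=matrix.index, columns=matrix.columns)
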