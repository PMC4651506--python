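"""Soft temporal clustering of DEG profiles by fuzzy c-means.

Replicates are averaged within stage, each gene's stage profile is
standardized to mean 0 / sd 1, and the standardized profiles are
partitioned softly: every gene receives a membership in (0, 1] for each of
c clusters, updated alternately with the cluster centroids to minimize the
fuzzy objective J = Σ_i Σ_k u_ik^m d_ik². The fuzzifier m (> 1) controls
softness: m → 1 recovers hard k-means, large m pushes memberships toward
uniform.

Because neither c nor m is known a priori, :func:`select_parameters`
estimates them from the data: m from the randomized-data criterion
(smallest fuzzifier at which structure-destroyed data yields near-uniform
memberships while the real data stays concentrated) and c from the
minimum-centroid-distance elbow (the largest c before the smallest
pairwise centroid distance collapses, i.e. before centroids start
splitting real clusters).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import kmeans_plusplus
from sklearn.utils.validation import check_is_fitted, check_random_state

from .data import ExpressionMatrix

__all__ = [
    "standardize_profiles",
    "FuzzyCMeans",
    "fcm_cluster",
    "select_parameters",
]


def standardize_profiles(
    expr: ExpressionMatrix, genes=None, ddof: int = 0
) -> pd.DataFrame:
    """Stage-mean profiles standardized per gene to mean 0 / sd 1.

    Constant profiles (zero sd) cannot be standardized and are dropped
    with a warning rather than producing NaNs.
    """
    means = expr.stage_means()
    if genes is not None:
        means = means.loc[list(genes)]
    values = means.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=ddof)
    constant = sd == 0
    if constant.any():
        dropped = list(means.index[constant])
        warnings.warn(
            f"dropping {len(dropped)} constant profile(s): {dropped[:5]}",
            stacklevel=2,
        )
        means = means.loc[~constant]
        values = values[~constant]
        sd = sd[~constant]
    out = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(out, index=means.index, columns=means.columns)


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means with Euclidean distance.

    Parameters
    ----------
    n_clusters : number of clusters c (≥ 1).
    m : fuzzifier, strictly > 1.
    tol : convergence threshold on the max absolute centroid change.
    max_iter : iteration cap per restart.
    n_init : number of k-means++-seeded restarts; the solution with the
        lowest final objective is kept.
    random_state : seed for centroid initialization.

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : (c, n_features) centroid matrix.
    membership_ : (n_samples, c) membership matrix; rows sum to 1.
    labels_ : hard assignment by argmax membership (ties → lowest index).
    objective_ : final value of J.
    objective_path_ : J per iteration of the winning restart
        (non-increasing).
    n_iter_ : iterations used by the winning restart.
    """

    def __init__(
        self,
        n_clusters: int = 8,
        m: float = 1.25,
        tol: float = 1e-6,
        max_iter: int = 300,
        n_init: int = 3,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _memberships(self, d2: np.ndarray) -> np.ndarray:
        """Membership update from squared distances, in log space for
        numerical stability at small m; zero-distance rows become one-hot
        on the nearest centroid (lowest index on ties)."""
        expo = 1.0 / (self.m - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logw = -expo * np.log(d2)
            logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        u = w / w.sum(axis=1, keepdims=True)
        zero_rows = np.flatnonzero((d2 <= 1e-300).any(axis=1))
        for i in zero_rows:
            u[i] = 0.0
            u[i, int(np.argmin(d2[i]))] = 1.0
        return u

    def _single_fit(self, X: np.ndarray, rng) -> dict:
        c = self.n_clusters
        if c == 1:
            centers = X.mean(axis=0, keepdims=True)
            u = np.ones((X.shape[0], 1))
            d2 = cdist(X, centers, "sqeuclidean")
            j = float((u**self.m * d2).sum())
            return dict(centers=centers, u=u, path=[j], n_iter=0)
        seed = int(rng.integers(0, 2**31 - 1))
        centers, _ = kmeans_plusplus(X, n_clusters=c, random_state=seed)
        path: list[float] = []
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            d2 = cdist(X, centers, "sqeuclidean")
            u = self._memberships(d2)
            path.append(float((u**self.m * d2).sum()))
            um = u**self.m
            new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
            shift = float(np.max(np.abs(new_centers - centers)))
            centers = new_centers
            if shift < self.tol:
                break
        d2 = cdist(X, centers, "sqeuclidean")
        u = self._memberships(d2)
        path.append(float((u**self.m * d2).sum()))
        return dict(centers=centers, u=u, path=path, n_iter=n_iter)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        X = self._validate(X)
        rng = np.random.default_rng(
            check_random_state(self.random_state).randint(2**31 - 1)
        )
        best = None
        for _ in range(max(1, self.n_init)):
            res = self._single_fit(X, rng)
            if best is None or res["path"][-1] < best["path"][-1]:
                best = res
        self.cluster_centers_ = best["centers"]
        self.membership_ = best["u"]
        self.labels_ = np.argmax(best["u"], axis=1)
        self.objective_ = best["path"][-1]
        self.objective_path_ = np.asarray(best["path"])
        self.n_iter_ = best["n_iter"]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = self._validate(X)
        d2 = cdist(X, self.cluster_centers_, "sqeuclidean")
        return np.argmax(self._memberships(d2), axis=1)

    def _validate(self, X) -> np.ndarray:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.m <= 1.0:
            raise ValueError("fuzzifier m must be > 1")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if np.isnan(X).any():
            raise ValueError("X contains missing values")
        if X.shape[0] < self.n_clusters:
            raise ValueError(
                f"cannot fit {self.n_clusters} clusters to {X.shape[0]} profiles"
            )
        return X


def fcm_cluster(
    profiles: pd.DataFrame,
    c: int,
    m: float,
    seed=None,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_init: int = 3,
) -> FuzzyCMeans:
    """Fit fuzzy c-means on a genes × stages profile table."""
    est = FuzzyCMeans(
        n_clusters=c, m=m, tol=tol, max_iter=max_iter, n_init=n_init, random_state=seed
    )
    return est.fit(profiles.to_numpy(dtype=float))


def _min_centroid_distance(centers: np.ndarray) -> float:
    d = cdist(centers, centers)
    iu = np.triu_indices_from(d, k=1)
    return float(d[iu].min()) if iu[0].size else np.inf


def select_parameters(
    profiles: pd.DataFrame,
    c_range=range(2, 16),
    m_candidates=(1.05, 1.15, 1.25, 1.5, 2.0, 2.5),
    seed: int = 0,
    uniform_margin: float = 0.1,
    collapse_frac: float = 0.1,
    n_init: int = 3,
) -> tuple[int, float, dict]:
    """Data-driven choice of (c, m) for fuzzy c-means.

    m: each candidate is evaluated on a structure-destroyed copy of the
    data (every stage column permuted independently); the selected m is
    the smallest at which the randomized control's mean maximal membership
    falls within ``uniform_margin`` of the uniform value 1/c — below that
    fuzzifier, FCM still reports confident (spurious) clusters on data
    with no structure. If no candidate reaches near-uniformity the one
    closest to it is used. Real-data concentrations are recorded in the
    diagnostics for inspection.

    c: for each candidate c the minimum pairwise centroid distance D(c) is
    recorded; past the true cluster count, extra centroids split existing
    clusters and D collapses. The selected c is the largest candidate
    before D first drops below ``collapse_frac`` times the maximum D over
    the candidate range (the whole range if D never collapses).

    Returns ``(c, m, diagnostics)`` with both curves in ``diagnostics``.
    """
    X = profiles.to_numpy(dtype=float)
    c_list = sorted(set(int(c) for c in c_range))
    if not c_list or not len(m_candidates):
        raise ValueError("c_range and m_candidates must be non-empty")
    if c_list[0] < 2 or c_list[-1] > X.shape[0] - 1:
        raise ValueError("c_range must lie within [2, n_profiles - 1]")
    rng = np.random.default_rng(seed)
    perm = np.column_stack(
        [X[rng.permutation(X.shape[0]), j] for j in range(X.shape[1])]
    )
    c_ref = int(np.clip(int(np.median(c_list)), 2, X.shape[0] - 1))

    m_diag = []
    chosen_m = None
    for m in sorted(m_candidates):
        seeds = rng.integers(0, 2**31 - 1, size=2)
        u_rand = (
            FuzzyCMeans(c_ref, m, n_init=n_init, random_state=int(seeds[0]))
            .fit(perm)
            .membership_.max(axis=1)
            .mean()
        )
        u_real = (
            FuzzyCMeans(c_ref, m, n_init=n_init, random_state=int(seeds[1]))
            .fit(X)
            .membership_.max(axis=1)
            .mean()
        )
        m_diag.append((m, float(u_rand), float(u_real)))
        if chosen_m is None and u_rand <= 1.0 / c_ref + uniform_margin:
            chosen_m = m
    if chosen_m is None:
        chosen_m = min(m_diag, key=lambda t: t[1])[0]
        warnings.warn(
            "no fuzzifier reached near-uniform memberships on randomized "
            f"data; falling back to m={chosen_m}",
            stacklevel=2,
        )

    dists = {}
    for c in c_list:
        fit = FuzzyCMeans(
            c, chosen_m, n_init=n_init, random_state=int(rng.integers(0, 2**31 - 1))
        ).fit(X)
        dists[c] = _min_centroid_distance(fit.cluster_centers_)
    threshold = collapse_frac * max(dists.values())
    chosen_c = c_list[0]
    for c in c_list:
        if dists[c] < threshold:
            break
        chosen_c = c
    diagnostics = {
        "m_curve": m_diag,
        "min_centroid_distance": dists,
        "c_ref": c_ref,
    }
    return chosen_c, float(chosen_m), diagnostics
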