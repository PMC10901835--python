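"""Kinetic co-expression clustering.

Fold-change profiles of features DE at >= 1 timepoint are z-scored per row
and grouped by fuzzy c-means (Euclidean distance, fuzzifier from the
Schwammle-Jensen estimate), following the soft-clustering convention for
expression time courses. Core members are features whose maximum membership
clears a threshold. Average-linkage hierarchical clustering on 1 - Pearson
distance is provided for profile heatmap ordering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted, check_random_state

logger = logging.getLogger(__name__)


class ClusterError(ValueError):
    pass


def build_profiles(de_tables: dict[float, pd.DataFrame]) -> pd.DataFrame:
    """Fold-change profile matrix of features DE at >= 1 timepoint.

    Columns are the timepoint grid including 0 h as an exact-zero anchor
    column; rows are features whose DE call (direction != ns) fires in at
    least one contrast.
    """
    tps = sorted(de_tables)
    any_de = None
    for tp in tps:
        de = de_tables[tp]["direction"] != "ns"
        any_de = de if any_de is None else (any_de | de)
    keep = any_de[any_de].index
    if keep.empty:
        logger.warning("no feature passes the DE filter; profile matrix is empty")
        return pd.DataFrame(columns=[0.0] + tps)
    prof = pd.DataFrame({0.0: 0.0}, index=keep)
    for tp in tps:
        prof[tp] = de_tables[tp]["log2fc"].reindex(keep)
    return prof


def standardize(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-scoring; rows with zero SD (flat profiles) are dropped."""
    if profiles.shape[1] < 2:
        raise ClusterError("standardization needs >= 2 timepoints")
    vals = profiles.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    if flat.any():
        logger.info("dropping %d flat profile(s) before clustering", int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    return pd.DataFrame(z[~flat], index=profiles.index[~flat], columns=profiles.columns)


def estimate_fuzzifier(n_features: int, n_timepoints: int) -> float:
    """Schwammle-Jensen fuzzifier estimate, clipped to [1.05, 3].

    m = 1 + (1418/N + 22.05) D^-2
        + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)
    """
    N, D = float(n_features), float(n_timepoints)
    if N < 1 or D < 1:
        raise ClusterError("n_features and n_timepoints must be >= 1")
    m = 1.0 + (1418.0 / N + 22.05) * D ** -2.0 \
        + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134)
    return float(np.clip(m, 1.05, 3.0))


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering (Bezdek alternating optimization).

    Parameters
    ----------
    n_clusters : number of clusters c (default 12, the time-course
        convention used here for a six-point grid).
    m : fuzzifier > 1; ``None`` applies the Schwammle-Jensen estimate from
        the data dimensions at fit time.
    tol : convergence threshold on max |delta u| between sweeps.
    max_iter : sweep cap.
    n_init : independent seeded restarts; the run with the lowest final
        objective is kept (guards against merged-cluster local optima).
    random_state : seeds the k-means++-style centroid initialization.

    Attributes
    ----------
    cluster_centers_ : (n_clusters, n_features) centroid matrix.
    membership_ : (n_samples, n_clusters) membership matrix u; rows sum to 1.
    objective_trace_ : J = sum u^m d^2 per sweep (non-increasing).
    fuzzifier_ : the fuzzifier actually used.
    labels_ : argmax membership per sample.
    n_iter_ : sweeps run.
    """

    def __init__(self, n_clusters: int = 12, m: float | None = None,
                 tol: float = 1e-6, max_iter: int = 1000, n_init: int = 5,
                 random_state=None):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def _init_centers(self, X: np.ndarray, rng) -> np.ndarray:
        """k-means++-style draw of initial centroids from the data rows."""
        n = X.shape[0]
        centers = [X[rng.randint(n)]]
        for _ in range(1, self.n_clusters):
            d2 = np.min(cdist(X, np.asarray(centers), "sqeuclidean"), axis=1)
            total = d2.sum()
            if total <= 0:
                centers.append(X[rng.randint(n)])
                continue
            centers.append(X[rng.choice(n, p=d2 / total)])
        return np.asarray(centers)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, d = X.shape
        if n < self.n_clusters:
            raise ClusterError(f"need >= {self.n_clusters} samples, got {n}")
        rng = check_random_state(self.random_state)
        m = self.m if self.m is not None else estimate_fuzzifier(n, d)
        if m <= 1:
            raise ClusterError("fuzzifier m must be > 1")

        best = None
        for _ in range(max(1, self.n_init)):
            centers = self._init_centers(X, rng)
            u = self._memberships(X, centers, m)
            trace = []
            for it in range(1, self.max_iter + 1):
                w = u ** m
                centers = (w.T @ X) / w.sum(axis=0)[:, None]
                u_new = self._memberships(X, centers, m)
                d2 = cdist(X, centers, "sqeuclidean")
                trace.append(float(np.sum((u_new ** m) * d2)))
                delta = np.max(np.abs(u_new - u))
                u = u_new
                if delta < self.tol:
                    break
            if best is None or trace[-1] < best[0]:
                best = (trace[-1], centers, u, trace, it)

        _, centers, u, trace, it = best
        self.cluster_centers_ = centers
        self.membership_ = u
        self.objective_trace_ = np.asarray(trace)
        self.fuzzifier_ = float(m)
        self.labels_ = np.argmax(u, axis=1)
        self.n_iter_ = it
        self.n_features_in_ = d
        return self

    @staticmethod
    def _memberships(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
        d2 = cdist(X, centers, "sqeuclidean")
        zero = d2 <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
            u = inv / inv.sum(axis=1, keepdims=True)
        hit = zero.any(axis=1)
        if hit.any():
            # coincident with a centroid: full membership there (singularity rule)
            u[hit] = 0.0
            u[hit, np.argmax(zero[hit], axis=1)] = 1.0
        return u

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        u = self._memberships(np.asarray(X, dtype=float), self.cluster_centers_, self.fuzzifier_)
        return np.argmax(u, axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def transform(self, X):
        """Membership matrix of new data against the fitted centroids."""
        check_is_fitted(self, "cluster_centers_")
        return self._memberships(np.asarray(X, dtype=float), self.cluster_centers_, self.fuzzifier_)


def fuzzy_cmeans(profiles: pd.DataFrame, c: int = 12, m: float | None = None,
                 seed: int | None = 0, tol: float = 1e-6,
                 max_iter: int = 1000) -> FuzzyCMeans:
    """Fit :class:`FuzzyCMeans` on a standardized profile matrix."""
    model = FuzzyCMeans(n_clusters=c, m=m, tol=tol, max_iter=max_iter, random_state=seed)
    return model.fit(profiles.to_numpy(dtype=float))


def core_members(model: FuzzyCMeans, feature_ids, threshold: float = 0.5) -> pd.DataFrame:
    """Hard assignments: argmax cluster, max membership, core flag.

    A feature is core iff its maximum membership is >= threshold AND the
    argmax is unique (exact ties break "not core").
    """
    u = model.membership_
    top = np.argmax(u, axis=1)
    top_val = u[np.arange(len(u)), top]
    n_at_max = np.sum(u == top_val[:, None], axis=1)
    core = (top_val >= threshold) & (n_at_max == 1)
    return pd.DataFrame({
        "cluster": top,
        "membership": top_val,
        "core": core,
    }, index=pd.Index(feature_ids, name="feature_id"))


def cluster_counts(assign: pd.DataFrame, n_clusters: int) -> pd.Series:
    """Core-member count per cluster."""
    counts = assign.loc[assign["core"], "cluster"].value_counts()
    return counts.reindex(range(n_clusters), fill_value=0).sort_index()


def hcluster_profiles(profiles: pd.DataFrame, n_clusters: int = 2):
    """Average-linkage (UPGMA) hierarchical clustering on 1 - Pearson distance.

    Constant rows (undefined correlation) are dropped with a log entry.
    Returns (linkage_matrix, flat_labels Series, kept_index).
    """
    vals = profiles.to_numpy(dtype=float)
    if vals.shape[0] < 2:
        raise ClusterError("need >= 2 profiles to cluster")
    sd = vals.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        logger.info("dropping %d constant profile(s) from hierarchical clustering",
                    int((~keep).sum()))
    vals = vals[keep]
    if vals.shape[0] < 2:
        raise ClusterError("fewer than 2 non-constant profiles")
    corr = np.corrcoef(vals)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    index = profiles.index[keep]
    return Z, pd.Series(labels, index=index, name="cluster"), index
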