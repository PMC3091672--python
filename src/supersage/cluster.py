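"""Expression-pattern clustering of differentially expressed tags.

Profiles are per-tag count vectors over an analysis-specific library
subset, normalised so the values sum to 100 (each value is the share of
the tag's counts falling in that library).  K-means is run under a
chi-square divergence suited to count profiles: the distance of a tag
with count vector x (total n) to a centroid with profile shape m (a
distribution over libraries) is the Pearson chi-square statistic of x
against the expected counts n*m.  The number of clusters is selected by
the Gap statistic, comparing the within-cluster dispersion of the data
against reference datasets drawn uniformly over the per-feature range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .diffexpr import DifferentialExpressionRecord
from .matrix import TagCountMatrix

#: Library roles entering each of the two clustering analyses.
ANALYSIS_LIBRARIES = {
    "LowCa": ["C2h", "LowCa2h", "C12h", "LowCa12h"],
    "12h": ["C12h", "LowCa12h", "HighCa12h"],
}

_EPS = 1e-10


def normalize(counts) -> np.ndarray:
    """Row-normalise count vectors to percent shares (each row sums to 100)."""
    X = np.atleast_2d(np.asarray(counts, float))
    if (X < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = X.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero profile cannot be normalised")
    return 100.0 * X / totals[:, None]


def select_tags(
    records: Iterable[DifferentialExpressionRecord],
    matrix: TagCountMatrix,
    analysis: str,
    role_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Inclusion filter for one clustering analysis.

    The LowCa analysis keeps retained tags except those significant only
    for the high-calcium challenge (class set {3}) and those with zero
    counts across all control and LowCa libraries; the 12 h analysis
    keeps retained tags with a nonzero count in at least one 12 h
    library.  Returns the count sub-matrix (tags x analysis libraries).
    """
    if analysis not in ANALYSIS_LIBRARIES:
        raise ValueError(f"unknown analysis {analysis!r}")
    role_map = dict(role_map) if role_map else None
    cols = [
        role_map[r] if role_map else r for r in ANALYSIS_LIBRARIES[analysis]
    ]
    keep = []
    for rec in records:
        if not rec.retained:
            continue
        if analysis == "LowCa" and rec.de_class == {3}:
            continue
        keep.append(rec.tag)
    sub = matrix.counts.loc[[t for t in keep if t in matrix.counts.index], cols]
    sub = sub[sub.sum(axis=1) > 0]
    return sub


class TransChisqKMeans(ClusterMixin, BaseEstimator):
    """K-means under a chi-square count-profile divergence.

    Parameters
    ----------
    n_clusters : int
        Number of clusters K.
    metric : {"chisq", "euclidean"}
        "chisq" measures each tag's count vector against the expected
        counts under the centroid's profile shape; "euclidean" is the
        ordinary distance on percent-normalised profiles.
    n_restarts : int
        Independent seeded initialisations; the run with the lowest
        within-cluster dispersion wins.
    max_iter : int
        Iteration cap per run.
    random_state : int or None
        Seed for initialisation.

    Attributes
    ----------
    labels_ : (n,) cluster assignment in 0..K-1
    cluster_centers_ : (K, L) centroid profiles on the percent scale
    inertia_ : total within-cluster dispersion of the best run
    """

    def __init__(
        self,
        n_clusters: int = 6,
        metric: str = "chisq",
        n_restarts: int = 20,
        max_iter: int = 100,
        random_state: int | None = None,
    ) -> None:
        self.n_clusters = n_clusters
        self.metric = metric
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internals -------------------------------------------------------
    def _distances(self, X: np.ndarray, totals: np.ndarray, centers: np.ndarray):
        """(n, K) divergence of each count vector from each centroid."""
        P = X / totals[:, None]
        return self._distances_fast(P, totals, centers, P * P)

    def _distances_fast(self, P, totals, centers, P2):
        M = centers / centers.sum(axis=1, keepdims=True)  # profile shapes
        M = np.clip(M, _EPS, None)
        M = M / M.sum(axis=1, keepdims=True)
        if self.metric == "chisq":
            # n * sum_j (p_j - m_j)^2 / m_j == n * (sum_j p_j^2 / m_j - 1)
            # since rows of P and M each sum to one
            d = P2 @ (1.0 / M).T - 1.0
            return totals[:, None] * np.maximum(d, 0.0)
        if self.metric == "euclidean":
            Q = 100.0 * P
            C = 100.0 * M
            d = (
                (Q * Q).sum(axis=1)[:, None]
                - 2.0 * Q @ C.T
                + (C * C).sum(axis=1)[None, :]
            )
            return np.maximum(d, 0.0)
        raise ValueError(f"unknown metric {self.metric!r}")

    def _single_run(self, X, totals, P, P2, uniq, rng):
        n = X.shape[0]
        K = self.n_clusters
        # init: K distinct profiles, sampled without replacement
        if len(uniq) >= K:
            pick = rng.choice(len(uniq), size=K, replace=False)
            centers = uniq[pick]
        else:
            pick = rng.choice(n, size=K, replace=False)
            centers = P[pick]
        labels = np.full(n, -1)
        for it in range(self.max_iter):
            d = self._distances_fast(P, totals, centers, P2)
            new_labels = d.argmin(axis=1)
            # re-seed empty clusters with the farthest points
            present = np.bincount(new_labels, minlength=K) > 0
            if not present.all():
                for k in np.where(~present)[0]:
                    far = d[np.arange(n), new_labels].argmax()
                    new_labels[far] = k
                    # exclude this point from further re-seeding picks
                    d[far, :] = -np.inf
            if (new_labels == labels).all():
                break
            labels = new_labels
            sums = np.zeros((K, P.shape[1]))
            np.add.at(sums, labels, P)
            sizes = np.bincount(labels, minlength=K).astype(float)
            centers = sums / sizes[:, None]
        d = self._distances_fast(P, totals, centers, P2)
        inertia = float(d[np.arange(n), labels].sum())
        return labels, centers, inertia, it + 1

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (tags x libraries)")
        if (X < 0).any():
            raise ValueError("counts must be nonnegative")
        n = X.shape[0]
        if not (1 <= self.n_clusters <= n):
            raise ValueError(f"n_clusters must be in [1, {n}]")
        totals = X.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("all-zero rows are not clusterable")
        P = X / totals[:, None]  # profile shapes, rows sum to one
        P2 = P * P
        uniq = np.unique(np.round(P, 9), axis=0)

        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_restarts)):
            labels, centers, inertia, n_iter = self._single_run(
                X, totals, P, P2, uniq, rng
            )
            if best is None or inertia < best[2] - 1e-12:
                best = (labels, centers, inertia, n_iter)
        labels, centers, inertia, n_iter = best
        self.labels_ = labels
        self.cluster_centers_ = 100.0 * centers / centers.sum(axis=1, keepdims=True)
        self.inertia_ = inertia
        self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = np.asarray(X, float)
        totals = X.sum(axis=1)
        d = self._distances(X, totals, self.cluster_centers_)
        return d.argmin(axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class GapResult:
    ks: list[int]
    gap: list[float]
    s: list[float]
    log_wk_data: list[float]
    log_wk_ref: list[float]
    B: int
    selected_k: int


def gap_statistic(
    X,
    k_range: Sequence[int] = range(1, 11),
    B: int = 50,
    random_state: int | None = None,
    metric: str = "chisq",
    n_restarts: int = 10,
    ref_restarts: int = 3,
) -> GapResult:
    """Gap-statistic selection of the number of clusters.

    Gap(K) = E*[log W_K(reference)] - log W_K(data) with B reference
    datasets drawn uniformly over the per-feature range of the data
    (floored at a small positive value so chi-square divergences stay
    defined).  The selected K is the smallest with
    Gap(K) >= Gap(K+1) - s_{K+1}; degenerate data (zero dispersion at
    K = 1) selects 1.
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    X = np.asarray(X, float)
    ks = sorted(int(k) for k in k_range)
    rng = np.random.default_rng(random_state)

    def w_k(data, k, restarts, seed):
        model = TransChisqKMeans(
            n_clusters=k, metric=metric, n_restarts=restarts, random_state=seed
        )
        model.fit(data)
        return model.inertia_

    w_data = [w_k(X, k, n_restarts, int(rng.integers(2**31))) for k in ks]
    if w_data[0] <= _EPS:
        return GapResult(ks, [0.0] * len(ks), [0.0] * len(ks),
                         [-np.inf] * len(ks), [0.0] * len(ks), B, 1)

    lo = np.maximum(X.min(axis=0), 0.0)
    hi = X.max(axis=0)
    log_w_ref = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref = np.clip(ref, _EPS, None)
        for j, k in enumerate(ks):
            log_w_ref[b, j] = np.log(
                max(w_k(ref, k, ref_restarts, int(rng.integers(2**31))), _EPS)
            )

    log_w_data = np.log(np.maximum(w_data, _EPS))
    gap = log_w_ref.mean(axis=0) - log_w_data
    sd = log_w_ref.std(axis=0)
    s = sd * np.sqrt(1.0 + 1.0 / B)

    selected = ks[int(np.argmax(gap))]
    for j in range(len(ks) - 1):
        if gap[j] >= gap[j + 1] - s[j + 1]:
            selected = ks[j]
            break
    return GapResult(
        ks, list(gap), list(s), list(log_w_data), list(log_w_ref.mean(axis=0)),
        B, selected,
    )


def cross_tabulate(
    labels_a: Mapping[str, int], labels_b: Mapping[str, int]
) -> pd.DataFrame:
    """Shared-tag counts between the clusters of two analyses.

    Entry (i, j) counts tags in cluster i of analysis A and cluster j of
    analysis B (1-based); row/column 0 collects tags absent from that
    analysis.  Entries sum to the size of the union of the tag sets.
    """
    tags = set(labels_a) | set(labels_b)
    ka = max(labels_a.values(), default=0)
    kb = max(labels_b.values(), default=0)
    table = np.zeros((ka + 1, kb + 1), dtype=int)
    for t in tags:
        table[labels_a.get(t, 0), labels_b.get(t, 0)] += 1
    return pd.DataFrame(
        table,
        index=pd.Index(range(ka + 1), name="cluster_a"),
        columns=pd.Index(range(kb + 1), name="cluster_b"),
    )


def summarize_clusters(label_sets: Iterable[Sequence[int]]) -> dict:
    """Pooled cluster sizes over one or more fitted partitions.

    Returns the per-cluster sizes and their mean and standard deviation
    across all clusters of all supplied partitions.
    """
    sizes: list[int] = []
    for labels in label_sets:
        labels = np.asarray(labels)
        for k in np.unique(labels):
            sizes.append(int((labels == k).sum()))
    if not sizes:
        raise ValueError("no clusters to summarise")
    arr = np.array(sizes, float)
    return {
        "sizes": sizes,
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
    }
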