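"""Subpopulation discovery by KS-similarity consensus clustering.

Cell lines contribute unequal numbers of colonies with heterogeneous
morphologies, and the number of morphological subpopulations is unknown.
This module implements a modified consensus clustering over per-colony
fingerprints:

1. fix a candidate cluster count ``k``;
2. draw an equal number ``n_samples`` of colonies from every line (without
   replacement) and pool them;
3. k-means the pooled fingerprints into ``k`` clusters;
4. build each line's cluster-assignment distribution from its sampled
   colonies;
5. fill an L x L similarity matrix with pairwise two-sample
   Kolmogorov-Smirnov p-values between the lines' cluster-label samples;
6. repeat for ``n_iter`` iterations and average into a consensus matrix;
7. sweep ``k`` and pick the cluster count from the consensus-CDF
   concentration criterion (peak proportional increase of the area under
   the CDF of consensus entries).

The final partition is obtained by average-linkage hierarchical clustering
of ``1 - consensus`` cut at the selected ``k``.

Cluster labels are nominal, so applying a KS test to them requires an
ordering; labels are canonicalized per iteration by sorting clusters by
centroid norm (descending), which makes runs reproducible.  Defaults follow
the standard protocol: 100 iterations, 6 samples per line, ``k`` swept from
2 to 7.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import ks_2samp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

__all__ = [
    "ConsensusMatrix",
    "ConsensusCDF",
    "SubpopulationPartition",
    "ks_pvalue",
    "consensus_for_k",
    "select_k",
    "partition_lines",
    "ConsensusKSClustering",
]

#: iterations and per-line sample count of the standard protocol
DEFAULT_N_ITER = 100
DEFAULT_N_SAMPLES = 6
DEFAULT_K_RANGE = tuple(range(2, 8))
EXACT_KS_MAX_N = 12


def ks_pvalue(samples_a: Sequence[float], samples_b: Sequence[float]) -> float:
    """Two-sample Kolmogorov-Smirnov p-value.

    Exact (enumeration-based null of the D statistic) for samples of at most
    :data:`EXACT_KS_MAX_N` observations per side, asymptotic otherwise.
    Symmetric in its arguments.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_pvalue requires two non-empty samples")
    n, m = a.size, b.size
    if max(n, m) > EXACT_KS_MAX_N:
        return float(ks_2samp(a, b, method="asymp").pvalue)
    # integer ECDF deviation c = max_t |#{a <= t} * m - #{b <= t} * n|,
    # so D = c / (n * m); ties are handled by evaluating at pooled values
    ts = np.union1d(a, b)
    ca = np.searchsorted(np.sort(a), ts, side="right")
    cb = np.searchsorted(np.sort(b), ts, side="right")
    c = int(np.abs(ca * m - cb * n).max())
    return _ks_exact_tail(n, m, c)


@lru_cache(maxsize=4096)
def _ks_exact_tail(n: int, m: int, c: int) -> float:
    """Exact two-sample KS tail probability P(D >= c / (n * m)).

    Counts, by dynamic programming over the lattice of interleavings of the
    two samples, the paths whose maximal ECDF deviation stays strictly below
    ``c / (n * m)`` (deviation at vertex (i, j) is |i*m - j*n| / (n*m));
    all C(n + m, n) interleavings are equally likely under the continuous
    null.  Exact rational arithmetic via integer counts.
    """
    if c <= 0:
        return 1.0
    dp = np.zeros((n + 1, m + 1), dtype=object)
    dp[0, 0] = 1
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            if abs(i * m - j * n) >= c:
                dp[i, j] = 0
                continue
            dp[i, j] = (dp[i - 1, j] if i > 0 else 0) + (dp[i, j - 1] if j > 0 else 0)
    return float(1.0 - dp[n, m] / comb(n + m, n))


def _pairwise_ks_matrix(per_line_labels: np.ndarray, k: int) -> np.ndarray:
    """L x L matrix of pairwise exact KS p-values between lines' label samples.

    ``per_line_labels`` is (L, n) canonical cluster labels.  All lines have
    the same sample size n, so the exact null depends only on the integer
    deviation c = max_j |cumA_j * n - cumB_j * n|, which is cached.
    """
    L, n = per_line_labels.shape
    counts = np.zeros((L, k), dtype=int)
    for i in range(L):
        counts[i] = np.bincount(per_line_labels[i], minlength=k)
    cum = counts.cumsum(axis=1)  # (L, k), out of n
    # c_ij = max_t |cum_i[t] - cum_j[t]| * n  (common denominator n * n)
    dev = np.abs(cum[:, None, :] - cum[None, :, :]).max(axis=2) * n
    sim = np.eye(L)
    for i in range(L):
        for j in range(i + 1, L):
            p = _ks_exact_tail(n, n, int(dev[i, j]))
            sim[i, j] = sim[j, i] = p
    return sim


@dataclass(frozen=True)
class ConsensusMatrix:
    """L x L aggregate of per-iteration KS similarity matrices for one k."""

    k: int
    line_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.line_ids),) * 2:
            raise ValueError("consensus matrix shape does not match line_ids")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.line_ids), k=1)
        return self.matrix[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.line_ids, columns=self.line_ids)


def _canonical_labels(labels: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Relabel clusters so that cluster 0 has the largest centroid norm."""
    order = np.argsort(-np.linalg.norm(centers, axis=1), kind="stable")
    remap = np.empty(len(centers), dtype=int)
    remap[order] = np.arange(len(centers))
    return remap[labels]


def consensus_for_k(
    fingerprints_by_line: Mapping[str, np.ndarray],
    k: int,
    n_samples: int = DEFAULT_N_SAMPLES,
    n_iter: int = DEFAULT_N_ITER,
    seed=None,
    aggregation: str = "mean",
    sample_with_replacement: bool = False,
    standardize: bool = True,
    kmeans_restarts: int = 10,
) -> ConsensusMatrix:
    """Consensus matrix for a fixed cluster count ``k``.

    Each iteration samples ``n_samples`` colonies per line, pools and
    (optionally) standardizes them, k-means clusters the pool, canonicalizes
    the cluster labels, and records pairwise KS p-values between the lines'
    label samples.  The consensus is the element-wise mean (or median) over
    iterations, with unit diagonal.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if aggregation not in ("mean", "median"):
        raise ValueError("aggregation must be 'mean' or 'median'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    line_ids = tuple(fingerprints_by_line)
    L = len(line_ids)
    fps = [np.asarray(fingerprints_by_line[ln], dtype=float) for ln in line_ids]
    for ln, f in zip(line_ids, fps):
        if not sample_with_replacement and f.shape[0] < n_samples:
            raise ValueError(
                f"line {ln!r} has only {f.shape[0]} colonies but n_samples="
                f"{n_samples}; pass sample_with_replacement=True to resample "
                f"with replacement")
        if f.shape[0] < 1:
            raise ValueError(f"line {ln!r} has no fingerprints")

    stack = np.empty((n_iter, L, L))
    for it in range(n_iter):
        chosen = []
        for f in fps:
            idx = rng.choice(f.shape[0], size=n_samples,
                             replace=sample_with_replacement)
            chosen.append(f[idx])
        pool = np.vstack(chosen)
        if standardize:
            sd = pool.std(axis=0)
            sd[sd == 0] = 1.0
            pool = (pool - pool.mean(axis=0)) / sd
        km = KMeans(n_clusters=k, n_init=kmeans_restarts,
                    random_state=int(rng.integers(2 ** 31)))
        labels = _canonical_labels(km.fit_predict(pool), km.cluster_centers_)
        per_line = labels.reshape(L, n_samples)
        if n_samples <= EXACT_KS_MAX_N:
            sim = _pairwise_ks_matrix(per_line, k)
        else:
            sim = np.eye(L)
            for i in range(L):
                for j in range(i + 1, L):
                    p = ks_pvalue(per_line[i], per_line[j])
                    sim[i, j] = sim[j, i] = p
        stack[it] = sim
    agg = np.mean(stack, axis=0) if aggregation == "mean" else np.median(stack, axis=0)
    np.fill_diagonal(agg, 1.0)
    return ConsensusMatrix(k=k, line_ids=line_ids, matrix=agg)


def assignment_pdf(labels: Sequence[int], k: int) -> np.ndarray:
    """Per-cluster assignment fractions of one line's sampled colonies."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("no labels")
    counts = np.bincount(labels, minlength=k).astype(float)
    return counts / counts.sum()


@dataclass(frozen=True)
class ConsensusCDF:
    """Consensus-entry CDF summary per k: area A(k) and proportional increase."""

    table: pd.DataFrame  # columns: k, area, delta

    def areas(self) -> pd.Series:
        return self.table.set_index("k")["area"]


def _cdf_area(entries: np.ndarray) -> float:
    """Area under the empirical CDF of consensus entries on [0, 1].

    For entries bounded in [0, 1] this equals 1 - mean(entries).
    """
    return float(1.0 - np.mean(entries))


def select_k(
    consensus_by_k: Mapping[int, ConsensusMatrix],
    delta_threshold: float = 0.02,
) -> tuple[int | None, ConsensusCDF]:
    """Select the cluster count from the consensus-CDF concentration criterion.

    ``A(k)`` is the area under the empirical CDF of off-diagonal consensus
    entries; the proportional increase is ``delta(2) = A(2)`` and
    ``delta(k) = (A(k) - A(k-1)) / A(k-1)`` for k > 2.  The selected ``k*``
    is the argmax of delta over k >= 3 when that peak exceeds
    ``delta_threshold``; otherwise 2.  If the consensus distribution does not
    change at all across k, no cluster structure is detected and ``k*`` is
    returned as None with a warning.
    """
    ks = sorted(consensus_by_k)
    if len(ks) < 2:
        raise ValueError("select_k requires at least 2 candidate cluster counts")
    if ks[0] != 2 or ks != list(range(2, 2 + len(ks))):
        raise ValueError("candidate cluster counts must be consecutive starting at 2")
    areas = {k: _cdf_area(consensus_by_k[k].upper_triangle()) for k in ks}
    deltas = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        denom = areas[prev]
        deltas[k] = (areas[k] - areas[prev]) / denom if denom > 0 else np.inf
    table = pd.DataFrame({"k": ks,
                          "area": [areas[k] for k in ks],
                          "delta": [deltas[k] for k in ks]})
    cdf = ConsensusCDF(table=table)
    if np.ptp(table["area"].to_numpy()) < 1e-12:
        warnings.warn("consensus distribution identical across k: no cluster "
                      "structure detected", stacklevel=2)
        return None, cdf
    k3 = [k for k in ks if k >= 3]
    if k3:
        best = max(k3, key=lambda k: deltas[k])
        if deltas[best] > delta_threshold:
            return best, cdf
    return 2, cdf


@dataclass(frozen=True)
class SubpopulationPartition:
    """Assignment of cell lines to morphological clusters at the selected k."""

    k: int
    labels: dict[str, int]          # line_id -> cluster (0-based)
    order: tuple[str, ...]          # dendrogram leaf order for heat maps

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for ln, c in self.labels.items():
            out.setdefault(c, []).append(ln)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"line_id": list(self.labels),
                             "cluster": list(self.labels.values())})


def partition_lines(consensus: ConsensusMatrix, k: int) -> SubpopulationPartition:
    """Cut an average-linkage dendrogram of 1 - consensus at ``k`` clusters."""
    if k < 2:
        raise ValueError("k must be >= 2")
    d = 1.0 - consensus.matrix
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    leaves = dendrogram(Z, no_plot=True)["leaves"]
    order = tuple(consensus.line_ids[i] for i in leaves)
    # relabel clusters 0..k-1 by order of first appearance along the dendrogram
    remap: dict[int, int] = {}
    for i in leaves:
        remap.setdefault(raw[i], len(remap))
    labels = {ln: remap[raw[i]] for i, ln in enumerate(consensus.line_ids)}
    return SubpopulationPartition(k=int(raw.max()), labels=labels, order=order)


class ConsensusKSClustering(BaseEstimator, ClusterMixin):
    """Consensus clustering of cell lines from per-colony fingerprints.

    Parameters follow the standard protocol: ``n_iter=100`` iterations of
    ``n_samples=6`` colonies per line, k swept over 2..7, mean aggregation,
    and the concentration-criterion threshold ``delta_threshold=0.02``.

    ``fit(X, groups=...)`` takes a colony-by-feature matrix and the per-colony
    line ids.  Fitted attributes:

    - ``consensus_matrices_``: dict k -> :class:`ConsensusMatrix`
    - ``cdf_``: :class:`ConsensusCDF` table of A(k) and delta(k)
    - ``n_clusters_``: selected k (None if no structure was detected)
    - ``partition_``: :class:`SubpopulationPartition` at the selected k
    - ``labels_``: per-line cluster labels, ordered by ``line_ids_``
    """

    def __init__(self, k_range: Sequence[int] = DEFAULT_K_RANGE,
                 n_samples: int = DEFAULT_N_SAMPLES, n_iter: int = DEFAULT_N_ITER,
                 aggregation: str = "mean", delta_threshold: float = 0.02,
                 sample_with_replacement: bool = False, standardize: bool = True,
                 kmeans_restarts: int = 10, random_state: int | None = None):
        self.k_range = k_range
        self.n_samples = n_samples
        self.n_iter = n_iter
        self.aggregation = aggregation
        self.delta_threshold = delta_threshold
        self.sample_with_replacement = sample_with_replacement
        self.standardize = standardize
        self.kmeans_restarts = kmeans_restarts
        self.random_state = random_state

    def fit(self, X, y=None, groups: Sequence[str] | None = None) -> "ConsensusKSClustering":
        if groups is None:
            raise ValueError("ConsensusKSClustering.fit requires groups= (per-colony line ids)")
        X = np.asarray(X, dtype=float)
        groups = np.asarray(groups)
        if X.shape[0] != groups.shape[0]:
            raise ValueError("X and groups must have one entry per colony")
        line_ids = list(dict.fromkeys(groups))  # keep first-seen order
        by_line = {ln: X[groups == ln] for ln in line_ids}
        rng = np.random.default_rng(self.random_state)
        self.consensus_matrices_ = {}
        for k in sorted(self.k_range):
            self.consensus_matrices_[k] = consensus_for_k(
                by_line, k, n_samples=self.n_samples, n_iter=self.n_iter,
                seed=rng, aggregation=self.aggregation,
                sample_with_replacement=self.sample_with_replacement,
                standardize=self.standardize, kmeans_restarts=self.kmeans_restarts)
        k_star, self.cdf_ = select_k(self.consensus_matrices_,
                                     delta_threshold=self.delta_threshold)
        self.n_clusters_ = k_star
        self.line_ids_ = tuple(line_ids)
        if k_star is not None:
            self.partition_ = partition_lines(self.consensus_matrices_[k_star], k_star)
            self.labels_ = np.array([self.partition_.labels[ln] for ln in line_ids])
        else:
            self.partition_ = None
            self.labels_ = np.zeros(len(line_ids), dtype=int)
        return self
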