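"""Phenotypic interval classes from trait clustering.

A trait's *intervals* are classes of individuals with similar phenotypic
values, obtained by clustering the one-dimensional trait vector.  Nine
clustering strategies are supported (Ward's minimum variance with and
without squared dissimilarities — WardWSD / WardWoSD, i.e. the ward.D2 /
ward.D distinction — single, complete, UPGMA, WPGMA, WPGMC, UPGMC and
k-means, all with Euclidean distances), and the number of clusters is picked
by a consensus over a fixed panel of cluster-number indices evaluated for
k in [2, 10]: each index votes for its best k and the plurality wins, with
ties broken toward the smallest k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score, silhouette_score

from .genodata import TraitVector

__all__ = [
    "CLUSTER_METHODS",
    "ClusteringScheme",
    "IntervalAssignment",
    "cluster_labels",
    "consensus_cluster_count",
    "define_intervals",
]

#: the nine supported strategies
CLUSTER_METHODS = (
    "wardWSD",
    "wardWoSD",
    "single",
    "complete",
    "UPGMA",
    "WPGMA",
    "WPGMC",
    "UPGMC",
    "kmeans",
)

_SCIPY_LINKAGE = {
    "single": "single",
    "complete": "complete",
    "UPGMA": "average",
    "WPGMA": "weighted",
    "WPGMC": "median",
    "UPGMC": "centroid",
}

INDEX_NAMES = (
    "calinski_harabasz",
    "silhouette",
    "davies_bouldin",
    "dunn",
    "c_index",
    "hartigan",
    "krzanowski_lai",
    "gap",
)


@dataclass
class ClusteringScheme:
    """A clustering method with the consensus search range."""

    method: str = "wardWSD"
    k_min: int = 2
    k_max: int = 10
    seed: int = 0  # k-means restarts and the gap-statistic reference draws
    gap_b: int = 20

    def __post_init__(self) -> None:
        if self.method not in CLUSTER_METHODS:
            raise ValueError(f"method must be one of {CLUSTER_METHODS}, got {self.method!r}")
        if self.k_min < 2:
            raise ValueError("k_min must be at least 2")


@dataclass
class IntervalAssignment:
    """Per-individual interval labels with their value ranges."""

    individuals: list[str]
    labels: np.ndarray  # 1..k, ordered by ascending class mean
    k: int
    method: str
    ranges: list[tuple[float, float]]  # (min, max) per class, index label-1
    index_votes: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        lo = np.array([self.ranges[l - 1][0] for l in self.labels])
        hi = np.array([self.ranges[l - 1][1] for l in self.labels])
        return pd.DataFrame(
            {"id": self.individuals, "label": self.labels, "class_min": lo, "class_max": hi}
        )


def _trait_values(y) -> np.ndarray:
    if isinstance(y, TraitVector):
        v = y.normalized if y.normalized is not None else y.values
    else:
        v = np.asarray(y, dtype=float)
    return v.ravel()


def _linkage_for(v: np.ndarray, method: str):
    x = v[:, None]
    if method == "wardWSD":
        # scipy's ward == ward.D2: the recursion runs on squared dissimilarities
        return linkage(x, method="ward")
    if method == "wardWoSD":
        # ward.D: feed sqrt distances so the recursion effectively sees raw ones
        return linkage(np.sqrt(pdist(x)), method="ward")
    return linkage(x, method=_SCIPY_LINKAGE[method])


def cluster_labels(y, scheme: ClusteringScheme, k: int) -> np.ndarray:
    """Labels (1..k) for ``k`` clusters under the scheme's method."""
    v = _trait_values(y)
    n = v.size
    if k < scheme.k_min:
        raise ValueError(f"k={k} below the minimum of {scheme.k_min}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of individuals ({n})")
    if scheme.method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=scheme.seed)
        lab = km.fit_predict(v[:, None]) + 1
    else:
        lab = fcluster(_linkage_for(v, scheme.method), t=k, criterion="maxclust")
    return np.asarray(lab)


def _within_ss(v: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for g in np.unique(labels):
        vv = v[labels == g]
        w += float(((vv - vv.mean()) ** 2).sum())
    return w


def _dunn(v: np.ndarray, labels: np.ndarray) -> float:
    groups = [v[labels == g] for g in np.unique(labels)]
    diam = max(float(g.max() - g.min()) for g in groups)
    sep = np.inf
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            d = np.abs(groups[i][:, None] - groups[j][None, :]).min()
            sep = min(sep, float(d))
    return sep / diam if diam > 0 else np.inf


def _c_index(v: np.ndarray, labels: np.ndarray) -> float:
    d = pdist(v[:, None])
    within = pdist(labels[:, None], metric="cityblock") == 0
    nw = int(within.sum())
    if nw == 0:
        return np.inf
    s = float(d[within].sum())
    d_sorted = np.sort(d)
    s_min = float(d_sorted[:nw].sum())
    s_max = float(d_sorted[-nw:].sum())
    return (s - s_min) / (s_max - s_min) if s_max > s_min else 0.0


def _labels_by_k(v, scheme, k_lo, k_hi):
    return {k: cluster_labels(v, scheme, k) for k in range(k_lo, min(k_hi, v.size) + 1)}


def consensus_cluster_count(y, scheme: ClusteringScheme | None = None):
    """Consensus number of clusters: plurality vote over the index panel.

    Returns ``(k, votes)`` where ``votes`` maps each index name to its best
    k in [k_min, k_max].  Ties in the plurality go to the smallest k.
    """
    scheme = scheme or ClusteringScheme()
    v = _trait_values(y)
    n = v.size
    if n < 3:
        raise ValueError("need at least three individuals to choose a cluster count")
    k_lo, k_hi = scheme.k_min, min(scheme.k_max, n - 1)
    ks = list(range(k_lo, k_hi + 1))
    # W_k needed one step past the range for Hartigan / KL / gap differences
    lab = _labels_by_k(v, scheme, k_lo, k_hi + 1)
    W = {1: float(((v - v.mean()) ** 2).sum())}
    W.update({k: _within_ss(v, l) for k, l in lab.items()})

    votes: dict[str, int] = {}
    x2 = v[:, None]
    scores = {
        "calinski_harabasz": [calinski_harabasz_score(x2, lab[k]) for k in ks],
        "silhouette": [silhouette_score(x2, lab[k]) for k in ks],
        "davies_bouldin": [-davies_bouldin_score(x2, lab[k]) for k in ks],
        "dunn": [_dunn(v, lab[k]) for k in ks],
        "c_index": [-_c_index(v, lab[k]) for k in ks],
    }
    for name, sc in scores.items():
        votes[name] = ks[int(np.argmax(sc))]

    # Hartigan: smallest k with H(k) = (W_k/W_{k+1} - 1)(n - k - 1) <= 10
    votes["hartigan"] = ks[-1]
    for k in ks:
        if k + 1 not in W or W[k + 1] <= 0:
            break
        h = (W[k] / W[k + 1] - 1.0) * (n - k - 1)
        if h <= 10.0:
            votes["hartigan"] = k
            break

    # Krzanowski-Lai (1-D, so the k^(2/m) factor uses m = 1)
    def diff(k):
        return (k - 1) ** 2 * W.get(k - 1, np.nan) - k**2 * W.get(k, np.nan)

    kl = []
    for k in ks:
        num, den = diff(k), diff(k + 1)
        kl.append(abs(num / den) if den not in (0.0,) and np.isfinite(den) and den != 0 else -np.inf)
    votes["krzanowski_lai"] = ks[int(np.argmax(kl))]

    # Gap statistic with uniform references over the trait range
    rng = np.random.default_rng(scheme.seed)
    logW_ref = np.zeros((scheme.gap_b, len(ks) + 1))
    lo, hi = v.min(), v.max()
    for b in range(scheme.gap_b):
        ref = rng.uniform(lo, hi, size=n)
        ref_lab = _labels_by_k(ref, scheme, k_lo, k_hi + 1)
        for j, k in enumerate(ks + [k_hi + 1]):
            if k in ref_lab:
                logW_ref[b, j] = np.log(max(_within_ss(ref, ref_lab[k]), 1e-300))
    logW_obs = np.array([np.log(max(W[k], 1e-300)) for k in ks + [k_hi + 1] if k in W])
    gap = logW_ref.mean(axis=0)[: logW_obs.size] - logW_obs
    sk = logW_ref.std(axis=0)[: logW_obs.size] * np.sqrt(1.0 + 1.0 / scheme.gap_b)
    votes["gap"] = ks[-1]
    for j, k in enumerate(ks):
        if j + 1 < gap.size and gap[j] >= gap[j + 1] - sk[j + 1]:
            votes["gap"] = k
            break

    counts = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return int(best), votes


def define_intervals(y, scheme: ClusteringScheme | None = None, individuals=None) -> IntervalAssignment:
    """Cluster a trait at the consensus k and order classes by their means."""
    scheme = scheme or ClusteringScheme()
    v = _trait_values(y)
    if individuals is None:
        individuals = y.individuals if isinstance(y, TraitVector) else [str(i) for i in range(v.size)]
    k, votes = consensus_cluster_count(v, scheme)
    raw = cluster_labels(v, scheme, k)
    order = np.argsort([v[raw == g].mean() for g in np.unique(raw)])
    relabel = {int(np.unique(raw)[g]): rank + 1 for rank, g in enumerate(order)}
    labels = np.array([relabel[int(g)] for g in raw])
    ranges = [(float(v[labels == c].min()), float(v[labels == c].max())) for c in range(1, k + 1)]
    return IntervalAssignment(
        individuals=list(individuals),
        labels=labels,
        k=k,
        method=scheme.method,
        ranges=ranges,
        index_votes=votes,
    )
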