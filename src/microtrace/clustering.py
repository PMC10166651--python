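"""Clustering of similarity matrices: Ward's linkage and community detection.

Both clusterers consume the shared-nearest-neighbor Jaccard similarity
matrix.  Ward's linkage operates on the dissimilarity 1 - J through the
Lance-Williams update, merging at each step the pair of clusters whose
fusion minimally increases the error sum of squares (ESS); the number of
clusters is chosen automatically as the cut with the largest merge-height
gap, subject to a minimum cluster count (2 when two species are expected,
3 for within-species individual discrimination, where solutions with two
or fewer clusters are discarded).  Community detection greedily merges
communities of the weighted similarity graph to maximise modularity Q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import _check_unique
from .similarity import DistanceMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` has one row per merge: (cluster_a, cluster_b, height, size)
    with leaves numbered 0..N-1 and the cluster created by merge t
    numbered N + t (the familiar linkage-matrix convention); a < b.
    """

    item_ids: tuple[str, ...]
    merges: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", tuple(str(i) for i in self.item_ids))
        _check_unique(self.item_ids, "item")
        m = np.asarray(self.merges, dtype=float)
        n = len(self.item_ids)
        if m.shape != (n - 1, 4):
            raise ValueError(f"expected {n - 1} merges of 4 fields, got shape {m.shape}")
        object.__setattr__(self, "merges", m)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "height", "size"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, encoding="utf-8")


@dataclass(frozen=True)
class Labeling:
    """Cluster assignment of items; cluster ids are contiguous from 1."""

    item_ids: tuple[str, ...]
    labels: tuple[int, ...]
    mode: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", tuple(str(i) for i in self.item_ids))
        _check_unique(self.item_ids, "item")
        labels = tuple(int(x) for x in self.labels)
        if len(labels) != len(self.item_ids):
            raise ValueError("labels and item_ids differ in length")
        if labels:
            distinct = sorted(set(labels))
            if distinct != list(range(1, len(distinct) + 1)):
                raise ValueError("cluster ids must be contiguous integers from 1")
        object.__setattr__(self, "labels", labels)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"item_id": list(self.item_ids), "cluster": list(self.labels)})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, encoding="utf-8")


def relabel_contiguous(raw_labels: Sequence[int]) -> tuple[int, ...]:
    """Renumber arbitrary labels as 1, 2, ... in order of first appearance."""
    mapping: dict[int, int] = {}
    out = []
    for x in raw_labels:
        if x not in mapping:
            mapping[x] = len(mapping) + 1
        out.append(mapping[x])
    return tuple(out)


def labeling_from_assignment(
    item_ids: Sequence[str], assignment: dict[str, str], mode: str = ""
) -> Labeling:
    """Build a Labeling from an item -> categorical label mapping."""
    raw = []
    seen: dict[str, int] = {}
    for i in item_ids:
        lab = assignment[i]
        if lab not in seen:
            seen[lab] = len(seen) + 1
        raw.append(seen[lab])
    return Labeling(tuple(item_ids), tuple(raw), mode=mode)


# ---------------------------------------------------------------------------


def similarity_to_dissimilarity(S: SimilarityMatrix) -> DistanceMatrix:
    """d = 1 - J elementwise (zero diagonal by construction)."""
    return DistanceMatrix(S.item_ids, 1.0 - S.values)


def ward_linkage(D: DistanceMatrix) -> Dendrogram:
    """Agglomerative Ward clustering on a precomputed dissimilarity.

    The Lance-Williams Ward recurrence is applied to squared input
    distances, so for genuinely Euclidean input the merge cost equals
    2 x the ESS increase of the fusion and the reported heights match the
    usual linkage convention (height = sqrt(2 * delta-ESS)).  At each
    step the pair with minimal merge cost is fused; exact ties are broken
    by the lowest (cluster_a, cluster_b) id pair.
    """
    n = len(D)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if np.any(~np.isfinite(D.values)):
        raise ValueError("distance matrix contains non-finite values")

    total = 2 * n - 1
    # W holds squared merge heights between active clusters
    W = np.full((total, total), np.inf)
    W[:n, :n] = D.values**2
    np.fill_diagonal(W, np.inf)
    size = np.zeros(total, dtype=np.int64)
    size[:n] = 1
    active = list(range(n))

    merges = np.empty((n - 1, 4))
    for t in range(n - 1):
        # smallest cost; ties -> lexicographically smallest (a, b)
        best = (np.inf, -1, -1)
        for ai in range(len(active)):
            a = active[ai]
            row = W[a]
            for bi in range(ai + 1, len(active)):
                b = active[bi]
                c = row[b]
                if c < best[0]:
                    best = (c, a, b)
        cost, a, b = best
        new = n + t
        na, nb = size[a], size[b]
        for c in active:
            if c == a or c == b:
                continue
            nc = size[c]
            W[new, c] = W[c, new] = (
                (na + nc) * W[a, c] + (nb + nc) * W[b, c] - nc * W[a, b]
            ) / (na + nb + nc)
        size[new] = na + nb
        active.remove(a)
        active.remove(b)
        active.append(new)
        merges[t] = (a, b, np.sqrt(max(cost, 0.0)), na + nb)
    return Dendrogram(D.item_ids, merges)


def cut_dendrogram(dend: Dendrogram, k: int) -> Labeling:
    """Labeling after applying the first N - k merges (k clusters)."""
    n = len(dend.item_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        a, b = int(dend.merges[t, 0]), int(dend.merges[t, 1])
        parent[find(a)] = find(n + t)
        parent[find(b)] = find(n + t)
    return Labeling(dend.item_ids, relabel_contiguous([find(i) for i in range(n)]))


def cut_by_height_gap(dend: Dendrogram, min_clusters: int) -> Labeling:
    """Automatic cluster count: the cut with the largest merge-height gap.

    Candidate solutions have min_clusters <= k <= N - 1 clusters; the
    score of a k-cluster cut is the gap between the last merge applied
    and the first merge refused.  Gap ties resolve toward smaller k.
    Solutions below ``min_clusters`` are never returned (the two-or-fewer
    rule for individual discrimination).
    """
    n = len(dend.item_ids)
    if min_clusters > n:
        raise ValueError(f"min_clusters={min_clusters} exceeds the {n} items")
    if min_clusters == n:
        return cut_dendrogram(dend, n)  # only admissible solution: singletons
    h = dend.heights
    best_k, best_gap = None, -np.inf
    for k in range(min_clusters, n):
        gap = h[n - k] - h[n - k - 1]
        # strict > keeps the smallest k on ties because k ascends
        if gap > best_gap:
            best_gap, best_k = gap, k
    assert best_k is not None
    labeling = cut_dendrogram(dend, best_k)
    logger.info(
        "cut_by_height_gap: k=%d (gap=%.6g, min_clusters=%d)", best_k, best_gap, min_clusters
    )
    return labeling


# ---------------------------------------------------------------------------
# greedy modularity community detection


def modularity(S: SimilarityMatrix, labeling: Labeling) -> float:
    """Weighted modularity Q = sum_c (e_c - a_c^2) of a partition.

    e_c is the fraction of total edge weight inside community c and a_c
    the fraction of edge-weight endpoints (weighted degree) in c; edges
    are all off-diagonal pairs with positive similarity.
    """
    n = len(S)
    A = S.values.copy()
    np.fill_diagonal(A, 0.0)
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    labels = np.asarray(labeling.labels)
    deg = A.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_c = A[np.ix_(mask, mask)].sum() / two_m  # = (intra weight) / m; A double-counts
        a_c = deg[mask].sum() / two_m
        q += e_c - a_c**2
    return float(q)


def community_detection(S: SimilarityMatrix) -> Labeling:
    """Newman-style greedy modularity maximisation on the weighted graph.

    Starting from singleton communities, the merge with the largest
    modularity gain is applied repeatedly (only communities joined by at
    least one positive-weight edge are merged; ties break toward the
    lowest community index pair).  The partition of maximal Q seen along
    the whole merge path is returned.  A graph with no positive
    off-diagonal similarity yields all-singleton communities.
    """
    n = len(S)
    A = S.values.copy()
    np.fill_diagonal(A, 0.0)
    two_m = A.sum()
    if two_m == 0:
        logger.warning("community_detection: empty graph; every item is its own cluster")
        return Labeling(S.item_ids, tuple(range(1, n + 1)))

    # community state: weights between communities, weighted-degree fractions
    between = {i: {} for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j] > 0:
                between[i][j] = A[i, j]
                between[j][i] = A[i, j]
    a = A.sum(axis=1) / two_m  # a_c
    e_in = np.zeros(n)  # e_c (intra fraction)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}

    q = float(np.sum(e_in[: n]) - np.sum(a[:n] ** 2))
    best_q = q
    best_members = {c: list(m) for c, m in members.items()}

    while True:
        best = None  # (dq, ca, cb); strict > over sorted pairs keeps lowest ids on ties
        for ca in sorted(members):
            for cb in sorted(between[ca]):
                if cb <= ca:
                    continue
                dq = 2.0 * (between[ca][cb] / two_m - a[ca] * a[cb])
                if best is None or dq > best[0]:
                    best = (dq, ca, cb)
        if best is None:
            break
        dq, ca, cb = best
        # merge cb into ca (ca < cb keeps the surviving index lowest)
        e_in[ca] += e_in[cb] + 2.0 * between[ca][cb] / two_m
        a[ca] += a[cb]
        members[ca].extend(members[cb])
        del members[cb]
        for other, w in list(between[cb].items()):
            if other == ca:
                continue
            between[ca][other] = between[ca].get(other, 0.0) + w
            between[other][ca] = between[ca][other]
            del between[other][cb]
        between[ca].pop(cb, None)
        between[cb].clear()
        q += dq
        if q > best_q + 1e-12:
            best_q = q
            best_members = {c: list(m) for c, m in members.items()}

    raw = np.empty(n, dtype=np.int64)
    for c in sorted(best_members):
        for i in best_members[c]:
            raw[i] = c
    labeling = Labeling(S.item_ids, relabel_contiguous(raw.tolist()))
    logger.info(
        "community_detection: %d communities, Q=%.6g", labeling.n_clusters, best_q
    )
    return labeling
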