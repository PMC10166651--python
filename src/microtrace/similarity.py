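"""Distances, shared-nearest-neighbor Jaccard similarity, and DTW.

Two branches feed the clusterers with structurally identical inputs:

* single-sample branch — Euclidean distances between per-sample
  relative-abundance vectors;
* time-series branch — dynamic time warping (DTW) distances between
  whole per-individual series, where the local cost of aligning day t of
  one series with day u of another is the Euclidean distance between the
  two day profiles.

Either distance matrix is then turned into a similarity matrix by the
shared-nearest-neighbor construction: each item's k nearest neighbors
(self included) form a set, and the similarity of two items is the
Jaccard index of their neighbor sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .data_io import AbundanceTable, MicrobiotaSeries, _check_unique

SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal."""

    item_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", tuple(str(i) for i in self.item_ids))
        _check_unique(self.item_ids, "item")
        v = np.asarray(self.values, dtype=float)
        n = len(self.item_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} items")
        if np.any(~np.isfinite(v)):
            raise ValueError("distance matrix contains non-finite values")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        if np.max(np.abs(v - v.T)) > SYMMETRY_TOL:
            raise ValueError("distance matrix is not symmetric")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.item_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.item_ids), columns=list(self.item_ids))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric matrix of similarities in [0, 1] with unit diagonal."""

    item_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", tuple(str(i) for i in self.item_ids))
        _check_unique(self.item_ids, "item")
        v = np.asarray(self.values, dtype=float)
        n = len(self.item_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} items")
        if np.any(~np.isfinite(v)) or np.any(v < -SYMMETRY_TOL) or np.any(v > 1 + SYMMETRY_TOL):
            raise ValueError("similarities must be finite and within [0, 1]")
        if np.max(np.abs(v - v.T)) > SYMMETRY_TOL:
            raise ValueError("similarity matrix is not symmetric")
        if np.max(np.abs(np.diag(v) - 1.0)) > SYMMETRY_TOL:
            raise ValueError("similarity matrix must have a unit diagonal")
        v = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(v, 1.0)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.item_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.item_ids), columns=list(self.item_ids))


@dataclass(frozen=True)
class NeighborSets:
    """Per item, the set of its k nearest items (self always included)."""

    item_ids: tuple[str, ...]
    k: int
    sets: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        n = len(self.item_ids)
        expected = min(self.k + 1, n)
        for i, s in enumerate(self.sets):
            if i not in s:
                raise ValueError(f"neighbor set of item {self.item_ids[i]!r} lacks itself")
            if len(s) != expected:
                raise ValueError(
                    f"neighbor set of item {self.item_ids[i]!r} has {len(s)} members, "
                    f"expected {expected}"
                )


def write_matrix(matrix: DistanceMatrix | SimilarityMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "item_id"
    df.to_csv(path, sep="\t", encoding="utf-8")


# ---------------------------------------------------------------------------


def sample_distance_matrix(table: AbundanceTable) -> DistanceMatrix:
    """All-pairs Euclidean distance between per-sample abundance profiles."""
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    if np.any(~np.isfinite(table.proportions)):
        raise ValueError("abundance table contains non-finite values")
    values = squareform(pdist(table.proportions, metric="euclidean"))
    return DistanceMatrix(table.sample_ids, values)


def default_knn_k(n_items: int) -> int:
    """SNN heuristic: k = round(sqrt(N)), clipped to [2, N-1]."""
    if n_items < 2:
        raise ValueError("need at least 2 items")
    return int(np.clip(round(math.sqrt(n_items)), 2, n_items - 1))


def knn_neighbor_sets(D: DistanceMatrix, k: int) -> NeighborSets:
    """For each item: itself plus the k others at smallest distance.

    Distance ties are broken by ascending item index so repeated runs
    give identical neighbor sets.
    """
    n = len(D)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= {n - 1}, got {k}")
    sets = []
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        order = others[np.lexsort((others, D.values[i, others]))]
        sets.append(frozenset([i, *order[:k].tolist()]))
    return NeighborSets(D.item_ids, k, tuple(sets))


def jaccard_from_neighbors(ns: NeighborSets) -> SimilarityMatrix:
    """J(i, j) = |N(i) ∩ N(j)| / |N(i) ∪ N(j)| over the kNN sets."""
    n = len(ns.item_ids)
    member = np.zeros((n, n), dtype=bool)
    for i, s in enumerate(ns.sets):
        member[i, list(s)] = True
    inter = (member @ member.T.astype(np.int64)).astype(float)
    sizes = member.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    return SimilarityMatrix(ns.item_ids, inter / union)


# ---------------------------------------------------------------------------
# dynamic time warping


def dtw_distance(
    a: MicrobiotaSeries,
    b: MicrobiotaSeries,
    *,
    band: int | None = None,
    normalize: bool = False,
) -> float:
    """Classic dynamic-programming DTW between two day-profile sequences.

    Local cost c(t, u) is the Euclidean distance between day profile t of
    ``a`` and day profile u of ``b``; the cumulative cost follows the
    symmetric three-way recursion

        D(t, u) = c(t, u) + min(D(t-1, u), D(t, u-1), D(t-1, u-1))

    with D(1, 1) = c(1, 1).  By default there is no warping-window
    constraint and no path-length normalisation; ``band`` adds a
    Sakoe-Chiba window of the given half-width and ``normalize`` divides
    the result by len(a) + len(b) (both for sensitivity analysis only).
    """
    if a.family_ids != b.family_ids:
        raise ValueError(
            f"series {a.series_id!r} and {b.series_id!r} have mismatched family universes"
        )
    C = cdist(a.profiles, b.profiles, metric="euclidean")
    n, m = C.shape
    if band is not None and band < abs(n - m):
        raise ValueError(f"band={band} is narrower than the length difference {abs(n - m)}")
    D = np.full((n, m), np.inf)
    for i in range(n):
        for j in range(m):
            if band is not None and abs(i - j) > band:
                continue
            if i == 0 and j == 0:
                prev = 0.0
            else:
                prev = np.inf
                if i > 0:
                    prev = min(prev, D[i - 1, j])
                if j > 0:
                    prev = min(prev, D[i, j - 1])
                if i > 0 and j > 0:
                    prev = min(prev, D[i - 1, j - 1])
            D[i, j] = C[i, j] + prev
    d = float(D[-1, -1])
    if normalize:
        d /= n + m
    return d


def series_distance_matrix(
    series_list: Sequence[MicrobiotaSeries],
    *,
    band: int | None = None,
    normalize: bool = False,
) -> DistanceMatrix:
    """All-pairs DTW distance between per-individual series.

    The result plugs into :func:`knn_neighbor_sets` and
    :func:`jaccard_from_neighbors` exactly like the sample-level branch.
    """
    if len(series_list) < 2:
        raise ValueError("need at least 2 series for a distance matrix")
    ids = tuple(s.series_id for s in series_list)
    _check_unique(ids, "series")
    n = len(series_list)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_distance(series_list[i], series_list[j], band=band, normalize=normalize)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values)
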