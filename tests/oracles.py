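"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from first principles by a route that
shares no code with the implementation it checks: exhaustive warping-path
enumeration for DTW, from-scratch ESS recomputation for Ward's linkage,
and exhaustive set-partition enumeration for modularity.
"""

from __future__ import annotations

import itertools

import numpy as np


def dtw_bruteforce(cost: np.ndarray) -> float:
    """Minimum cumulative cost over all monotone warping paths.

    Enumerates every path from (0, 0) to (n-1, m-1) built from steps
    (1, 0), (0, 1) and (1, 1).  Exponential — use only for tiny inputs.
    """
    n, m = cost.shape
    best = [np.inf]

    def walk(i: int, j: int, acc: float) -> None:
        acc += cost[i, j]
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)

    walk(0, 0, 0.0)
    return float(best[0])


def ward_bruteforce(points: np.ndarray) -> list[tuple[int, int, float]]:
    """Ward merge sequence by recomputing the ESS increase from scratch.

    Clusters are numbered like the implementation: leaves 0..n-1, the
    cluster created by merge t is n + t.  At every step the pair with
    the smallest increase in the error sum of squares is merged; exact
    ties break toward the lowest (a, b) pair.  Returns (a, b, delta_ess)
    per merge.  O(n^4) — small n only.
    """
    n = len(points)

    def ess(idx: list[int]) -> float:
        x = points[idx]
        return float(((x - x.mean(axis=0)) ** 2).sum())

    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    for t in range(n - 1):
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            delta = ess(clusters[a] + clusters[b]) - ess(clusters[a]) - ess(clusters[b])
            if best is None or delta < best[0] - 1e-12 or (
                abs(delta - best[0]) <= 1e-12 and (a, b) < (best[1], best[2])
            ):
                best = (delta, a, b)
        delta, a, b = best
        clusters[n + t] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, delta))
    return merges


def set_partitions(items: list[int]):
    """All partitions of a list (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[first] + partial[i]] + partial[i + 1 :]
        yield [[first]] + partial


def modularity_of_partition(A: np.ndarray, parts: list[list[int]]) -> float:
    """Q = sum_c (e_c - a_c^2) for a weighted adjacency matrix (no self loops)."""
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    deg = A.sum(axis=1)
    q = 0.0
    for block in parts:
        idx = np.asarray(block)
        q += A[np.ix_(idx, idx)].sum() / two_m - (deg[idx].sum() / two_m) ** 2
    return float(q)


def max_modularity_bruteforce(A: np.ndarray) -> float:
    """Exhaustive maximum modularity over all partitions of the nodes."""
    n = A.shape[0]
    return max(
        modularity_of_partition(A, parts) for parts in set_partitions(list(range(n)))
    )
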