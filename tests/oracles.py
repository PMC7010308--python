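"""Independent brute-force oracles used to cross-check the package's
network statistics.  Deliberately naive implementations with code paths
distinct from the library's."""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.spatial.distance import jensenshannon


def wnodf_bruteforce(A: np.ndarray) -> float:
    """Weighted NODF by direct enumeration of every row and column pair
    (no sorting: the pair orientation is decided per pair by totals)."""
    A = np.asarray(A)

    def pair_scores(M: np.ndarray) -> list[float]:
        totals = M.sum(axis=1)
        scores = []
        for i, j in combinations(range(M.shape[0]), 2):
            if totals[i] == totals[j]:
                scores.append(0.0)
                continue
            up, lo = (i, j) if totals[i] > totals[j] else (j, i)
            filled = [k for k in range(M.shape[1]) if M[lo, k] > 0]
            if not filled:
                scores.append(0.0)
                continue
            hits = sum(1 for k in filled if M[lo, k] < M[up, k])
            scores.append(100.0 * hits / len(filled))
        return scores

    scores = pair_scores(A) + pair_scores(A.T)
    return float(np.mean(scores))


def enumerate_tables(r: list[int], c: list[int]):
    """Yield every non-negative integer table with the given marginals."""
    n_r, n_c = len(r), len(c)

    def fill(row: int, col_rem: list[int]):
        if row == n_r - 1:
            if all(x >= 0 for x in col_rem) and sum(col_rem) == r[row]:
                yield [list(col_rem)]
            return
        target = r[row]

        def cells(j: int, rem: int, acc: list[int]):
            if j == n_c - 1:
                if 0 <= rem <= col_rem[j]:
                    yield acc + [rem]
                return
            for x in range(min(rem, col_rem[j]) + 1):
                yield from cells(j + 1, rem - x, acc + [x])

        for row_fill in cells(0, target, []):
            new_rem = [col_rem[j] - row_fill[j] for j in range(n_c)]
            for rest in fill(row + 1, new_rem):
                yield [row_fill] + rest

    yield from fill(0, list(c))


def h2_bounds_enumeration(A: np.ndarray) -> tuple[float, float]:
    """Exact (H2min, H2max) by exhausting all integer tables with the
    observed marginals."""
    A = np.asarray(A)
    m = A.sum()

    def entropy(T: np.ndarray) -> float:
        p = np.asarray(T, float).ravel() / m
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    hs = [
        entropy(np.array(T))
        for T in enumerate_tables(list(A.sum(axis=1)), list(A.sum(axis=0)))
    ]
    return min(hs), max(hs)


def h2_prime_enumeration(A: np.ndarray) -> float:
    """H2' with the entropy extremes taken from full enumeration."""
    A = np.asarray(A)
    m = A.sum()
    p = A.ravel() / m
    p = p[p > 0]
    h2 = float(-(p * np.log(p)).sum())
    h_min, h_max = h2_bounds_enumeration(A)
    if h_max - h_min <= 1e-12:
        return 0.0
    return float(np.clip((h_max - h2) / (h_max - h_min), 0.0, 1.0))


def set_partitions(items: list):
    """Yield all set partitions of ``items`` (restricted-growth)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def best_partition_q(A: np.ndarray) -> float:
    """Exhaustive maximum of Barber's bipartite modularity over all
    joint set partitions of the row and column nodes."""
    A = np.asarray(A, float)
    n_r, n_c = A.shape
    m = A.sum()
    B = A - np.outer(A.sum(axis=1), A.sum(axis=0)) / m
    nodes = [("r", i) for i in range(n_r)] + [("c", j) for j in range(n_c)]
    best = -np.inf
    for part in set_partitions(nodes):
        q = 0.0
        for module in part:
            rows = [i for kind, i in module if kind == "r"]
            cols = [j for kind, j in module if kind == "c"]
            if rows and cols:
                q += B[np.ix_(rows, cols)].sum()
        best = max(best, q / m)
    return float(best)


def horn_bruteforce(p: np.ndarray, q: np.ndarray) -> float:
    """Horn overlap through its Jensen-Shannon identity:
    R = 1 - JSD(p, q) / ln 2."""
    p = np.asarray(p, float) / np.sum(p)
    q = np.asarray(q, float) / np.sum(q)
    jsd = jensenshannon(p, q) ** 2  # squared distance = divergence (nats... base e)
    return float(1.0 - jsd / np.log(2.0))


def mean_horn_bruteforce(A: np.ndarray) -> float:
    """Mean pairwise Horn overlap over the rows of ``A``."""
    A = np.asarray(A, float)
    vals = [
        horn_bruteforce(A[i], A[j]) for i, j in combinations(range(A.shape[0]), 2)
    ]
    return float(np.mean(vals))
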