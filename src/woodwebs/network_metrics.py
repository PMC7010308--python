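"""Weighted bipartite network structure and species-level indices.

Implements the quantitative (count-weighted) network statistics used to
characterize insect-host interaction networks:

* **WNODF** — weighted nestedness by overlap and decreasing fill,
  0 (not nested) to 100 (perfectly nested);
* **Barber modularity Q** maximized by a weighted bipartite label
  propagation with an agglomerative refinement and multiple restarts;
* **H2'** — network-level interaction specialization, the observed
  Shannon interaction entropy standardized between the extremes
  achievable under the fixed marginal totals;
* **Horn niche overlap** averaged over species pairs of one level;
* species-level indices: degree, Blüthgen's d', effective partners
  (exp Shannon), and species strength (summed partner dependence).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import InteractionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "wnodf",
    "modularity_lp",
    "barber_modularity",
    "h2_prime",
    "niche_overlap",
    "species_indices",
    "NetworkStructure",
    "network_structure",
]


def _xlogx(p: np.ndarray) -> np.ndarray:
    """x*ln(x) with 0*ln(0) = 0."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


# ---------------------------------------------------------------------------
# WNODF


def _axis_order(A: np.ndarray, axis: int) -> np.ndarray:
    """Sort indices by decreasing marginal total, then decreasing fill,
    then original position (stable tie-break)."""
    totals = A.sum(axis=1 - axis)
    fills = (A > 0).sum(axis=1 - axis)
    return np.lexsort((np.arange(len(totals)), -fills, -totals))


def wnodf(matrix: InteractionMatrix | np.ndarray) -> float:
    """Weighted NODF nestedness on the 0-100 scale.

    Rows and columns are sorted by decreasing marginal total.  For every
    ordered pair (upper row i, lower row j) with strictly larger total
    for i, the pair score is the percentage of j's non-zero cells whose
    count is positive yet strictly smaller than i's count in the same
    column; pairs with equal totals score 0.  Column pairs are treated
    symmetrically, and WNODF is the mean over all row and column pairs.
    """
    A = matrix.A if isinstance(matrix, InteractionMatrix) else np.asarray(matrix)
    n_r, n_c = A.shape
    if n_r < 2 or n_c < 2:
        raise ValueError("WNODF requires at least 2 rows and 2 columns")
    total, n_pairs = 0.0, 0
    for axis in (0, 1):
        M = A if axis == 0 else A.T
        order = _axis_order(A, axis)
        M = M[order]
        totals = M.sum(axis=1)
        n = M.shape[0]
        for u in range(n - 1):
            for v in range(u + 1, n):
                n_pairs += 1
                if totals[u] <= totals[v]:
                    continue
                lower_nz = M[v] > 0
                if not lower_nz.any():
                    continue
                overlap = np.count_nonzero(lower_nz & (M[v] < M[u]))
                total += 100.0 * overlap / lower_nz.sum()
    return total / n_pairs


# ---------------------------------------------------------------------------
# Barber modularity via weighted label propagation


def barber_modularity(
    matrix: InteractionMatrix | np.ndarray,
    row_labels: np.ndarray,
    col_labels: np.ndarray,
) -> float:
    """Barber's weighted bipartite modularity of a given partition.

    Q = (1/m) sum_ij (a_ij - r_i c_j / m) delta(g_i, g_j), where g are
    module labels on rows and columns and m the grand total.
    """
    A = matrix.A if isinstance(matrix, InteractionMatrix) else np.asarray(matrix, float)
    m = A.sum()
    if m == 0:
        return 0.0
    r = A.sum(axis=1)
    c = A.sum(axis=0)
    B = A - np.outer(r, c) / m
    same = row_labels[:, None] == col_labels[None, :]
    return float((B * same).sum() / m)


def _lp_sweep(B: np.ndarray, row_lab: np.ndarray, col_lab: np.ndarray) -> None:
    """One label-propagation sweep: columns adopt the row-label with the
    largest modularity contribution, then rows likewise.  In place."""
    labels = np.unique(row_lab)
    # columns
    contrib = np.vstack([B[row_lab == L].sum(axis=0) for L in labels])
    col_lab[:] = labels[np.argmax(contrib, axis=0)]
    # rows
    labels = np.unique(col_lab)
    contrib = np.vstack([B[:, col_lab == L].sum(axis=1) for L in labels])
    row_lab[:] = labels[np.argmax(contrib, axis=0)]


def _agglomerate(
    B: np.ndarray, row_lab: np.ndarray, col_lab: np.ndarray, m: float
) -> float:
    """Greedy module merging: accept the best pairwise merge while it
    increases Q.  Returns the final Q."""
    def q() -> float:
        return float((B * (row_lab[:, None] == col_lab[None, :])).sum() / m)

    best = q()
    improved = True
    while improved:
        improved = False
        labels = sorted(set(row_lab) | set(col_lab))
        best_gain, best_pair = 0.0, None
        for a_i in range(len(labels) - 1):
            for b_i in range(a_i + 1, len(labels)):
                La, Lb = labels[a_i], labels[b_i]
                ra, rb = row_lab == La, row_lab == Lb
                ca, cb = col_lab == La, col_lab == Lb
                gain = (B[np.ix_(ra, cb)].sum() + B[np.ix_(rb, ca)].sum()) / m
                if gain > best_gain + 1e-12:
                    best_gain, best_pair = gain, (La, Lb)
        if best_pair is not None:
            La, Lb = best_pair
            row_lab[row_lab == Lb] = La
            col_lab[col_lab == Lb] = La
            best += best_gain
            improved = True
    return q()


def modularity_lp(
    matrix: InteractionMatrix | np.ndarray,
    n_trials: int = 20,
    seed: int | None = None,
    tol: float = 1e-10,
) -> tuple[dict[str, np.ndarray], float]:
    """Maximize Barber's weighted bipartite modularity by label
    propagation with agglomerative refinement (LPA-style, repeated from
    random and constrained-module-count starts).

    Returns ``(partition, Q)`` where ``partition`` maps ``"rows"`` and
    ``"cols"`` to integer module labels and Q is the best value found.
    """
    is_im = isinstance(matrix, InteractionMatrix)
    A = np.asarray(matrix.A if is_im else matrix, dtype=float)
    n_r, n_c = A.shape
    m = A.sum()
    if m == 0:
        return {"rows": np.zeros(n_r, int), "cols": np.zeros(n_c, int)}, 0.0
    r = A.sum(axis=1)
    c = A.sum(axis=0)
    B = A - np.outer(r, c) / m

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = [np.arange(n_r)]  # every row its own module
    for k in range(1, n_r + 1):
        starts.append(rng.integers(0, k, size=n_r))
    for _ in range(max(0, n_trials - len(starts))):
        k = int(rng.integers(1, n_r + 1))
        starts.append(rng.integers(0, k, size=n_r))
    starts = starts[: max(n_trials, 1) + n_r]

    best_q = -np.inf
    best_rows = np.zeros(n_r, int)
    best_cols = np.zeros(n_c, int)
    for init in starts:
        row_lab = init.copy()
        col_lab = np.zeros(n_c, dtype=int)
        prev_q = -np.inf
        for _ in range(200):
            _lp_sweep(B, row_lab, col_lab)
            q = barber_modularity(A, row_lab, col_lab)
            if q - prev_q < tol:
                break
            prev_q = q
        q = _agglomerate(B, row_lab, col_lab, m)
        if q > best_q + tol:
            best_q, best_rows, best_cols = q, row_lab.copy(), col_lab.copy()

    # canonical relabelling: modules numbered by first appearance
    mapping: dict[int, int] = {}
    for lab in list(best_rows) + list(best_cols):
        if lab not in mapping:
            mapping[lab] = len(mapping)
    best_rows = np.array([mapping[x] for x in best_rows])
    best_cols = np.array([mapping[x] for x in best_cols])
    return {"rows": best_rows, "cols": best_cols}, max(best_q, 0.0)


# ---------------------------------------------------------------------------
# H2' specialization


def _greedy_min_entropy_table(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Concentrated integer table with the given marginals: repeatedly
    pair the largest remaining row total with the largest remaining
    column total and allocate the minimum of the two."""
    r = r.astype(np.int64).copy()
    c = c.astype(np.int64).copy()
    T = np.zeros((len(r), len(c)), dtype=np.int64)
    while r.sum() > 0:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        x = min(r[i], c[j])
        T[i, j] += x
        r[i] -= x
        c[j] -= x
    return T


def _greedy_max_entropy_table(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Near-independence integer table with the given marginals: the
    floor of the expected table r_i c_j / m, with the leftover units
    assigned one at a time to the feasible cell with the largest
    remaining expected residual."""
    r = r.astype(np.int64)
    c = c.astype(np.int64)
    m = int(r.sum())
    E = np.outer(r, c) / m
    T = np.floor(E).astype(np.int64)
    dr = r - T.sum(axis=1)
    dc = c - T.sum(axis=0)
    residual = E - T
    while dr.sum() > 0:
        feasible = (dr[:, None] > 0) & (dc[None, :] > 0)
        masked = np.where(feasible, residual, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), T.shape)
        T[i, j] += 1
        residual[i, j] -= 1
        dr[i] -= 1
        dc[j] -= 1
    return T


def _refine_entropy_table(T: np.ndarray, maximize: bool, max_sweeps: int = 500) -> np.ndarray:
    """Improve a table's entropy by elementary 4-cycle unit swaps.

    A swap moves one unit from (i, j) to (i, l) and one from (k, l) to
    (k, j), preserving both marginals.  The best swap over all (i, k,
    j, l) decomposes over column pairs, so each sweep costs
    O(C^2 R).  Hill-climbs until no swap improves the (maximized or
    minimized) Shannon entropy.
    """
    T = T.astype(np.int64).copy()
    m = T.sum()
    sign = 1.0 if maximize else -1.0

    def e(k: np.ndarray) -> np.ndarray:
        return -_xlogx(k / m)

    for _ in range(max_sweeps):
        ent = e(T)
        d_plus = sign * (e(T + 1) - ent)  # gain of adding a unit
        d_minus = np.where(T >= 1, sign * (e(np.maximum(T - 1, 0)) - ent), -np.inf)
        n_c = T.shape[1]
        best_gain, best_move = 1e-11, None
        for j in range(n_c):
            for l in range(n_c):
                if j == l:
                    continue
                a = d_minus[:, j] + d_plus[:, l]  # row i: unit j -> l
                b = d_plus[:, j] + d_minus[:, l]  # row k: unit l -> j
                ia = int(np.argmax(a))
                ib = int(np.argmax(b))
                if ia == ib:
                    # rows must differ; try second-best on either side
                    a2 = a.copy()
                    a2[ia] = -np.inf
                    b2 = b.copy()
                    b2[ib] = -np.inf
                    cands = []
                    if np.isfinite(a2.max()):
                        cands.append((a2.max() + b[ib], int(np.argmax(a2)), ib))
                    if np.isfinite(b2.max()):
                        cands.append((a[ia] + b2.max(), ia, int(np.argmax(b2))))
                    if not cands:
                        continue
                    gain, i_sel, k_sel = max(cands)
                else:
                    gain, i_sel, k_sel = a[ia] + b[ib], ia, ib
                if gain > best_gain:
                    best_gain = gain
                    best_move = (i_sel, k_sel, j, l)
        if best_move is None:
            break
        i, k, j, l = best_move
        T[i, j] -= 1
        T[i, l] += 1
        T[k, l] -= 1
        T[k, j] += 1
    return T


#: exact entropy-bound algorithms are used up to these sizes; beyond
#: them the greedy heuristics (with local refinement for the maximum)
#: take over
_EXACT_MIN_ENTROPY_LIMIT = 12
_EXACT_MIN_ENTROPY_TOTAL = 40
_EXACT_MAX_ENTROPY_TOTAL = 80


def _max_entropy_exact(r: np.ndarray, c: np.ndarray) -> float:
    """Exact maximum Shannon entropy over integer tables with the
    given marginals, by successive shortest-path min-cost flow.

    Entropy is separable and concave in the cell counts, so placing
    units one at a time along the cheapest augmenting path (source ->
    row -> column -> sink, with residual back-arcs) yields the optimal
    integer table.  Bellman-Ford handles the negative unit costs.
    """
    r = r.astype(np.int64)
    c = c.astype(np.int64)
    m = int(r.sum())
    n_r, n_c = len(r), len(c)

    def e(k: float) -> float:
        return 0.0 if k == 0 else -(k / m) * np.log(k / m)

    T = np.zeros((n_r, n_c), dtype=np.int64)
    row_used = np.zeros(n_r, dtype=np.int64)
    col_used = np.zeros(n_c, dtype=np.int64)
    # nodes: 0 = source, 1..n_r rows, n_r+1..n_r+n_c cols, last = sink
    n_nodes = n_r + n_c + 2
    SRC, SNK = 0, n_nodes - 1
    for _ in range(m):
        dist = np.full(n_nodes, np.inf)
        dist[SRC] = 0.0
        pred = np.full(n_nodes, -1, dtype=int)
        for _sweep in range(n_nodes):
            changed = False
            for i in range(n_r):
                if row_used[i] < r[i] and dist[SRC] < dist[1 + i]:
                    dist[1 + i] = dist[SRC]
                    pred[1 + i] = SRC
                    changed = True
            for i in range(n_r):
                for j in range(n_c):
                    u, v = 1 + i, 1 + n_r + j
                    fwd = -(e(T[i, j] + 1) - e(T[i, j]))
                    if dist[u] + fwd < dist[v] - 1e-15:
                        dist[v] = dist[u] + fwd
                        pred[v] = u
                        changed = True
                    if T[i, j] > 0:
                        bwd = e(T[i, j]) - e(T[i, j] - 1)
                        if dist[v] + bwd < dist[u] - 1e-15:
                            dist[u] = dist[v] + bwd
                            pred[u] = v
                            changed = True
            for j in range(n_c):
                v = 1 + n_r + j
                if col_used[j] < c[j] and dist[v] < dist[SNK]:
                    dist[SNK] = dist[v]
                    pred[SNK] = v
                    changed = True
            if not changed:
                break
        # walk the path back, flipping units
        node = SNK
        path = []
        while node != SRC:
            path.append(node)
            node = pred[node]
        path.reverse()
        col_used[path[-2] - 1 - n_r] += 1
        row_used[path[0] - 1] += 1
        for a, b in zip(path[:-1], path[1:]):
            if 1 <= a <= n_r and a < b <= n_r + n_c:
                T[a - 1, b - 1 - n_r] += 1
            elif 1 <= b <= n_r and b < a <= n_r + n_c:
                T[b - 1, a - 1 - n_r] -= 1
    return float(-_xlogx(T / m).sum())


def _min_entropy_exact(r: np.ndarray, c: np.ndarray) -> float:
    """Exact minimum Shannon entropy over integer tables with the
    given marginals.

    The entropy minimum (a concave function minimized over the
    transportation polytope) is attained at a vertex, and every vertex
    can be produced by repeatedly allocating min(remaining row,
    remaining column) to some row-column pair.  Depth-first search over
    those saturating allocations, memoized on the multisets of
    remaining marginals, therefore finds the exact minimum.
    """
    m = int(r.sum())

    def e(t: int) -> float:
        return -(t / m) * np.log(t / m)

    memo: dict[tuple, float] = {}

    def rec(rs: tuple, cs: tuple) -> float:
        if not rs:
            return 0.0
        key = (rs, cs)
        if key not in memo:
            best = np.inf
            for a in set(rs):
                for b in set(cs):
                    t = min(a, b)
                    new_r = list(rs)
                    new_r.remove(a)
                    if a > t:
                        new_r.append(a - t)
                    new_c = list(cs)
                    new_c.remove(b)
                    if b > t:
                        new_c.append(b - t)
                    best = min(
                        best,
                        e(t) + rec(tuple(sorted(new_r)), tuple(sorted(new_c))),
                    )
            memo[key] = best
        return memo[key]

    return rec(tuple(sorted(int(x) for x in r)), tuple(sorted(int(x) for x in c)))


def h2_prime(matrix: InteractionMatrix | np.ndarray) -> float:
    """Network-level specialization H2' in [0, 1].

    The observed Shannon entropy of the interaction proportions is
    standardized between H2max (entropy of a greedy near-independence
    integer table with the observed marginals) and H2min (entropy of a
    greedy integer concentration of the marginals).  0 = interactions
    follow partner availability; 1 = maximally specialized given the
    marginals.
    """
    A = matrix.A if isinstance(matrix, InteractionMatrix) else np.asarray(matrix)
    m = A.sum()
    if m <= 0:
        raise ValueError("H2' requires a non-empty matrix")
    if A.shape == (1, 1):
        warnings.warn("H2' of a single-cell matrix has no degrees of freedom; returning 0")
        return 0.0
    p = A / m
    h2 = -_xlogx(p).sum()
    r, c = A.sum(axis=1), A.sum(axis=0)
    if m <= _EXACT_MAX_ENTROPY_TOTAL:
        h2_max = _max_entropy_exact(r, c)
    else:
        t_max = _refine_entropy_table(_greedy_max_entropy_table(r, c), maximize=True)
        h2_max = -_xlogx(t_max / m).sum()
    if len(r) + len(c) <= _EXACT_MIN_ENTROPY_LIMIT and m <= _EXACT_MIN_ENTROPY_TOTAL:
        h2_min = _min_entropy_exact(r, c)
    else:
        h2_min = -_xlogx(_greedy_min_entropy_table(r, c) / m).sum()
    if h2_max - h2_min <= 1e-12:
        return 0.0
    return float(np.clip((h2_max - h2) / (h2_max - h2_min), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Horn niche overlap


def horn_overlap(p: np.ndarray, q: np.ndarray) -> float:
    """Horn's overlap index between two normalized usage vectors."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    p = p / p.sum()
    q = q / q.sum()
    num = _xlogx(p + q).sum() - _xlogx(p).sum() - _xlogx(q).sum()
    return float(np.clip(num / (2.0 * np.log(2.0)), 0.0, 1.0))


def niche_overlap(matrix: InteractionMatrix, level: str = "beetle") -> float:
    """Mean Horn overlap over all unordered species pairs of one level.

    Measures how similarly species of the same trophic level use their
    partners: 0 = no shared resource use, 1 = identical use.
    """
    A = matrix.A if level == "host" else matrix.A.T
    n = A.shape[0]
    if n < 2:
        raise ValueError(f"niche overlap needs >= 2 {level} species")
    vals = [
        horn_overlap(A[i], A[j]) for i in range(n - 1) for j in range(i + 1, n)
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# species-level indices


def _d_prime(usage: np.ndarray, availability: np.ndarray) -> float:
    """Blüthgen's standardized specialization d' of one species.

    d = KL divergence of the species' usage proportions from partner
    availability; standardized by d_min = 0 and d_max = the divergence
    of the species' whole integer total concentrated on the partner
    with the lowest availability (the KL-maximizing allocation, which a
    point mass attains among all integer allocations).
    """
    total = usage.sum()
    if total == 0:
        return 0.0
    p = usage / total
    q = availability / availability.sum()
    nz = p > 0
    d = float((p[nz] * np.log(p[nz] / q[nz])).sum())
    d_max = float(-np.log(q[q > 0].min()))
    if d_max <= 1e-12:
        return 0.0
    return float(np.clip(d / d_max, 0.0, 1.0))


@dataclass(frozen=True)
class SpeciesIndexRow:
    species: str
    level: str
    degree: int
    d_prime: float
    effective_partners: float
    species_strength: float


def species_indices(matrix: InteractionMatrix, level: str = "beetle") -> pd.DataFrame:
    """Species-level indices for one trophic level.

    degree
        number of realized partner species;
    d_prime
        standardized Kullback-Leibler specialization in [0, 1];
    effective_partners
        exp(Shannon entropy) of the species' interaction frequencies —
        the number of equally-used partners;
    species_strength
        sum over the species' partners of the partner's proportional
        dependence on it (each partner's dependencies sum to 1 across
        the focal level, so strengths at one level sum to the number of
        partner-level species).
    """
    if level == "host":
        M = matrix.A
        labels = matrix.hosts
    else:
        M = matrix.A.T
        labels = matrix.beetles
    availability = M.sum(axis=0)  # partner-level totals
    partner_totals = availability.astype(float)
    rows = []
    for i, sp in enumerate(labels):
        v = M[i].astype(float)
        total = v.sum()
        degree = int(np.count_nonzero(v))
        p = v[v > 0] / total
        eff = float(np.exp(-(p * np.log(p)).sum()))
        strength = float((v / partner_totals).sum())
        rows.append(
            SpeciesIndexRow(
                species=sp,
                level=level,
                degree=degree,
                d_prime=_d_prime(v, availability),
                effective_partners=eff,
                species_strength=strength,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# bundled network structure


@dataclass
class NetworkStructure:
    """All network-level statistics of one treatment's matrix."""

    n_hosts: int
    n_beetles: int
    network_size: int
    m: int
    wnodf: float
    Q: float
    partition: dict[str, np.ndarray]
    h2: float
    niche_overlap_hosts: float
    niche_overlap_beetles: float


def network_structure(
    matrix: InteractionMatrix, *, n_trials: int = 20, seed: int | None = None
) -> NetworkStructure:
    partition, q = modularity_lp(matrix, n_trials=n_trials, seed=seed)
    return NetworkStructure(
        n_hosts=len(matrix.hosts),
        n_beetles=len(matrix.beetles),
        network_size=matrix.network_size,
        m=matrix.m,
        wnodf=wnodf(matrix),
        Q=q,
        partition=partition,
        h2=h2_prime(matrix),
        niche_overlap_hosts=niche_overlap(matrix, "host"),
        niche_overlap_beetles=niche_overlap(matrix, "beetle"),
    )
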