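"""Optimal alignment with at most one recombination between two paths.

A recombination is a switch from a prefix of one distinguished path to a
suffix of another, possibly through a "virtual" arc absent from the graph.
Its cost is affine in the *displacement*: anchor the junction (rho, psi) in
the smallest bubble containing it — bounded by the branching vertex alpha
(deepest vertex common to both paths preceding the junction) and the
consolidating vertex beta (shallowest common vertex following it) — and
measure how unbalanced the two bubble sides are:

    d_r = | |a1| - |a2| + 1 | + | |b1| - |b2| - 1 |

where a1 (alpha..rho on p1), a2 (alpha..psi on p2), b1 (rho..beta on p1)
and b2 (psi..beta on p2) are vertex counts inclusive of both endpoints.
The total recombination penalty is ``rec_open_penalty + d_r *
rec_ext_penalty``.

The search combines the forward matrix M (query prefix vs path prefix) and
backward matrix R (query suffix vs path suffix) of :mod:`.linear_dp`: for
every ordered pair of distinct paths, every junction (v, w) and every
breakpoint j inside the configured window, the candidate score is
``M[v, j, p1] + R[w, j, p2] - d_o - d_e * d_r(v, w)``, compared against the
best recombination-free alignment.  Iterating over path pairs (rather than
taking per-vertex argmax paths) keeps the optimum exact even though the
displacement term depends on which pair is chosen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph_model import CanonicalGraph, Walk
from .linear_dp import (
    NEG_INF,
    AlignmentRecord,
    DPState,
    Query,
    RecombinationEvent,
    ScoringScheme,
    _traceback_backward,
    _traceback_forward,
    align_no_recombination,
    backward_matrix,
    forward_matrix,
)

__all__ = [
    "DisplacementTable",
    "build_displacement_table",
    "displacement",
    "align_with_recombination",
    "enforce_distinct_paths",
    "breakpoint_window_bounds",
]

_BIG = np.iinfo(np.int64).max // 4


@dataclass
class _PairIndex:
    """Parallel-scan index for one ordered pair of paths.

    ``pos1``/``pos2``: vertex -> position in the full vertex sequence
    (source = 0, sink = last).  ``shared`` lists the common vertices, which
    occur in the same relative order on both paths (the graph is acyclic);
    ``spos1``/``spos2`` are their positions.  ``sb*``/``sa*`` give, for
    every position, the index in ``shared`` of the nearest common vertex
    at-or-before / at-or-after that position.
    """

    shared: list[int]
    spos1: np.ndarray
    spos2: np.ndarray
    sb1: np.ndarray
    sa1: np.ndarray
    sb2: np.ndarray
    sa2: np.ndarray

    def anchors(self, i1: int, i2: int) -> tuple[int, int]:
        """Shared-list indices of (alpha, beta) for rho at i1, psi at i2.

        alpha must strictly precede both junction vertices; when none does
        (a junction at the source) it falls back to the source itself, and
        symmetrically for beta at the sink.
        """
        a = min(self.sb1[i1 - 1] if i1 > 0 else -1, self.sb2[i2 - 1] if i2 > 0 else -1)
        if a < 0:
            a = 0
        last = len(self.shared) - 1
        b1 = self.sa1[i1 + 1] if i1 + 1 < len(self.sa1) else _BIG
        b2 = self.sa2[i2 + 1] if i2 + 1 < len(self.sa2) else _BIG
        b = max(b1, b2)
        if b > last:
            b = last
        return int(a), int(b)


def _nearest_shared(path: list[int], shared_set: dict[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(at-or-before, at-or-after) shared-index arrays over path positions."""
    L = len(path)
    sb = np.empty(L, dtype=np.int64)
    sa = np.empty(L, dtype=np.int64)
    cur = -1
    for i, v in enumerate(path):
        if v in shared_set:
            cur = shared_set[v]
        sb[i] = cur
    cur = _BIG
    for i in range(L - 1, -1, -1):
        if path[i] in shared_set:
            cur = shared_set[path[i]]
        sa[i] = cur
    return sb, sa


@dataclass
class DisplacementTable:
    """O(1) bubble-anchor and displacement queries for all ordered path pairs."""

    graph: CanonicalGraph
    pairs: dict[tuple[str, str], _PairIndex]
    positions: dict[str, dict[int, int]]

    def pair(self, p1: str, p2: str) -> _PairIndex:
        return self.pairs[(p1, p2)]

    def displacement_matrix(self, p1: str, p2: str) -> np.ndarray:
        """d_r for every (position-on-p1, position-on-p2) junction, vectorised."""
        px = self.pairs[(p1, p2)]
        L1, L2 = len(px.sb1), len(px.sb2)
        i1 = np.arange(L1)[:, None]
        i2 = np.arange(L2)[None, :]
        sb1m = np.concatenate(([-1], px.sb1[:-1]))[:, None]
        sb2m = np.concatenate(([-1], px.sb2[:-1]))[None, :]
        A = np.maximum(np.minimum(sb1m, sb2m), 0)
        sa1p = np.concatenate((px.sa1[1:], [_BIG]))[:, None]
        sa2p = np.concatenate((px.sa2[1:], [_BIG]))[None, :]
        B = np.minimum(np.maximum(sa1p, sa2p), len(px.shared) - 1)
        a1 = i1 - px.spos1[A] + 1
        a2 = i2 - px.spos2[A] + 1
        b1 = px.spos1[B] - i1 + 1
        b2 = px.spos2[B] - i2 + 1
        return np.abs(a1 - a2 + 1) + np.abs(b1 - b2 - 1)


def build_displacement_table(g: CanonicalGraph) -> DisplacementTable:
    """One linear parallel scan per ordered pair of distinct paths."""
    positions = {name: {v: i for i, v in enumerate(p)} for name, p in g.paths.items()}
    pairs: dict[tuple[str, str], _PairIndex] = {}
    names = list(g.paths)
    for n1 in names:
        p1 = g.paths[n1]
        for n2 in names:
            if n1 == n2:
                continue
            p2 = g.paths[n2]
            in2 = positions[n2]
            shared = [v for v in p1 if v in in2]
            shared_set = {v: k for k, v in enumerate(shared)}
            spos1 = np.array([positions[n1][v] for v in shared], dtype=np.int64)
            spos2 = np.array([in2[v] for v in shared], dtype=np.int64)
            sb1, sa1 = _nearest_shared(p1, shared_set)
            sb2, sa2 = _nearest_shared(p2, shared_set)
            pairs[(n1, n2)] = _PairIndex(shared, spos1, spos2, sb1, sa1, sb2, sa2)
    return DisplacementTable(g, pairs, positions)


def displacement(tab: DisplacementTable, p1: str, p2: str, rho: int, psi: int) -> tuple[int, int, int]:
    """(alpha, beta, d_r) for the recombination (p1, p2, rho, psi)."""
    if p1 == p2:
        raise ValueError("a recombination needs two different paths")
    if rho not in tab.positions[p1]:
        raise ValueError(f"rho={rho} is not on path {p1!r}")
    if psi not in tab.positions[p2]:
        raise ValueError(f"psi={psi} is not on path {p2!r}")
    px = tab.pairs[(p1, p2)]
    i1 = tab.positions[p1][rho]
    i2 = tab.positions[p2][psi]
    a, b = px.anchors(i1, i2)
    a1 = i1 - px.spos1[a] + 1
    a2 = i2 - px.spos2[a] + 1
    b1 = px.spos1[b] - i1 + 1
    b2 = px.spos2[b] - i2 + 1
    dr = abs(int(a1) - int(a2) + 1) + abs(int(b1) - int(b2) - 1)
    return px.shared[a], px.shared[b], dr


def breakpoint_window_bounds(n: int, window: float) -> tuple[int, int]:
    """Inclusive bounds on the breakpoint j for a query of length n.

    ``window`` = 0.95 keeps j within the middle 95% of the sequence;
    ``window`` = 1 allows any split 0..n.
    """
    lo = math.ceil(n * (1.0 - window) / 2.0)
    hi = math.floor(n * (1.0 + window) / 2.0)
    return lo, hi


def enforce_distinct_paths(state: DPState, v: int, w: int, j: int) -> tuple[str | None, str | None, float]:
    """Best combined M[v,j,p] + R[w,j,q] over path pairs with p != q.

    Uses the per-vertex best / second-best summaries: if the two argmax
    paths coincide, the optimum with distinct paths swaps one side to its
    runner-up.  Returns (None, None, -inf) when no distinct pair exists.
    """
    names = list(state.graph.paths)
    bm, bm_p = state.bestM[v][j], int(state.bestM_path[v][j])
    sm, sm_p = state.best2M[v][j], int(state.best2M_path[v][j])
    br, br_p = state.bestR[w][j], int(state.bestR_path[w][j])
    sr, sr_p = state.best2R[w][j], int(state.best2R_path[w][j])
    if bm_p < 0 or br_p < 0:
        return None, None, NEG_INF
    if bm_p != br_p:
        return names[bm_p], names[br_p], float(bm + br)
    cands = []
    if sm_p >= 0:
        cands.append((float(sm + br), sm_p, br_p))
    if sr_p >= 0:
        cands.append((float(bm + sr), bm_p, sr_p))
    if not cands:
        return None, None, NEG_INF
    score, pi, qi = max(cands, key=lambda c: c[0])
    return names[pi], names[qi], score


def _m_rowmap(k: int) -> np.ndarray:
    # path position (0=source .. k+1=sink) -> forward-table row
    return np.concatenate((np.arange(k + 1), [k]))


def _r_rowmap(k: int) -> np.ndarray:
    # path position -> backward-table row (suffix starting at that vertex)
    return np.concatenate(([0], np.arange(k + 1)))


def align_with_recombination(
    g: CanonicalGraph,
    q: Query,
    sc: ScoringScheme,
    state: DPState | None = None,
    table: DisplacementTable | None = None,
) -> AlignmentRecord:
    """Optimal global alignment allowing at most one recombination.

    Returns the recombination-free optimum whenever it is at least as good
    (so an exact tie is resolved in favour of parsimony).  Among equal
    recombination candidates the tie-break is: smallest breakpoint j, then
    smallest (v, w) in topological order, then path-pair order.
    """
    if state is None:
        state = forward_matrix(g, q, sc)
        backward_matrix(g, q, sc, state)
    elif not state.R:
        backward_matrix(g, q, sc, state)
    if table is None:
        table = build_displacement_table(g)
    n = len(q)
    norec = align_no_recombination(g, q, sc, state)
    if len(g.paths) < 2:
        return norec

    lo, hi = breakpoint_window_bounds(n, sc.breakpoint_window)
    js = np.arange(lo, hi + 1)
    names = list(g.paths)
    d_o, d_e = sc.rec_open_penalty, sc.rec_ext_penalty

    best = NEG_INF
    pair_data = {}
    chunk = 32
    for i1, n1 in enumerate(names):
        for i2, n2 in enumerate(names):
            if n1 == n2:
                continue
            k1 = len(state.labelled(n1))
            k2 = len(state.labelled(n2))
            P = state.M[n1][_m_rowmap(k1)][:, js]
            S = state.R[n2][_r_rowmap(k2)][:, js]
            D = (d_e * table.displacement_matrix(n1, n2))[:, :, None]
            permax = np.empty(len(js))
            for c in range(0, len(js), chunk):
                block = P[:, None, c : c + chunk] + S[None, :, c : c + chunk] - d_o - D
                permax[c : c + chunk] = block.max(axis=(0, 1))
            pair_data[(n1, n2)] = (P, S, D[:, :, 0], permax)
            m = permax.max()
            if m > best:
                best = m
    if not math.isfinite(best) or norec.score >= best:
        return norec

    # locate the optima (only where the per-(pair, j) maximum reaches the
    # global best) and keep the deterministic tie-break winner
    winner = None
    for (n1, n2), (P, S, D, permax) in pair_data.items():
        i1, i2 = names.index(n1), names.index(n2)
        p1_seq, p2_seq = g.paths[n1], g.paths[n2]
        for jx in np.nonzero(permax == best)[0]:
            cand = (P[:, jx][:, None] + S[:, jx][None, :]) - d_o - D
            for a, b in zip(*np.nonzero(cand == best)):
                v, w = p1_seq[a], p2_seq[b]
                key = (int(js[jx]), v, w, i1, i2)
                if winner is None or key < winner[0]:
                    winner = (key, n1, n2, int(a), int(b))
    (j, v, w, _, _), n1, n2, pos1, pos2 = winner
    return _build_recombinant_record(g, q, sc, state, table, n1, n2, pos1, pos2, j, float(best))


def _build_recombinant_record(
    g: CanonicalGraph,
    q: Query,
    sc: ScoringScheme,
    state: DPState,
    table: DisplacementTable,
    n1: str,
    n2: str,
    pos1: int,
    pos2: int,
    j: int,
    score: float,
) -> AlignmentRecord:
    p1_seq, p2_seq = g.paths[n1], g.paths[n2]
    v, w = p1_seq[pos1], p2_seq[pos2]
    alpha, beta, dr = displacement(table, n1, n2, v, w)
    px = table.pairs[(n1, n2)]
    a_idx, b_idx = px.anchors(pos1, pos2)
    ev = RecombinationEvent(
        p1=n1,
        p2=n2,
        rho=v,
        psi=w,
        alpha=alpha,
        beta=beta,
        a1_len=pos1 - int(px.spos1[a_idx]) + 1,
        a2_len=pos2 - int(px.spos2[a_idx]) + 1,
        b1_len=int(px.spos1[b_idx]) - pos1 + 1,
        b2_len=int(px.spos2[b_idx]) - pos2 + 1,
        displacement=dr,
        breakpoint=j,
    )
    k1, k2 = len(p1_seq) - 2, len(p2_seq) - 2
    t_end = min(pos1, k1)  # forward-table row of v (sink maps to last row)
    t_start = max(pos2 - 1, 0)  # backward-table row of w
    labelled1 = p1_seq[1:-1]
    labelled2 = p2_seq[1:-1]
    pre = _traceback_forward(state.M[n1], labelled1, q.sequence, sc, t_end, j, g.vertices)
    suf = _traceback_backward(state.R[n2], labelled2, q.sequence, sc, t_start, j, g.vertices)
    walk_vertices = p1_seq[: pos1 + 1] + p2_seq[pos2:]
    virtual = None if (v, w) in g.arcs else pos1
    walk = Walk(walk_vertices, virtual_arc_index=virtual)
    return AlignmentRecord(q, walk, (n1, n2), pre + suf, score, recombination=ev)
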