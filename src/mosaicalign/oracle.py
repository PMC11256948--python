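"""Brute-force reference implementations, kept independent of the DP modules.

These are deliberately plain reimplementations — cell-by-cell
Needleman-Wunsch in pure Python, bubble anchors by direct set-intersection
scans, and recombination search by exhaustive enumeration over path pairs,
junction vertices and breakpoints.  They share no alignment code with
:mod:`.linear_dp` / :mod:`.recombination_dp` and exist to cross-check them
on small instances (guards refuse anything large).
"""

from __future__ import annotations

import numpy as np

from .graph_model import CanonicalGraph, spell_path
from .linear_dp import Query, ScoringScheme
from .recombination_dp import breakpoint_window_bounds

__all__ = [
    "nw_global",
    "nw_matrix",
    "brute_force_recombination",
    "naive_alpha_beta_displacement",
]


def nw_matrix(a: str, b: str, sc: ScoringScheme) -> list[list[float]]:
    """Full global-alignment table of a (rows) vs b (columns), linear gaps."""
    g = sc.gap_penalty
    m, mm = sc.match_score, sc.mismatch_penalty
    rows = [[0.0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for j in range(1, len(b) + 1):
        rows[0][j] = rows[0][j - 1] - g
    for i in range(1, len(a) + 1):
        prev, cur = rows[i - 1], rows[i]
        cur[0] = prev[0] - g
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            diag = prev[j - 1] + (m if ai == b[j - 1] else -mm)
            up = prev[j] - g
            left = cur[j - 1] - g
            cur[j] = diag if diag >= up and diag >= left else (up if up >= left else left)
    return rows


def nw_global(a: str, b: str, sc: ScoringScheme) -> float:
    """Textbook global alignment score of two strings."""
    return nw_matrix(a, b, sc)[-1][-1]


def naive_alpha_beta_displacement(
    g: CanonicalGraph, p1: str, p2: str, rho: int, psi: int
) -> tuple[int, int, int]:
    """(alpha, beta, d_r) by direct scanning of the two vertex sequences."""
    if p1 == p2:
        raise ValueError("a recombination needs two different paths")
    seq1, seq2 = g.paths[p1], g.paths[p2]
    if rho not in seq1:
        raise ValueError(f"rho={rho} is not on path {p1!r}")
    if psi not in seq2:
        raise ValueError(f"psi={psi} is not on path {p2!r}")
    i1, i2 = seq1.index(rho), seq2.index(psi)
    common = set(seq1) & set(seq2)
    alpha = g.source
    for v in seq1:
        if v in common and seq1.index(v) < i1 and seq2.index(v) < i2:
            alpha = v
    beta = g.sink
    for v in reversed(seq1):
        if v in common and seq1.index(v) > i1 and seq2.index(v) > i2:
            beta = v
    a1 = i1 - seq1.index(alpha) + 1
    a2 = i2 - seq2.index(alpha) + 1
    b1 = seq1.index(beta) - i1 + 1
    b2 = seq2.index(beta) - i2 + 1
    return alpha, beta, abs(a1 - a2 + 1) + abs(b1 - b2 - 1)


def _pair_displacements(g: CanonicalGraph, n1: str, n2: str) -> np.ndarray:
    """Displacement for every junction position pair on (n1, n2).

    Precomputes, by explicit scans, the nearest common vertex before/after
    each position, then applies the displacement formula cell by cell.
    Spot-checked against :func:`naive_alpha_beta_displacement` by callers.
    """
    seq1, seq2 = g.paths[n1], g.paths[n2]
    pos2 = {v: i for i, v in enumerate(seq2)}
    common = [v for v in seq1 if v in pos2]
    cidx = {v: c for c, v in enumerate(common)}
    cpos1 = [i for i, v in enumerate(seq1) if v in cidx]
    cpos2 = [pos2[v] for v in common]

    def before_after(seq: list[int]) -> tuple[list[int], list[int]]:
        nb, na = [], []
        cur = -1
        for v in seq:
            if v in cidx:
                cur = cidx[v]
            nb.append(cur)
        cur = len(common)
        for v in reversed(seq):
            if v in cidx:
                cur = cidx[v]
            na.append(cur)
        na.reverse()
        return nb, na

    nb1, na1 = before_after(seq1)
    nb2, na2 = before_after(seq2)
    last = len(common) - 1
    D = np.empty((len(seq1), len(seq2)))
    for a in range(len(seq1)):
        strictly_before_a = nb1[a - 1] if a > 0 else -1
        strictly_after_a = na1[a + 1] if a + 1 < len(seq1) else len(common)
        for b in range(len(seq2)):
            ac = min(strictly_before_a, nb2[b - 1] if b > 0 else -1)
            if ac < 0:
                ac = 0
            bc = max(strictly_after_a, na2[b + 1] if b + 1 < len(seq2) else len(common))
            if bc > last:
                bc = last
            a1 = a - cpos1[ac] + 1
            a2 = b - cpos2[ac] + 1
            b1 = cpos1[bc] - a + 1
            b2 = cpos2[bc] - b + 1
            D[a, b] = abs(a1 - a2 + 1) + abs(b1 - b2 - 1)
    return D


def _suffix_matrix(path_str: str, query: str, sc: ScoringScheme) -> np.ndarray:
    """suffix[t, i] = nw score of path_str[t:] vs query[i:], via reversal."""
    rev = nw_matrix(path_str[::-1], query[::-1], sc)
    k, n = len(path_str), len(query)
    out = np.empty((k + 1, n + 1))
    for t in range(k + 1):
        for i in range(n + 1):
            out[t, i] = rev[k - t][n - i]
    return out


def brute_force_recombination(
    g: CanonicalGraph, q: Query, sc: ScoringScheme
) -> tuple[float, set[tuple[str, str, int]]]:
    """Exhaustive optimum over all distinct path pairs, junctions and breakpoints.

    Returns the optimal score and, when a recombination wins, the tie-set of
    (p1, p2, j) triples achieving it; the tie-set is empty when the
    recombination-free optimum is at least as good.
    """
    if len(g.paths) > 8 or len(q) > 100:
        raise ValueError("oracle guard: instance too large for brute force")
    s = q.sequence
    n = len(s)
    spelled = {name: spell_path(g, p[1:-1]) for name, p in g.paths.items()}
    best_norec = max(nw_global(spelled[name], s, sc) for name in g.paths)

    prefix = {name: np.array(nw_matrix(spelled[name], s, sc)) for name in g.paths}
    suffix = {name: _suffix_matrix(spelled[name], s, sc) for name in g.paths}
    lo, hi = breakpoint_window_bounds(n, sc.breakpoint_window)
    d_o, d_e = sc.rec_open_penalty, sc.rec_ext_penalty

    best_rec = float("-inf")
    ties: set[tuple[str, str, int]] = set()
    for n1 in g.paths:
        seq1 = g.paths[n1]
        k1 = len(seq1) - 2
        # forward-table row for each position on the path (sink = last row)
        rows1 = list(range(k1 + 1)) + [k1]
        for n2 in g.paths:
            if n1 == n2:
                continue
            seq2 = g.paths[n2]
            k2 = len(seq2) - 2
            rows2 = [0] + list(range(k2 + 1))
            D = _pair_displacements(g, n1, n2)
            # spot-check the tabulated displacements against the direct scan
            rng = np.random.default_rng(len(seq1) * 1000 + len(seq2))
            for _ in range(3):
                a = int(rng.integers(len(seq1)))
                b = int(rng.integers(len(seq2)))
                assert D[a, b] == naive_alpha_beta_displacement(g, n1, n2, seq1[a], seq2[b])[2]
            P = prefix[n1][rows1]
            S = suffix[n2][rows2]
            for j in range(lo, hi + 1):
                cand = (P[:, j][:, None] + S[:, j][None, :]) - d_o - d_e * D
                m = cand.max()
                if m > best_rec:
                    best_rec = m
                    ties = set()
                if m == best_rec:
                    ties.add((n1, n2, j))
    if best_norec >= best_rec:
        return best_norec, set()
    return float(best_rec), ties
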