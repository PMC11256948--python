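"""Global alignment of a query against the distinguished paths of a graph.

Because every distinguished path of a canonical variation graph visits a
vertex at most once, the 3-D table M[v, i, p] factorises into one dense
(|p|+1) x (n+1) Needleman-Wunsch table per path: row t holds the optimal
score of aligning the t-character prefix of the path's spelling against
each query prefix.  The backward table R mirrors this for path/query
suffixes; combining a column of M with a column of R is what lets the
recombination pass place a breakpoint (see :mod:`.recombination_dp`).

Scoring convention: ``match_score`` is added for a match; mismatch and gap
penalties are stored as nonnegative magnitudes and subtracted.  Gaps are
linear (cost ``gap_penalty`` per gap column).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_model import CanonicalGraph, Walk, spell_path

__all__ = [
    "ScoringScheme",
    "Query",
    "DPState",
    "AlignmentRecord",
    "RecombinationEvent",
    "forward_matrix",
    "backward_matrix",
    "align_no_recombination",
    "rescore_alignment",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ScoringScheme:
    """Scores and penalties for recombination-aware global alignment.

    All penalty fields are nonnegative magnitudes.  ``rec_open_penalty``
    (d_o) is charged once per recombination and ``rec_ext_penalty`` (d_e)
    once per unit of displacement, giving the affine recombination cost
    d_o + d_r * d_e.  ``breakpoint_window`` is the centred fraction of the
    query within which a breakpoint may be placed (0.95 = middle 95%).
    """

    match_score: float = 2.0
    mismatch_penalty: float = 4.0
    gap_penalty: float = 4.0
    rec_open_penalty: float = 4.0
    rec_ext_penalty: float = 0.1
    breakpoint_window: float = 0.95

    def __post_init__(self) -> None:
        for name in ("mismatch_penalty", "gap_penalty", "rec_open_penalty", "rec_ext_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a nonnegative magnitude")
        if not 0.0 < self.breakpoint_window <= 1.0:
            raise ValueError("breakpoint_window must lie in (0, 1]")


@dataclass(frozen=True)
class Query:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"query {self.name!r} is empty")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RecombinationEvent:
    """A path switch (p1, p2, rho, psi) with its bubble anchors and penalty.

    ``alpha``/``beta`` are the branching and consolidating vertices (the
    boundaries of the smallest bubble containing the junction); the a/b
    lengths count vertices inclusive of both endpoints; ``displacement`` is
    \\|\\|a1|-|a2|+1\\| + \\|\\|b1|-|b2|-1\\|.  ``breakpoint`` is the 0-based query
    coordinate j splitting prefix s[:j] from suffix s[j:].
    """

    p1: str
    p2: str
    rho: int
    psi: int
    alpha: int
    beta: int
    a1_len: int
    a2_len: int
    b1_len: int
    b2_len: int
    displacement: int
    breakpoint: int


@dataclass
class AlignmentRecord:
    """A (possibly mosaic) global alignment of a query to the graph.

    ``columns`` are ordered pairs (vertex-id or None, query index or None);
    indices are 0-based and each labelled walk vertex / query position
    occurs exactly once.  ``walk`` is the full source-to-sink vertex
    sequence the query is aligned to (a distinguished path, or the
    concatenation of two path portions joined at the recombination
    junction — in which case the junction pair is the walk's declared
    virtual arc, possibly ``(v, v)``).
    """

    query: Query
    walk: Walk
    path_names: tuple[str, ...]
    columns: list[tuple[int | None, int | None]]
    score: float
    recombination: RecombinationEvent | None = None


@dataclass
class DPState:
    """Per-path forward/backward matrices plus per-vertex best summaries.

    ``M[p][t, i]``: score of aligning the t-char path prefix vs s[:i].
    ``R[p][t, i]``: score of aligning the path suffix starting at 0-based
    labelled position t vs s[i:].
    ``row_of[p]`` maps vertex id -> labelled 1-based position on path p.
    The best/second summaries (filled alongside the matrices) give, per
    (vertex, i), the top score over paths through that vertex and the best
    score over any *different* path — needed to force the two halves of a
    mosaic onto distinct paths.
    """

    graph: CanonicalGraph
    query: Query
    scoring: ScoringScheme
    M: dict[str, np.ndarray] = field(default_factory=dict)
    R: dict[str, np.ndarray] = field(default_factory=dict)
    row_of: dict[str, dict[int, int]] = field(default_factory=dict)
    bestM: dict[int, np.ndarray] = field(default_factory=dict)
    bestM_path: dict[int, np.ndarray] = field(default_factory=dict)
    best2M: dict[int, np.ndarray] = field(default_factory=dict)
    best2M_path: dict[int, np.ndarray] = field(default_factory=dict)
    bestR: dict[int, np.ndarray] = field(default_factory=dict)
    bestR_path: dict[int, np.ndarray] = field(default_factory=dict)
    best2R: dict[int, np.ndarray] = field(default_factory=dict)
    best2R_path: dict[int, np.ndarray] = field(default_factory=dict)

    def labelled(self, pname: str) -> list[int]:
        p = self.graph.paths[pname]
        return p[1:-1]

    def m_cell(self, v: int, i: int, pname: str) -> float:
        """M[v, i, p]: -inf when v is not on p."""
        g = self.graph
        if v == g.source:
            t = 0
        elif v == g.sink:
            t = len(self.labelled(pname))
        else:
            t = self.row_of[pname].get(v)
            if t is None:
                return NEG_INF
        return float(self.M[pname][t, i])

    def r_cell(self, v: int, i: int, pname: str) -> float:
        """R[v, i, p]: score of aligning the suffix of p starting at v vs s[i:]."""
        g = self.graph
        k = len(self.labelled(pname))
        if v == g.source:
            t = 0
        elif v == g.sink:
            t = k
        else:
            t = self.row_of[pname].get(v)
            if t is None:
                return NEG_INF
            t -= 1
        return float(self.R[pname][t, i])


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)


def _substitution_rows(path_chars: np.ndarray, query_chars: np.ndarray, sc: ScoringScheme) -> np.ndarray:
    """sub[t, i] = score of pairing path char t with query char i."""
    eq = path_chars[:, None] == query_chars[None, :]
    return np.where(eq, sc.match_score, -sc.mismatch_penalty)


def _fill_forward(path_str: str, query: str, sc: ScoringScheme) -> np.ndarray:
    """Needleman-Wunsch table (k+1) x (n+1), linear gaps, prefix semantics."""
    k, n = len(path_str), len(query)
    g = sc.gap_penalty
    sub = _substitution_rows(_encode(path_str), _encode(query), sc)
    M = np.empty((k + 1, n + 1), dtype=np.float64)
    idx = np.arange(n + 1, dtype=np.float64)
    M[0] = -g * idx
    for t in range(1, k + 1):
        cand = np.empty(n + 1)
        cand[0] = -g * t
        # consume the path char (query gap) or pair it with s[i]
        cand[1:] = np.maximum(M[t - 1, 1:] - g, M[t - 1, :-1] + sub[t - 1])
        # query-gap chains: M[t,i] = max(cand[i], M[t,i-1] - g), as a prefix max
        M[t] = np.maximum.accumulate(cand + g * idx) - g * idx
    return M


def _fill_backward(path_str: str, query: str, sc: ScoringScheme) -> np.ndarray:
    """Suffix table (k+1) x (n+1): R[t, i] aligns path_str[t:] vs query[i:]."""
    k, n = len(path_str), len(query)
    g = sc.gap_penalty
    sub = _substitution_rows(_encode(path_str), _encode(query), sc)
    R = np.empty((k + 1, n + 1), dtype=np.float64)
    idx = np.arange(n + 1, dtype=np.float64)
    rev = n - idx
    R[k] = -g * rev
    for t in range(k - 1, -1, -1):
        cand = np.empty(n + 1)
        cand[n] = -g * (k - t)
        cand[:-1] = np.maximum(R[t + 1, :-1] - g, R[t + 1, 1:] + sub[t])
        acc = cand + g * rev
        R[t] = np.maximum.accumulate(acc[::-1])[::-1] - g * rev
    return R


def forward_matrix(g: CanonicalGraph, q: Query, sc: ScoringScheme, state: DPState | None = None) -> DPState:
    """Fill the forward tables M for every distinguished path."""
    state = state or DPState(g, q, sc)
    for pname, p in g.paths.items():
        labelled = p[1:-1]
        state.row_of.setdefault(pname, {v: t + 1 for t, v in enumerate(labelled)})
        state.M[pname] = _fill_forward(spell_path(g, labelled), q.sequence, sc)
    _summarize(state, forward=True)
    return state


def backward_matrix(g: CanonicalGraph, q: Query, sc: ScoringScheme, state: DPState | None = None) -> DPState:
    """Fill the backward tables R (suffix alignment) for every path."""
    state = state or DPState(g, q, sc)
    for pname, p in g.paths.items():
        labelled = p[1:-1]
        state.row_of.setdefault(pname, {v: t + 1 for t, v in enumerate(labelled)})
        state.R[pname] = _fill_backward(spell_path(g, labelled), q.sequence, sc)
    _summarize(state, forward=False)
    return state


def _summarize(state: DPState, forward: bool) -> None:
    """Per-(vertex, i) best and second-best (distinct-path) score summaries."""
    g = state.graph
    n = len(state.query)
    names = list(g.paths)
    if forward:
        best, bpath = state.bestM, state.bestM_path
        second, spath = state.best2M, state.best2M_path
    else:
        best, bpath = state.bestR, state.bestR_path
        second, spath = state.best2R, state.best2R_path
    for v in g.vertices:
        best[v] = np.full(n + 1, NEG_INF)
        bpath[v] = np.full(n + 1, -1, dtype=np.int64)
        second[v] = np.full(n + 1, NEG_INF)
        spath[v] = np.full(n + 1, -1, dtype=np.int64)
    def row_index(pname: str, v: int) -> int:
        k = len(state.labelled(pname))
        if v == g.source:
            return 0
        if v == g.sink:
            return k
        t = state.row_of[pname][v]
        return t if forward else t - 1

    # first pass: best path per (vertex, position)
    for pi, pname in enumerate(names):
        table = state.M[pname] if forward else state.R[pname]
        for v in state.graph.paths[pname]:
            col = table[row_index(pname, v)]
            better = col > best[v]
            best[v] = np.where(better, col, best[v])
            bpath[v] = np.where(better, pi, bpath[v])
    # second pass: best over paths different from the argmax path
    for pi, pname in enumerate(names):
        table = state.M[pname] if forward else state.R[pname]
        for v in state.graph.paths[pname]:
            col = table[row_index(pname, v)]
            upd = (bpath[v] != pi) & (col > second[v])
            second[v] = np.where(upd, col, second[v])
            spath[v] = np.where(upd, pi, spath[v])


def _traceback_forward(M: np.ndarray, path_vids: list[int], query: str, sc: ScoringScheme, t_end: int, i_end: int, labels: dict[int, str]) -> list[tuple[int | None, int | None]]:
    """Columns of an optimal alignment of path_vids[:t_end] vs query[:i_end].

    Tie-break: prefer the diagonal (match/mismatch), then consuming the path
    vertex, then consuming the query character — deterministic output.
    """
    g = sc.gap_penalty
    cols: list[tuple[int | None, int | None]] = []
    t, i = t_end, i_end
    while t > 0 or i > 0:
        here = M[t, i]
        if t > 0 and i > 0:
            sub = sc.match_score if labels[path_vids[t - 1]] == query[i - 1] else -sc.mismatch_penalty
            if here == M[t - 1, i - 1] + sub:
                cols.append((path_vids[t - 1], i - 1))
                t, i = t - 1, i - 1
                continue
        if t > 0 and here == M[t - 1, i] - g:
            cols.append((path_vids[t - 1], None))
            t -= 1
            continue
        cols.append((None, i - 1))
        i -= 1
    cols.reverse()
    return cols


def _traceback_backward(R: np.ndarray, path_vids: list[int], query: str, sc: ScoringScheme, t_start: int, i_start: int, labels: dict[int, str]) -> list[tuple[int | None, int | None]]:
    """Columns aligning path_vids[t_start:] vs query[i_start:] (forward order)."""
    g = sc.gap_penalty
    k, n = len(path_vids), len(query)
    cols: list[tuple[int | None, int | None]] = []
    t, i = t_start, i_start
    while t < k or i < n:
        here = R[t, i]
        if t < k and i < n:
            sub = sc.match_score if labels[path_vids[t]] == query[i] else -sc.mismatch_penalty
            if here == R[t + 1, i + 1] + sub:
                cols.append((path_vids[t], i))
                t, i = t + 1, i + 1
                continue
        if t < k and here == R[t + 1, i] - g:
            cols.append((path_vids[t], None))
            t += 1
            continue
        cols.append((None, i))
        i += 1
    return cols


def align_no_recombination(g: CanonicalGraph, q: Query, sc: ScoringScheme, state: DPState | None = None) -> AlignmentRecord:
    """Optimal global alignment of q against the best single distinguished path.

    Among equal-scoring paths the first in the graph's path order wins.
    """
    if state is None or not state.M:
        state = forward_matrix(g, q, sc, state)
    n = len(q)
    best_name, best_score = None, NEG_INF
    for pname in g.paths:
        s = state.M[pname][-1, n]
        if s > best_score:
            best_name, best_score = pname, s
    labelled = state.labelled(best_name)
    cols = _traceback_forward(state.M[best_name], labelled, q.sequence, sc, len(labelled), n, g.vertices)
    walk = Walk(list(g.paths[best_name]))
    return AlignmentRecord(q, walk, (best_name,), cols, float(best_score))


def rescore_alignment(a: AlignmentRecord, g: CanonicalGraph, q: Query, sc: ScoringScheme) -> float:
    """Re-evaluate an alignment from its columns (independent of the DP score).

    Sums substitution scores over non-gap columns and a linear penalty over
    maximal gap runs.  Validates the column monotonicity/coverage rules.
    """
    labelled_walk = [v for v in a.walk.vertices if v not in (g.source, g.sink)]
    pos_in_walk: dict[int, list[int]] = {}
    for i, v in enumerate(labelled_walk):
        pos_in_walk.setdefault(v, []).append(i)
    seen_x = -1
    seen_y = -1
    n_x = 0
    n_y = 0
    total = 0.0
    in_gap = False
    walk_iter = 0
    for x, y in a.columns:
        if x is None and y is None:
            raise ValueError("column with two gaps")
        if y is not None:
            if y != seen_y + 1:
                raise ValueError("query positions not consecutive")
            seen_y = y
            n_y += 1
        if x is not None:
            if walk_iter >= len(labelled_walk) or labelled_walk[walk_iter] != x:
                raise ValueError("walk vertices not consumed in order")
            walk_iter += 1
            n_x += 1
        if x is None or y is None:
            if not in_gap:
                in_gap = True
            total -= sc.gap_penalty
        else:
            in_gap = False
            total += sc.match_score if g.vertices[x] == q.sequence[y] else -sc.mismatch_penalty
    if n_y != len(q) or walk_iter != len(labelled_walk):
        raise ValueError("alignment does not cover the query and walk exactly once")
    if a.recombination is not None:
        ev = a.recombination
        total -= sc.rec_open_penalty + sc.rec_ext_penalty * ev.displacement
    return total
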