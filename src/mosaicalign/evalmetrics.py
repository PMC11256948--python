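"""Alignment-accuracy metrics: node Jaccard, edit distance, path switches.

These quantify how well a computed alignment reproduces a known mosaic:
the Jaccard similarity between aligned and true vertex sets, the edit
distance between the query and the sequence spelled by the walk it was
aligned to, the minimum number of path switches needed to explain the
walk, and the breakpoint localisation error.
"""

from __future__ import annotations

import csv
import io

import edlib

from .graph_model import VariationGraph, Walk, spell_path
from .linear_dp import AlignmentRecord, Query
from .simgen import SimTruth

__all__ = [
    "jaccard_nodes",
    "aligned_node_set",
    "edit_distance_to_path",
    "min_switches",
    "breakpoint_error",
    "report_table",
]


def jaccard_nodes(true_nodes: set[int], aligned_nodes: set[int]) -> float:
    if not true_nodes and not aligned_nodes:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(true_nodes & aligned_nodes) / len(true_nodes | aligned_nodes)


def aligned_node_set(a: AlignmentRecord, g: VariationGraph) -> set[int]:
    """Labelled vertices of the walk the query was aligned to."""
    return {v for v in a.walk.vertices if v not in (g.source, g.sink)}


def edit_distance_to_path(q: Query, g: VariationGraph, walk: Walk | list[int]) -> int:
    """Levenshtein distance between the query and the walk's spelled sequence."""
    return edlib.align(q.sequence, spell_path(g, walk))["editDistance"]


def min_switches(walk: Walk | list[int], g: VariationGraph) -> int:
    """Minimum number of path switches explaining the walk.

    The walk must decompose into consecutive blocks, each a *contiguous*
    subpath of a single distinguished path; the result is the minimal block
    count minus one, found by a DP over (walk position x path).
    """
    vids = walk.vertices if isinstance(walk, Walk) else walk
    if not vids:
        return 0
    pos = {name: {v: i for i, v in enumerate(p)} for name, p in g.paths.items()}
    INF = float("inf")
    cost = {}
    for name in g.paths:
        cost[name] = 0 if vids[0] in pos[name] else INF
    if all(c == INF for c in cost.values()):
        raise ValueError(f"walk vertex {vids[0]} (position 0) lies on no distinguished path")
    for i in range(1, len(vids)):
        v_prev, v = vids[i - 1], vids[i]
        best_prev = min(cost.values())
        new = {}
        for name in g.paths:
            if v not in pos[name]:
                new[name] = INF
                continue
            stay = INF
            if v_prev in pos[name] and pos[name][v] == pos[name][v_prev] + 1:
                stay = cost[name]
            new[name] = min(stay, best_prev + 1)
        if all(c == INF for c in new.values()):
            raise ValueError(f"walk vertex {v} (position {i}) lies on no distinguished path")
        cost = new
    return int(min(cost.values()))


def breakpoint_error(reported: int | None, truth: SimTruth) -> int | None:
    """|reported - true| in bp; None marks a missed recombination."""
    if truth.breakpoint is None:
        raise ValueError("truth carries no recombination breakpoint")
    if reported is None:
        return None
    return abs(reported - truth.breakpoint)


def report_table(rows: list[dict]) -> str:
    """One TSV row per query: name, jaccard, edit_distance, n_switches, bp_error."""
    cols = ["query", "jaccard", "edit_distance", "n_switches", "breakpoint_error"]
    buf = io.StringIO()
    w = csv.DictWriter(buf, fieldnames=cols, delimiter="\t", extrasaction="ignore")
    w.writeheader()
    for r in rows:
        w.writerow(r)
    return buf.getvalue()
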