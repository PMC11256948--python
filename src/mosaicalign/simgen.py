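"""Synthetic variation graphs and recombinant queries for controlled studies.

The generator emulates a bacterial gene pangenome: a shared backbone
sequence interrupted by SNP and short-indel bubbles, spanned by a set of
labelled strain paths, from which recombinant queries are formed as a
prefix of one strain followed by a suffix of another.  Breakpoints are
drawn uniformly from a configurable central window (by default the middle
10–90% of the sequence), and point mutations can be sprinkled on top at a
configurable per-base rate.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .graph_model import CanonicalGraph, VariationGraph, canonicalize, spell_path

__all__ = [
    "SimTruth",
    "make_graph",
    "select_edge_cover_paths",
    "simulate_recombinant",
    "sample_identifiable_recombinant",
    "mutate",
    "mosaic_explanations",
]

_BASES = "ACGT"


@dataclass
class SimTruth:
    """Ground truth for one simulated query.

    ``breakpoint`` is the 0-based query coordinate of the junction (prefix
    from ``p1``, suffix from ``p2``); ``breakpoint_window`` is the inclusive
    range of query coordinates indistinguishable from it (the variant-free
    stretch over which the cut can slide without changing the sequence).
    ``mosaic_nodes`` are canonical labelled vertex ids of the true mosaic
    walk.  ``sequence_cut_fallback`` marks queries whose junction could not
    be anchored at a shared vertex; otherwise ``junction_vertex`` is the
    canonical id of the shared vertex the prefix ends at.
    """

    p1: str
    p2: str | None
    is_recombinant: bool
    breakpoint: int | None
    breakpoint_window: tuple[int, int] | None
    mosaic_nodes: set[int]
    mutation_positions: list[int] = field(default_factory=list)
    seed: int | None = None
    sequence_cut_fallback: bool = False
    junction_vertex: int | None = None

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["mosaic_nodes"] = sorted(self.mosaic_nodes)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        d["mosaic_nodes"] = set(d["mosaic_nodes"])
        if d.get("breakpoint_window") is not None:
            d["breakpoint_window"] = tuple(d["breakpoint_window"])
        return cls(**d)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def make_graph(
    n_paths: int,
    n_variant_sites: int,
    base_length: int,
    indel_fraction: float = 0.25,
    seed: int = 0,
    return_haplotypes: bool = False,
):
    """A backbone-with-bubbles variation graph spanned by ``n_paths`` strains.

    The backbone is split into ``n_variant_sites + 1`` nonempty chunks; at
    each junction a bubble is planted — a biallelic SNP, or (with
    probability ``indel_fraction``) a presence/absence indel of 1–3 bp.
    Each strain carries one allele per site; allele columns are
    non-constant, and strains get pairwise-distinct allele vectors whenever
    the site count allows it.
    """
    if n_paths < 2:
        raise ValueError("need at least two paths")
    if base_length < n_variant_sites + 1:
        raise ValueError("base_length too small: a variant site would get a zero-length chunk")
    rng = np.random.default_rng(seed)
    backbone = _random_seq(rng, base_length)
    cuts = sorted(rng.choice(np.arange(1, base_length), size=n_variant_sites, replace=False).tolist())
    chunks = []
    prev = 0
    for c in cuts + [base_length]:
        chunks.append(backbone[prev:c])
        prev = c

    # site alleles: list of (label0, label1); empty label means skip arc
    sites: list[tuple[str, str]] = []
    for _ in range(n_variant_sites):
        if rng.random() < indel_fraction:
            ins = _random_seq(rng, int(rng.integers(1, 4)))
            sites.append((ins, ""))
        else:
            a, b = rng.choice(4, size=2, replace=False)
            sites.append((_BASES[a], _BASES[b]))

    # allele matrix: non-constant columns, distinct rows where possible
    for _ in range(200):
        alleles = rng.integers(0, 2, size=(n_paths, n_variant_sites))
        ok = all(0 < alleles[:, s].sum() < n_paths for s in range(n_variant_sites))
        if ok and n_variant_sites > 0 and 2**n_variant_sites >= n_paths:
            ok = len({tuple(r) for r in alleles}) == n_paths
        if ok or n_variant_sites == 0:
            break

    vertices: dict[int, str] = {0: ""}
    segment_names: dict[int, str] = {}
    nid = 1

    def add(label: str, name: str) -> int:
        nonlocal nid
        vertices[nid] = label
        segment_names[nid] = name
        nid += 1
        return nid - 1

    chunk_ids = [add(chunks[i], f"c{i}") for i in range(len(chunks))]
    site_ids: list[dict[int, int | None]] = []
    for s, (lab0, lab1) in enumerate(sites):
        d: dict[int, int | None] = {0: add(lab0, f"s{s}a") if lab0 else None}
        d[1] = add(lab1, f"s{s}b") if lab1 else None
        site_ids.append(d)
    sink = nid
    vertices[sink] = ""

    arcs: set[tuple[int, int]] = set()
    paths: dict[str, list[int]] = {}
    haplotypes: dict[str, str] = {}
    for pidx in range(n_paths):
        name = f"strain{pidx:02d}"
        walk = [0, chunk_ids[0]]
        hap = [chunks[0]]
        for s in range(n_variant_sites):
            allele = int(alleles[pidx, s])
            vid = site_ids[s][allele]
            if vid is not None:
                walk.append(vid)
                hap.append(vertices[vid])
            walk.append(chunk_ids[s + 1])
            hap.append(chunks[s + 1])
        walk.append(sink)
        for u, v in zip(walk, walk[1:]):
            arcs.add((u, v))
        paths[name] = walk
        haplotypes[name] = "".join(hap)

    g = VariationGraph(vertices, arcs, paths, 0, sink, segment_names)
    g.validate()
    if return_haplotypes:
        return g, haplotypes
    return g


def select_edge_cover_paths(g: VariationGraph) -> list[str]:
    """Minimal-by-iterative-removal path subset covering every covered arc.

    Visiting paths in name order, a path is dropped when it contains no arc
    uniquely covered by it (every one of its arcs is covered by another
    path still kept).  Deterministic.
    """
    keep = sorted(g.paths)
    path_arcs = {name: set(zip(g.paths[name], g.paths[name][1:])) for name in keep}
    for name in sorted(g.paths):
        others = set()
        for other in keep:
            if other != name:
                others |= path_arcs[other]
        if path_arcs[name] <= others:
            keep.remove(name)
    return keep


def _labelled_prefix_len(cg: CanonicalGraph, path: list[int], upto: int) -> int:
    """Spelled length of the path prefix ending at position ``upto`` (inclusive)."""
    return sum(1 for v in path[: upto + 1] if v not in (cg.source, cg.sink))


def simulate_recombinant(
    g: VariationGraph,
    p1: str,
    p2: str,
    window: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
    cg: CanonicalGraph | None = None,
) -> tuple["Query", SimTruth]:
    """A mosaic query: prefix of ``p1`` joined to a suffix of ``p2``.

    The junction is anchored at a vertex shared by the two paths whose
    prefix length falls inside ``window`` (fractions of p1's sequence
    length), chosen uniformly; this guarantees the query corresponds to a
    valid mosaic walk of the graph.  With ``p1 == p2`` the query is simply
    that strain's sequence (a non-recombinant control).  If no shared
    vertex lands in the window, the cut falls back to a raw sequence
    coordinate and is flagged.
    """
    from .linear_dp import Query  # local import to avoid a cycle

    cg = cg or canonicalize(g)
    rng = np.random.default_rng(seed)
    seq1 = cg.paths[p1]
    spell1 = spell_path(cg, seq1)
    n1 = len(spell1)
    if p1 == p2:
        nodes = {v for v in seq1 if v not in (cg.source, cg.sink)}
        truth = SimTruth(p1, None, False, None, None, nodes, seed=seed)
        return Query(f"control_{p1}_{seed}", spell1), truth

    seq2 = cg.paths[p2]
    spell2 = spell_path(cg, seq2)
    pos2 = {v: i for i, v in enumerate(seq2)}
    lo = window[0] * n1
    hi = window[1] * n1
    candidates = []
    for i, v in enumerate(seq1[:-1]):  # cutting after the sink is vacuous
        if v not in pos2:
            continue
        bp = _labelled_prefix_len(cg, seq1, i)
        if lo <= bp <= hi:
            candidates.append((i, pos2[v], bp))
    junction = None
    if candidates:
        i1, i2, bp = candidates[int(rng.integers(len(candidates)))]
        junction = seq1[i1]
        query_seq = spell1[:bp] + spell2[_labelled_prefix_len(cg, seq2, i2):]
        nodes = {v for v in seq1[: i1 + 1] if v not in (cg.source, cg.sink)}
        nodes |= {v for v in seq2[i2 + 1 :] if v not in (cg.source, cg.sink)}
        fallback = False
    else:
        bp = int(rng.integers(int(np.ceil(lo)), int(np.floor(hi)) + 1))
        query_seq = spell1[:bp] + spell2[min(bp, len(spell2)):]
        nodes = set()
        fallback = True
    win = _breakpoint_slide_window(query_seq, spell1, spell2)
    truth = SimTruth(
        p1,
        p2,
        True,
        bp,
        win,
        nodes,
        seed=seed,
        sequence_cut_fallback=fallback,
        junction_vertex=junction,
    )
    return Query(f"recombinant_{p1}_{p2}_{seed}", query_seq), truth


def _breakpoint_slide_window(query: str, spell1: str, spell2: str) -> tuple[int, int]:
    """Inclusive range of cuts j with query == spell1[:j] + tail_j(spell2)."""
    n, n2 = len(query), len(spell2)
    valid = [
        j
        for j in range(n + 1)
        if n - j <= n2 and query[:j] == spell1[:j] and query[j:] == spell2[n2 - (n - j):]
    ]
    return (min(valid), max(valid)) if valid else (-1, -1)


def mosaic_explanations(
    cg: CanonicalGraph, query: str, window: tuple[float, float] = (0.0, 1.0)
) -> tuple[set[str], set[tuple[str, str]]]:
    """Which strains, and which ordered strain pairs, spell the query exactly.

    Returns (single-path explanations, two-path mosaic explanations); a
    simulated recombinant is unambiguous when the singles are empty and the
    only pair explanation is its true parent pair.
    """
    spells = {name: spell_path(cg, p) for name, p in cg.paths.items()}
    singles = {name for name, s in spells.items() if s == query}
    pairs = set()
    n = len(query)
    for a, sa in spells.items():
        for b, sb in spells.items():
            if a == b:
                continue
            lo = int(np.ceil(window[0] * n))
            hi = int(np.floor(window[1] * n))
            for j in range(lo, hi + 1):
                if n - j <= len(sb) and query[:j] == sa[:j] and query[j:] == sb[len(sb) - (n - j):]:
                    pairs.add((a, b))
                    break
    return singles, pairs


def sample_identifiable_recombinant(
    g: VariationGraph,
    cg: CanonicalGraph,
    rng: np.random.Generator,
    window: tuple[float, float] = (0.1, 0.9),
    min_edits: int = 2,
    max_tries: int = 50,
):
    """Draw a mutation-free recombinant whose mosaic structure is identifiable.

    A draw is kept only when (i) the junction is anchored at a shared
    vertex, (ii) no single strain spells the query and the only two-strain
    mosaic explanation is the true parent pair, and (iii) every single
    strain is at least ``min_edits`` edits away from the query — so no
    plain path alignment can rival the mosaic.  Returns (query, truth) or
    None after ``max_tries`` rejected draws.
    """
    import edlib

    names = sorted(g.paths)
    for _ in range(max_tries):
        i1, i2 = rng.choice(len(names), size=2, replace=False)
        p1, p2 = names[i1], names[i2]
        sub = int(rng.integers(2**31))
        q, truth = simulate_recombinant(g, p1, p2, window, sub, cg=cg)
        if truth.sequence_cut_fallback:
            continue
        singles, pairs = mosaic_explanations(cg, q.sequence)
        if singles or pairs != {(p1, p2)}:
            continue
        spells = (spell_path(cg, cg.paths[name]) for name in names)
        if min(edlib.align(q.sequence, s)["editDistance"] for s in spells) < min_edits:
            continue
        return q, truth
    return None


def mutate(q, rate: float, seed: int = 0):
    """Substitute each position independently with probability ``rate``.

    A mutated base is always changed to a *different* base (uniform over
    the other three).  Returns the mutated query and the positions hit.
    """
    from .linear_dp import Query

    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    seq = list(q.sequence)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        cur = seq[i]
        options = [b for b in _BASES if b != cur]
        seq[i] = options[int(rng.integers(3))] if cur in _BASES else _BASES[int(rng.integers(4))]
    return Query(q.name + "_mut", "".join(seq)), [int(i) for i in hits]
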