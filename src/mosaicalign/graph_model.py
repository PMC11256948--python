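"""Variation-graph data model: a vertex-labelled DAG with distinguished paths.

A variation graph encodes a set of known haplotypes (e.g. the alleles of a
bacterial gene across strains) as source-to-sink paths of a labelled DAG.
Alignment operates on the *canonical* form, in which every vertex carries a
single-character label; :func:`canonicalize` converts arbitrary segment
graphs (as read from GFA) into that form while remembering, for every
canonical vertex, which original segment and offset it came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "VariationGraph",
    "CanonicalGraph",
    "Walk",
    "GraphError",
    "load_gfa",
    "write_gfa",
    "canonicalize",
    "spell_path",
    "topological_order",
]

SOURCE_LABEL = ""
SINK_LABEL = ""


class GraphError(ValueError):
    """Raised for structurally invalid graphs or unsupported GFA features."""


@dataclass
class VariationGraph:
    """A labelled DAG with a nonempty set of distinguished source-to-sink paths.

    Vertices are dense integer ids.  ``vertices`` maps id -> label string
    (empty exactly for ``source`` and ``sink``); ``paths`` maps path name ->
    vertex-id sequence, each starting at ``source`` and ending at ``sink``.
    ``segment_names`` maps vertex id -> the original GFA segment name (used
    for GAF output); generated graphs fill it with stringified ids.
    """

    vertices: dict[int, str]
    arcs: set[tuple[int, int]]
    paths: dict[str, list[int]]
    source: int
    sink: int
    segment_names: dict[int, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.paths:
            raise GraphError("a variation graph needs at least one distinguished path")
        if self.vertices.get(self.source) != SOURCE_LABEL:
            raise GraphError("source must carry an empty label")
        if self.vertices.get(self.sink) != SINK_LABEL:
            raise GraphError("sink must carry an empty label")
        for u, v in self.arcs:
            if u not in self.vertices or v not in self.vertices:
                raise GraphError(f"arc ({u},{v}) references an unknown vertex")
        # acyclicity
        topological_order(self)
        for name, p in self.paths.items():
            if not p or p[0] != self.source or p[-1] != self.sink:
                raise GraphError(f"path {name!r} does not run source-to-sink")
            if len(set(p)) != len(p):
                raise GraphError(f"path {name!r} visits a vertex twice")
            for u, v in zip(p, p[1:]):
                if (u, v) not in self.arcs:
                    raise GraphError(f"path {name!r} uses missing arc ({u},{v})")

    def successors(self, v: int) -> list[int]:
        return sorted(w for (u, w) in self.arcs if u == v)


@dataclass
class CanonicalGraph(VariationGraph):
    """A :class:`VariationGraph` whose every labelled vertex has a 1-char label.

    ``origin_map`` sends each labelled canonical vertex to the original
    segment name and the 0-based offset of its character within that
    segment's label.
    """

    origin_map: dict[int, tuple[str, int]] = field(default_factory=dict)

    def validate(self) -> None:
        super().validate()
        for v, lab in self.vertices.items():
            if v in (self.source, self.sink):
                continue
            if len(lab) != 1:
                raise GraphError(f"canonical vertex {v} has label of length {len(lab)}")
            if v not in self.origin_map:
                raise GraphError(f"canonical vertex {v} missing from origin_map")


@dataclass
class Walk:
    """An ordered vertex sequence, optionally with one declared virtual arc.

    Every consecutive pair must be an arc of the graph except at
    ``virtual_arc_index`` (if set), where the pair is the declared
    recombination junction ``(rho, psi)`` — which may be ``(v, v)`` when the
    switch happens at a shared vertex.
    """

    vertices: list[int]
    virtual_arc_index: int | None = None

    def validate(self, g: VariationGraph) -> None:
        for i, (u, v) in enumerate(zip(self.vertices, self.vertices[1:])):
            if i == self.virtual_arc_index:
                continue
            if (u, v) not in g.arcs:
                raise GraphError(f"walk pair ({u},{v}) at {i} is not an arc")


def topological_order(g: VariationGraph) -> list[int]:
    """Deterministic topological order of the vertices (ties by vertex id)."""
    dg = nx.DiGraph()
    dg.add_nodes_from(g.vertices)
    dg.add_edges_from(g.arcs)
    try:
        return list(nx.lexicographical_topological_sort(dg))
    except nx.NetworkXUnfeasible:
        raise GraphError("not a DAG") from None


def spell_path(g: VariationGraph, walk: Walk | list[int]) -> str:
    """Concatenate the labels of the walk's vertices."""
    vids = walk.vertices if isinstance(walk, Walk) else walk
    out = []
    for v in vids:
        try:
            out.append(g.vertices[v])
        except KeyError:
            raise GraphError(f"unknown vertex id {v}") from None
    return "".join(out)


def load_gfa(gfa_text: str) -> VariationGraph:
    """Parse a GFA 1.x document (S, L, P lines) into a validated graph.

    Only forward (+/+) links are accepted and overlaps must be ``*`` or
    ``0M``.  A virtual empty-labelled source and sink are always added, with
    arcs to every path start and from every path end, and every path is
    extended to include them.
    """
    segments: dict[str, str] = {}
    links: list[tuple[str, str]] = []
    plines: list[tuple[str, list[str]]] = []
    for raw in gfa_text.splitlines():
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "S":
            if len(fields) < 3:
                raise GraphError(f"malformed S-line: {line!r}")
            segments[fields[1]] = fields[2].upper()
        elif tag == "L":
            if len(fields) < 5:
                raise GraphError(f"malformed L-line: {line!r}")
            _, frm, fo, to, to_o = fields[:5]
            if fo != "+" or to_o != "+":
                raise GraphError("reverse-orientation links are not supported")
            if len(fields) >= 6 and fields[5] not in ("*", "0M", ""):
                raise GraphError(f"unsupported overlap {fields[5]!r}")
            links.append((frm, to))
        elif tag == "P":
            if len(fields) < 3:
                raise GraphError(f"malformed P-line: {line!r}")
            steps = []
            for step in fields[2].split(","):
                if not step.endswith("+"):
                    raise GraphError(f"reverse-orientation path step {step!r}")
                steps.append(step[:-1])
            plines.append((fields[1], steps))
    if not plines:
        raise GraphError("GFA document declares no P-lines (paths)")

    ids = {name: i + 1 for i, name in enumerate(sorted(segments))}
    nseg = len(ids)
    source, sink = 0, nseg + 1
    vertices = {source: SOURCE_LABEL, sink: SINK_LABEL}
    segment_names = {}
    for name, i in ids.items():
        vertices[i] = segments[name]
        segment_names[i] = name
    arcs = set()
    for frm, to in links:
        if frm not in ids or to not in ids:
            raise GraphError(f"link references unknown segment {frm!r}/{to!r}")
        arcs.add((ids[frm], ids[to]))
    paths: dict[str, list[int]] = {}
    for pname, steps in plines:
        vp = []
        for s in steps:
            if s not in ids:
                raise GraphError(f"P-line {pname!r} references unknown segment {s!r}")
            vp.append(ids[s])
        arcs.add((source, vp[0]))
        arcs.add((vp[-1], sink))
        paths[pname] = [source] + vp + [sink]
    g = VariationGraph(vertices, arcs, paths, source, sink, segment_names)
    g.validate()
    return g


def write_gfa(g: VariationGraph) -> str:
    """Serialize to GFA 1.0, omitting the virtual source/sink."""
    lines = ["H\tVN:Z:1.0"]
    virt = {g.source, g.sink}
    name = lambda v: g.segment_names.get(v, str(v))
    for v in sorted(set(g.vertices) - virt):
        lines.append(f"S\t{name(v)}\t{g.vertices[v]}")
    for u, v in sorted(g.arcs):
        if u in virt or v in virt:
            continue
        lines.append(f"L\t{name(u)}\t+\t{name(v)}\t+\t0M")
    for pname in g.paths:
        steps = [name(v) + "+" for v in g.paths[pname] if v not in virt]
        lines.append(f"P\t{pname}\t{','.join(steps)}\t*")
    return "\n".join(lines) + "\n"


def canonicalize(g: VariationGraph) -> CanonicalGraph:
    """Expand every multi-character vertex into a chain of 1-char vertices.

    Incoming arcs attach to the chain head, outgoing arcs to the tail, and
    every distinguished path is remapped through the chains, so path
    spellings are preserved exactly.
    """
    g.validate()
    vertices: dict[int, str] = {}
    origin_map: dict[int, tuple[str, int]] = {}
    segment_names: dict[int, str] = {}
    head: dict[int, int] = {}
    tail: dict[int, int] = {}
    chain: dict[int, list[int]] = {}
    arcs: set[tuple[int, int]] = set()
    nxt = 0

    def fresh() -> int:
        nonlocal nxt
        nxt += 1
        return nxt - 1

    for v in topological_order(g):
        lab = g.vertices[v]
        if v in (g.source, g.sink):
            cid = fresh()
            vertices[cid] = lab
            head[v] = tail[v] = cid
            chain[v] = [cid]
            continue
        if not lab:
            raise GraphError(f"labelled vertex {v} has an empty label")
        seg = g.segment_names.get(v, str(v))
        ids = []
        for off, ch in enumerate(lab):
            cid = fresh()
            vertices[cid] = ch
            origin_map[cid] = (seg, off)
            segment_names[cid] = f"{seg}:{off}" if len(lab) > 1 else seg
            ids.append(cid)
        for a, b in zip(ids, ids[1:]):
            arcs.add((a, b))
        head[v], tail[v] = ids[0], ids[-1]
        chain[v] = ids
    for u, v in g.arcs:
        arcs.add((tail[u], head[v]))
    paths = {
        name: [cid for v in p for cid in chain[v]] for name, p in g.paths.items()
    }
    cg = CanonicalGraph(
        vertices=vertices,
        arcs=arcs,
        paths=paths,
        source=head[g.source],
        sink=head[g.sink],
        segment_names=segment_names,
        origin_map=origin_map,
    )
    cg.validate()
    return cg
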