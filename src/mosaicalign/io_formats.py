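"""FASTA input and GAF output for graph alignments.

GAF (Graph Alignment Format) has no notion of a recombination junction, so
a mosaic alignment is emitted as one contiguous segment walk plus a
reserved ``rc:Z:`` tag carrying the event:
``rc:Z:<p1>,<p2>,<rho-segment>,<psi-segment>,<breakpoint>,<displacement>``.
Scores may be fractional (the displacement multiplier usually is), so the
rounded score goes into the standard ``AS:i:`` tag and the exact value into
``ZS:f:``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

from Bio import SeqIO

from .graph_model import CanonicalGraph
from .linear_dp import AlignmentRecord, Query

__all__ = ["read_fasta", "write_gaf", "parse_gaf", "GafFields", "cigar_of"]


def read_fasta(source) -> list[Query]:
    """Read queries from a path or file-like FASTA document, uppercased."""
    if isinstance(source, (str, os.PathLike)):
        handle: io.TextIOBase = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        queries = []
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
            queries.append(Query(rec.id, seq))
        return queries
    finally:
        if close:
            handle.close()


def cigar_of(columns: list[tuple[int | None, int | None]]) -> str:
    """M/I/D cigar derived from the alignment columns.

    M: both sides present; I: query base against a graph gap; D: graph
    character against a query gap.
    """
    ops = []
    for x, y in columns:
        op = "M" if (x is not None and y is not None) else ("I" if x is None else "D")
        if ops and ops[-1][1] == op:
            ops[-1][0] += 1
        else:
            ops.append([1, op])
    return "".join(f"{n}{op}" for n, op in ops)


def _segment_walk(a: AlignmentRecord, g: CanonicalGraph) -> list[str]:
    """Original-segment names along the walk, consecutive duplicates collapsed."""
    segs: list[str] = []
    for v in a.walk.vertices:
        if v in (g.source, g.sink):
            continue
        seg = g.origin_map[v][0]
        if not segs or segs[-1] != seg:
            segs.append(seg)
    return segs


def write_gaf(a: AlignmentRecord, g: CanonicalGraph) -> str:
    """One GAF line: the 12 mandatory columns plus AS/ZS/cg (and rc) tags."""
    n = len(a.query)
    labelled = [v for v in a.walk.vertices if v not in (g.source, g.sink)]
    path_len = len(labelled)
    matches = sum(
        1
        for x, y in a.columns
        if x is not None and y is not None and g.vertices[x] == a.query.sequence[y]
    )
    block = len(a.columns)
    walk = "".join(">" + s for s in _segment_walk(a, g))
    fields = [
        a.query.name,
        str(n),
        "0",
        str(n),
        "+",
        walk,
        str(path_len),
        "0",
        str(path_len),
        str(matches),
        str(block),
        "255",
        f"AS:i:{round(a.score)}",
        f"ZS:f:{a.score:g}",
        f"cg:Z:{cigar_of(a.columns)}",
    ]
    if a.recombination is not None:
        ev = a.recombination
        rho_seg = g.segment_names.get(ev.rho, ".")
        psi_seg = g.segment_names.get(ev.psi, ".")
        fields.append(
            f"rc:Z:{ev.p1},{ev.p2},{rho_seg},{psi_seg},{ev.breakpoint},{ev.displacement}"
        )
    return "\t".join(fields)


@dataclass
class GafFields:
    """A parsed GAF line (mandatory columns and tag dictionary)."""

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    walk: list[str]
    path_length: int
    path_start: int
    path_end: int
    matches: int
    block_length: int
    mapping_quality: int
    tags: dict[str, str] = field(default_factory=dict)


def parse_gaf(line: str) -> GafFields:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 12:
        raise ValueError("GAF line needs 12 mandatory columns")
    walk = [s for s in parts[5].split(">") if s]
    tags = {}
    for t in parts[12:]:
        key, _typ, val = t.split(":", 2)
        tags[key] = val
    return GafFields(
        query_name=parts[0],
        query_length=int(parts[1]),
        query_start=int(parts[2]),
        query_end=int(parts[3]),
        strand=parts[4],
        walk=walk,
        path_length=int(parts[6]),
        path_start=int(parts[7]),
        path_end=int(parts[8]),
        matches=int(parts[9]),
        block_length=int(parts[10]),
        mapping_quality=int(parts[11]),
        tags=tags,
    )
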