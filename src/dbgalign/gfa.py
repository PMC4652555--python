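"""GFA 1.0 serialization of condensed de Bruijn graphs.

One segment per physical contig (the canonical orientation, i.e. the
lexicographically smaller of the sequence and its reverse complement);
links carry orientations. A link and its reverse-complement mirror are the
same GFA line, so each edge pair is written once. The k-mer size rides in a
``kk:i:`` header tag; coverage in ``dp:f:`` segment tags.
"""

from __future__ import annotations

from .graph import CondensedGraph, Node
from .sequences import reverse_complement

__all__ = ["GFAParseError", "write_gfa", "read_gfa"]


class GFAParseError(ValueError):
    """Malformed GFA input; carries the offending line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"GFA line {line_no}: {message}")


def _split_oriented(node_id: str) -> tuple[str, str]:
    return node_id[:-1], node_id[-1]


def write_gfa(g: CondensedGraph, destination) -> None:
    """Write *g* as GFA 1.0 to a path or text handle."""
    close = False
    if not hasattr(destination, "write"):
        destination = open(destination, "w")
        close = True
    try:
        destination.write(f"H\tVN:Z:1.0\tkk:i:{g.k}\n")
        seen_segments = set()
        for nid in g.node_ids():
            seg, orient = _split_oriented(nid)
            if seg in seen_segments:
                continue
            # canonical orientation is the '+' node by construction
            if orient == "-":
                continue
            seen_segments.add(seg)
            destination.write(
                f"S\t{seg}\t{g.seq(nid)}\tdp:f:{g.coverage(nid):.6g}\n")
        written = set()
        for a, b in sorted(g.edges):
            sa, oa = _split_oriented(a)
            sb, ob = _split_oriented(b)
            mirror = (g.twin(b), g.twin(a))
            key = min((a, b), mirror)
            if key in written:
                continue
            written.add(key)
            ca, cb = key
            sa, oa = _split_oriented(ca)
            sb, ob = _split_oriented(cb)
            destination.write(f"L\t{sa}\t{oa}\t{sb}\t{ob}\t{g.k - 1}M\n")
    finally:
        if close:
            destination.close()


def read_gfa(source) -> CondensedGraph:
    """Read a GFA 1.0 graph written by :func:`write_gfa`.

    Round-trips losslessly up to node-id relabeling. Raises
    :class:`GFAParseError` with the line number on malformed input.
    """
    close = False
    if not hasattr(source, "read"):
        source = open(source)
        close = True
    try:
        k = None
        seqs: dict[str, str] = {}
        covs: dict[str, float] = {}
        links: list[tuple[int, str, str, str, str]] = []
        for line_no, raw in enumerate(source, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "H":
                for f in fields[1:]:
                    if f.startswith("kk:i:"):
                        try:
                            k = int(f[5:])
                        except ValueError:
                            raise GFAParseError(line_no, f"bad k tag {f!r}")
            elif tag == "S":
                if len(fields) < 3:
                    raise GFAParseError(line_no, "segment needs name and sequence")
                name, seq = fields[1], fields[2].upper()
                if name in seqs:
                    raise GFAParseError(line_no, f"duplicate segment {name!r}")
                if not seq or any(c not in "ACGT" for c in seq):
                    raise GFAParseError(line_no, f"segment {name!r}: invalid sequence")
                seqs[name] = seq
                cov = 1.0
                for f in fields[3:]:
                    if f.startswith("dp:f:") or f.startswith("DP:f:"):
                        try:
                            cov = float(f[5:])
                        except ValueError:
                            raise GFAParseError(line_no, f"bad coverage tag {f!r}")
                covs[name] = cov
            elif tag == "L":
                if len(fields) < 5:
                    raise GFAParseError(line_no, "link needs 4 fields")
                links.append((line_no, fields[1], fields[2], fields[3], fields[4]))
            # other record types ignored
        if k is None:
            raise GFAParseError(0, "missing kk:i: header tag (k-mer size)")

        nodes: list[Node] = []
        oriented: dict[tuple[str, str], str] = {}
        for i, name in enumerate(sorted(seqs)):
            seq = seqs[name]
            rc = reverse_complement(seq)
            plus = f"n{i}+"
            if rc == seq:
                nodes.append(Node(plus, seq, covs[name], plus))
                oriented[(name, "+")] = plus
                oriented[(name, "-")] = plus
            else:
                minus = f"n{i}-"
                nodes.append(Node(plus, seq, covs[name], minus))
                nodes.append(Node(minus, rc, covs[name], plus))
                oriented[(name, "+")] = plus
                oriented[(name, "-")] = minus

        twin = {n.id: n.twin_id for n in nodes}
        edges = set()
        for line_no, sa, oa, sb, ob in links:
            if oa not in "+-" or ob not in "+-":
                raise GFAParseError(line_no, "orientation must be + or -")
            if (sa, oa) not in oriented or (sb, ob) not in oriented:
                missing = sa if (sa, oa) not in oriented else sb
                raise GFAParseError(line_no, f"link references unknown segment {missing!r}")
            a = oriented[(sa, oa)]
            b = oriented[(sb, ob)]
            edges.add((a, b))
            edges.add((twin[b], twin[a]))
        return CondensedGraph(k, nodes, sorted(edges))
    finally:
        if close:
            source.close()
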