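"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written from the definitions, without reuse
of the package's data structures or algorithms: a k-mer-level de Bruijn
graph with naive chain collapse (networkx), a substring-enumeration local
aligner on top of a naive global affine DP, and an exhaustive walk
enumerator for the extension search.
"""

from __future__ import annotations

import math

import networkx as nx

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


# ---------------------------------------------------------------------------
# brute-force condensed de Bruijn graph
# ---------------------------------------------------------------------------

def brute_force_graph(reads, k):
    """(nodes, edges, coverages) of the condensed graph, by naive collapse.

    nodes: set of node sequence strings (both orientations present).
    edges: set of (seq_a, seq_b) pairs.
    coverages: dict seq -> mean pooled k-mer multiplicity.
    Isolated cycles are returned as special entries: ('cycle', canonical)
    where canonical is the rotation/reverse-complement-invariant form of the
    cyclic core sequence.
    """
    counts: dict[str, int] = {}
    support = set()
    for read in reads:
        read = str(read).upper()
        frags = []
        cur = []
        for ch in read:
            if ch in "ACGT":
                cur.append(ch)
            else:
                frags.append("".join(cur))
                cur = []
        frags.append("".join(cur))
        for frag in frags:
            for i in range(len(frag) - k + 1):
                km = frag[i:i + k]
                counts[km] = counts.get(km, 0) + 1
            for i in range(len(frag) - k):
                w = frag[i:i + k + 1]
                support.add(w)
                support.add(rc(w))
    if not counts:
        return None

    mult = {}
    for km, c in counts.items():
        r = rc(km)
        mult[km] = c if r == km else c + counts.get(r, 0)
        if r not in mult:
            mult[r] = mult[km]

    G = nx.DiGraph()
    G.add_nodes_from(mult)
    for x in mult:
        for b in "ACGT":
            y = x[1:] + b
            if y in mult and (x + b) in support:
                G.add_edge(x, y)

    # naive collapse: each weakly ordered linear chain -> one contig
    nodes: dict[str, list[str]] = {}   # contig seq -> kmer list
    cyclic: list[list[str]] = []
    visited = set()
    for x in G.nodes:
        indeg, outdeg = G.in_degree(x), G.out_degree(x)
        pred = next(iter(G.predecessors(x)), None)
        starts = not (indeg == 1 and pred != x and G.out_degree(pred) == 1)
        if not starts:
            continue
        chain = [x]
        cur = x
        while G.out_degree(cur) == 1:
            nxt = next(iter(G.successors(cur)))
            if nxt == cur or nxt == x or G.in_degree(nxt) != 1:
                break
            p2 = next(iter(G.predecessors(nxt)))
            if G.out_degree(p2) != 1:
                break
            chain.append(nxt)
            cur = nxt
        seq = chain[0] + "".join(c[-1] for c in chain[1:])
        nodes[seq] = chain
        visited.update(chain)
    for x in G.nodes:
        if x in visited:
            continue
        cyc = [x]
        cur = next(iter(G.successors(x)))
        while cur != x:
            cyc.append(cur)
            cur = next(iter(G.successors(cur)))
        if set(cyc) & visited:
            continue
        visited.update(cyc)
        cyclic.append(cyc)

    edges = set()
    kmer_to_contig = {}
    for seq, chain in nodes.items():
        for km in chain:
            kmer_to_contig.setdefault(km, seq)
    for seq, chain in nodes.items():
        for nxt in G.successors(chain[-1]):
            tgt = kmer_to_contig.get(nxt)
            if tgt is not None and nodes[tgt][0] == nxt:
                edges.add((seq, tgt))

    covs = {seq: sum(mult[km] for km in chain) / len(chain)
            for seq, chain in nodes.items()}
    return {"nodes": nodes, "edges": edges, "covs": covs,
            "cycles": cyclic, "mult": mult}


def cycle_canonical(kmers: list[str]) -> str:
    """Rotation- and reverse-complement-invariant form of a k-mer cycle."""
    core = "".join(km[-1] for km in kmers)  # cyclic core sequence
    variants = []
    for s in (core, rc(core)):
        variants.extend(s[i:] + s[:i] for i in range(len(s)))
    return min(variants)


# ---------------------------------------------------------------------------
# brute-force local alignment
# ---------------------------------------------------------------------------

def global_affine_max(q, s, score_fn, gap_open, gap_extend):
    """Max over (x, y) of the global affine score of q[:x] vs s[:y].

    Gap of length L costs gap_open + L*gap_extend. Scanning all prefixes of
    all suffixes (see brute_force_local) realizes the max over substrings.
    """
    NEG = -math.inf
    m, n = len(q), len(s)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in s (consume q)
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in q (consume s)
    M[0][0] = 0.0
    best = 0.0
    for i in range(m + 1):
        for j in range(n + 1):
            if i > 0:
                X[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                              X[i - 1][j] - gap_extend)
            if j > 0:
                Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                              Y[i][j - 1] - gap_extend)
            if i > 0 and j > 0:
                diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                if diag > NEG:
                    M[i][j] = diag + score_fn(q[i - 1], s[j - 1])
            if i or j:
                best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def brute_force_local(q, s, score_fn, gap_open, gap_extend):
    """Best local score: max over substring pairs of global affine scores."""
    best = 0.0
    for i in range(len(q)):
        for j in range(len(s)):
            best = max(best, global_affine_max(
                q[i:], s[j:], score_fn, gap_open, gap_extend))
    return best


def brute_force_local_nt(q, s, match, mismatch, gap_open, gap_extend,
                         both_strands=True):
    def sf(a, b):
        return match if a == b else mismatch
    best = brute_force_local(q, s, sf, gap_open, gap_extend)
    if both_strands:
        best = max(best, brute_force_local(q, rc(s), sf, gap_open, gap_extend))
    return best


# ---------------------------------------------------------------------------
# exhaustive walk search for the extension oracle
# ---------------------------------------------------------------------------

def all_walks_from(g, start, max_nodes, max_revisits):
    """All walks in CondensedGraph *g* starting at *start*, within limits."""
    out = []

    def grow(walk):
        out.append(tuple(walk))
        if len(walk) >= max_nodes:
            return
        for nxt in g.successors(walk[-1]):
            if walk.count(nxt) + 1 > max_revisits:
                continue
            walk.append(nxt)
            grow(walk)
            walk.pop()

    grow([start])
    return out
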