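"""Double-stranded condensed de Bruijn graphs built from short reads.

A de Bruijn graph takes every k-mer occurring in the reads (and, implicitly,
in their reverse complements) as a vertex; a directed edge joins two k-mers
when the (k-1)-suffix of the first equals the (k-1)-prefix of the second and
the corresponding (k+1)-mer was actually observed in a read. Maximal
branchless chains are collapsed into single nodes ("contigs"), giving the
condensed graph this module exposes.

The graph is double-stranded in the usual assembler sense: every node has a *twin*
representing the reverse-complement sequence on the opposite strand, and the
edge set mirrors under twinning — edge (a, b) exists iff edge
(twin(b), twin(a)) exists. A node whose sequence is its own reverse
complement is its own twin.

Node coverage is the mean multiplicity of the node's constituent k-mers,
where a k-mer's multiplicity counts its occurrences across the reads on
either strand (a k-mer and its reverse complement are pooled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .sequences import reverse_complement, split_on_ambiguous

__all__ = [
    "Node",
    "CondensedGraph",
    "EmptyGraphError",
    "InvalidPathError",
    "build_graph",
    "apply_coverage_cutoff",
    "path_sequence",
]

MIN_K = 3
MAX_K = 63


class EmptyGraphError(ValueError):
    """No read contributed a single k-mer."""


class InvalidPathError(ValueError):
    """A walk references non-adjacent consecutive nodes."""


def validate_k(k: int) -> int:
    if not (MIN_K <= int(k) <= MAX_K):
        raise ValueError(f"k must satisfy {MIN_K} <= k <= {MAX_K}, got {k}")
    return int(k)


@dataclass(frozen=True)
class Node:
    """A condensed (branchless) contig in one orientation.

    ``kmer_count`` (= len(seq) - k + 1) is provided by
    :meth:`CondensedGraph.kmer_count` since it depends on the graph's k.
    """

    id: str
    seq: str
    coverage: float
    twin_id: str


class CondensedGraph:
    """Condensed double-stranded de Bruijn graph.

    Nodes are oriented views: a physical contig appears as two nodes (or one,
    when palindromic) linked by ``twin_id``. Edges are directed pairs of node
    ids obeying the (k-1)-overlap rule.
    """

    def __init__(self, k: int, nodes: Iterable[Node | Node],
                 edges: Iterable[tuple[str, str]]):
        self.k = validate_k(k)
        self._nodes: dict[str, Node] = {}
        for n in nodes:
            self._nodes[n.id] = Node(n.id, n.seq, float(n.coverage), n.twin_id)
        self._succ: dict[str, list[str]] = {nid: [] for nid in self._nodes}
        self._pred: dict[str, list[str]] = {nid: [] for nid in self._nodes}
        for a, b in edges:
            if a not in self._nodes or b not in self._nodes:
                raise ValueError(f"edge ({a},{b}) references unknown node")
            if b not in self._succ[a]:
                self._succ[a].append(b)
                self._pred[b].append(a)
        for nid in self._nodes:
            self._succ[nid].sort()
            self._pred[nid].sort()

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> dict[str, Node]:
        return self._nodes

    def node_ids(self) -> list[str]:
        return sorted(self._nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset((a, b) for a, succ in self._succ.items() for b in succ)

    def successors(self, node_id: str) -> list[str]:
        return list(self._succ[node_id])

    def predecessors(self, node_id: str) -> list[str]:
        return list(self._pred[node_id])

    def twin(self, node_id: str) -> str:
        return self._nodes[node_id].twin_id

    def seq(self, node_id: str) -> str:
        return self._nodes[node_id].seq

    def coverage(self, node_id: str) -> float:
        return self._nodes[node_id].coverage

    def kmer_count(self, node_id: str) -> int:
        return len(self._nodes[node_id].seq) - self.k + 1

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self._succ.values())

    def __len__(self) -> int:
        return len(self._nodes)

    # -- paths -----------------------------------------------------------
    def path_sequence(self, path: Sequence[str]) -> str:
        """Splice the node sequences along *path*, removing (k-1) overlaps."""
        if not path:
            raise InvalidPathError("empty path")
        parts = [self.seq(path[0])]
        for a, b in zip(path, path[1:]):
            if b not in self._succ[a]:
                raise InvalidPathError(f"no edge {a} -> {b}")
            parts.append(self.seq(b)[self.k - 1:])
        return "".join(parts)

    def is_walk(self, path: Sequence[str]) -> bool:
        return bool(path) and all(b in self._succ[a] for a, b in zip(path, path[1:]))

    # -- integrity (used by the test suite) ------------------------------
    def check_invariants(self, require_maximal: bool = True) -> None:
        for nid, n in self._nodes.items():
            t = self._nodes[n.twin_id]
            assert t.twin_id == nid, "twin is not an involution"
            assert t.seq == reverse_complement(n.seq), "twin seq mismatch"
            assert abs(t.coverage - n.coverage) < 1e-9, "twin coverage mismatch"
            assert len(n.seq) >= self.k
        edge_set = self.edges
        for a, b in edge_set:
            assert self.seq(a)[-(self.k - 1):] == self.seq(b)[: self.k - 1], \
                f"edge ({a},{b}) violates (k-1)-overlap"
            mirror = (self.twin(b), self.twin(a))
            assert mirror in edge_set, f"edge ({a},{b}) lacks mirror {mirror}"
        if not require_maximal:
            return
        for a in self._nodes:
            succ = self._succ[a]
            if len(succ) == 1 and succ[0] != a:
                b = succ[0]
                if self._pred[b] == [a]:
                    raise AssertionError(f"graph not maximally condensed: {a}->{b}")


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _chain_collapse(
    item_seq: dict[str, str],
    item_cov: dict[str, float],
    item_kc: dict[str, int],
    succ: dict[str, list[str]],
    pred: dict[str, list[str]],
    twin_of: Callable[[str], str],
    k: int,
) -> CondensedGraph:
    """Collapse maximal branchless chains of *items* into a CondensedGraph.

    Items are either raw k-mers or already-condensed nodes; consecutive items
    overlap by (k-1) bases. Twinning of items must mirror the edge set.
    """

    def is_internal(x: str) -> bool:
        p = pred[x]
        return len(p) == 1 and p[0] != x and len(succ[p[0]]) == 1

    chains: list[list[str]] = []
    in_chain: set[str] = set()
    for x in sorted(item_seq):
        if is_internal(x):
            continue
        chain = [x]
        cur = x
        while True:
            nxt_l = succ[cur]
            if len(nxt_l) != 1:
                break
            nxt = nxt_l[0]
            if not is_internal(nxt) or nxt in in_chain or nxt == x or nxt == cur:
                break
            chain.append(nxt)
            in_chain.add(nxt)
            cur = nxt
        chains.append(chain)
        in_chain.update(chain)

    # leftover items belong to isolated simple cycles
    leftover = set(item_seq) - in_chain
    done: set[str] = set()
    for x in sorted(leftover):
        if x in done:
            continue
        cyc = [x]
        cur = succ[x][0]
        while cur != x:
            cyc.append(cur)
            cur = succ[cur][0]
        cyc_set = set(cyc)
        rc_set = {twin_of(y) for y in cyc}
        if rc_set == cyc_set:
            # self-reverse-complement cycle: break at a reflection-fixed
            # edge when one exists so the linearization is palindromic
            n = len(cyc)
            fixed = None
            for j in range(n):
                if twin_of(cyc[(j + 1) % n]) == cyc[j]:
                    fixed = (j + 1) % n
                    break
            if fixed is not None:
                chains.append(cyc[fixed:] + cyc[:fixed])
            else:
                start = cyc.index(min(cyc))
                chain = cyc[start:] + cyc[:start]
                chains.append(chain)
                chains.append([twin_of(y) for y in reversed(chain)])
            done.update(cyc_set)
        else:
            rep = min(min(cyc_set), min(rc_set))
            if rep in cyc_set:
                start = cyc.index(rep)
                chain = cyc[start:] + cyc[:start]
            else:
                # trace the twin cycle and break it at rep, then mirror back
                tc = [rep]
                cur = succ[rep][0]
                while cur != rep:
                    tc.append(cur)
                    cur = succ[cur][0]
                chain = [twin_of(y) for y in reversed(tc)]
            chains.append(chain)
            chains.append([twin_of(y) for y in reversed(chain)])
            done.update(cyc_set | rc_set)

    # spell out each chain
    spelled: list[tuple[str, float, int, list[str]]] = []
    for chain in chains:
        seq = item_seq[chain[0]] + "".join(item_seq[y][k - 1:] for y in chain[1:])
        kc = sum(item_kc[y] for y in chain)
        cov = sum(item_cov[y] * item_kc[y] for y in chain) / kc
        spelled.append((seq, cov, kc, chain))

    # deterministic ids: sort physical contigs by canonical sequence; every
    # contig's reverse-complement chain is also in `spelled` (graph symmetry),
    # so the canonical orientation is always available as representative
    by_seq = {s[0]: s for s in spelled}
    canon: dict[str, tuple] = {}
    for seq, cov, kc, chain in spelled:
        if seq == min(seq, reverse_complement(seq)):
            canon[seq] = (seq, cov, kc, chain)

    nodes: list[Node] = []
    head_of: dict[str, str] = {}   # first item id -> oriented node id
    tail_of: dict[str, str] = {}   # oriented node id -> last item id
    for i, key in enumerate(sorted(canon)):
        seq, cov, kc, chain = canon[key]
        plus_id = f"n{i}+"
        rc_seq = reverse_complement(seq)
        if rc_seq == seq:
            nodes.append(Node(plus_id, seq, cov, plus_id))
            head_of[chain[0]] = plus_id
            tail_of[plus_id] = chain[-1]
        else:
            minus_id = f"n{i}-"
            nodes.append(Node(plus_id, seq, cov, minus_id))
            nodes.append(Node(minus_id, rc_seq, cov, plus_id))
            head_of[chain[0]] = plus_id
            tail_of[plus_id] = chain[-1]
            other = by_seq.get(rc_seq)
            if other is None:
                raise AssertionError("twin contig missing from collapse")
            _, _, _, tchain = other
            head_of[tchain[0]] = minus_id
            tail_of[minus_id] = tchain[-1]

    edges: set[tuple[str, str]] = set()
    for nid, tail in tail_of.items():
        for s in succ[tail]:
            b = head_of.get(s)
            if b is None:
                raise AssertionError(f"chain successor {s} is not a chain head")
            edges.add((nid, b))

    return CondensedGraph(k, nodes, sorted(edges))


def build_graph(reads: Iterable[str], k: int) -> CondensedGraph:
    """Build the condensed double-stranded de Bruijn graph of *reads*.

    Reads containing non-ACGT characters are split at the ambiguous bases;
    fragments of length >= k contribute k-mers. An edge requires its
    (k+1)-mer to be observed in a read (on either strand).

    Raises
    ------
    EmptyGraphError
        If no read fragment reaches length k.
    """
    k = validate_k(k)
    kmer_cnt: dict[str, int] = {}
    edge_support: set[str] = set()
    for read in reads:
        for frag in split_on_ambiguous(str(read)):
            if len(frag) < k:
                continue
            for i in range(len(frag) - k + 1):
                km = frag[i:i + k]
                kmer_cnt[km] = kmer_cnt.get(km, 0) + 1
            for i in range(len(frag) - k):
                edge_support.add(frag[i:i + k + 1])
    if not kmer_cnt:
        raise EmptyGraphError(f"no read fragment of length >= k={k}")

    # vertex set closed under reverse complement; pooled multiplicities
    mult: dict[str, float] = {}
    for km, c in kmer_cnt.items():
        rc = reverse_complement(km)
        if rc == km:
            mult[km] = float(c)
        else:
            mult[km] = float(c + kmer_cnt.get(rc, 0))
            mult.setdefault(rc, mult[km])
    for w in list(edge_support):
        edge_support.add(reverse_complement(w))

    succ: dict[str, list[str]] = {x: [] for x in mult}
    pred: dict[str, list[str]] = {x: [] for x in mult}
    for x in mult:
        suf = x[1:]
        for b in "ACGT":
            y = suf + b
            if y in mult and (x + b) in edge_support:
                succ[x].append(y)
                pred[y].append(x)
    for x in mult:
        succ[x].sort()
        pred[x].sort()

    item_kc = {x: 1 for x in mult}
    return _chain_collapse({x: x for x in mult}, mult, item_kc, succ, pred,
                           reverse_complement, k)


def apply_coverage_cutoff(g: CondensedGraph, c: float) -> CondensedGraph:
    """Drop nodes with coverage strictly below *c* and re-collapse.

    Twins share coverage, so twin pairs are removed together; surviving
    branchless chains are merged back into maximal nodes.
    """
    if c < 0:
        raise ValueError("coverage cutoff must be >= 0")
    keep = {nid for nid, n in g.nodes.items() if n.coverage >= c}
    item_seq = {nid: g.seq(nid) for nid in keep}
    item_cov = {nid: g.coverage(nid) for nid in keep}
    item_kc = {nid: g.kmer_count(nid) for nid in keep}
    succ = {nid: sorted(b for b in g.successors(nid) if b in keep) for nid in keep}
    pred = {nid: sorted(a for a in g.predecessors(nid) if a in keep) for nid in keep}
    return _chain_collapse(item_seq, item_cov, item_kc, succ, pred, g.twin, g.k)


def path_sequence(path: Sequence[str], g: CondensedGraph) -> str:
    """Functional wrapper around :meth:`CondensedGraph.path_sequence`."""
    return g.path_sequence(path)
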