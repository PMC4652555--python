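"""Extension: planted-instance oracle, improvement chains, twins, termination."""

import math
import random

import pytest

from dbgalign.align import align_log_evalue, nucleotide_scheme
from dbgalign.extend import (ExtensionLimits, GraphPath, alternate,
                             extend_side, merge_twins, run_extension, seed)
from dbgalign.graph import CondensedGraph, Node, build_graph
from dbgalign.sequences import reverse_complement

from .conftest import mutate_dna, random_dna
from .oracles import all_walks_from

K = 21
NT = nucleotide_scheme(word_size=0)


def graph_from_segments(segments, decoys, k=K):
    """Build a CondensedGraph holding a planted chain plus decoy branches.

    ``segments`` are the node sequences of the planted walk; consecutive
    segments must already share a (k-1) overlap. ``decoys`` maps a segment
    index i to a list of decoy sequences sharing segment i's (k-1)-suffix.
    """
    nodes, edges = [], []
    ids = []
    for i, seg in enumerate(segments):
        nodes.append(Node(f"p{i}+", seg, 10.0, f"p{i}-"))
        nodes.append(Node(f"p{i}-", reverse_complement(seg), 10.0, f"p{i}+"))
        ids.append(f"p{i}+")
        if i:
            edges.append((f"p{i-1}+", f"p{i}+"))
            edges.append((f"p{i}-", f"p{i-1}-"))
    for i, decs in decoys.items():
        for j, d in enumerate(decs):
            nodes.append(Node(f"d{i}_{j}+", d, 10.0, f"d{i}_{j}-"))
            nodes.append(Node(f"d{i}_{j}-", reverse_complement(d), 10.0,
                              f"d{i}_{j}+"))
            edges.append((f"p{i}+", f"d{i}_{j}+"))
            edges.append((f"d{i}_{j}-", f"p{i}-"))
    g = CondensedGraph(k, nodes, edges)
    # hand-built chains need not be maximally condensed (junctions without
    # decoys); twin/overlap invariants still must hold
    g.check_invariants(require_maximal=False)
    return g, ids


def planted_instance(rng, n_segments, decoys_per_junction=1, seg_len=60,
                     divergence=0.03, k=K):
    """A planted walk whose homolog is the opposing target.

    Returns (graph, planted ids, target sequence). Regenerates decoys until
    every junction has the strict-improvement property: the planted successor
    beats staying put, every decoy extension does not.
    """
    while True:
        transcript = random_dna(rng, n_segments * (seg_len - k + 1) + k - 1)
        segments = []
        pos = 0
        for i in range(n_segments):
            segments.append(transcript[pos: pos + seg_len])
            pos += seg_len - (k - 1)
        decoys = {
            i: [segments[i][-(k - 1):] + random_dna(rng, seg_len - k + 1)
                for _ in range(decoys_per_junction)]
            for i in range(n_segments - 1)}
        target = mutate_dna(rng, transcript, divergence)
        g, ids = graph_from_segments(segments, decoys, k)
        if _strictly_improving(g, ids, target):
            return g, ids, target


def _strictly_improving(g, ids, target):
    prefix_seq = g.seq(ids[0])
    e_prev = align_log_evalue(prefix_seq, target, NT)
    if not math.isfinite(e_prev):
        return False
    for i in range(1, len(ids)):
        prefix_seq = prefix_seq + g.seq(ids[i])[g.k - 1:]
        e = align_log_evalue(prefix_seq, target, NT)
        if not e < e_prev:
            return False
        # every decoy extension from the previous planted prefix must fail
        prev = prefix_seq[: -(len(g.seq(ids[i])) - g.k + 1)]
        for d in g.successors(ids[i - 1]):
            if d == ids[i]:
                continue
            alt = prev + g.seq(d)[g.k - 1:]
            if align_log_evalue(alt, target, NT) < e_prev:
                return False
        e_prev = e
    return True


def target_path(seq):
    return GraphPath(2, ("t0",), seq, 0.0)


class TestExtendSide:
    @pytest.mark.parametrize("seed_", range(12))
    def test_frontier_equals_exhaustive_minimum(self, seed_):
        rng = random.Random(seed_)
        n_seg = rng.randint(2, 5)
        g, ids, target = planted_instance(
            rng, n_seg, decoys_per_junction=rng.randint(1, 2))
        lim = ExtensionLimits(max_nodes_per_path=8, max_node_revisits=1)
        start = ids[0]
        p = GraphPath(1, (start,), g.seq(start),
                      align_log_evalue(g.seq(start), target, NT))
        frontier, retained, history = extend_side(
            p, [target_path(target)], g, NT, lim)
        assert frontier.nodes == tuple(ids)

        walks = all_walks_from(g, start, lim.max_nodes_per_path,
                               lim.max_node_revisits)
        best_walk = min(
            walks, key=lambda w: (align_log_evalue(g.path_sequence(w), target, NT), w))
        assert frontier.nodes == best_walk
        # improvement chain strictly decreasing
        assert all(b < a for a, b in zip([p.log_evalue] + history, history))

    def test_no_outgoing_edges(self):
        g = build_graph(["ACGTACGTTACGGATCCATGG"], 8)
        nid = g.node_ids()[0]
        p = GraphPath(1, (nid,), g.seq(nid), -3.0)
        frontier, retained, history = extend_side(
            p, [target_path(g.seq(nid))], g, NT, ExtensionLimits())
        assert frontier is p and retained == [] and history == []

    def test_worsening_extensions_not_taken(self):
        rng = random.Random(4)
        seg = random_dna(rng, 60)
        decoy = seg[-(K - 1):] + random_dna(rng, 40)
        g, ids = graph_from_segments([seg], {0: [decoy]})
        p = GraphPath(1, (ids[0],), seg, align_log_evalue(seg, seg, NT))
        frontier, retained, _ = extend_side(p, [target_path(seg)], g, NT,
                                            ExtensionLimits())
        assert frontier.nodes == (ids[0],) and retained == []


class TestAlternate:
    def _seedpair(self, g1, g2, u, v):
        e = align_log_evalue(g1.seq(u), g2.seq(v), NT)
        from dbgalign.extend import SeedPair
        return SeedPair(u=u, v=v, evalue=10.0 ** e, log_evalue=e)

    def test_homologous_chain_fully_extended_against_long_node(self):
        """A segmented chain grows to full length against a whole homolog.

        The opposing graph holds the homolog as one long node, as happens
        when the two organisms' graphs break contigs at different points;
        every one-node growth then strictly improves the e-value.
        """
        rng = random.Random(21)
        g1, ids1, _ = planted_instance(rng, 3, decoys_per_junction=0)
        t1 = g1.path_sequence(ids1)
        t2 = mutate_dna(rng, t1, 0.02)
        g2, ids2 = graph_from_segments([t2], {})
        res = alternate(self._seedpair(g1, g2, ids1[0], ids2[0]), g1, g2, NT,
                        ExtensionLimits())
        assert res.frontier1.nodes == tuple(ids1)
        assert res.frontier2.nodes == tuple(ids2)   # single node, no growth
        for i in range(1, 4):
            assert tuple(ids1[:i]) in res.retained1
        assert set(res.retained2) == {tuple(ids2)}
        # improvement chain strictly decreasing
        hist = res.history1
        assert len(hist) == 2
        assert all(b < a for a, b in zip(hist, hist[1:]))

    def test_identically_segmented_chains_stall(self):
        """With symmetric segmentation no extension can improve the e-value:
        the alignment cannot grow but the query length does."""
        rng = random.Random(23)
        g1, ids1, _ = planted_instance(rng, 3, decoys_per_junction=0)
        t2 = mutate_dna(rng, g1.path_sequence(ids1), 0.02)
        segs2 = [t2[i * (60 - K + 1): i * (60 - K + 1) + 60] for i in range(3)]
        g2, ids2 = graph_from_segments(segs2, {})
        res = alternate(self._seedpair(g1, g2, ids1[0], ids2[0]), g1, g2, NT,
                        ExtensionLimits())
        assert res.frontier1.nodes == (ids1[0],)
        assert res.frontier2.nodes == (ids2[0],)

    def test_isolated_homologous_nodes(self):
        rng = random.Random(31)
        a = random_dna(rng, 80)
        b = mutate_dna(rng, a, 0.02)
        g1 = build_graph([a], 21)
        g2 = build_graph([b], 21)
        u, v = g1.node_ids()[0], g2.node_ids()[0]
        res = alternate(self._seedpair(g1, g2, u, v), g1, g2, NT,
                        ExtensionLimits())
        assert set(res.retained1) == {(u,)}
        assert set(res.retained2) == {(v,)}

    def test_termination_on_cycle_graph(self):
        # two-node cycle; target contains many tandem copies so growth would
        # keep improving without the caps
        rng = random.Random(8)
        core = random_dna(rng, 30)
        seg_a = core + core[: K - 1]
        g = build_graph([core * 4], K)
        cyc_nodes = [nid for nid in g.node_ids()
                     if nid in g.successors(nid) or g.successors(nid)]
        target = core * 40
        start = g.node_ids()[0]
        lim = ExtensionLimits(max_nodes_per_path=6, max_node_revisits=6)
        p = GraphPath(1, (start,), g.seq(start),
                      align_log_evalue(g.seq(start), target, NT))
        frontier, retained, _ = extend_side(p, [target_path(target)], g, NT, lim)
        assert len(frontier.nodes) <= lim.max_nodes_per_path


class TestMergeTwins:
    def test_twin_halves_joined(self):
        """Paths retained from B and from twin(B) merge into the full walk."""
        rng = random.Random(17)
        g1, ids1, _ = planted_instance(rng, 3, decoys_per_junction=0)
        full1 = g1.path_sequence(ids1)
        t2 = mutate_dna(rng, full1, 0.02)
        g2, ids2 = graph_from_segments([t2], {})   # whole homolog, one node

        a, b, c = ids1
        mid = "p1+"
        assert mid == b
        tmid = g1.twin(mid)
        s = NT
        lim = ExtensionLimits()
        from dbgalign.extend import SeedPair

        def sp(u, vid):
            e = align_log_evalue(g1.seq(u), g2.seq(vid), s)
            return SeedPair(u=u, v=vid, evalue=10.0 ** e, log_evalue=e)

        # forward seed covers [B], [B,C]; twin seed covers [B'], [B',A']
        res_b = alternate(sp(mid, ids2[0]), g1, g2, s, lim)
        res_tb = alternate(sp(tmid, g2.twin(ids2[0])), g1, g2, s, lim)
        assert (mid, c) in res_b.retained1
        assert (tmid, g1.twin(a)) in res_tb.retained1
        results = {mid: res_b, tmid: res_tb}
        merge_twins(results, g1, s)
        assert (a, b, c) in results[mid].retained1

    def test_self_twin_skipped(self):
        g = build_graph(["CGCGC"], 3)   # palindromic self-twin node
        nid = g.node_ids()[0]
        assert g.twin(nid) == nid
        from dbgalign.extend import SeedPair
        res = alternate(SeedPair(nid, nid, 1e-3, -3.0), g, g, NT,
                        ExtensionLimits(max_nodes_per_path=3))
        merge_twins({nid: res}, g, NT)   # must not raise or duplicate

    def test_missing_twin_result_is_noop(self):
        rng = random.Random(2)
        a = random_dna(rng, 80)
        g = build_graph([a], 21)
        u = g.node_ids()[0]
        from dbgalign.extend import SeedPair
        res = alternate(SeedPair(u, u, 1e-3, -3.0), g, g, NT, ExtensionLimits())
        before = dict(res.retained1)
        merge_twins({u: res}, g, NT)
        assert res.retained1 == before


class TestRunExtension:
    def test_identical_graphs_symmetric(self):
        rng = random.Random(12)
        g = build_graph([random_dna(rng, 120)], 21)
        p1, p2 = run_extension(g, g, [NT], 0.1)
        assert sorted(p.nodes for p in p1) == sorted(p.nodes for p in p2)
        assert len(p1) == g.n_nodes   # every node seeds itself

    def test_empty_seed_list(self):
        rng = random.Random(13)
        g1 = build_graph([random_dna(rng, 60)], 21)
        g2 = build_graph([random_dna(rng, 60)], 21)
        # disjoint random 40-mers: chance e-value above cutoff
        p1, p2 = run_extension(g1, g2, [NT], 1e-12)
        assert p1 == [] and p2 == []

    def test_determinism_and_worker_equivalence(self):
        rng = random.Random(14)
        base = random_dna(rng, 200)
        hom = mutate_dna(rng, base, 0.03)
        reads1 = [base[i:i + 60] for i in range(0, 140, 10)]
        reads2 = [hom[i:i + 60] for i in range(0, 140, 10)]
        g1, g2 = build_graph(reads1, 21), build_graph(reads2, 21)
        runs = [run_extension(g1, g2, [NT], 0.1, n_jobs=n) for n in (1, 1, 4)]
        key = lambda out: [(p.graph, p.nodes, p.log_evalue) for p in out[0] + out[1]]
        assert key(runs[0]) == key(runs[1]) == key(runs[2])

    def test_seed_cutoff_is_strict(self):
        rng = random.Random(15)
        a = random_dna(rng, 100)
        g1 = build_graph([a], 21)
        g2 = build_graph([a], 21)
        sds = seed(g1, g2, NT, cutoff=0.1)
        assert sds and all(s.log_evalue < math.log10(0.1) for s in sds)
        assert seed(g1, g2, NT, cutoff=0.0) == []
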