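"""Iterative, alternating extension of paths in two de Bruijn graphs.

This is the heart of the method. Given condensed graphs G1 and G2 for two
related organisms, every node u of G1 is paired with its most similar node v
of G2 (e-value below a seeding cutoff). Starting from the single-node paths
[u] and [v], the two sides take turns growing: the current best path
("frontier") is extended by one node along each outgoing edge, every
extension is aligned against *all* retained paths on the opposing side, the
extensions whose best e-value strictly improves on the frontier's are
retained, and the single best of them becomes the new frontier. A side stops
when no one-node extension improves its e-value; the alternation stops when a
full round retains nothing new on either side.

Extension is forward-only (along outgoing edges); growth in the other
direction is recovered by the twin mechanism: the retained paths seeded at a
node's twin are reverse-complemented into walks *ending* at the node and
concatenated with the paths seeded at the node itself, keeping the
concatenations whose e-values improve on both constituents.

Cycles in the graph are handled by two caps (walk length and per-node revisit
count); the alternation itself terminates because every productive round
strictly lengthens a frontier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from joblib import Parallel, delayed

from .align import ScoringScheme, WordIndex, align_log_evalue
from .graph import CondensedGraph

__all__ = [
    "SeedPair",
    "GraphPath",
    "ExtensionLimits",
    "RetainedSet",
    "seed",
    "seed_both_roles",
    "extend_side",
    "alternate",
    "merge_twins",
    "run_extension",
]


@dataclass(frozen=True)
class SeedPair:
    """A node of one graph paired with its most similar node in the other.

    ``log_evalue`` (log10) is the comparison scale used throughout; the plain
    e-value underflows for long near-identical sequences.
    """

    u: str
    v: str
    evalue: float
    log_evalue: float


@dataclass
class GraphPath:
    """An ordered node walk in one graph with its spliced sequence.

    ``log_evalue`` is the log10 of the minimum e-value of ``seq`` against the
    opposing retained set at the time the path was recorded (log scale: the
    plain e-value underflows to 0.0 for long near-identical sequences, which
    would break strict-improvement comparisons). ``best_partner`` is the node
    tuple of the opposing path achieving it.
    """

    graph: int
    nodes: tuple[str, ...]
    seq: str
    log_evalue: float
    best_partner: tuple[str, ...] | None = None

    @property
    def best_evalue(self) -> float:
        """The best e-value itself (may underflow to 0.0; display only)."""
        return 10.0 ** self.log_evalue


@dataclass(frozen=True)
class ExtensionLimits:
    """Termination guarantees for cyclic graphs."""

    max_nodes_per_path: int = 500
    max_node_revisits: int = 2

    def __post_init__(self):
        if self.max_nodes_per_path < 1 or self.max_node_revisits < 1:
            raise ValueError("extension limits must be >= 1")


@dataclass
class RetainedSet:
    """Everything accumulated around one seed pair.

    ``retained1``/``retained2`` map node tuples to GraphPaths (always
    including the single-node seed paths); ``frontier1``/``frontier2`` are
    the fully extended top paths. ``history1``/``history2`` record the
    frontier e-value at every extension event, for the improvement-chain
    audit: each list is strictly decreasing.
    """

    seed: SeedPair
    retained1: dict[tuple[str, ...], GraphPath]
    retained2: dict[tuple[str, ...], GraphPath]
    frontier1: GraphPath
    frontier2: GraphPath
    history1: list[float] = field(default_factory=list)
    history2: list[float] = field(default_factory=list)


def _score_against(seq: str, targets: list[GraphPath],
                   s: ScoringScheme) -> tuple[float, tuple[str, ...] | None]:
    """Minimum log10 e-value of *seq* over the opposing retained paths."""
    best_e, best_p = math.inf, None
    for t in sorted(targets, key=lambda t: t.nodes):
        e = align_log_evalue(seq, t.seq, s)
        if e < best_e:
            best_e, best_p = e, t.nodes
    return best_e, best_p


def seed(g1: CondensedGraph, g2: CondensedGraph, s: ScoringScheme,
         cutoff: float) -> list[SeedPair]:
    """One SeedPair per node of *g1* whose best hit in *g2* beats *cutoff*.

    Ordered by node id; both a node and its twin may seed independently.
    """
    seeds, _ = seed_both_roles(g1, g2, s, cutoff)
    return seeds


def seed_both_roles(g1: CondensedGraph, g2: CondensedGraph, s: ScoringScheme,
                    cutoff: float) -> tuple[list[SeedPair], list[SeedPair]]:
    """Seeds from g1's nodes and from g2's nodes in one pass.

    The alignment scores this package builds are symmetric in the two
    sequences (both subject strands / the mirror-complete frame grid), so
    every cross-graph node pair is scored once and both seeding directions
    are read off the same table. Ties break toward the smaller partner id.
    """
    if g1.n_nodes == 0 or g2.n_nodes == 0:
        return [], []
    candidates = [(nid, g2.seq(nid)) for nid in g2.node_ids()]
    index = WordIndex(candidates, s)
    log_cut = math.log10(cutoff) if cutoff > 0 else -math.inf
    best1: dict[str, tuple[float, str]] = {}
    best2: dict[str, tuple[float, str]] = {}
    for u in g1.node_ids():
        qu = g1.seq(u)
        for v in index.hits(qu):
            e = align_log_evalue(qu, g2.seq(v), s)
            if not e < log_cut:
                continue
            if u not in best1 or (e, v) < best1[u]:
                best1[u] = (e, v)
            if v not in best2 or (e, u) < best2[v]:
                best2[v] = (e, u)
    seeds1 = [SeedPair(u=u, v=best1[u][1], evalue=10.0 ** best1[u][0],
                       log_evalue=best1[u][0]) for u in sorted(best1)]
    seeds2 = [SeedPair(u=v, v=best2[v][1], evalue=10.0 ** best2[v][0],
                       log_evalue=best2[v][0]) for v in sorted(best2)]
    return seeds1, seeds2


def extend_side(p: GraphPath, targets: list[GraphPath], g: CondensedGraph,
                s: ScoringScheme, lim: ExtensionLimits,
                ) -> tuple[GraphPath, list[GraphPath], list[float]]:
    """Greedily extend *p* one node at a time while its e-value improves.

    Every one-node extension is scored against all *targets* (minimum
    e-value); all strictly improving extensions are retained, and the best
    one becomes the new frontier. Ties break toward the smaller appended node
    id. Returns (frontier, newly retained paths, frontier e-value history).
    """
    cur = p
    retained: list[GraphPath] = []
    history: list[float] = []
    while True:
        if len(cur.nodes) >= lim.max_nodes_per_path:
            break
        improving: list[GraphPath] = []
        for nxt in g.successors(cur.nodes[-1]):
            if cur.nodes.count(nxt) + 1 > lim.max_node_revisits:
                continue
            new_nodes = cur.nodes + (nxt,)
            new_seq = cur.seq + g.seq(nxt)[g.k - 1:]
            e, partner = _score_against(new_seq, targets, s)
            if e < cur.log_evalue:
                improving.append(GraphPath(p.graph, new_nodes, new_seq, e, partner))
        if not improving:
            break
        retained.extend(improving)
        # best e-value; ties toward the smaller appended node id
        cur = min(improving, key=lambda q: (q.log_evalue, q.nodes[-1]))
        history.append(cur.log_evalue)
    return cur, retained, history


def _merge_into(pool: dict[tuple[str, ...], GraphPath], paths) -> int:
    added = 0
    for q in paths:
        old = pool.get(q.nodes)
        if old is None:
            pool[q.nodes] = q
            added += 1
        elif q.log_evalue < old.log_evalue:
            pool[q.nodes] = q
    return added


def alternate(seedpair: SeedPair, g1: CondensedGraph, g2: CondensedGraph,
              s: ScoringScheme, lim: ExtensionLimits,
              graph_labels: tuple[int, int] = (1, 2)) -> RetainedSet:
    """Run the full alternating extension for one seed pair.

    Side 1 (the seed's graph) and side 2 take turns: each side's frontier is
    re-scored against the opposing retained set (which may have grown), then
    extended while improving. The loop ends when a whole round retains
    nothing new on either side.
    """
    la, lb = graph_labels
    u, v = seedpair.u, seedpair.v
    p1 = GraphPath(la, (u,), g1.seq(u), seedpair.log_evalue, (v,))
    p2 = GraphPath(lb, (v,), g2.seq(v), seedpair.log_evalue, (u,))
    res = RetainedSet(seed=seedpair,
                      retained1={p1.nodes: p1}, retained2={p2.nodes: p2},
                      frontier1=p1, frontier2=p2)
    for _ in range(lim.max_nodes_per_path):
        added = 0
        for side in (1, 2):
            if side == 1:
                frontier, g, targets_pool = res.frontier1, g1, res.retained2
            else:
                frontier, g, targets_pool = res.frontier2, g2, res.retained1
            targets = list(targets_pool.values())
            # re-score the frontier: the opposing set may have grown. Copy so
            # the e-value recorded at retention time stays untouched.
            e, partner = _score_against(frontier.seq, targets, s)
            if e < frontier.log_evalue:
                frontier = GraphPath(frontier.graph, frontier.nodes,
                                     frontier.seq, e, partner)
            frontier, new, hist = extend_side(frontier, targets, g, s, lim)
            if side == 1:
                res.frontier1 = frontier
                added += _merge_into(res.retained1, new)
                res.history1.extend(hist)
            else:
                res.frontier2 = frontier
                added += _merge_into(res.retained2, new)
                res.history2.extend(hist)
        if added == 0:
            break
    # improvement-chain audit: frontier e-values strictly decrease along
    # every extension history; a violation is a bug, not a data effect
    for hist in (res.history1, res.history2):
        assert all(b < a for a, b in zip(hist, hist[1:])),             "improvement chain not strictly decreasing"
    return res


def merge_twins(results: dict[str, RetainedSet], g: CondensedGraph,
                s: ScoringScheme) -> None:
    """Join paths seeded at twin nodes into longer candidate walks.

    For each seeded node u whose twin u' was also seeded: every retained path
    q from u' is reverse-complemented into a walk ending at u (reverse the
    node order, twin each node) and concatenated with every retained path r
    from u. The concatenation is scored against the union of both seeds'
    opposing retained sets and kept when its e-value improves on both
    constituents'. Mutates *results* in place.
    """
    # snapshot first: merged paths must combine only originally retained
    # paths, not products of an earlier twin's merge in the same pass
    snapshot = {u: sorted(res.retained1.values(), key=lambda p: p.nodes)
                for u, res in results.items()}
    for u in sorted(results):
        tu = g.twin(u)
        if tu == u or tu not in results:
            continue
        res_u, res_tu = results[u], results[tu]
        opposing = {}
        opposing.update(res_u.retained2)
        opposing.update(res_tu.retained2)
        targets = list(opposing.values())
        new_paths = []
        for q in snapshot[tu]:
            if len(q.nodes) < 2 or q.nodes[0] != tu:
                continue
            tq_nodes = tuple(g.twin(x) for x in reversed(q.nodes))
            for r in snapshot[u]:
                if r.nodes[0] != u:
                    continue
                cand_nodes = tq_nodes[:-1] + r.nodes
                if not g.is_walk(cand_nodes):
                    continue
                cand_seq = g.path_sequence(cand_nodes)
                e, partner = _score_against(cand_seq, targets, s)
                if e < q.log_evalue and e < r.log_evalue:
                    new_paths.append(
                        GraphPath(r.graph, cand_nodes, cand_seq, e, partner))
        _merge_into(res_u.retained1, new_paths)


def _run_seed_batch(seeds, g1, g2, s, lim, labels):
    return [alternate(sp, g1, g2, s, lim, labels) for sp in seeds]


def run_extension(g1: CondensedGraph, g2: CondensedGraph,
                  s_modes: list[ScoringScheme], cutoff: float,
                  lim: ExtensionLimits | None = None,
                  n_jobs: int = 1,
                  ) -> tuple[list[GraphPath], list[GraphPath]]:
    """Full extension: every mode, both seeding roles, twins merged.

    For each scoring mode, seeds are taken from every node of g1 (role 1),
    extended, twin-merged; then the roles of the graphs are switched and the
    procedure repeats. Returns the retained paths of each graph, pooled over
    modes and roles, deduplicated by node tuple keeping the best e-value.
    Results are independent of ``n_jobs``.
    """
    if lim is None:
        lim = ExtensionLimits()
    pools: tuple[dict, dict] = ({}, {})
    for s in s_modes:
        seeds_by_role = seed_both_roles(g1, g2, s, cutoff)
        for role in (0, 1):
            ga, gb = (g1, g2) if role == 0 else (g2, g1)
            labels = (1, 2) if role == 0 else (2, 1)
            seeds = seeds_by_role[role]
            if not seeds:
                continue
            if n_jobs > 1 and len(seeds) > 1:
                chunks = [seeds[i::n_jobs] for i in range(n_jobs)]
                chunks = [c for c in chunks if c]
                outs = Parallel(n_jobs=n_jobs)(
                    delayed(_run_seed_batch)(c, ga, gb, s, lim, labels)
                    for c in chunks)
                results = {r.seed.u: r for out in outs for r in out}
            else:
                results = {sp.u: alternate(sp, ga, gb, s, lim, labels)
                           for sp in seeds}
            merge_twins(results, ga, s)
            pool_a, pool_b = pools[role], pools[1 - role]
            for uid in sorted(results):
                res = results[uid]
                _merge_into(pool_a, sorted(res.retained1.values(),
                                           key=lambda p: p.nodes))
                _merge_into(pool_b, sorted(res.retained2.values(),
                                           key=lambda p: p.nodes))
    out1 = [pools[0][key] for key in sorted(pools[0])]
    out2 = [pools[1][key] for key in sorted(pools[1])]
    return out1, out2
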