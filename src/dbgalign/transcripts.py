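"""Reduce the retained-path pool to predicted transcripts.

Two greedy filters, both processing paths in ascending e-value order
(ties broken by node-id tuple):

1. *witness filter* — a path is kept only if it contains at least one node
   not covered by an already-kept (better-ranked) path; a node is covered by
   a path that contains the node itself or its twin.
2. *multiplicity cap* — among kept paths, again in rank order, a path is
   dropped if adding it would push any node's pooled occurrence count
   (node + twin together) above ``max_per_node`` (default 10). A path
   visiting a node twice contributes two occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .extend import GraphPath
from .graph import CondensedGraph

__all__ = ["PredictedTranscript", "select_transcripts"]


@dataclass(frozen=True)
class PredictedTranscript:
    """A retained path that survived both selection filters."""

    path: GraphPath

    @property
    def rank_evalue(self) -> float:
        return self.path.best_evalue

    @property
    def rank_log_evalue(self) -> float:
        return self.path.log_evalue

    @property
    def seq(self) -> str:
        return self.path.seq

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.path.nodes


def _canonical(node: str, g: CondensedGraph) -> str:
    """Pool a node with its twin under one key."""
    return min(node, g.twin(node))


def select_transcripts(paths: Sequence[GraphPath], g: CondensedGraph,
                       max_per_node: int = 10) -> list[PredictedTranscript]:
    """Apply the witness filter then the multiplicity cap; rank order output."""
    ranked = sorted(paths, key=lambda p: (p.log_evalue, p.nodes))

    covered: set[str] = set()
    witnessed: list[GraphPath] = []
    for p in ranked:
        keys = {_canonical(n, g) for n in p.nodes}
        if not keys <= covered:
            witnessed.append(p)
            covered |= keys
    counts: dict[str, int] = {}
    out: list[PredictedTranscript] = []
    for p in witnessed:
        incr: dict[str, int] = {}
        for n in p.nodes:
            key = _canonical(n, g)
            incr[key] = incr.get(key, 0) + 1
        if any(counts.get(k, 0) + d > max_per_node for k, d in incr.items()):
            continue
        for k, d in incr.items():
            counts[k] = counts.get(k, 0) + d
        out.append(PredictedTranscript(p))
    return out
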