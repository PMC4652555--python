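"""Call predicted shared transcripts by the bidirectional-hit rule.

Every predicted transcript of one organism is aligned against the set of all
predicted transcripts of the other (all-vs-all, every scoring mode, both
directions). A transcript is called *shared* when it has at least one hit
below the cutoff as a query AND appears at least once as the subject of the
other organism's queries. With symmetric scoring the two conditions coincide
(the hit relations are transposes); they are tracked separately so the rule
survives asymmetric scoring variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .align import ScoringScheme, WordIndex, align_log_evalue, local_align, AlignmentHit
from .transcripts import PredictedTranscript

__all__ = ["SharedCall", "call_shared"]


@dataclass
class SharedCall:
    """A predicted transcript with bidirectional cross-organism evidence."""

    transcript: PredictedTranscript
    organism: int
    index: int                      # position within its organism's transcript list
    forward_hits: list[tuple[int, str, AlignmentHit]] = field(default_factory=list)
    reverse_hit_count: int = 0


def _pair_log_evalues(seqs1: list[str], seqs2: list[str],
                      s: ScoringScheme) -> dict[tuple[int, int], float]:
    """log10 e-value for every (i, j) pair sharing a prefilter word.

    Scores are symmetric in the two sequences under every scheme this
    package builds (both subject strands / the mirror-complete frame grid
    are searched), so each unordered pair is computed once.
    """
    index = WordIndex(list(enumerate(seqs2)), s)
    out: dict[tuple[int, int], float] = {}
    for i, q in enumerate(seqs1):
        for j in index.hits(q):
            e = align_log_evalue(q, seqs2[j], s)
            if math.isfinite(e):
                out[(i, j)] = e
    return out


def call_shared(tx1: list[PredictedTranscript], tx2: list[PredictedTranscript],
                s_modes: list[ScoringScheme], cutoff: float,
                ) -> tuple[list[SharedCall], list[SharedCall]]:
    """Bidirectional all-vs-all calling at *cutoff* (default pipelines use
    1e-7; 1e-20 is the stringent alternative).

    Returns the shared calls of each organism, each carrying its forward
    query hits (subject index, mode, alignment) and the number of times it
    was hit as a subject.
    """
    log_cut = math.log10(cutoff) if cutoff > 0 else -math.inf
    seqs1 = [t.seq for t in tx1]
    seqs2 = [t.seq for t in tx2]
    calls1 = {i: SharedCall(t, 1, i) for i, t in enumerate(tx1)}
    calls2 = {j: SharedCall(t, 2, j) for j, t in enumerate(tx2)}

    for s in s_modes:
        if not seqs1 or not seqs2:
            break
        pairs = _pair_log_evalues(seqs1, seqs2, s)
        for (i, j), e in pairs.items():
            if not e < log_cut:
                continue
            hit_fwd = local_align(seqs1[i], seqs2[j], s)
            hit_rev = local_align(seqs2[j], seqs1[i], s)
            mode = s.mode
            calls1[i].forward_hits.append((j, mode, hit_fwd))
            calls2[j].reverse_hit_count += 1
            calls2[j].forward_hits.append((i, mode, hit_rev))
            calls1[i].reverse_hit_count += 1

    shared1 = [c for _, c in sorted(calls1.items())
               if c.forward_hits and c.reverse_hit_count >= 1]
    shared2 = [c for _, c in sorted(calls2.items())
               if c.forward_hits and c.reverse_hit_count >= 1]
    return shared1, shared2
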