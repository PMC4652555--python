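"""Synthetic two-organism transcriptome and read simulation, plus evaluation.

The simulator emulates the study design the pipeline targets: a set of
*shared* transcripts present in both organisms at a stated nucleotide
divergence (substitutions plus occasional short indels), organism-private
transcripts with no homolog, and uniform-coverage single-end short reads
drawn from both strands with a constant-quality string and an optional
per-base error rate. Ancestral transcript sequences are uniform over
{A,C,G,T}; each organism's copy mutates away from the ancestor at half the
stated rates so the *pairwise* divergence between the two copies matches the
configured value.

Evaluation aligns predicted shared transcripts ("calls") to the ground-truth
shared sequences of the same organism and reports:

* precision — fraction of call positions included in their best alignments
  (pooled over calls; micro-average, macro optional),
* recall — fraction of ground-truth positions covered by those alignments
  (pooled over truth sequences),
* F-score — harmonic mean of the two,
* the number of truth transcripts with an 80%-full-length call (best
  alignment covering at least 80% of the truth sequence length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import ScoringScheme, WordIndex, align_log_evalue, local_align
from .io import quality_trim  # re-exported for convenience  # noqa: F401

__all__ = ["SimConfig", "GroundTruth", "Metrics", "simulate", "evaluate",
           "quality_trim"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated two-organism experiment."""

    n_shared: int = 50
    n_private: int = 10
    length_range: tuple[int, int] = (600, 1200)
    divergence: float = 0.02
    indel_rate: float = 0.001
    read_length: int = 100
    depth: float = 20.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("divergence", "indel_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not self.read_length < self.length_range[0]:
            raise ValueError("read_length must be below the minimum transcript length")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")


@dataclass
class GroundTruth:
    """True transcript sequences with shared-pair bookkeeping."""

    shared1: dict[str, str]
    shared2: dict[str, str]
    private1: dict[str, str]
    private2: dict[str, str]
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def database(self, organism: int) -> dict[str, str]:
        """The ground-truth shared transcripts of one organism."""
        return self.shared1 if organism == 1 else self.shared2

    def all_sequences(self, organism: int) -> dict[str, str]:
        db = dict(self.database(organism))
        db.update(self.private1 if organism == 1 else self.private2)
        return db


def _spawn(seed: int, *key: int) -> np.random.Generator:
    """Deterministic keyed substream, independent of all other keys."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float,
            indel_rate: float) -> str:
    """Independent per-base substitutions plus occasional 1-3 base indels.

    All random draws have shapes that depend only on len(seq), never on the
    rates. With keyed substreams this couples simulations across rate
    settings (common random numbers): the substitutions applied at a lower
    rate are a subset of those applied at a higher one, and indel layouts at
    fixed indel_rate are identical across divergence settings — which is
    what makes monotone comparative statics (e.g. recall vs divergence)
    testable without huge replication.
    """
    L = len(seq)
    u_sub = rng.random(L)
    repl = rng.integers(0, 3, L)
    u_indel = rng.random(L)
    indel_size = rng.integers(1, 4, L)
    u_del = rng.random(L)
    ins_bases = rng.integers(0, 4, (L, 3))

    out = []
    for i, ch in enumerate(seq):
        if u_sub[i] < sub_rate:
            ch = "ACGT".replace(ch, "")[repl[i]]
        if u_indel[i] < indel_rate:
            size = int(indel_size[i])
            if u_del[i] < 0.5:
                continue  # delete this base (one base per event)
            out.append(ch)
            out.extend(_BASES[b].decode() for b in ins_bases[i, :size])
        else:
            out.append(ch)
    return "".join(out)


def simulate(cfg: SimConfig) -> tuple[list[SeqRecord], list[SeqRecord], GroundTruth]:
    """Generate reads for both organisms and the ground truth behind them.

    Fully reproducible from ``cfg.seed``; the same config yields
    byte-identical FASTQ records. Randomness is organized into keyed
    substreams per transcript (ancestors, per-organism mutations, reads), so
    simulations at different divergence settings share ancestors, indel
    layouts and read positions, and their substitution sets are nested
    (common random numbers).
    """
    lo, hi = cfg.length_range
    seed = cfg.seed

    shared1: dict[str, str] = {}
    shared2: dict[str, str] = {}
    pairs = []
    for i in range(cfg.n_shared):
        r_anc = _spawn(seed, 0, i)
        length = int(r_anc.integers(lo, hi + 1))
        ancestor = _random_seq(r_anc, length)
        c1 = _mutate(_spawn(seed, 1, 1, i), ancestor,
                     cfg.divergence / 2, cfg.indel_rate / 2)
        c2 = _mutate(_spawn(seed, 1, 2, i), ancestor,
                     cfg.divergence / 2, cfg.indel_rate / 2)
        id1, id2 = f"shared{i}_org1", f"shared{i}_org2"
        shared1[id1], shared2[id2] = c1, c2
        pairs.append((id1, id2))

    private1, private2 = {}, {}
    for org, store in ((1, private1), (2, private2)):
        for i in range(cfg.n_private):
            r_priv = _spawn(seed, 2, org, i)
            store[f"private{i}_org{org}"] = _random_seq(
                r_priv, int(r_priv.integers(lo, hi + 1)))

    truth = GroundTruth(shared1, shared2, private1, private2, pairs)

    def reads_for(organism: int) -> list[SeqRecord]:
        txs = truth.all_sequences(organism)
        records = []
        serial = 0
        for j, tx_id in enumerate(txs):  # shared then private, stable order
            seq = txs[tx_id]
            rng = _spawn(seed, 3, organism, j)
            n_reads = int(round(cfg.depth * len(seq) / cfg.read_length))
            starts = rng.integers(0, len(seq) - cfg.read_length + 1, size=n_reads)
            strands = rng.random(n_reads) < 0.5
            for start, minus in zip(starts, strands):
                frag = seq[start:start + cfg.read_length]
                if minus:
                    frag = str(Seq(frag).reverse_complement())
                if cfg.error_rate > 0:
                    frag_l = list(frag)
                    errs = np.nonzero(rng.random(len(frag_l)) < cfg.error_rate)[0]
                    for p in errs:
                        frag_l[p] = "ACGT".replace(frag_l[p], "")[rng.integers(3)]
                    frag = "".join(frag_l)
                rec = SeqRecord(Seq(frag), id=f"r{organism}_{serial}",
                                description=tx_id)
                rec.letter_annotations["phred_quality"] = [40] * len(frag)
                records.append(rec)
                serial += 1
        return records

    return reads_for(1), reads_for(2), truth


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f_score: float
    n_80pct_full_length: int
    n_calls: int
    n_truth: int


def _call_seq(call) -> str:
    return call.transcript.seq if hasattr(call, "transcript") else str(call)


def evaluate(shared_calls, truth_db: dict[str, str], s: ScoringScheme,
             pooling: str = "micro") -> Metrics:
    """Score predicted shared transcripts against ground-truth sequences.

    Each call contributes its best alignment (minimum e-value) against the
    truth set; calls with no positive-scoring alignment contribute zero
    coverage. ``pooling="micro"`` pools positions over all calls/truth
    sequences; ``"macro"`` averages per-sequence fractions.
    """
    if pooling not in ("micro", "macro"):
        raise ValueError("pooling must be 'micro' or 'macro'")
    truth_ids = sorted(truth_db)
    if not shared_calls or not truth_db:
        return Metrics(0.0, 0.0, 0.0, 0, len(shared_calls or []), len(truth_db))

    index = WordIndex([(tid, truth_db[tid]) for tid in truth_ids], s)
    q_cov: list[tuple[int, int]] = []           # (covered, length) per call
    s_ranges: dict[str, list[tuple[int, int]]] = {tid: [] for tid in truth_ids}
    full80: set[str] = set()

    for call in shared_calls:
        qseq = _call_seq(call)
        best_id, best_e = None, math.inf
        for tid in index.hits(qseq):
            e = align_log_evalue(qseq, truth_db[tid], s)
            if e < best_e:
                best_id, best_e = tid, e
        if best_id is None:
            q_cov.append((0, len(qseq)))
            continue
        hit = local_align(qseq, truth_db[best_id], s)
        qb, qe = hit.query_range
        sb, se = hit.subject_range
        q_cov.append((qe - qb, len(qseq)))
        s_ranges[best_id].append((sb, se))
        if (se - sb) >= 0.8 * len(truth_db[best_id]):
            full80.add(best_id)

    def union_len(ranges):
        total, end = 0, -1
        for b, e in sorted(ranges):
            b = max(b, end)
            if e > b:
                total += e - b
                end = e
            end = max(end, e)
        return total

    if pooling == "micro":
        precision = sum(c for c, _ in q_cov) / sum(l for _, l in q_cov)
        recall = (sum(union_len(s_ranges[t]) for t in truth_ids)
                  / sum(len(truth_db[t]) for t in truth_ids))
    else:
        precision = float(np.mean([c / l for c, l in q_cov]))
        recall = float(np.mean([union_len(s_ranges[t]) / len(truth_db[t])
                                for t in truth_ids]))
    f = (2 * precision * recall / (precision + recall)
         if precision + recall > 0 else 0.0)
    return Metrics(precision, recall, f, len(full80), len(q_cov), len(truth_ids))
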