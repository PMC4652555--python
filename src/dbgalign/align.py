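"""Local alignment with BLAST-style e-values, in nucleotide and translated modes.

This module plays the role of pairwise BLAST: optimal local alignment
under affine gap penalties (a gap of length L costs open + L*extend), with
significance expressed as a Karlin-Altschul e-value

    E = K * m * n * exp(-lambda * score)

where lambda solves sum_ij p_i p_j exp(lambda * s_ij) = 1 over the background
residue frequencies and K is computed by the standard lattice formula
(verified against NCBI's published ungapped values: +1/-2 uniform bases give
lambda = 1.3327, K = 0.621; BLOSUM62 over Robinson-Robinson frequencies gives
lambda = 0.3176, K = 0.134). Effective-length corrections are deliberately
omitted: cutoffs throughout the package are calibrated against these
statistics, not against NCBI BLAST's.

Nucleotide mode searches both strands of the subject. Translated mode
translates all six reading frames of the query against the three forward
frames of the subject and aligns the peptides; the omitted subject
reverse-strand combinations are exact score-preserving mirror images of
combinations already searched.

An optional BLAST-like word prefilter (exact shared words; default 12 nt /
6 aa) lets callers skip full dynamic programming for candidate pairs sharing
no word; it is configurable and can be disabled (`word_size=0`). The filter
relation is symmetric in the two sequences, so all-vs-all stages may compute
each unordered pair once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import reduce
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy.optimize import brentq

from .sequences import reverse_complement

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "nucleotide_scheme",
    "translated_scheme",
    "karlin_altschul_params",
    "evalue",
    "log10_evalue",
    "local_align",
    "align_evalue",
    "align_log_evalue",
    "best_hit",
    "WordIndex",
]

NUCLEOTIDE = "nucleotide"
TRANSLATED = "translated"

#: Robinson & Robinson (1991) amino-acid background frequencies, the standard
#: background for BLOSUM62 Karlin-Altschul statistics.
ROBINSON_FREQS = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

DEFAULT_WORD_SIZE = {NUCLEOTIDE: 12, TRANSLATED: 6}


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters for one mode.

    Penalties are non-negative magnitudes; a gap of length L costs
    ``gap_open + L * gap_extend``.
    """

    mode: str = NUCLEOTIDE
    match: int = 1
    mismatch: int = -2
    matrix_name: str = "BLOSUM62"
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int | None = None   # None = mode default; 0 disables prefilter

    def __post_init__(self):
        if self.mode not in (NUCLEOTIDE, TRANSLATED):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")

    @property
    def effective_word_size(self) -> int:
        if self.word_size is None:
            return DEFAULT_WORD_SIZE[self.mode]
        return self.word_size

    @property
    def ka(self) -> tuple[float, float]:
        """(lambda, K) for this scheme's ungapped scoring system."""
        return _scheme_stats(self)


def nucleotide_scheme(**kw) -> ScoringScheme:
    return ScoringScheme(mode=NUCLEOTIDE, **kw)


def translated_scheme(**kw) -> ScoringScheme:
    kw.setdefault("gap_open", 11)
    kw.setdefault("gap_extend", 1)
    return ScoringScheme(mode=TRANSLATED, **kw)


@dataclass(frozen=True)
class AlignmentHit:
    """Outcome of one local alignment.

    Ranges are 0-based half-open on the *forward strand* of the original
    sequences, whichever strand or frame the alignment used. ``frame`` is the
    query reading frame in translated mode (+-1..3) and 0 otherwise;
    ``subject_frame`` likewise. ``subject_strand`` is -1 when the nucleotide
    alignment matched the reverse complement of the subject.
    """

    score: float
    evalue: float
    log10_evalue: float
    query_range: tuple[int, int]
    subject_range: tuple[int, int]
    mode: str
    frame: int = 0
    subject_frame: int = 0
    subject_strand: int = 1


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics
# ---------------------------------------------------------------------------

def karlin_altschul_params(scores: Sequence[int], probs: Sequence[float],
                           jmax: int = 60) -> tuple[float, float, float]:
    """(lambda, K, H) for an integer-valued ungapped scoring system.

    ``scores``/``probs`` give the distribution of the score of one aligned
    residue pair under the background frequencies. The expected score must be
    negative and a positive score must be possible.
    """
    scores = np.asarray(scores, dtype=int)
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    if (probs * scores).sum() >= 0:
        raise ValueError("expected score per aligned pair must be negative")
    if scores.max() <= 0:
        raise ValueError("a positive score must be achievable")

    def f(lam):
        return (probs * np.exp(lam * scores)).sum() - 1.0

    lam = brentq(f, 1e-9, 50.0)
    H = lam * (scores * probs * np.exp(lam * scores)).sum()
    d = reduce(math.gcd, [abs(int(s)) for s in scores if s != 0])

    lo, hi = int(scores.min()), int(scores.max())
    base = np.zeros(hi - lo + 1)
    for s, p in zip(scores, probs):
        base[s - lo] += p
    dist = np.array([1.0])
    offset = 0
    sigma = 0.0
    for j in range(1, jmax + 1):
        dist = np.convolve(dist, base)
        offset += lo
        vals = offset + np.arange(len(dist))
        neg = vals < 0
        sigma += (dist[~neg].sum() + (dist[neg] * np.exp(lam * vals[neg])).sum()) / j
    K = d * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * d)))
    return float(lam), float(K), float(H)


_STATS_CACHE: dict[tuple, tuple[float, float]] = {}


def _scheme_stats(s: ScoringScheme) -> tuple[float, float]:
    if s.mode == NUCLEOTIDE:
        key = (NUCLEOTIDE, s.match, s.mismatch)
        if key not in _STATS_CACHE:
            scores, probs = [], []
            for a in range(4):
                for b in range(4):
                    scores.append(s.match if a == b else s.mismatch)
                    probs.append(1.0 / 16.0)
            lam, K, _ = karlin_altschul_params(scores, probs)
            _STATS_CACHE[key] = (lam, K)
    else:
        key = (TRANSLATED, s.matrix_name)
        if key not in _STATS_CACHE:
            mat = _load_matrix(s.matrix_name)
            scores, probs = [], []
            for a, pa in ROBINSON_FREQS.items():
                for b, pb in ROBINSON_FREQS.items():
                    scores.append(int(mat[a][b]))
                    probs.append(pa * pb)
            lam, K, _ = karlin_altschul_params(scores, probs)
            _STATS_CACHE[key] = (lam, K)
    return _STATS_CACHE[key]


def evalue(score: float, m: int, n: int, s: ScoringScheme) -> float:
    """Expected number of chance local alignments scoring >= *score*."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    lam, K = s.ka
    return K * m * n * math.exp(-lam * score)


def log10_evalue(score: float, m: int, n: int, s: ScoringScheme) -> float:
    """log10 of :func:`evalue`, exact where the e-value itself underflows.

    Long highly similar sequences reach e-values far below the smallest
    float; every strict-improvement comparison in the package is done on
    this scale.
    """
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    lam, K = s.ka
    return (math.log(K) + math.log(m) + math.log(n) - lam * score) / math.log(10.0)


# ---------------------------------------------------------------------------
# alignment engines
# ---------------------------------------------------------------------------

_MATRIX_CACHE: dict[str, substitution_matrices.Array] = {}
_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _load_matrix(name: str):
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = substitution_matrices.load(name)
    return _MATRIX_CACHE[name]


def _aligner(s: ScoringScheme) -> Align.PairwiseAligner:
    if s.mode == NUCLEOTIDE:
        key = (NUCLEOTIDE, s.match, s.mismatch, s.gap_open, s.gap_extend)
    else:
        key = (TRANSLATED, s.matrix_name, s.gap_open, s.gap_extend)
    if key not in _ALIGNER_CACHE:
        al = Align.PairwiseAligner()
        al.mode = "local"
        if s.mode == NUCLEOTIDE:
            al.match_score = s.match
            al.mismatch_score = s.mismatch
        else:
            al.substitution_matrix = _load_matrix(s.matrix_name)
        al.open_gap_score = -(s.gap_open + s.gap_extend)
        al.extend_gap_score = -s.gap_extend
        _ALIGNER_CACHE[key] = al
    return _ALIGNER_CACHE[key]


def translate_frame(seq: str, frame: int) -> str:
    """Peptide of *seq* in reading frame +-1..3 (stops as '*')."""
    s = seq if frame > 0 else reverse_complement(seq)
    off = abs(frame) - 1
    usable = (len(s) - off) // 3 * 3
    if usable <= 0:
        return ""
    return str(Seq(s[off:off + usable]).translate())


def _pep_len(n: int) -> int:
    return max(n // 3, 1)


def _frame_pairs(query: str, subject: str):
    """Yield (qframe, sframe, qpep, spep) over the searched frame grid."""
    spep = {f: translate_frame(subject, f) for f in (1, 2, 3)}
    for qf in (1, 2, 3, -1, -2, -3):
        qpep = translate_frame(query, qf)
        if not qpep:
            continue
        for sf in (1, 2, 3):
            if spep[sf]:
                yield qf, sf, qpep, spep[sf]


def raw_local_score(query: str, subject: str, s: ScoringScheme) -> float:
    """Best local alignment score over the searched strand/frame grid."""
    al = _aligner(s)
    if s.mode == NUCLEOTIDE:
        best = al.score(query, subject)
        rc = al.score(query, reverse_complement(subject))
        return max(best, rc)
    best = 0.0
    for _, _, qpep, spep in _frame_pairs(query, subject):
        sc = al.score(qpep, spep)
        if sc > best:
            best = sc
    return best


def align_evalue(query: str, subject: str, s: ScoringScheme) -> float:
    """Minimum e-value of *query* vs *subject* (score-only, no traceback).

    Returns ``inf`` when the best local score is <= 0.
    """
    e = align_log_evalue(query, subject, s)
    return math.inf if math.isinf(e) else 10.0 ** e


def align_log_evalue(query: str, subject: str, s: ScoringScheme) -> float:
    """log10 minimum e-value of *query* vs *subject* (score-only).

    Returns ``inf`` when the best local score is <= 0.
    """
    score = raw_local_score(query, subject, s)
    if score <= 0:
        return math.inf
    if s.mode == NUCLEOTIDE:
        return log10_evalue(score, len(query), len(subject), s)
    return log10_evalue(score, _pep_len(len(query)), _pep_len(len(subject)), s)


def local_align(query: str, subject: str, s: ScoringScheme) -> AlignmentHit | None:
    """Optimal local alignment of *query* vs *subject* with hit details.

    Returns None when the optimal score is <= 0 (no positive-scoring local
    alignment exists).
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    al = _aligner(s)
    if s.mode == NUCLEOTIDE:
        fwd = al.score(query, subject)
        rc_subject = reverse_complement(subject)
        rev = al.score(query, rc_subject)
        if max(fwd, rev) <= 0:
            return None
        strand = 1 if fwd >= rev else -1
        target = subject if strand == 1 else rc_subject
        aln = al.align(query, target)[0]
        qr = (int(aln.coordinates[0][0]), int(aln.coordinates[0][-1]))
        sr = (int(aln.coordinates[1][0]), int(aln.coordinates[1][-1]))
        if strand == -1:
            n = len(subject)
            sr = (n - sr[1], n - sr[0])
        return AlignmentHit(
            score=float(aln.score),
            evalue=evalue(float(aln.score), len(query), len(subject), s),
            log10_evalue=log10_evalue(float(aln.score), len(query),
                                      len(subject), s),
            query_range=qr, subject_range=sr, mode=s.mode,
            subject_strand=strand)

    best = None
    for qf, sf, qpep, spep in _frame_pairs(query, subject):
        sc = al.score(qpep, spep)
        if sc <= 0:
            continue
        if best is None or sc > best[0]:
            best = (sc, qf, sf, qpep, spep)
    if best is None:
        return None
    sc, qf, sf, qpep, spep = best
    aln = al.align(qpep, spep)[0]
    qp = (int(aln.coordinates[0][0]), int(aln.coordinates[0][-1]))
    sp = (int(aln.coordinates[1][0]), int(aln.coordinates[1][-1]))
    qr = _pep_to_nt(qp, qf, len(query))
    sr = _pep_to_nt(sp, sf, len(subject))
    return AlignmentHit(
        score=float(aln.score),
        evalue=evalue(float(aln.score), _pep_len(len(query)),
                      _pep_len(len(subject)), s),
        log10_evalue=log10_evalue(float(aln.score), _pep_len(len(query)),
                                  _pep_len(len(subject)), s),
        query_range=qr, subject_range=sr, mode=s.mode,
        frame=qf, subject_frame=sf)


def _pep_to_nt(pep_range: tuple[int, int], frame: int, nt_len: int) -> tuple[int, int]:
    off = abs(frame) - 1
    b = off + 3 * pep_range[0]
    e = off + 3 * pep_range[1]
    if frame > 0:
        return (b, e)
    return (nt_len - e, nt_len - b)


# ---------------------------------------------------------------------------
# word prefilter + best hit
# ---------------------------------------------------------------------------

class WordIndex:
    """Exact-word index over a candidate set, BLAST-seeding style.

    In nucleotide mode, words are drawn from each candidate sequence and its
    reverse complement (both subject strands are searched). In translated
    mode, words are drawn from all six frame peptides of each candidate so
    that the query/subject filter relation is symmetric.
    """

    def __init__(self, candidates: Iterable[tuple], s: ScoringScheme):
        self.s = s
        self.w = s.effective_word_size
        self._index: dict[str, set] = {}
        self._all_ids: list = []
        for cid, seq in candidates:
            self._all_ids.append(cid)
            if self.w <= 0:
                continue
            for word in self._words_of(seq, query_side=False):
                self._index.setdefault(word, set()).add(cid)

    def _words_of(self, seq: str, query_side: bool):
        w = self.w
        out = set()
        if self.s.mode == NUCLEOTIDE:
            texts = [seq]
            if not query_side:   # subject side: both strands are searched
                texts.append(reverse_complement(seq))
            for t in texts:
                out.update(t[i:i + w] for i in range(len(t) - w + 1))
        else:
            frames = (1, 2, 3, -1, -2, -3)
            for f in frames:
                pep = translate_frame(seq, f)
                out.update(pep[i:i + w] for i in range(len(pep) - w + 1))
        return out

    def hits(self, query: str) -> list:
        """Candidate ids sharing at least one word with *query* (sorted)."""
        if self.w <= 0:
            return sorted(self._all_ids)
        found: set = set()
        for word in self._words_of(query, query_side=True):
            found |= self._index.get(word, set())
        return sorted(found)


def best_hit(query: str, candidates: Sequence[tuple], s: ScoringScheme,
             cutoff: float, index: WordIndex | None = None):
    """Most similar candidate to *query* with e-value strictly below *cutoff*.

    ``candidates`` is a sequence of (id, sequence). Ties in e-value break
    toward the smaller candidate id. Returns (id, AlignmentHit) or None.
    """
    if index is None:
        index = WordIndex(candidates, s)
    shortlist = set(index.hits(query))
    best_id, best_e = None, math.inf
    seqs = dict(candidates)
    for cid in sorted(seqs):
        if cid not in shortlist:
            continue
        e = align_log_evalue(query, seqs[cid], s)
        if e < best_e:
            best_id, best_e = cid, e
    if best_id is None or not (best_e < math.log10(cutoff) if cutoff > 0
                               else False):
        return None
    hit = local_align(query, seqs[best_id], s)
    return best_id, hit
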