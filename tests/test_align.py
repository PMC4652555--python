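"""Alignment scores vs brute force; Karlin-Altschul e-value properties."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbgalign.align import (AlignmentHit, ScoringScheme, WordIndex,
                            align_evalue, align_log_evalue, best_hit, evalue,
                            karlin_altschul_params, local_align, log10_evalue,
                            nucleotide_scheme, translate_frame,
                            translated_scheme)
from dbgalign.sequences import reverse_complement

from .oracles import brute_force_local, brute_force_local_nt

dna_short = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestLocalAlignExamples:
    def test_identity_scores_length_times_match(self, nt):
        h = local_align("ACGTACGT", "ACGTACGT", nt)
        assert h.score == 8
        assert h.query_range == (0, 8) and h.subject_range == (0, 8)

    def test_reverse_strand_hit(self, nt):
        h = local_align("AAAA", "TTTT", nt)
        assert h.score == 4
        assert h.subject_strand == -1
        assert h.subject_range == (0, 4)

    def test_single_base_match_is_reported(self, nt):
        h = local_align("ACGT", "CCCC", nt)
        assert h is not None and h.score == 1

    def test_empty_sequence_rejected(self, nt):
        with pytest.raises(ValueError):
            local_align("", "ACGT", nt)


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(100))
    def test_nucleotide_score_matches_substring_enumeration(self, seed, nt):
        rng = random.Random(seed)
        q = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
        s = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
        expected = brute_force_local_nt(q, s, nt.match, nt.mismatch,
                                        nt.gap_open, nt.gap_extend)
        h = local_align(q, s, nt)
        got = h.score if h else 0.0
        assert got == pytest.approx(expected)

    @given(dna_short, dna_short)
    @settings(deadline=None, max_examples=60)
    def test_score_symmetry(self, q, s):
        nt = nucleotide_scheme(word_size=0)
        hq = local_align(q, s, nt)
        hs = local_align(s, q, nt)
        assert (hq.score if hq else 0) == (hs.score if hs else 0)

    def test_translated_peptides_match_oracle(self, aa):
        from dbgalign.align import _aligner, _load_matrix
        rng = random.Random(5)
        mat = _load_matrix(aa.matrix_name)
        for _ in range(20):
            p1 = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(1, 10)))
            p2 = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(1, 10)))
            expected = brute_force_local(
                p1, p2, lambda a, b: float(mat[a][b]), aa.gap_open, aa.gap_extend)
            got = _aligner(aa).score(p1, p2)
            assert max(got, 0.0) == pytest.approx(expected)


class TestTranslatedMode:
    def test_self_alignment_forward_frame_is_best(self, aa):
        # an ORF without stops: identity in frame +1/+1
        rng = random.Random(11)
        codons = ["GCT", "TGC", "GAC", "GAA", "TTC", "GGA", "CAC", "ATC",
                  "AAA", "CTG", "ATG", "AAC", "CCA", "CAG", "AGA", "AGC"]
        seq = "".join(rng.choice(codons) for _ in range(40))
        h = local_align(seq, seq, aa)
        assert h.frame == 1 and h.subject_frame == 1
        pep = translate_frame(seq, 1)
        from dbgalign.align import _aligner
        assert h.score == pytest.approx(_aligner(aa).score(pep, pep))

    def test_frame_ranges_map_to_nucleotide_coordinates(self, aa):
        codons = "GCTTGCGACGAATTCGGACACATCAAACTGATGAACCCA"
        h = local_align(codons, codons, aa)
        assert 0 <= h.query_range[0] < h.query_range[1] <= len(codons)
        assert 0 <= h.subject_range[0] < h.subject_range[1] <= len(codons)

    def test_reverse_frame_found(self, aa):
        codons = "GCTTGCGACGAATTCGGACACATCAAACTGATGAACCCAGCTTGC"
        h = local_align(reverse_complement(codons), codons, aa)
        assert h is not None and h.frame < 0


class TestEvalue:
    def test_direct_arithmetic(self):
        # E = K m n exp(-lambda s) with the scheme's own constants
        s = nucleotide_scheme()
        lam, K = s.ka
        assert evalue(10, 100, 100, s) == pytest.approx(
            K * 100 * 100 * math.exp(-lam * 10), rel=1e-12)
        assert 10 ** log10_evalue(10, 100, 100, s) == pytest.approx(
            evalue(10, 100, 100, s), rel=1e-9)

    def test_reference_constants(self):
        # published ungapped values: +1/-2 uniform bases and BLOSUM62/Robinson
        lam, K = nucleotide_scheme().ka
        assert lam == pytest.approx(1.33, abs=0.005)
        assert K == pytest.approx(0.621, abs=0.005)
        lam, K = translated_scheme().ka
        assert lam == pytest.approx(0.3176, abs=0.001)
        assert K == pytest.approx(0.134, abs=0.005)

    @given(st.integers(5, 60), st.integers(10, 500), st.integers(10, 500))
    @settings(deadline=None, max_examples=50)
    def test_monotonicity(self, score, m, n):
        s = nucleotide_scheme()
        assert evalue(score + 1, m, n, s) < evalue(score, m, n, s)
        assert evalue(score, 2 * m, n, s) == pytest.approx(
            2 * evalue(score, m, n, s), rel=1e-9)
        assert evalue(score, m, 2 * n, s) > evalue(score, m, n, s)

    def test_invalid_distributions_rejected(self):
        with pytest.raises(ValueError):
            karlin_altschul_params([1, 1], [0.5, 0.5])       # positive mean
        with pytest.raises(ValueError):
            karlin_altschul_params([-1, -2], [0.5, 0.5])     # no positive score


class TestBestHit:
    def test_identity_dominates(self, nt):
        rng = random.Random(3)
        target = "".join(rng.choice("ACGT") for _ in range(80))
        cands = [(i, "".join(rng.choice("ACGT") for _ in range(80)))
                 for i in range(4)] + [(4, target)]
        got = best_hit(target, cands, nt, cutoff=1e-3)
        assert got is not None and got[0] == 4

    def test_zero_cutoff_returns_none(self, nt):
        assert best_hit("ACGTACGT", [(0, "ACGTACGT")], nt, cutoff=0.0) is None

    def test_tie_breaks_to_smaller_id(self, nt):
        cands = [(2, "ACGTACGTACGT"), (1, "ACGTACGTACGT")]
        got = best_hit("ACGTACGTACGT", cands, nt, cutoff=1.0)
        assert got[0] == 1

    def test_prefilter_equivalence_on_homologs(self):
        """Word-prefiltered and unfiltered searches find identical best hits."""
        rng = random.Random(9)
        from .conftest import mutate_dna, random_dna
        cands = []
        queries = []
        for i in range(6):
            t = random_dna(rng, 150)
            cands.append((i, t))
            queries.append(mutate_dna(rng, t, 0.05))
        filt = nucleotide_scheme()          # default word size 12
        nofilt = nucleotide_scheme(word_size=0)
        for q in queries:
            a = best_hit(q, cands, filt, cutoff=1e-5)
            b = best_hit(q, cands, nofilt, cutoff=1e-5)
            assert a is not None and b is not None
            assert a[0] == b[0] and a[1].score == b[1].score


class TestWordIndex:
    def test_reverse_complement_words_indexed(self):
        s = nucleotide_scheme(word_size=8)
        seq = "ACGTTGCAGGAT"
        idx = WordIndex([(0, seq)], s)
        assert idx.hits(reverse_complement(seq)) == [0]

    def test_disabled_filter_returns_everything(self):
        s = nucleotide_scheme(word_size=0)
        idx = WordIndex([(0, "AAAA"), (1, "CCCC")], s)
        assert idx.hits("GGGG") == [0, 1]
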