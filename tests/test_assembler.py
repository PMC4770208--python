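"""Overlap aligner and consensus constructor for mate-pair merging."""

from functools import lru_cache

import pytest
from Bio import Align

from pbfilter.assembler import AlignParams, global_align, make_contig
from pbfilter.seqio import QualityRead, reverse_complement

MATCH, MISMATCH, GAP = 1.0, -1.0, -2.0


def enumerate_best_score(seq1: str, seq2: str) -> float:
    """Exhaustive optimal score over every global alignment with free end gaps.

    Scores each candidate alignment directly from its gapped strings, so it
    shares no machinery with the dynamic programme it checks. Feasible for
    sequences up to length ~8.
    """

    def all_alignments(i, j):
        if i == len(seq1) and j == len(seq2):
            yield ("", "")
            return
        if i < len(seq1) and j < len(seq2):
            for a, b in all_alignments(i + 1, j + 1):
                yield (seq1[i] + a, seq2[j] + b)
        if i < len(seq1):
            for a, b in all_alignments(i + 1, j):
                yield (seq1[i] + a, "-" + b)
        if j < len(seq2):
            for a, b in all_alignments(i, j + 1):
                yield ("-" + a, seq2[j] + b)

    def score(a, b):
        # free terminal gaps: the maximal leading run of gap columns on one
        # consistent side, and likewise the maximal trailing run (possibly on
        # the other side), score zero; all other columns score normally
        cols = list(zip(a, b))
        start, end = 0, len(cols)
        if "-" in cols[0]:
            side = 0 if cols[0][0] == "-" else 1
            while start < end and cols[start][side] == "-":
                start += 1
        if end > start and "-" in cols[end - 1]:
            side = 0 if cols[end - 1][0] == "-" else 1
            while end > start and cols[end - 1][side] == "-":
                end -= 1
        total = 0.0
        for c1, c2 in cols[start:end]:
            if "-" in (c1, c2):
                total += GAP
            elif c1 == c2:
                total += MATCH
            else:
                total += MISMATCH
        return total

    return max(score(a, b) for a, b in all_alignments(0, 0))


def biopython_best_score(seq1: str, seq2: str) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP
    aligner.extend_gap_score = GAP
    if hasattr(aligner, "end_insertion_score"):
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    else:  # older Biopython attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return float(aligner.score(seq1, seq2))


@lru_cache(maxsize=None)
def _pairs(seed=0, n=40, maxlen=8):
    import numpy as np

    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        l1 = int(rng.integers(1, maxlen + 1))
        l2 = int(rng.integers(1, maxlen + 1))
        s1 = "".join(rng.choice(list("ACGT"), l1))
        s2 = "".join(rng.choice(list("ACGT"), l2))
        pairs.append((s1, s2))
    return pairs


class TestGlobalAlign:
    def test_identity_alignment(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.aligned1 == aln.aligned2 == "ACGT"
        assert aln.score == 4 * MATCH

    def test_free_end_gaps_bound(self):
        aln = global_align("AAAA", "TTTT")
        assert aln.score >= 4 * MISMATCH

    def test_overlap_layout(self):
        aln = global_align("ACGTACGT", "GTACGTTT")
        # overlap GTACGT aligned; tails end-gapped and unpenalized
        assert aln.score == 6 * MATCH
        assert aln.aligned1.replace("-", "") == "ACGTACGT"
        assert aln.aligned2.replace("-", "") == "GTACGTTT"

    def test_gap_removal_reproduces_inputs(self):
        for s1, s2 in _pairs():
            aln = global_align(s1, s2)
            assert aln.aligned1.replace("-", "") == s1
            assert aln.aligned2.replace("-", "") == s2
            assert len(aln.aligned1) == len(aln.aligned2)

    def test_score_matches_exhaustive_enumeration(self):
        for s1, s2 in _pairs(n=25, maxlen=6) + _pairs(seed=1, n=5, maxlen=8):
            assert global_align(s1, s2).score == enumerate_best_score(s1, s2), (
                s1, s2,
            )

    def test_score_matches_biopython_aligner(self):
        for s1, s2 in _pairs(seed=2, n=40, maxlen=8):
            assert global_align(s1, s2).score == biopython_best_score(s1, s2)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_deterministic(self):
        for s1, s2 in _pairs(seed=3, n=10):
            first = global_align(s1, s2)
            second = global_align(s1, s2)
            assert (first.aligned1, first.aligned2) == (
                second.aligned1, second.aligned2,
            )


class TestMakeContig:
    def test_perfect_pair_identity(self):
        fwd = QualityRead("f", "ACGTTGCAAC", [30] * 10)
        rev = reverse_complement(QualityRead("r", "ACGTTGCAAC", [30] * 10))
        contig = make_contig(fwd, rev)
        assert contig.read.sequence == fwd.sequence
        assert contig.n_mismatches == 0

    def test_conflict_resolved_by_quality(self):
        fwd = QualityRead("f", "ACGTACGT", [40] * 8)
        rev_template = QualityRead("r", "ACGTACTT", [10] * 8)  # conflict at pos 6
        rev = reverse_complement(rev_template)
        contig = make_contig(fwd, rev, AlignParams(deltaq=6))
        assert contig.read.sequence == "ACGTACGT"
        assert contig.read.quals[6] == 40
        assert contig.n_mismatches == 1

    def test_close_quality_conflict_yields_n(self):
        fwd = QualityRead("f", "ACGTACGT", [20] * 8)
        rev = reverse_complement(QualityRead("r", "ACGTACTT", [19] * 8))
        contig = make_contig(fwd, rev, AlignParams(deltaq=6))
        assert contig.read.sequence[6] == "N"
        assert contig.read.quals[6] == 20
        assert contig.n_mismatches == 1

    def test_consensus_quality_is_column_max(self):
        fwd = QualityRead("f", "ACGTACGT", [11, 12, 13, 14, 15, 16, 17, 18])
        rev = reverse_complement(
            QualityRead("r", "ACGTACGT", [38, 37, 36, 35, 34, 33, 32, 31])
        )
        contig = make_contig(fwd, rev)
        # the mate contributes its original quals 38..31 once re-oriented to
        # the forward strand, so the column maxima are all from the mate
        assert contig.read.quals == [38, 37, 36, 35, 34, 33, 32, 31]

    def test_overhangs_keep_single_coverage_base(self):
        # fwd covers positions 0-7, rev (rc) covers 2-9 of a 10-nt template
        template = "ACGTTGCAAC"
        fwd = QualityRead("f", template[:8], [30] * 8)
        rev = reverse_complement(QualityRead("r", template[2:], [20] * 8))
        contig = make_contig(fwd, rev)
        assert contig.read.sequence == template
        assert contig.read.quals[:2] == [30, 30]
        assert contig.read.quals[-2:] == [20, 20]

    def test_empty_read_rejected(self):
        fwd = QualityRead("f", "ACGT", [30] * 4)
        with pytest.raises(ValueError):
            make_contig(fwd, QualityRead("r", "", []))
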