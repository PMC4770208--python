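"""Paired-end contig assembly with consensus quality scores.

Mate pairs are merged by globally aligning the forward read against the
reverse complement of the reverse read with a Needleman-Wunsch variant in
which terminal gaps are free (overlap / semi-global alignment), so the
non-overlapping tails of the mates carry no penalty. The consensus walks
the alignment column by column; at every column with two bases the
consensus quality is the larger of the two input qualities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import QualityRead, reverse_complement

_GAP = "-"

# traceback codes, in tie-break preference order
_DIAG, _UP, _LEFT = 0, 1, 2


@dataclass(frozen=True)
class AlignParams:
    """Scores for the overlap aligner and the consensus conflict rule."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    #: Minimum quality difference for resolving a conflicting column toward
    #: the higher-quality base; smaller differences yield ``N``.
    deltaq: int = 6


@dataclass
class Alignment:
    """A pairwise global alignment as two equal-length gapped strings."""

    aligned1: str
    aligned2: str
    score: float


@dataclass
class Contig:
    """Merged mate pair: consensus read plus the number of conflicting columns."""

    read: QualityRead
    n_mismatches: int


def global_align(
    seq1: str,
    seq2: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> Alignment:
    """Optimal global alignment of two sequences with free terminal gaps.

    Standard Needleman-Wunsch dynamic programme, modified so that leading
    and trailing gaps score zero: the first row and column are initialised
    to zero and the optimum is taken over the last row and column, which is
    the conventional set-up for merging overlapping mate pairs. Traceback
    is deterministic: ties prefer diagonal, then up (gap in ``seq2``), then
    left (gap in ``seq1``); among equally scoring end cells the one aligning
    the most bases wins.
    """
    if not seq1 or not seq2:
        raise ValueError("cannot align an empty sequence")
    n, m = len(seq1), len(seq2)
    score = np.zeros((n + 1, m + 1))
    move = np.zeros((n + 1, m + 1), dtype=np.int8)
    move[1:, 0] = _UP
    move[0, 1:] = _LEFT
    for i in range(1, n + 1):
        row = score[i]
        above = score[i - 1]
        c1 = seq1[i - 1]
        for j in range(1, m + 1):
            diag = above[j - 1] + (match if c1 == seq2[j - 1] else mismatch)
            up = above[j] + gap
            left = row[j - 1] + gap
            # tie-break: diagonal > up > left
            if diag >= up and diag >= left:
                row[j], move[i, j] = diag, _DIAG
            elif up >= left:
                row[j], move[i, j] = up, _UP
            else:
                row[j], move[i, j] = left, _LEFT

    # free end gaps: best score anywhere on the last row or column;
    # ties go to the cell consuming the most of both sequences.
    end_i, end_j = n, m
    best = score[n, m]
    for i in range(n, -1, -1):
        if score[i, m] > best:
            best, end_i, end_j = score[i, m], i, m
    for j in range(m, -1, -1):
        if score[n, j] > best:
            best, end_i, end_j = score[n, j], n, j

    # trailing free gaps: only one of the two overhangs can be non-empty
    tail1 = seq1[end_i:] + _GAP * (m - end_j)
    tail2 = _GAP * (n - end_i) + seq2[end_j:]

    i, j = end_i, end_j
    core1: list[str] = []
    core2: list[str] = []
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == _DIAG:
            i -= 1
            j -= 1
            core1.append(seq1[i])
            core2.append(seq2[j])
        elif mv == _UP:
            i -= 1
            core1.append(seq1[i])
            core2.append(_GAP)
        else:
            j -= 1
            core1.append(_GAP)
            core2.append(seq2[j])
    core1.reverse()
    core2.reverse()

    aligned1 = "".join(core1) + tail1
    aligned2 = "".join(core2) + tail2
    return Alignment(aligned1=aligned1, aligned2=aligned2, score=float(best))


def make_contig(
    fwd: QualityRead, rev: QualityRead, params: AlignParams = AlignParams()
) -> Contig:
    """Merge a mate pair into a consensus contig.

    ``rev`` is the raw reverse-strand mate and is reverse-complemented
    internally before alignment. Per alignment column:

    * gap in one read: the other read's base and quality are kept
      (covers the single-coverage terminal overhangs);
    * agreeing bases: that base, with the larger of the two qualities;
    * conflicting bases: the base of the higher-quality read if the quality
      difference exceeds ``params.deltaq``, else ``N`` — the consensus
      quality is the column maximum either way, and the column counts as a
      mismatch.
    """
    if not fwd.sequence or not rev.sequence:
        raise ValueError("cannot assemble a contig from an empty read")
    rc = reverse_complement(rev)
    aln = global_align(
        fwd.sequence, rc.sequence, params.match, params.mismatch, params.gap
    )
    bases: list[str] = []
    quals: list[int] = []
    n_mismatches = 0
    i1 = i2 = 0
    for c1, c2 in zip(aln.aligned1, aln.aligned2):
        assert not (c1 == _GAP and c2 == _GAP), "gap-gap column cannot occur"
        if c1 == _GAP:
            bases.append(c2)
            quals.append(rc.quals[i2])
            i2 += 1
        elif c2 == _GAP:
            bases.append(c1)
            quals.append(fwd.quals[i1])
            i1 += 1
        else:
            q1, q2 = fwd.quals[i1], rc.quals[i2]
            if c1 == c2:
                bases.append(c1)
            else:
                n_mismatches += 1
                if abs(q1 - q2) > params.deltaq:
                    bases.append(c1 if q1 > q2 else c2)
                else:
                    bases.append("N")
            quals.append(max(q1, q2))
            i1 += 1
            i2 += 1
    read = QualityRead(id=fwd.id, sequence="".join(bases), quals=quals)
    return Contig(read=read, n_mismatches=n_mismatches)
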