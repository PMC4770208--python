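"""Sequence I/O for the filtering pipeline.

Reads and writes the formats an amplicon preprocessing pipeline touches:
4-line FASTQ with a selectable Phred offset (33 or 64), the 454-era
FASTA + ``.qual`` pair, and the mothur ``names`` dereplication file.
Parsing is delegated to Biopython; this module adds strict validation
(sequence alphabet, quality range) and error messages that point at the
offending record.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, TYPE_CHECKING

from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import CollapsedGroup

#: Largest Phred score representable in printable FASTQ (chr 126 at offset 33).
MAX_PHRED = 93

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class QualityRead:
    """A sequence with per-base Phred quality scores.

    The unit of work for the error model: ``quals[i]`` encodes the
    probability that base ``sequence[i]`` was miscalled.
    """

    id: str
    sequence: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"number of quality scores {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _validate_sequence(seq: str, read_id: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"read {read_id!r}: unexpected characters {sorted(bad)}; "
            "only A, C, G, T and N are accepted"
        )
    return seq


def _decode_quals(qual_str: str, offset: int, read_id: str, index: int) -> list[int]:
    quals = [ord(c) - offset for c in qual_str]
    for q in quals:
        if q < 0 or q > MAX_PHRED:
            raise ValueError(
                f"record {index} ({read_id!r}): decoded Phred score {q} outside "
                f"[0, {MAX_PHRED}] at offset {offset}; is the quality "
                f"encoding actually Phred+{97 - offset}?"
            )
    return quals


def read_fastq(path: str | os.PathLike, offset: int = 33) -> Iterator[QualityRead]:
    """Stream reads from a 4-line FASTQ file.

    Quality characters are decoded as ``ord(char) - offset``; sequences are
    uppercased. Malformed records raise ``ValueError`` naming the record
    index; out-of-range scores raise with a hint that the offset is wrong.
    """
    if offset not in (33, 64):
        raise ValueError(f"Phred offset must be 33 or 64, got {offset}")
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {index}: {exc}") from exc
            read_id = title.split()[0] if title.split() else title
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record {index} ({read_id!r}): sequence and "
                    "quality strings differ in length"
                )
            yield QualityRead(
                id=read_id,
                sequence=_validate_sequence(seq, read_id),
                quals=_decode_quals(qual, offset, read_id, index),
            )
            index += 1


def read_fasta_qual(
    fasta_path: str | os.PathLike, qual_path: str | os.PathLike
) -> Iterator[QualityRead]:
    """Stream reads from a FASTA file paired with a ``.qual`` score file.

    Records must appear in the same order in both files; a divergent or
    missing id raises ``ValueError`` naming it.
    """
    from itertools import zip_longest

    from Bio import SeqIO

    with open(fasta_path) as fasta_handle, open(qual_path) as qual_handle:
        fasta_records = SeqIO.parse(fasta_handle, "fasta")
        qual_records = SeqIO.parse(qual_handle, "qual")
        for fasta_rec, qual_rec in zip_longest(fasta_records, qual_records):
            if fasta_rec is None or qual_rec is None:
                present = fasta_rec or qual_rec
                raise ValueError(
                    f"FASTA/qual record count mismatch: {present.id!r} has no "
                    "counterpart"
                )
            if fasta_rec.id != qual_rec.id:
                raise ValueError(
                    f"FASTA/qual id mismatch: {fasta_rec.id!r} vs {qual_rec.id!r}"
                )
            quals = qual_rec.letter_annotations["phred_quality"]
            if len(quals) != len(fasta_rec.seq):
                raise ValueError(
                    f"read {fasta_rec.id!r}: {len(quals)} quality values for "
                    f"{len(fasta_rec.seq)} bases"
                )
            yield QualityRead(
                id=fasta_rec.id,
                sequence=_validate_sequence(str(fasta_rec.seq), fasta_rec.id),
                quals=[int(q) for q in quals],
            )


def write_fastq(
    reads: Iterable[QualityRead], path: str | os.PathLike, offset: int = 33
) -> None:
    """Write reads as unwrapped 4-line FASTQ records."""
    with open(path, "w") as out:
        for read in reads:
            chars = []
            for q in read.quals:
                code = q + offset
                if q < 0 or code > 126:
                    raise ValueError(
                        f"read {read.id!r}: Phred score {q} not representable "
                        f"at offset {offset}"
                    )
                chars.append(chr(code))
            out.write(f"@{read.id}\n{read.sequence}\n+\n{''.join(chars)}\n")


def write_names(groups: Iterable["CollapsedGroup"], path: str | os.PathLike) -> None:
    """Write dereplication groups as a mothur-style names file.

    One line per group: representative id, a tab, then the comma-separated
    member ids with the representative first.
    """
    seen: set[str] = set()
    with open(path, "w") as out:
        for group in groups:
            members = [group.representative] + [
                m for m in group.members if m != group.representative
            ]
            for member in members:
                if member in seen:
                    raise ValueError(f"duplicate member id across groups: {member!r}")
                seen.add(member)
            out.write(f"{group.representative}\t{','.join(members)}\n")


def reverse_complement(read: QualityRead) -> QualityRead:
    """Watson-Crick reverse complement, with the quality string reversed too."""
    seq = _validate_sequence(read.sequence, read.id)
    # Bio.Seq would silently accept IUPAC ambiguity codes; the alphabet is
    # checked first so they fail loudly instead.
    rc = str(Seq(seq).reverse_complement())
    return QualityRead(id=read.id, sequence=rc, quals=list(reversed(read.quals)))
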