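"""The filtering pipeline: assemble, truncate, predict errors, collapse, filter.

Stages run in a fixed order:

1. if the input is paired, merge each mate pair into a contig;
2. truncate sequences to a fixed length, discarding shorter ones;
3. compute each read's predicted maximum errors ``j_xi`` at confidence
   ``xi = 1 - alpha``;
4. collapse identical sequences, with the member of least ``j_xi`` as the
   group representative;
5. keep a group iff its representative's ``j_xi`` does not exceed
   ``j_tol = uncert * length``.

Collapsing before filtering is deliberate: reads from rare templates are
judged by their best-quality representative, which mitigates the
taxon-correlated quality bias that per-read filtering introduces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .assembler import AlignParams, make_contig
from .errormodel import (
    FilterParams,
    phred_to_prob,
    poisson_lambda,
    poisson_predicted_max_errors,
    predicted_max_errors,
)
from .seqio import (
    QualityRead,
    read_fasta_qual,
    read_fastq,
    write_fastq,
    write_names,
)

logger = logging.getLogger("pbfilter")


@dataclass
class CollapsedGroup:
    """A set of byte-identical sequences, represented by its best member."""

    sequence: str
    members: list[str]
    representative: str
    rep_jxi: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class FilterReport:
    """Per-read decisions plus stage-by-stage counts."""

    table: pd.DataFrame
    n_input: int
    n_truncated_away: int
    n_kept: int
    n_discarded: int


@dataclass
class PipelineConfig:
    """Inputs, outputs and switches for one pipeline run."""

    params: FilterParams = field(default_factory=FilterParams)
    input_path: str | Path | None = None
    reverse_path: str | Path | None = None  # mate file for paired mode
    fasta_path: str | Path | None = None
    qual_path: str | Path | None = None
    output_prefix: str | Path = "pbfilter_out"
    offset: int = 33
    align: AlignParams = field(default_factory=AlignParams)


def truncate_read(read: QualityRead, length: int) -> QualityRead | None:
    """First ``length`` bases of the read, or ``None`` if it is too short."""
    if length <= 0:
        raise ValueError(f"truncation length must be positive, got {length}")
    if len(read) < length:
        return None
    return QualityRead(
        id=read.id, sequence=read.sequence[:length], quals=read.quals[:length]
    )


def compute_jtol(length: int, uncert: float) -> float:
    """Maximum tolerable error count: ``uncert`` errors per nucleotide times
    the (trimmed) read length. Not rounded: at the default ``uncert=0.01``
    this is 2.5 for 250-nt reads and 2 for 200-nt reads."""
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    if not 0.0 <= uncert <= 1.0:
        raise ValueError(f"uncert must be in [0, 1], got {uncert}")
    return uncert * length


def collapse_reads(
    reads: Sequence[QualityRead], jxis: Sequence[float]
) -> list[CollapsedGroup]:
    """Group byte-identical sequences; the member with the least predicted
    maximum errors represents the group (input order breaks ties).

    Groups are ordered by descending multiplicity, then lexicographically by
    sequence, for deterministic output.
    """
    if len(reads) != len(jxis):
        raise ValueError("reads and jxis must have equal length")
    by_seq: dict[str, CollapsedGroup] = {}
    for read, jxi in zip(reads, jxis):
        group = by_seq.get(read.sequence)
        if group is None:
            by_seq[read.sequence] = CollapsedGroup(
                sequence=read.sequence,
                members=[read.id],
                representative=read.id,
                rep_jxi=jxi,
            )
        else:
            group.members.append(read.id)
            if jxi < group.rep_jxi:
                group.rep_jxi = jxi
                group.representative = read.id
    return sorted(by_seq.values(), key=lambda g: (-g.size, g.sequence))


def filter_reads(
    groups: Iterable[CollapsedGroup], params: FilterParams, j_tol: float
) -> tuple[list[CollapsedGroup], list[CollapsedGroup]]:
    """Split groups into (kept, discarded): kept iff ``rep_jxi <= j_tol``."""
    if j_tol < 0:
        raise ValueError(f"j_tol must be non-negative, got {j_tol}")
    kept: list[CollapsedGroup] = []
    discarded: list[CollapsedGroup] = []
    for group in groups:
        (kept if group.rep_jxi <= j_tol else discarded).append(group)
    return kept, discarded


def _load_reads(config: PipelineConfig) -> list[QualityRead]:
    params = config.params
    if config.fasta_path is not None:
        if config.qual_path is None:
            raise ValueError("FASTA input requires a companion quality file")
        return list(read_fasta_qual(config.fasta_path, config.qual_path))
    if config.input_path is None:
        raise ValueError("no input file given")
    fwd_reads = read_fastq(config.input_path, offset=config.offset)
    if not params.paired:
        return list(fwd_reads)
    if config.reverse_path is None:
        raise ValueError("paired mode requires a reverse mate file")
    rev_reads = read_fastq(config.reverse_path, offset=config.offset)
    contigs: list[QualityRead] = []
    for fwd, rev in zip(fwd_reads, rev_reads, strict=True):
        contigs.append(make_contig(fwd, rev, config.align).read)
    return contigs


def run(config: PipelineConfig) -> FilterReport:
    """Execute the full pipeline and write the output artifacts.

    Writes ``<prefix>.kept.fastq``, ``<prefix>.discarded.fastq``, a
    ``<prefix>.names`` file when collapsing, and ``<prefix>.report.tsv``.
    Reads discarded for being shorter than the truncation length appear in
    the discarded FASTQ and in the report with reason ``short``.
    """
    params = config.params
    prefix = str(config.output_prefix)

    try:
        reads = _load_reads(config)
    except Exception as exc:
        raise RuntimeError(f"input stage failed: {exc}") from exc
    n_input = len(reads)
    logger.info("input: %d reads", n_input)

    short_reads: list[QualityRead] = []
    if params.trunc_len is not None:
        surviving = []
        for read in reads:
            trimmed = truncate_read(read, params.trunc_len)
            if trimmed is None:
                short_reads.append(read)
            else:
                surviving.append(trimmed)
        reads = surviving
        logger.info(
            "truncation to %d nt: %d kept, %d too short",
            params.trunc_len, len(reads), len(short_reads),
        )

    predict = poisson_predicted_max_errors if params.use_poisson_approx \
        else predicted_max_errors
    probs_per_read = [phred_to_prob(read.quals) for read in reads]
    jxis = [predict(p, params.xi) for p in probs_per_read]
    lambdas = [poisson_lambda(p) for p in probs_per_read]

    if params.collapse:
        groups = collapse_reads(reads, jxis)
    else:
        groups = [
            CollapsedGroup(
                sequence=r.sequence, members=[r.id], representative=r.id, rep_jxi=j
            )
            for r, j in zip(reads, jxis)
        ]
    logger.info("collapsing: %d groups from %d reads", len(groups), len(reads))

    # j_tol per group; members of a group share one sequence, hence one length
    kept_groups: list[CollapsedGroup] = []
    discarded_groups: list[CollapsedGroup] = []
    for group in groups:
        j_tol = compute_jtol(len(group.sequence), params.uncert)
        k, d = filter_reads([group], params, j_tol)
        kept_groups.extend(k)
        discarded_groups.extend(d)

    kept_ids = {m for g in kept_groups for m in g.members}
    rep_of = {m: g.representative for g in groups for m in g.members}
    by_id = {read.id: read for read in reads}

    rows = []
    for read, jxi, lam in zip(reads, jxis, lambdas):
        kept = read.id in kept_ids
        rows.append(
            {
                "id": read.id,
                "length": len(read),
                "expected_errors": lam,
                "jxi": jxi,
                "representative": rep_of[read.id],
                "decision": "kept" if kept else "discarded",
                "reason": "" if kept else "filtered",
            }
        )
    for read in short_reads:
        rows.append(
            {
                "id": read.id,
                "length": len(read),
                "expected_errors": float("nan"),
                "jxi": float("nan"),
                "representative": "",
                "decision": "discarded",
                "reason": "short",
            }
        )
    columns = [
        "id", "length", "expected_errors", "jxi",
        "representative", "decision", "reason",
    ]
    table = pd.DataFrame(rows, columns=columns)

    kept_reads = [by_id[m] for g in kept_groups for m in g.members]
    discarded_reads = [by_id[m] for g in discarded_groups for m in g.members]
    write_fastq(kept_reads, f"{prefix}.kept.fastq", offset=config.offset)
    write_fastq(
        discarded_reads + short_reads, f"{prefix}.discarded.fastq",
        offset=config.offset,
    )
    if params.collapse:
        write_names(groups, f"{prefix}.names")
    table.to_csv(f"{prefix}.report.tsv", sep="\t", index=False, float_format="%.6g")

    n_kept = len(kept_reads)
    n_discarded = len(discarded_reads)
    logger.info(
        "filtering: %d reads kept, %d discarded, %d lost to truncation",
        n_kept, n_discarded, len(short_reads),
    )
    if n_kept == 0:
        logger.warning("no reads survived filtering")
    return FilterReport(
        table=table,
        n_input=n_input,
        n_truncated_away=len(short_reads),
        n_kept=n_kept,
        n_discarded=n_discarded,
    )
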