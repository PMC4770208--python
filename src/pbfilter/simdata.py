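"""Calibrated read simulator.

Generates reads whose true error process matches their emitted quality
strings exactly: a quality string is drawn from a profile, and each base is
then flipped to a uniformly random *different* base with probability
``10**(-q/10)``. Emitted Phred scores are therefore perfectly calibrated
per-base error probabilities by construction, which makes the simulator a
ground-truth harness for the error model: the true error count of every
read is recorded alongside the read.

Errors are substitutions only. The error model is positionwise and
indel-agnostic, so indel realism (homopolymer over/under-calls, platform
flow artifacts) is deliberately out of scope here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .seqio import QualityRead

__all__ = [
    "SimulatedRead",
    "ConstantProfile",
    "LinearDecayProfile",
    "simulate_reads",
    "simulate_pair",
    "write_truth",
]

#: A quality profile: callable mapping (read length, rng) -> integer Phred array.
QualityProfile = Callable[[int, np.random.Generator], np.ndarray]


@dataclass
class SimulatedRead:
    """A simulated read together with its ground truth."""

    read: QualityRead
    template_id: str
    true_errors: int
    error_positions: list[int]


@dataclass(frozen=True)
class ConstantProfile:
    """Every base gets the same Phred score (default Q40, MiSeq-like ceiling)."""

    q: int = 40

    def __call__(self, length: int, rng: np.random.Generator) -> np.ndarray:
        if not 0 <= self.q <= 93:
            raise ValueError(f"invalid Phred score {self.q}")
        return np.full(length, self.q, dtype=int)


@dataclass(frozen=True)
class LinearDecayProfile:
    """Quality declines linearly from 5' to 3' (pyrosequencing-like tail decay).

    Defaults 38 -> 15 span the typical range from near-perfect start to an
    error-rich tail (~3% error probability).
    """

    q_start: int = 38
    q_end: int = 15

    def __call__(self, length: int, rng: np.random.Generator) -> np.ndarray:
        if not (0 <= self.q_start <= 93 and 0 <= self.q_end <= 93):
            raise ValueError("profile Phred scores must lie in [0, 93]")
        return np.rint(np.linspace(self.q_start, self.q_end, length)).astype(int)


def _read_rng(seed: int, index: int) -> np.random.Generator:
    # one substream per read, derived from (seed, read index)
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _plant_errors(
    template: str, quals: np.ndarray, rng: np.random.Generator
) -> tuple[str, list[int]]:
    probs = np.power(10.0, -quals / 10.0)
    hits = np.flatnonzero(rng.random(len(template)) < probs)
    if hits.size == 0:
        return template, []
    bases = list(template)
    # substitute a uniformly random different base (N templates mutate to ACGT)
    for pos in hits:
        choices = [b for b in "ACGT" if b != bases[pos]]
        bases[pos] = choices[rng.integers(len(choices))]
    return "".join(bases), [int(h) for h in hits]


def simulate_reads(
    templates: Sequence[str],
    n: int,
    quality_profile: QualityProfile,
    seed: int,
    template_ids: Sequence[str] | None = None,
) -> list[SimulatedRead]:
    """Simulate ``n`` reads from the given template sequences.

    For each read a template is drawn uniformly, a quality string is drawn
    from the profile, and each base is flipped with probability
    ``10**(-q/10)``. Fully reproducible: each read uses a private random
    substream derived from ``(seed, read_index)``.
    """
    if not templates:
        raise ValueError("at least one template sequence is required")
    if n <= 0:
        raise ValueError(f"number of reads must be positive, got {n}")
    if template_ids is None:
        template_ids = [f"template_{i}" for i in range(len(templates))]
    if len(template_ids) != len(templates):
        raise ValueError("template_ids must match templates in length")

    sims: list[SimulatedRead] = []
    for index in range(n):
        rng = _read_rng(seed, index)
        t = int(rng.integers(len(templates)))
        template = templates[t].upper()
        quals = np.asarray(quality_profile(len(template), rng))
        if quals.shape != (len(template),) or np.any(quals < 0) or np.any(quals > 93):
            raise ValueError("quality profile produced an invalid Phred array")
        seq, positions = _plant_errors(template, quals, rng)
        sims.append(
            SimulatedRead(
                read=QualityRead(
                    id=f"sim_{index}", sequence=seq, quals=[int(q) for q in quals]
                ),
                template_id=template_ids[t],
                true_errors=len(positions),
                error_positions=positions,
            )
        )
    return sims


def simulate_pair(
    template: str,
    read_len: int,
    overlap: int,
    quality_profile: QualityProfile,
    seed: int,
) -> tuple[QualityRead, QualityRead, SimulatedRead]:
    """Simulate a mate pair spanning ``2 * read_len - overlap`` template bases.

    The forward read covers the first ``read_len`` template bases; the
    reverse mate is emitted as the reverse complement of the last
    ``read_len`` bases of the span, so its reverse complement overlaps the
    forward read by exactly ``overlap`` bases. The returned
    :class:`SimulatedRead` describes the merged span: its error positions
    are span coordinates, counting an error at most once per mate.
    """
    template = template.upper()
    if not 0 < overlap <= read_len:
        raise ValueError("need 0 < overlap <= read_len")
    span = 2 * read_len - overlap
    if span > len(template):
        raise ValueError(
            f"template of length {len(template)} too short for span {span}"
        )
    from .seqio import reverse_complement  # local import avoids cycle at module load

    rng = _read_rng(seed, 0)
    fwd_template = template[:read_len]
    rev_template = template[span - read_len : span]

    fwd_quals = np.asarray(quality_profile(read_len, rng))
    fwd_seq, fwd_pos = _plant_errors(fwd_template, fwd_quals, rng)
    rev_quals = np.asarray(quality_profile(read_len, rng))
    rev_seq_plus, rev_pos = _plant_errors(rev_template, rev_quals, rng)

    fwd = QualityRead(id="pair_fwd", sequence=fwd_seq, quals=[int(q) for q in fwd_quals])
    # the mate is sequenced from the opposite strand: reverse-complement the
    # erroneous plus-strand sequence along with its qualities
    rev = reverse_complement(
        QualityRead(
            id="pair_rev", sequence=rev_seq_plus, quals=[int(q) for q in rev_quals]
        )
    )
    span_positions = sorted(
        {int(p) for p in fwd_pos} | {int(p) + span - read_len for p in rev_pos}
    )
    truth = SimulatedRead(
        read=QualityRead(
            id="pair_truth",
            sequence=template[:span],
            quals=[0] * span,
        ),
        template_id="pair_template",
        true_errors=len(span_positions),
        error_positions=span_positions,
    )
    return fwd, rev, truth


def write_truth(sims: Iterable[SimulatedRead], path: str | os.PathLike) -> None:
    """Write the ground truth as a tab-separated table."""
    with open(path, "w") as out:
        out.write("id\ttemplate_id\ttrue_errors\terror_positions\n")
        for sim in sims:
            positions = ",".join(str(p) for p in sim.error_positions)
            out.write(
                f"{sim.read.id}\t{sim.template_id}\t{sim.true_errors}\t{positions}\n"
            )
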