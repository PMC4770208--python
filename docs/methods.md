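# Methods

## Error model

A read of length *N* with Phred scores *q₁…q_N* is modelled as *N*
independent Bernoulli trials with per-base error probabilities
*pᵢ = 10^(−qᵢ/10)*. The error count *S_N = Σ Xᵢ* follows a Poisson
binomial distribution. Two equivalent routes to its pmf are implemented:

* `error_distribution` — iterated discrete convolution of the Bernoulli
  variables, one base at a time. Because each *Xᵢ* takes only values
  {0, 1}, a convolution step is `new[j] = old[j]·(1−pᵢ) + old[j−1]·pᵢ`.
  Terms above a cap `j_cap` never influence terms below it, so capped
  computation is exact for the retained prefix (this is asserted
  bit-for-bit in the tests).
* `brute_force_distribution` — explicit summation over all 2^N error
  patterns. This closed form is unusable beyond tiny *N* (it refuses
  *N* > 15) and exists as an independent oracle for the test suite.

The assumptions are exactly two: errors at different bases are
independent, and quality scores truly encode per-base error
probabilities. No platform-specific error model is used. Both
assumptions fail in characteristic ways on real data — see
*Limitations*.

## Predicted maximum errors

`predicted_max_errors` produces pmf terms lazily for *j* = 0, 1, 2, …
until the cumulative mass first reaches the confidence level ξ at
*j_max*; terms beyond *j_max* are never computed, so the cost is
O(*N*·*j_max*) — a handful of O(*N*) passes for a high-quality read. The
lazy evaluation walks the convolution table column-wise (`cur[k] =
P(S_k = j)` for the current *j*), which reproduces the row-wise
convolution cell-for-cell.

The predicted maximum errors is the linearly interpolated cdf crossing:

    j_ξ = j_max − 1 + (ξ − F(j_max − 1)) / P(S_N = j_max)

with three explicit boundary rules:

* the stopping rule is inclusive: *j_max* is the first *j* with
  cumulative mass **≥** ξ (a cumulative sum exactly equal to ξ stops);
* when *P(S_N = 0) ≥ ξ* the formula yields a small negative number; it
  is clamped to 0, since a negative error count is meaningless;
* if *P(S_N = j_max)* is exactly zero in floating point (pathological),
  *j_ξ* falls back to *j_max*, which is conservative.

`predicted_max_errors_batch` vectorizes the same computation across many
equal-length reads with a doubling cap; it may evaluate a few terms past
an individual read's *j_max* but is asserted to agree with the scalar
routine to 1e-12. The pipeline uses the scalar routine; the batch
routine serves simulation-scale calibration runs.

### Calibration semantics and the discreteness boundary

The intended reading of *j_ξ* is "with probability ξ the read has no
more than *j_ξ* errors", i.e. the exceedance probability is
α = 1 − ξ. For a **discrete** error count this holds exactly for the
integer ⌈*j_ξ*⌉ (equivalently *j_max*): by construction
*P(S_N ≤ j_max) ≥ ξ*, so at most α of perfectly calibrated reads carry
more than ⌈*j_ξ*⌉ errors. The interpolated value itself sits strictly
below *j_max*, so its exceedance probability is

    P(S_N > j_ξ) = 1 − F(j_max − 1) = α + u,   u = ξ − F(j_max − 1) ∈ (0, P(S_N = j_max)]

— slightly *above* α, by up to one pmf term. The effect is largest where
the pmf is coarse: for uniform-Q40 250-nt reads (λ = 0.025) the
measured exceedance of *j_ξ* is ≈ 0.02–0.03 at α = 0.005, while the
exceedance of ⌈*j_ξ*⌉ is ≈ 0.0002. The test suite therefore asserts the
ceiling guarantee (the mathematically exact statement), and the
acceptance script reports the literal interpolated-quantile exceedance
so the gap is visible rather than hidden. In practice *j_ξ* is used only
for ranking reads against *j_tol* and for picking dereplication
representatives, where the sub-integer resolution is what matters.

### Poisson approximation

With λ = Σ *pᵢ*, *S_N* is approximately Poisson(λ) when all *pᵢ* are
small. `poisson_predicted_max_errors` applies the same stopping and
interpolation rules to Poisson pmf terms (via scipy). The approximation
fails for reads mixing a few very low-quality bases into an otherwise
clean sequence: a single *p* = 0.9 base among 200 bases at *p* = 10⁻⁴
makes the exact distribution concentrate near one error
(*j_ξ* ≈ 1.7) while the Poisson smears it (*j_ξ* ≈ 3.8). A regression
test asserts the direction of this divergence.

## Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `alpha` | 0.005 | probability | accepted chance of underestimating a read's errors; ξ = 1 − α |
| `uncert` | 0.01 | errors/nt | tolerance; *j_tol* = `uncert` × trimmed length (2.5 at 250 nt, 2 at 200 nt) |
| `trunc_len` | none | nt | fixed truncation length; shorter reads are discarded |
| `deltaq` | 6 | Phred units | quality gap needed to resolve a mate conflict toward the higher-quality base; smaller gaps emit N |
| `match/mismatch/gap` | +1/−1/−2 | score | overlap-aligner scores; terminal gaps are free |
| `offset` | 33 | — | FASTQ quality encoding (64 selectable for legacy data) |

## Pipeline order and design choices

Stages run: assemble (if paired) → truncate → predict *j_ξ* → collapse →
filter. Choices that were genuinely open:

* *j_ξ* is computed **before** collapsing, on truncated sequences,
  because the group representative is the member with the least
  predicted maximum errors.
* Collapsing precedes filtering deliberately: rare templates whose reads
  skew low-quality are judged by their best member, which suppresses the
  taxon-correlated bias that per-read filtering introduces when quality
  distributions differ between taxa.
* Filtering keeps a group iff its representative's *j_ξ* ≤ *j_tol*
  (boundary kept; the discard rule is a strict inequality).
* Group output order is multiplicity-descending, then lexicographic by
  sequence; representative ties go to input order. Both rules exist only
  to make runs byte-for-byte reproducible.
* Reads shorter than the truncation length are both written to the
  discarded FASTQ and tagged `short` in the report, so no read silently
  vanishes.
* The aligner's "modification" of global alignment is free terminal
  gaps (overlap mode), the conventional choice for merging mates whose
  tails do not overlap; traceback tie-breaks prefer diagonal, then up,
  then left. Correctness is established against an exhaustive
  enumeration oracle and an independent aligner implementation, not
  against the score constants.
* Bases called N carry their emitted quality score (typically 2) into
  the model unmodified; the model consumes only quality scores.

## Synthetic data

`simdata` generates reads whose true error process matches their emitted
quality strings *by construction*: a quality string is drawn from a
profile, then each base is flipped to a uniformly random different base
with probability 10^(−q/10). This makes the emitted scores perfectly
calibrated — the idealized condition under which the error model's
guarantees are exact — and records every read's true error count.

Profiles: `ConstantProfile(40)` (modern-instrument quality ceiling) and
`LinearDecayProfile(38, 15)` (monotone 5'→3' decline from near-perfect
to ≈3% error probability, the shape typical of pyrosequencing tails).
Reproducibility comes from one global seed with per-read substreams
derived from (seed, read index). Errors are substitutions only — the
error model is positionwise and indel-agnostic, so indel realism would
test the simulator, not the filter.

What passing tests on this simulator do **not** show about real data:
real quality scores are imperfectly calibrated (some platforms encode
homopolymer-length confidence rather than substitution probability),
errors are correlated along reads, and PCR errors and chimeras carry
high quality scores. The simulator is a harness for the statistics, not
a platform emulator.

## Problem sizes

Default verification runs use 50,000 simulated 250-nt reads for
calibration measurements, 1,000 random probability vectors up to length
500 for distribution invariants, 200 random instances (N ≤ 12) for
oracle equivalence, and exhaustive alignment enumeration up to length 8.

## Limitations

* The independence and calibration assumptions are the method's whole
  exposure: miscalibrated quality strings shift *j_ξ* systematically.
* The interpolated *j_ξ* is anti-conservative by up to one pmf term (see
  above); use ⌈*j_ξ*⌉ where a strict coverage guarantee is needed.
* Only substitution errors are modelled; indels shift downstream bases
  and are invisible to the per-base model.
* The assembler re-pairs mates by file order, not by id, and does not
  recompute posterior qualities in the overlap (consensus quality is the
  column maximum, which overstates confidence at agreeing columns).
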