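"""Exact Poisson binomial error model for quality-scored reads.

The number of miscalled bases in a read of length ``N`` is the sum
``S_N = X_1 + ... + X_N`` of independent Bernoulli variables, where
``X_i ~ Bernoulli(p_i)`` and ``p_i = 10**(-q_i/10)`` comes from the base's
Phred score. ``S_N`` follows a Poisson binomial distribution; its pmf is
obtained exactly by iterated discrete convolution:

    P(S_k = j) = P(S_{k-1} = j) * (1 - p_k) + P(S_{k-1} = j-1) * p_k

Two per-read summary statistics drive filtering:

* ``lambda = sum(p_i)`` — the expected number of errors (also the rate of
  the Poisson approximation to ``S_N``);
* ``j_xi`` — the confidence-``xi`` quantile of ``S_N``, linearly
  interpolated between the two integers where the cumulative distribution
  crosses ``xi``. A read is discarded when ``j_xi`` exceeds the error
  tolerance ``j_tol``.

The quantile computation is lazy: pmf terms are produced for
``j = 0, 1, ..., j_max`` only, where ``j_max`` is the first ``j`` with
cumulative mass >= ``xi``, so the cost is O(N * j_max) rather than O(N**2).

Boundary note: because ``S_N`` is discrete, the interpolated ``j_xi``
undershoots the exact ``xi``-quantile by up to one pmf term. The statement
"at most ``alpha = 1 - xi`` of reads carry more than ``j`` errors" holds
exactly for ``j = ceil(j_xi)`` (equivalently ``j_max``); for the
interpolated value itself the exceedance probability is
``alpha + (xi - F(j_max - 1))``, slightly above ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterator, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ErrorDistribution",
    "FilterParams",
    "phred_to_prob",
    "error_distribution",
    "predicted_max_errors",
    "predicted_max_errors_batch",
    "poisson_lambda",
    "poisson_predicted_max_errors",
    "brute_force_distribution",
]


@dataclass
class ErrorDistribution:
    """The pmf of a read's error count, ``P(S_N = j)`` for ``j = 0..j_cap``."""

    probs: np.ndarray
    cumulative: np.ndarray
    j_cap: int
    n_bases: int


@dataclass
class FilterParams:
    """Filtering parameters.

    alpha
        Accepted probability of underestimating a read's errors;
        the confidence coefficient is ``xi = 1 - alpha``.
    uncert
        Tolerated errors per nucleotide; ``j_tol = uncert * length``.
    trunc_len
        Fixed truncation length in nucleotides, or ``None`` to skip
        truncation.
    paired, collapse, use_poisson_approx
        Pipeline switches: assemble mate pairs first, dereplicate before
        filtering, and use the Poisson approximation instead of the exact
        distribution.
    """

    alpha: float = 0.005
    uncert: float = 0.01
    trunc_len: int | None = None
    paired: bool = False
    collapse: bool = True
    use_poisson_approx: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 <= self.uncert <= 1.0:
            raise ValueError(f"uncert must be in [0, 1], got {self.uncert}")
        if self.trunc_len is not None and self.trunc_len <= 0:
            raise ValueError(f"trunc_len must be positive, got {self.trunc_len}")

    @property
    def xi(self) -> float:
        return 1.0 - self.alpha


def phred_to_prob(q):
    """Error probability of a base with Phred score ``q``: ``10**(-q/10)``."""
    q_arr = np.asarray(q)
    if np.any(q_arr < 0):
        raise ValueError("Phred scores must be non-negative")
    result = np.power(10.0, -q_arr / 10.0)
    return float(result) if np.isscalar(q) or q_arr.ndim == 0 else result


def _check_probs(probs) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1:
        raise ValueError("per-base error probabilities must be a 1-D sequence")
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("per-base error probabilities must lie in [0, 1]")
    return p


def error_distribution(probs: Sequence[float], j_cap: int) -> ErrorDistribution:
    """Exact pmf of the error count, truncated at ``j_cap``.

    Convolves the per-base Bernoulli variables one at a time. Terms above
    ``j_cap`` never feed back into lower terms, so the truncation is exact:
    the first ``j_cap + 1`` values equal those of the full computation.
    """
    p = _check_probs(probs)
    n = p.size
    if not 0 <= j_cap <= n:
        raise ValueError(f"j_cap must be in [0, {n}], got {j_cap}")
    dist = np.zeros(j_cap + 1)
    dist[0] = 1.0
    for p_i in p:
        new = dist * (1.0 - p_i)
        new[1:] += dist[:-1] * p_i
        dist = new
    return ErrorDistribution(
        probs=dist, cumulative=np.cumsum(dist), j_cap=j_cap, n_bases=n
    )


def _pmf_terms(p: np.ndarray) -> Iterator[float]:
    """Yield ``P(S_N = j)`` for ``j = 0, 1, 2, ...`` lazily.

    Column-wise evaluation of the convolution table: ``cur[k]`` holds
    ``P(S_k = j)`` for the current ``j`` and ``prev`` the ``j - 1`` column,
    so each additional pmf term costs O(N). The arithmetic per table cell
    is identical to :func:`error_distribution`.
    """
    n = p.size
    comp = 1.0 - p
    prev: list[float] | None = None
    j = 0
    while True:
        cur = [0.0] * (n + 1)
        cur[0] = 1.0 if j == 0 else 0.0
        if j == 0:
            for k in range(1, n + 1):
                cur[k] = cur[k - 1] * comp[k - 1]
        else:
            assert prev is not None
            for k in range(1, n + 1):
                cur[k] = cur[k - 1] * comp[k - 1] + prev[k - 1] * p[k - 1]
        yield cur[n]
        prev = cur
        j += 1
        if j > n:
            return


def _interpolate(j_max: int, cum_before: float, pmf_at: float, xi: float) -> float:
    # linear interpolation of the cdf between j_max - 1 and j_max;
    # pmf exactly 0 (floating-point pathology) falls back to j_max.
    if pmf_at <= 0.0:
        return float(j_max)
    return max(0.0, j_max - 1 + (xi - cum_before) / pmf_at)


def _stop_and_interpolate(terms: Iterator[float], xi: float, limit: int) -> float:
    cum = 0.0
    for j, pj in enumerate(terms):
        if cum + pj >= xi:
            return _interpolate(j, cum, pj, xi)
        cum += pj
        if j >= limit:  # cdf never reached xi (floating-point loss)
            return float(limit)
    return float(limit)


def predicted_max_errors(probs: Sequence[float], xi: float = 0.995) -> float:
    """Predicted maximum number of errors ``j_xi`` at confidence ``xi``.

    Grows the error-count pmf term by term until the cumulative mass first
    reaches ``xi`` at ``j_max`` (terms beyond ``j_max`` are never computed),
    then interpolates the cdf linearly:

        j_xi = j_max - 1 + (xi - F(j_max - 1)) / P(S_N = j_max)

    clamped below at zero.
    """
    if not 0.0 < xi < 1.0:
        raise ValueError(f"xi must be in (0, 1), got {xi}")
    p = _check_probs(probs)
    if p.size == 0:
        raise ValueError("cannot predict errors for an empty read")
    return _stop_and_interpolate(_pmf_terms(p), xi, p.size)


def predicted_max_errors_batch(prob_matrix: np.ndarray, xi: float = 0.995) -> np.ndarray:
    """``j_xi`` for many equal-length reads at once.

    Vectorized across reads: the pmf of every read is convolved up to a
    shared cap, which doubles until every read's cumulative mass has crossed
    ``xi``. Results agree with :func:`predicted_max_errors` applied per row.
    """
    if not 0.0 < xi < 1.0:
        raise ValueError(f"xi must be in (0, 1), got {xi}")
    pm = np.asarray(prob_matrix, dtype=float)
    if pm.ndim != 2 or pm.shape[1] == 0:
        raise ValueError("prob_matrix must be 2-D with at least one column")
    if np.any(pm < 0.0) or np.any(pm > 1.0):
        raise ValueError("per-base error probabilities must lie in [0, 1]")
    n_reads, length = pm.shape

    result = np.empty(n_reads)
    pending = np.arange(n_reads)
    cap = min(8, length)
    while pending.size:
        sub = pm[pending]
        dist = np.zeros((pending.size, cap + 1))
        dist[:, 0] = 1.0
        for i in range(length):
            p_col = sub[:, i][:, None]
            new = dist * (1.0 - p_col)
            new[:, 1:] += dist[:, :-1] * p_col
            dist = new
        cum = np.cumsum(dist, axis=1)
        done = (cum[:, -1] >= xi) | (cap >= length)
        for row in np.flatnonzero(done):
            crossing = np.flatnonzero(cum[row] >= xi)
            if crossing.size == 0:  # cdf never reached xi at full support
                result[pending[row]] = float(length)
                continue
            j_max = int(crossing[0])
            cum_before = cum[row, j_max - 1] if j_max > 0 else 0.0
            result[pending[row]] = _interpolate(
                j_max, cum_before, dist[row, j_max], xi
            )
        pending = pending[~done]
        cap = min(cap * 2, length)
    return result


def poisson_lambda(probs: Sequence[float]) -> float:
    """Expected error count ``lambda = sum(p_i)`` (Poisson approximation rate)."""
    return float(_check_probs(probs).sum())


def poisson_predicted_max_errors(probs: Sequence[float], xi: float = 0.995) -> float:
    """``j_xi`` under the Poisson approximation ``S_N ~ Poisson(sum(p_i))``.

    Same stopping rule and interpolation as :func:`predicted_max_errors`,
    with Poisson pmf terms. Accurate when all ``p_i`` are small, but can
    diverge badly from the exact value when a read mixes a few very
    low-quality bases into an otherwise clean sequence.
    """
    if not 0.0 < xi < 1.0:
        raise ValueError(f"xi must be in (0, 1), got {xi}")
    p = _check_probs(probs)
    if p.size == 0:
        raise ValueError("cannot predict errors for an empty read")
    lam = p.sum()

    def terms() -> Iterator[float]:
        j = 0
        while True:
            yield float(stats.poisson.pmf(j, lam))
            j += 1

    # Poisson support is unbounded; cap the scan generously for safety.
    return _stop_and_interpolate(terms(), xi, max(1000, 10 * p.size))


def brute_force_distribution(probs: Sequence[float]) -> ErrorDistribution:
    """Exact error-count pmf by enumerating every error pattern.

    Sums the probability of all ``2**N`` subsets of positions; the explicit
    closed form of the Poisson binomial pmf, feasible only for tiny reads
    (``N <= 15``). Serves as an independent oracle for
    :func:`error_distribution` in the test suite.
    """
    p = _check_probs(probs)
    n = p.size
    if n > 15:
        raise ValueError(f"brute force enumeration refuses N > 15 (got {n})")
    pmf = np.zeros(n + 1)
    for pattern in product((0, 1), repeat=n):
        mass = 1.0
        for p_i, bit in zip(p, pattern):
            mass *= p_i if bit else (1.0 - p_i)
        pmf[sum(pattern)] += mass
    return ErrorDistribution(
        probs=pmf, cumulative=np.cumsum(pmf), j_cap=n, n_bases=n
    )
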