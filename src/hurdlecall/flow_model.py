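"""Weighted Poisson count model for per-flow homopolymer lengths.

In flow-cycle sequencing (454-style pyrosequencing) each flow incorporates
``n`` identical nucleotides, ``n = 0`` when the flowed base does not match
the template.  Two departures from a Poisson law dominate: an excess of
zero flows (three of every four flows miss, on average) and marked
underdispersion of the positive counts.  The model used throughout this
package is therefore a hurdle mixture: a Bernoulli component for the
zero/positive split and, conditional on a positive flow, a zero-truncated
*weighted* Poisson distribution whose exponential distance weights

    w_n = exp(-theta * (lambda - n)**2),   theta >= 0,

shrink the variance below the mean.  ``theta = 0`` recovers the ordinary
(zero-truncated) Poisson and is admitted as a testable limit.

This module is pure numerics: densities, the normalizing constant of the
weighted Poisson series, and moments by enumeration.  Rates ``lambda`` and
hurdle probabilities ``pi`` vary per flow through covariates (see
:mod:`hurdlecall.gam`); ``theta`` is a single global dispersion parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

# Series truncation: stop when the next raw term falls below TERM_RTOL times
# the running sum, hard cap at HARD_CAP terms.  lambda rarely exceeds ~10 in
# flow data; terms decay factorially.
TERM_RTOL = 1e-15
HARD_CAP = 200


@dataclass(frozen=True)
class WeightedPoissonParams:
    """Parameters of one weighted Poisson flow distribution.

    Parameters
    ----------
    lam : float
        Poisson rate ``lambda`` for the flow; strictly positive.
    theta : float
        Global dispersion weight parameter; non-negative. ``0`` is the
        plain-Poisson limit.
    n_max : int
        Upper bound of homopolymer lengths in reported probability
        vectors (sums for normalization use the series truncation rule,
        not ``n_max``).
    """

    lam: float
    theta: float
    n_max: int = 12

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lam) and self.lam > 0):
            raise ValueError(f"lam must be finite and > 0, got {self.lam!r}")
        if not (math.isfinite(self.theta) and self.theta >= 0):
            raise ValueError(f"theta must be finite and >= 0, got {self.theta!r}")
        if self.n_max < 1:
            raise ValueError(f"n_max must be >= 1, got {self.n_max!r}")


@dataclass(frozen=True)
class HurdleParams:
    """Hurdle mixture parameters: P(positive flow) and the positive part."""

    pi: float
    wp: WeightedPoissonParams

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pi) and 0.0 <= self.pi <= 1.0):
            raise ValueError(f"pi must be a probability in [0, 1], got {self.pi!r}")


def _raw_term(n: int, lam: float, theta: float) -> float:
    """Unnormalized weighted Poisson term w_n e^-lam lam^n / n!."""
    log_t = -lam + n * math.log(lam) - math.lgamma(n + 1) - theta * (lam - n) ** 2
    return math.exp(log_t)


def normalizing_constant(params: WeightedPoissonParams) -> float:
    """Normalizing constant W = sum_{n>=0} w_n e^-lam lam^n / n!.

    The series is summed until the next raw term drops below
    ``TERM_RTOL`` times the running sum (hard cap ``HARD_CAP`` terms).
    For ``theta >= 0`` every weight is <= 1, hence ``0 < W <= 1``.
    """
    lam, theta = params.lam, params.theta
    total = 0.0
    for n in range(HARD_CAP + 1):
        term = _raw_term(n, lam, theta)
        if n > lam and total > 0 and term < TERM_RTOL * total:
            break
        total += term
    return total


def weighted_poisson_pmf(n: int, params: WeightedPoissonParams) -> float:
    """P(N = n) under the weighted Poisson law (normalized)."""
    if n < 0:
        raise ValueError(f"count must be >= 0, got {n}")
    return _raw_term(n, params.lam, params.theta) / normalizing_constant(params)


def zt_weighted_poisson_pmf(n: int, params: WeightedPoissonParams) -> float:
    """P(N = n | N >= 1): the zero-truncated weighted Poisson density."""
    if n < 1:
        raise ValueError(
            f"zero-truncated pmf is defined for counts >= 1, got {n} "
            "(the zero class belongs to the hurdle component)"
        )
    # normalize over the positive raw terms directly (robust when the
    # zero class carries almost all weighted Poisson mass)
    lam, theta = params.lam, params.theta
    pos_total = 0.0
    for m in range(1, HARD_CAP + 1):
        term = _raw_term(m, lam, theta)
        if m > lam and pos_total > 0 and term < TERM_RTOL * pos_total:
            break
        pos_total += term
    return _raw_term(n, lam, theta) / pos_total


def hurdle_pmf(n: int, params: HurdleParams) -> float:
    """Hurdle mixture: P(N=0) = 1 - pi; P(N=n) = pi * f_ZTWP(n) for n >= 1."""
    if n < 0:
        raise ValueError(f"count must be >= 0, got {n}")
    if n == 0:
        return 1.0 - params.pi
    if params.pi == 0.0:
        return 0.0
    return params.pi * zt_weighted_poisson_pmf(n, params.wp)


def hurdle_pmf_vector(params: HurdleParams, renormalize: bool = False) -> np.ndarray:
    """Probability vector over HPL 0..n_max.

    With ``renormalize=True`` the reported range is rescaled to sum to 1
    (used when emitting per-flow probability matrices).
    """
    probs = np.array([hurdle_pmf(n, params) for n in range(params.wp.n_max + 1)])
    if renormalize:
        probs = probs / probs.sum()
    return probs


def hurdle_moments(params: HurdleParams) -> tuple[float, float]:
    """Mean and variance of the hurdle distribution by enumeration.

    Enumeration follows the series truncation rule (cap ``HARD_CAP``) so
    that moments match untruncated closed forms where they exist, e.g. the
    zero-truncated Poisson mean ``lam / (1 - exp(-lam))`` at ``theta=0``.
    """
    lam, theta = params.wp.lam, params.wp.theta
    n = np.arange(HARD_CAP + 1)
    raw = np.exp(-lam + n * np.log(lam) - gammaln(n + 1) - theta * (lam - n) ** 2)
    pmf = raw / raw.sum()
    if params.pi == 0.0:
        return 0.0, 0.0
    zt = pmf.copy()
    zt[0] = 0.0
    zt /= zt.sum()
    probs = params.pi * zt
    probs[0] += 1.0 - params.pi
    mean = float(np.dot(n, probs))
    var = float(np.dot((n - mean) ** 2, probs))
    return mean, var


# ---------------------------------------------------------------------------
# Vectorized log-density helpers used by the GAM fitting loop.
# ---------------------------------------------------------------------------


def _grid_size(lam_max: float) -> int:
    """Length of the summation grid for a batch with maximal rate lam_max."""
    return int(min(HARD_CAP, math.ceil(lam_max + 8.0 * math.sqrt(lam_max + 1.0) + 15.0)))


def _log_term_grid(lam: np.ndarray, theta: float) -> np.ndarray:
    """Matrix of log raw series terms, flows x grid counts 0..N."""
    lam = np.asarray(lam, dtype=float)
    grid = np.arange(_grid_size(float(lam.max())) + 1)
    return (
        -lam[:, None]
        + grid[None, :] * np.log(lam[:, None])
        - gammaln(grid + 1)[None, :]
        - theta * (lam[:, None] - grid[None, :]) ** 2
    )


def log_normalizing_constant(lam: np.ndarray, theta: float) -> np.ndarray:
    """log W for a vector of rates (shared theta), via log-sum-exp on a grid."""
    return logsumexp(_log_term_grid(lam, theta), axis=1)


def zt_log_pmf(counts: np.ndarray, lam: np.ndarray, theta: float) -> np.ndarray:
    """log f_ZTWP(counts; lam, theta), vectorized over flows.

    ``counts`` must all be >= 1 (the hurdle owns the zero class).
    """
    counts = np.asarray(counts)
    lam = np.asarray(lam, dtype=float)
    if np.any(counts < 1):
        raise ValueError("zero-truncated log-pmf requires all counts >= 1")
    log_terms = _log_term_grid(lam, theta)
    log_num = (
        -lam
        + counts * np.log(lam)
        - gammaln(counts + 1)
        - theta * (lam - counts) ** 2
    )
    # denominator P(N >= 1) summed directly over the positive grid terms:
    # robust when P(0) -> 1 and 1 - f0 would underflow
    log_pos = logsumexp(log_terms[:, 1:], axis=1)
    return log_num - log_pos


def hurdle_pmf_matrix(
    pi: np.ndarray, lam: np.ndarray, theta: float, n_max: int
) -> np.ndarray:
    """Per-flow hurdle probability matrix over HPL 0..n_max (rows: flows).

    Rows are exact hurdle probabilities on 0..n_max (they sum to 1 up to the
    mass beyond n_max); callers that report the matrix renormalize rows.
    """
    pi = np.asarray(pi, dtype=float)
    lam = np.asarray(lam, dtype=float)
    log_terms = _log_term_grid(lam, theta)
    log_pos = logsumexp(log_terms[:, 1:], axis=1)
    n_report = min(n_max, log_terms.shape[1] - 1)
    zt = np.exp(log_terms[:, : n_report + 1] - log_pos[:, None])
    if n_report < n_max:
        zt = np.pad(zt, ((0, 0), (0, n_max - n_report)))
    zt[:, 0] = 0.0
    out = pi[:, None] * zt
    out[:, 0] = 1.0 - pi
    return out
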