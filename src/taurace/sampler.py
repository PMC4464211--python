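"""Inverse-transform sampling with guaranteed-bracketing CDF inversion.

Inverse-transform sampling draws a waiting time τ by solving F(τ) = r for a
uniform variate r ∈ (0, 1).  For most waiting-time laws — notably the
single-molecule Michaelis-Menten density — F has no closed-form inverse, so
the root is isolated numerically.  The contract here mirrors interval
methods: the result is an *enclosure* [τ_low, τ_high] that provably contains
the unique root (a verified sign change of F − r across it) and whose width
is at most the requested precision.  Bisection from a verified bracket keeps
that guarantee at every step; because F is strictly increasing where we
invert it (β > γ for the MM family), the root is unique and the procedure is
complete: if the quantile exists, expansion + bisection finds it.

A closed-form quantile is used as a fast path when the family has one
(exponential, Erlang); the numeric inverter remains available for every
family and is what the enclosure semantics are stated for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import InversionError
from .distributions import WaitingTimeDistribution

__all__ = ["InversionConfig", "InversionResult", "invert_cdf", "sample", "sample_many"]

#: relative (to the distribution mean) enclosure width used when
#: InversionConfig.precision is None
DEFAULT_RELATIVE_PRECISION = 1e-9
#: absolute floor so that tiny-mean distributions still terminate
PRECISION_FLOOR = 1e-15


@dataclass(frozen=True)
class InversionConfig:
    """Tunables of the numeric inverter.

    precision
        Absolute width of the final enclosing interval for τ (time units).
        ``None`` (default) means ``1e-9 × mean(dist)``, floored at 1e-15.
    max_bracket_expansions
        Cap on the geometric (×2) expansions of the upper bracket end.
    max_bisections
        Cap on bisection steps; generous, since each step halves the bracket.
    """

    precision: float | None = None
    max_bracket_expansions: int = 200
    max_bisections: int = 20000

    def __post_init__(self):
        if self.precision is not None and not (self.precision > 0):
            raise ValueError(f"precision must be > 0, got {self.precision}")
        if self.max_bracket_expansions < 1 or self.max_bisections < 1:
            raise ValueError("iteration caps must be >= 1")

    def resolved_precision(self, dist: WaitingTimeDistribution) -> float:
        if self.precision is not None:
            return self.precision
        return max(DEFAULT_RELATIVE_PRECISION * dist.mean(), PRECISION_FLOOR)


@dataclass(frozen=True)
class InversionResult:
    """Verified enclosure of the quantile: cdf(τ_low) ≤ r ≤ cdf(τ_high).

    ``tau`` is the reported point value, the midpoint of the enclosure.
    """

    tau_low: float
    tau_high: float
    tau: float


def invert_cdf(dist: WaitingTimeDistribution, r: float,
               config: InversionConfig | None = None) -> InversionResult:
    """Solve F(τ) = r by bracket expansion + bisection.

    Parameters
    ----------
    dist
        Any waiting-time distribution with a strictly increasing CDF on the
        support (for the MM family this is the β > γ case, which holds for
        every valid parameter set).
    r
        Target quantile, strictly inside (0, 1).
    config
        Precision and iteration caps; defaults to :class:`InversionConfig()`.

    Raises
    ------
    InversionError
        If r is outside (0, 1), the upper bracket cannot be expanded to reach
        F > r within the cap, or the bisection cap is exceeded.
    """
    if config is None:
        config = InversionConfig()
    if not (0.0 < r < 1.0):
        raise InversionError(f"quantile r must lie strictly in (0, 1), got {r}")

    precision = config.resolved_precision(dist)

    # initial bracket [0, mean]; F(0) = 0 < r always
    lo, f_lo = 0.0, 0.0
    hi = dist.mean()
    f_hi = dist.cdf(hi)
    expansions = 0
    while f_hi < r:
        expansions += 1
        if expansions > config.max_bracket_expansions:
            raise InversionError(
                f"no upper bracket with F > r={r} found within "
                f"{config.max_bracket_expansions} geometric expansions"
            )
        lo, f_lo = hi, f_hi  # F is monotone: the root lies above hi
        hi *= 2.0
        f_hi = dist.cdf(hi)

    # bisection: the invariant f_lo <= r <= f_hi holds throughout
    bisections = 0
    while hi - lo > precision:
        bisections += 1
        if bisections > config.max_bisections:
            raise InversionError(f"bisection cap {config.max_bisections} exceeded")
        mid = 0.5 * (lo + hi)
        if mid <= lo or mid >= hi:  # interval at floating-point resolution
            break
        if dist.cdf(mid) < r:
            lo = mid
        else:
            hi = mid

    return InversionResult(tau_low=lo, tau_high=hi, tau=0.5 * (lo + hi))


def _draw_open_uniform(rng: np.random.Generator) -> float:
    # reject 0 so r lies in the open interval (0,1); random() never returns 1.0
    r = rng.random()
    while r == 0.0:
        r = rng.random()
    return r


def sample(dist: WaitingTimeDistribution, rng: np.random.Generator,
           config: InversionConfig | None = None, *,
           use_analytic: bool = True) -> float:
    """Draw one waiting time from ``dist`` by inverse-transform sampling.

    r is uniform on the open interval (0, 1); the numeric route returns the
    midpoint of the verified enclosure.  With ``use_analytic=True`` (default)
    a closed-form quantile is used when the family provides one — the draw
    consumes exactly one uniform either way, so switching routes does not
    shift the RNG stream.
    """
    r = _draw_open_uniform(rng)
    if use_analytic:
        tau = dist.ppf_analytic(r)
        if tau is not None:
            return float(tau)
    return invert_cdf(dist, r, config).tau


def sample_many(dist: WaitingTimeDistribution, rng: np.random.Generator, n: int,
                config: InversionConfig | None = None, *,
                use_analytic: bool = True) -> np.ndarray:
    """Draw ``n`` i.i.d. waiting times (a convenience loop over :func:`sample`)."""
    return np.array([sample(dist, rng, config, use_analytic=use_analytic)
                     for _ in range(int(n))])
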