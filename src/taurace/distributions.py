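"""Waiting-time distributions for reaction events.

The central object is the exact waiting-time density of a single enzyme
turning substrate into product under the Michaelis-Menten (MM) scheme

    E + S <=>[k1, k_minus1] ES ->[k2] E + P

Single-molecule experiments measure the interval τ between two consecutive
product formations by one enzyme molecule.  In the absence of dynamic
disorder that interval has the exact two-exponential density

    f(τ) = α (e^{βτ} − e^{γτ}),      τ ≥ 0

with, writing σ = k1·[S] + k_minus1 + k2,

    B = −σ/2 < 0,
    A = sqrt(σ²/4 − k1·k2·[S]) > 0,
    α = k1·k2·[S] / (2A),  β = A + B,  γ = B − A.

Both exponents are negative and β > γ, so f vanishes at τ = 0 (unlike an
exponential), rises to a single maximum and decays.  The reciprocal mean
obeys the ensemble MM rate law,

    1/⟨τ⟩ = k2·[S] / ([S] + K_M),      K_M = (k_minus1 + k2)/k1,

which is the ergodic link between single-molecule and ensemble kinetics and
lets bulk-measured constants parameterise single-molecule simulations.

Also provided: exponential, Erlang and hyperexponential families under the
same interface, so a simulation engine can race reactions whose waiting
times follow any of them.  Units are the caller's responsibility: k1 and
[S] need only be mutually consistent (M with M⁻¹s⁻¹, μM with μM⁻¹s⁻¹, or
copy numbers with per-copy rates); no conversion is performed.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._errors import DegenerateAError, ParameterError

__all__ = [
    "MMWaitingTimeParams",
    "ExponentialParams",
    "ErlangParams",
    "HyperexponentialParams",
    "WaitingTimeDistribution",
    "MMWaitingTime",
    "Exponential",
    "Erlang",
    "Hyperexponential",
    "mm_derive",
    "mm_mean_rate",
    "pdf",
    "cdf",
    "mean",
]


# --------------------------------------------------------------------------
# parameter records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MMWaitingTimeParams:
    """Raw and derived parameters of the single-molecule MM waiting-time density.

    Raw: ``k1`` (per-concentration per-time), ``k2`` (per-time), ``k_minus1``
    (per-time, may be 0) and the substrate concentration ``S``.  Derived:
    ``A``, ``B``, ``alpha``, ``beta``, ``gamma_`` as in the module docstring.
    Construct through :func:`mm_derive`, which validates everything.
    """

    k1: float
    k2: float
    k_minus1: float
    S: float
    A: float = field(repr=False)
    B: float = field(repr=False)
    alpha: float
    beta: float
    gamma_: float

    @property
    def K_M(self) -> float:
        """Michaelis constant (k_minus1 + k2)/k1, in units of S."""
        return (self.k_minus1 + self.k2) / self.k1


@dataclass(frozen=True)
class ExponentialParams:
    lam: float

    def __post_init__(self):
        if not (self.lam > 0):
            raise ParameterError(f"exponential rate must be > 0, got {self.lam}")


@dataclass(frozen=True)
class ErlangParams:
    k: int
    lam: float

    def __post_init__(self):
        if int(self.k) != self.k or self.k < 1:
            raise ParameterError(f"Erlang shape must be a positive integer, got {self.k}")
        if not (self.lam > 0):
            raise ParameterError(f"Erlang rate must be > 0, got {self.lam}")


@dataclass(frozen=True)
class HyperexponentialParams:
    weights: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self):
        w = tuple(float(x) for x in self.weights)
        r = tuple(float(x) for x in self.rates)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "rates", r)
        if len(w) != len(r) or len(w) == 0:
            raise ParameterError("weights and rates must be equal-length, non-empty")
        if any(x <= 0 for x in w):
            raise ParameterError("all mixture weights must be > 0")
        if any(x <= 0 for x in r):
            raise ParameterError("all mixture rates must be > 0")
        if abs(sum(w) - 1.0) > 1e-12:
            raise ParameterError(f"mixture weights must sum to 1, got {sum(w)}")


def mm_derive(k1: float, k2: float, k_minus1: float, S: float) -> MMWaitingTimeParams:
    """Validate raw MM rate constants and derive A, B, α, β, γ.

    Raises
    ------
    ParameterError
        If k1 ≤ 0, k2 ≤ 0, k_minus1 < 0 or S ≤ 0.
    DegenerateAError
        If σ²/4 − k1·k2·S ≤ 0 (A = 0 double-root set, or complex A).  This is
        a measure-zero boundary (k1·S = k2 when k_minus1 = 0); the limiting
        α·τ·e^{Bτ} form is deliberately not implemented.
    """
    if not (k1 > 0):
        raise ParameterError(f"k1 must be > 0, got {k1}")
    if not (k2 > 0):
        raise ParameterError(f"k2 must be > 0, got {k2}")
    if not (k_minus1 >= 0):
        raise ParameterError(f"k_minus1 must be >= 0, got {k_minus1}")
    if not (S > 0):
        raise ParameterError(f"substrate concentration must be > 0, got {S}")

    sigma = k1 * S + k_minus1 + k2
    B = -sigma / 2.0
    disc = B * B - k1 * k2 * S
    if disc <= 0:
        raise DegenerateAError(
            f"B² − k1·k2·S = {disc:g} ≤ 0: the two-exponential density "
            "degenerates (A = 0); perturb the parameters"
        )
    A = math.sqrt(disc)
    alpha = k1 * k2 * S / (2.0 * A)
    beta = A + B
    gamma_ = B - A
    # With positive rates, 0 < A < |B| always, hence γ < β < 0.
    assert beta < 0 and gamma_ < beta
    return MMWaitingTimeParams(
        k1=k1, k2=k2, k_minus1=k_minus1, S=S,
        A=A, B=B, alpha=alpha, beta=beta, gamma_=gamma_,
    )


def mm_mean_rate(params: MMWaitingTimeParams) -> float:
    """Reciprocal mean waiting time 1/⟨τ⟩ = k2·[S]/([S] + K_M).

    This is the single-molecule MM equation: the single-enzyme mean turnover
    rate coincides with the ensemble MM velocity at the same concentration.
    """
    return params.k2 * params.S / (params.S + params.K_M)


# --------------------------------------------------------------------------
# distributions
# --------------------------------------------------------------------------

def _check_tau(tau, lenient: bool):
    t = np.asarray(tau, dtype=float)
    if not lenient and np.any(t < 0):
        raise ValueError("waiting time τ must be >= 0 (pass lenient=True to map τ<0 to 0)")
    return t


class WaitingTimeDistribution(ABC):
    """A waiting-time law: non-negative density, CDF with F(0)=0 and F(∞)=1.

    ``pdf``/``cdf`` accept scalars or arrays.  Negative τ is an error unless
    ``lenient=True`` (then the density/CDF is 0 there).  ``ppf_analytic``
    returns a closed-form quantile where one exists, else None — the numeric
    bracketing inverter in :mod:`taurace.sampler` covers every family.
    """

    family: str

    @abstractmethod
    def pdf(self, tau, *, lenient: bool = False): ...

    @abstractmethod
    def cdf(self, tau, *, lenient: bool = False): ...

    @abstractmethod
    def mean(self) -> float: ...

    @abstractmethod
    def second_moment(self) -> float: ...

    def variance(self) -> float:
        m = self.mean()
        return self.second_moment() - m * m

    def ppf_analytic(self, r: float) -> float | None:
        return None


class MMWaitingTime(WaitingTimeDistribution):
    """Exact single-molecule MM turnover-time density f(τ) = α(e^{βτ} − e^{γτ})."""

    family = "mm_single_molecule"

    def __init__(self, params: MMWaitingTimeParams):
        self.params = params

    def pdf(self, tau, *, lenient: bool = False):
        t = _check_tau(tau, lenient)
        p = self.params
        out = p.alpha * (np.exp(p.beta * t) - np.exp(p.gamma_ * t))
        out = np.where(t < 0, 0.0, out)
        return out if out.ndim else float(out)

    def cdf(self, tau, *, lenient: bool = False):
        # F(τ) = α[(e^{βτ}−1)/β − (e^{γτ}−1)/γ]; expm1 keeps precision at small τ.
        t = _check_tau(tau, lenient)
        p = self.params
        out = p.alpha * (np.expm1(p.beta * t) / p.beta - np.expm1(p.gamma_ * t) / p.gamma_)
        out = np.where(t < 0, 0.0, out)
        return out if out.ndim else float(out)

    def mean(self) -> float:
        # ⟨τ⟩ = α(1/β² − 1/γ²); equals 1/mm_mean_rate analytically.
        p = self.params
        return p.alpha * (1.0 / p.beta**2 - 1.0 / p.gamma_**2)

    def second_moment(self) -> float:
        p = self.params
        return -2.0 * p.alpha * (1.0 / p.beta**3 - 1.0 / p.gamma_**3)


class Exponential(WaitingTimeDistribution):
    """Memoryless waiting time, f(τ) = λe^{−λτ} — the Markov-jump special case."""

    family = "exponential"

    def __init__(self, params: ExponentialParams | float):
        if not isinstance(params, ExponentialParams):
            params = ExponentialParams(float(params))
        self.params = params

    def pdf(self, tau, *, lenient: bool = False):
        t = _check_tau(tau, lenient)
        lam = self.params.lam
        out = np.where(t < 0, 0.0, lam * np.exp(-lam * np.maximum(t, 0.0)))
        return out if out.ndim else float(out)

    def cdf(self, tau, *, lenient: bool = False):
        t = _check_tau(tau, lenient)
        out = np.where(t < 0, 0.0, -np.expm1(-self.params.lam * np.maximum(t, 0.0)))
        return out if out.ndim else float(out)

    def mean(self) -> float:
        return 1.0 / self.params.lam

    def second_moment(self) -> float:
        return 2.0 / self.params.lam**2

    def ppf_analytic(self, r: float) -> float:
        return -math.log1p(-r) / self.params.lam


class Erlang(WaitingTimeDistribution):
    """Sum of k i.i.d. exponential stages of rate λ (integer-shape gamma)."""

    family = "erlang"

    def __init__(self, params: ErlangParams | None = None, *, k: int | None = None,
                 lam: float | None = None):
        if params is None:
            params = ErlangParams(k=k, lam=lam)
        self.params = params
        self._frozen = stats.erlang(a=int(params.k), scale=1.0 / params.lam)

    def pdf(self, tau, *, lenient: bool = False):
        t = _check_tau(tau, lenient)
        out = np.where(t < 0, 0.0, self._frozen.pdf(np.maximum(t, 0.0)))
        return out if out.ndim else float(out)

    def cdf(self, tau, *, lenient: bool = False):
        t = _check_tau(tau, lenient)
        out = np.where(t < 0, 0.0, self._frozen.cdf(np.maximum(t, 0.0)))
        return out if out.ndim else float(out)

    def mean(self) -> float:
        return self.params.k / self.params.lam

    def second_moment(self) -> float:
        k, lam = self.params.k, self.params.lam
        return k * (k + 1) / lam**2

    def ppf_analytic(self, r: float) -> float:
        return float(self._frozen.ppf(r))


class Hyperexponential(WaitingTimeDistribution):
    """Finite mixture of exponentials: f(τ) = Σᵢ wᵢ λᵢ e^{−λᵢτ}.

    Coefficient of variation ≥ 1; models a reaction that proceeds through one
    of several alternative memoryless channels chosen with probability wᵢ.
    """

    family = "hyperexponential"

    def __init__(self, params: HyperexponentialParams | None = None, *,
                 weights=None, rates=None):
        if params is None:
            params = HyperexponentialParams(tuple(weights), tuple(rates))
        self.params = params
        self._w = np.asarray(params.weights)
        self._lam = np.asarray(params.rates)

    def pdf(self, tau, *, lenient: bool = False):
        t = _check_tau(tau, lenient)
        tt = np.maximum(t, 0.0)[..., None]
        out = np.sum(self._w * self._lam * np.exp(-self._lam * tt), axis=-1)
        out = np.where(t < 0, 0.0, out)
        return out if out.ndim else float(out)

    def cdf(self, tau, *, lenient: bool = False):
        t = _check_tau(tau, lenient)
        tt = np.maximum(t, 0.0)[..., None]
        out = np.sum(self._w * (-np.expm1(-self._lam * tt)), axis=-1)
        out = np.where(t < 0, 0.0, out)
        return out if out.ndim else float(out)

    def mean(self) -> float:
        return float(np.sum(self._w / self._lam))

    def second_moment(self) -> float:
        return float(np.sum(2.0 * self._w / self._lam**2))


# --------------------------------------------------------------------------
# functional façade
# --------------------------------------------------------------------------

def pdf(dist: WaitingTimeDistribution, tau, *, lenient: bool = False):
    """Density of ``dist`` at ``tau`` (per-time)."""
    return dist.pdf(tau, lenient=lenient)


def cdf(dist: WaitingTimeDistribution, tau, *, lenient: bool = False):
    """Cumulative probability F(τ) ∈ [0, 1]."""
    return dist.cdf(tau, lenient=lenient)


def mean(dist: WaitingTimeDistribution) -> float:
    """Analytic mean waiting time."""
    return dist.mean()
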