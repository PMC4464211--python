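"""Reference parameter sets, statistical validation helpers, and generators.

The bundled parameter sets are literature values for single-enzyme turnover:
the A-sets are single-molecule kinetic constants at fixed substrate
concentration (k1 = 1e7 M⁻¹s⁻¹, k2 = 250 s⁻¹, k−1 ∈ {0, 50, 2000} s⁻¹,
[S] = 0.005 mM), and the B-sets are ensemble-measured β-lactamase constants
(μM units) used to sweep the substrate axis of the saturation curve.  Both
let every validation stage run without external data; a seeded random
generator of valid parameter records covers the space between them.

Statistical checks follow standard practice: a Pearson χ² goodness-of-fit
of sampled waiting times against the analytic density over equal-probability
bins, and a sampled saturation curve ([S] vs the reciprocal mean waiting
time) compared against the ensemble MM rate law with delta-method error
bars.  "Pass" for a true-null χ² check means p > α.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._errors import ParameterError
from .distributions import (
    MMWaitingTime,
    MMWaitingTimeParams,
    WaitingTimeDistribution,
    mm_derive,
    mm_mean_rate,
)
from .engine import ReactionSystem, parse_reactions
from .sampler import InversionConfig, invert_cdf, sample_many

__all__ = [
    "FixtureSet",
    "FIXTURES",
    "GofReport",
    "histogram_vs_pdf",
    "saturation_curve",
    "make_random_valid_params",
    "example5_system",
    "mm_elementary_system",
    "mm_lumped_nonmarkov_system",
    "mm_lumped_markov_system",
]


@dataclass(frozen=True)
class FixtureSet:
    """A named kinetic parameter set; ``S`` is None for sets meant to be
    swept over substrate concentrations."""

    name: str
    k1: float
    k2: float
    k_minus1: float
    S: float | None
    units: str

    def params(self, S: float | None = None) -> MMWaitingTimeParams:
        S_eff = S if S is not None else self.S
        if S_eff is None:
            raise ParameterError(f"fixture {self.name} needs an explicit S")
        return mm_derive(self.k1, self.k2, self.k_minus1, S_eff)

    def dist(self, S: float | None = None) -> MMWaitingTime:
        return MMWaitingTime(self.params(S))


#: single-molecule A-sets (M units, [S] = 0.005 mM) and ensemble β-lactamase
#: B-sets (μM units, substrate swept externally)
FIXTURES: dict[str, FixtureSet] = {
    "A1": FixtureSet("A1", k1=1e7, k2=250.0, k_minus1=0.0, S=5e-6,
                     units="k1 in M^-1 s^-1; S in M (0.005 mM)"),
    "A2": FixtureSet("A2", k1=1e7, k2=250.0, k_minus1=50.0, S=5e-6,
                     units="k1 in M^-1 s^-1; S in M (0.005 mM)"),
    "A3": FixtureSet("A3", k1=1e7, k2=250.0, k_minus1=2000.0, S=5e-6,
                     units="k1 in M^-1 s^-1; S in M (0.005 mM)"),
    "B1": FixtureSet("B1", k1=41.0, k2=1920.0, k_minus1=2320.0, S=None,
                     units="k1 in uM^-1 s^-1; S in uM"),
    "B2": FixtureSet("B2", k1=22.0, k2=62.0, k_minus1=196.0, S=None,
                     units="k1 in uM^-1 s^-1; S in uM"),
    "B3": FixtureSet("B3", k1=123.0, k2=980.0, k_minus1=11800.0, S=None,
                     units="k1 in uM^-1 s^-1; S in uM"),
}


# --------------------------------------------------------------------------
# goodness of fit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GofReport:
    """Pearson χ² of an empirical waiting-time sample against an analytic law."""

    statistic: float
    dof: int
    p_value: float
    bin_edges: np.ndarray
    observed: np.ndarray
    expected: np.ndarray

    def passed(self, alpha: float = 0.01) -> bool:
        """True when the sample is consistent with the law at level α."""
        return self.p_value > alpha


def _quantile(dist: WaitingTimeDistribution, q: float,
              config: InversionConfig) -> float:
    tau = dist.ppf_analytic(q)
    if tau is not None:
        return float(tau)
    return invert_cdf(dist, q, config).tau


def histogram_vs_pdf(samples: np.ndarray, dist: WaitingTimeDistribution,
                     bins: int = 20) -> GofReport:
    """Pearson χ² over equal-probability bins of ``dist``.

    Bin edges are the j/bins quantiles of the analytic CDF, so every bin has
    expected mass 1/bins; adjacent bins are merged until every expected count
    is ≥ 5.  No parameters are fitted from the sample, so dof = bins − 1.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    if n < 100:
        raise ParameterError(f"need at least 100 samples for the χ² check, got {n}")
    cfg = InversionConfig()
    edges = np.array([0.0] +
                     [_quantile(dist, j / bins, cfg) for j in range(1, bins)] +
                     [np.inf])
    observed = np.histogram(samples, bins=edges)[0].astype(float)
    expected = np.full(bins, n / bins)

    # merge adjacent bins (right-to-left) until expected counts are all >= 5
    obs, exp, edge = list(observed), list(expected), list(edges)
    i = len(obs) - 1
    while i >= 0 and len(obs) > 1:
        if exp[i] < 5.0:
            j = i - 1 if i > 0 else 1
            exp[j] += exp[i]
            obs[j] += obs[i]
            del obs[i], exp[i], edge[i]
        i -= 1
    observed = np.asarray(obs)
    expected = np.asarray(exp)
    edges = np.asarray(edge)

    statistic = float(np.sum((observed - expected) ** 2 / expected))
    dof = len(observed) - 1
    p_value = float(stats.chi2.sf(statistic, dof))
    return GofReport(statistic=statistic, dof=dof, p_value=p_value,
                     bin_edges=edges, observed=observed, expected=expected)


# --------------------------------------------------------------------------
# saturation curve
# --------------------------------------------------------------------------

def saturation_curve(k1: float, k2: float, k_minus1: float,
                     S_grid: np.ndarray, n_per_point: int,
                     rng: np.random.Generator,
                     config: InversionConfig | None = None):
    """Sampled MM saturation curve: for each substrate concentration draw
    ``n_per_point`` waiting times and report the reciprocal sample mean
    alongside the analytic rate k2·[S]/([S]+K_M).

    Returns a pandas DataFrame with columns ``S``, ``inv_mean_tau``,
    ``analytic_rate`` and ``se`` — the delta-method standard error of the
    reciprocal mean, sqrt(Var τ / n)/⟨τ⟩², from the analytic moments.
    """
    import pandas as pd

    S_grid = np.asarray(S_grid, dtype=float)
    if np.any(S_grid <= 0):
        raise ParameterError("all substrate concentrations must be > 0")
    if n_per_point < 2:
        raise ParameterError("n_per_point must be >= 2")
    rows = []
    for S in S_grid:
        params = mm_derive(k1, k2, k_minus1, S)
        dist = MMWaitingTime(params)
        taus = sample_many(dist, rng, n_per_point, config)
        m, var = dist.mean(), dist.variance()
        rows.append({
            "S": S,
            "inv_mean_tau": 1.0 / taus.mean(),
            "analytic_rate": mm_mean_rate(params),
            "se": np.sqrt(var / n_per_point) / m**2,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# random valid parameter sets
# --------------------------------------------------------------------------

#: log-uniform sampling ranges (mutually consistent arbitrary units)
_RANGES = {"k1": (1e-2, 1e2), "k2": (1e-2, 1e3), "k_minus1": (1e-3, 1e3),
           "S": (1e-3, 1e3)}


def make_random_valid_params(rng: np.random.Generator,
                             max_tries: int = 1000) -> MMWaitingTimeParams:
    """Draw a random valid MM parameter record: log-uniform k1, k2, k−1, S
    over the documented ranges, rejecting draws too close to the degenerate
    A = 0 boundary (A < 1e-3·|B|), where the two-exponential form loses
    precision.  The output always passes :func:`mm_derive`."""
    for _ in range(max_tries):
        vals = {key: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                for key, (lo, hi) in _RANGES.items()}
        try:
            params = mm_derive(vals["k1"], vals["k2"], vals["k_minus1"], vals["S"])
        except ParameterError:
            continue
        if params.A < 1e-3 * abs(params.B):
            continue
        return params
    raise ParameterError(f"no valid parameter set found in {max_tries} draws")


# --------------------------------------------------------------------------
# ready-made reaction systems
# --------------------------------------------------------------------------

def example5_system() -> tuple[ReactionSystem, dict[str, int]]:
    """Two-reaction race on a shared reactant: A→B with the single-molecule
    MM waiting time (substrate = live A; k1 = 1, k2 = 1, k−1 = 10) and A→C
    exponential with live rate 10·[A].  Initial counts A=100, B=0, C=0."""
    text = (
        "A -> B [dist=mm_single_molecule; k1=1.0; k2=1.0; k_minus1=10.0; substrate=A]\n"
        "A -> C [dist=exponential; lam_coeff=10.0; species=A]\n"
    )
    return parse_reactions(text), {"A": 100, "B": 0, "C": 0}


def mm_elementary_system(k1: float, k_minus1: float, k2: float
                         ) -> ReactionSystem:
    """Full elementary MM scheme (the exact Markovian "full model"):
    E+S→ES, ES→E+S, ES→E+P with mass-action propensities (per-copy rates)."""
    text = (
        f"E + S -> ES [dist=mass_action; c={k1!r}]\n"
        f"ES -> E + S [dist=mass_action; c={k_minus1!r}]\n"
        f"ES -> E + P [dist=mass_action; c={k2!r}]\n"
    )
    return parse_reactions(text)


def mm_lumped_nonmarkov_system(k1: float, k2: float, k_minus1: float,
                               substrate: str = "S", product: str = "P"
                               ) -> ReactionSystem:
    """Single S→P channel with the exact single-molecule waiting-time density
    evaluated at the live substrate amount."""
    text = (f"{substrate} -> {product} [dist=mm_single_molecule; k1={k1!r}; "
            f"k2={k2!r}; k_minus1={k_minus1!r}; substrate={substrate}]\n")
    return parse_reactions(text)


def mm_lumped_markov_system(k1: float, k2: float, k_minus1: float,
                            substrate: str = "S", product: str = "P"
                            ) -> ReactionSystem:
    """Single S→P channel with exponential waiting time at the ensemble MM
    velocity — the memoryless lumped approximation."""
    text = (f"{substrate} -> {product} [dist=mm_lumped; k1={k1!r}; "
            f"k2={k2!r}; k_minus1={k_minus1!r}; substrate={substrate}]\n")
    return parse_reactions(text)
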