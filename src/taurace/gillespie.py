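"""Markovian reference simulator: Gillespie's Direct Method.

Serves as the benchmark for the non-Markovian engine in two modes that share
the engine's reaction-file grammar:

* elementary mode (``dist=mass_action; c=...``): the full reaction scheme
  with standard combinatorial propensities — e.g. the three elementary MM
  steps E+S→ES, ES→E+S, ES→E+P.  Exact for mass-action kinetics, hence the
  "full model" against which lumped descriptions are judged.
* lumped Markovian mode (``dist=mm_lumped; k1=..; k2=..; k_minus1=..;
  substrate=..``): a single S→P jump whose propensity is the ensemble MM
  velocity v = k2·[S]/([S]+K_M) — the memoryless approximation whose
  waiting-time law (an exponential) disagrees with the exact single-molecule
  density near τ = 0.

Each Direct Method step draws τ ~ Exp(a0) with a0 the total propensity and
picks channel j with probability a_j/a0.
"""

from __future__ import annotations

import numpy as np

from ._errors import ParameterError
from .distributions import mm_derive, mm_mean_rate
from .engine import (
    ConcentrationScale,
    Reaction,
    ReactionSystem,
    StopCriterion,
    SystemState,
    Trajectory,
    TrajectoryRecord,
    fireable,
    mass_action_propensity,
)

__all__ = ["propensity", "ssa_direct_step", "ssa_simulate"]


def propensity(rxn: Reaction, state: SystemState,
               scale: ConcentrationScale = ConcentrationScale()) -> float:
    """Propensity of one channel at the current state.

    ``mass_action``: c × combinatorial reactant count (c·nA·nB for A+B→…,
    c·nA(nA−1)/2 for 2A→…).  ``mm_lumped``: k2·[S]/([S]+K_M) with [S] the
    scaled live amount of the substrate species — zero once exhausted.
    """
    fam = rxn.dist_spec.family
    p = rxn.dist_spec.params
    if fam == "mass_action":
        return mass_action_propensity(rxn, state, p["c"])
    if fam == "mm_lumped":
        S = scale.scale * state.count(p["substrate"])
        if S <= 0:
            return 0.0
        return mm_mean_rate(mm_derive(p["k1"], p["k2"], p["k_minus1"], S))
    raise ParameterError(
        f"the Markovian reference handles dist=mass_action or dist=mm_lumped, "
        f"not '{fam}'"
    )


def ssa_direct_step(system: ReactionSystem, state: SystemState,
                    rng: np.random.Generator,
                    scale: ConcentrationScale = ConcentrationScale()
                    ) -> tuple[int, float, SystemState] | None:
    """One Direct Method iteration; None (halt) when the total propensity is 0."""
    a = np.array([propensity(r, state, scale) if fireable(r, state) else 0.0
                  for r in system.reactions])
    a0 = float(a.sum())
    if a0 <= 0.0:
        return None
    tau = rng.exponential(1.0 / a0)
    # linear search over the cumulative propensities, as in the Direct Method
    target = rng.random() * a0
    acc = 0.0
    idx = len(a) - 1
    for j, aj in enumerate(a):
        acc += aj
        if target < acc:
            idx = j
            break
    new_counts = dict(state.counts)
    for name, coeff in system.reactions[idx].reactants:
        new_counts[name] = new_counts.get(name, 0) - coeff
    for name, coeff in system.reactions[idx].products:
        new_counts[name] = new_counts.get(name, 0) + coeff
    new_state = SystemState(counts=new_counts, time=state.time + tau)
    return idx, tau, new_state


def ssa_simulate(system: ReactionSystem, initial_state: SystemState | dict,
                 stop: StopCriterion, rng: np.random.Generator,
                 scale: ConcentrationScale = ConcentrationScale()) -> Trajectory:
    """Direct Method trajectory under the same stop semantics as the
    non-Markovian engine; ``Trajectory.iterations`` is the firing count."""
    if isinstance(initial_state, dict):
        initial_state = SystemState(counts=dict(initial_state))
    state = initial_state.copy()

    species = system.species()
    for name in state.counts:
        if name not in species:
            species.append(name)

    records = [TrajectoryRecord(time=state.time, counts=dict(state.counts),
                                reaction=None)]
    iterations = 0
    while not stop.reached(state, iterations):
        result = ssa_direct_step(system, state, rng, scale)
        if result is None:
            break
        idx, _tau, new_state = result
        if stop.max_time is not None and new_state.time > stop.max_time:
            break
        state = new_state
        iterations += 1
        records.append(TrajectoryRecord(time=state.time, counts=dict(state.counts),
                                        reaction=idx))
    return Trajectory(species=species, records=records)
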