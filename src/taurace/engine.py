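"""Reaction-system parsing and the non-Markovian min-τ simulation loop.

A system is a list of reactions of the generic form

    a1 X1 + … + an Xn  ->  b1 Y1 + … + bm Ym

each carrying a waiting-time distribution specification.  One simulation
step samples a waiting time τ independently for every reaction that has
enough reactants, fires the reaction with the smallest τ (consuming
reactants, producing products), adds that τ to the simulation clock, and
starts over — all candidate clocks are resampled at the next step; losing
draws are discarded, not retained.  The trajectory is the ordered list of
(time stamp, species counts, last reaction fired).

Distribution parameters may reference the *live* state: the MM family reads
the current amount of its ``substrate=`` species, and an exponential may set
its rate proportionally to a named species (``lam_coeff`` × amount).  Copy
numbers are mapped to the "concentration" fed to such parameters by a
single multiplicative factor (:class:`ConcentrationScale`, default 1.0).

Reaction-file grammar (one reaction per line, ``#`` comments)::

    2 A + B -> C [dist=exponential; lam=0.5]
    S -> P [dist=mm_single_molecule; k1=1e-4; k2=1.0; k_minus1=100; substrate=S]

Supported families: ``mm_single_molecule``, ``exponential`` (fixed ``lam``
or live ``lam_coeff``/``species``), ``erlang`` (``k``, ``lam``),
``hyperexponential`` (``weights``, ``rates``, comma-separated),
``mass_action`` (``c``; exponential waiting time with the standard
combinatorial propensity) and ``mm_lumped`` (exponential waiting time with
the ensemble MM velocity as rate).  The last two make the same input file
runnable under the Markovian reference simulator.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ParameterError, ReactionSyntaxError, TauraceError
from .distributions import (
    Erlang,
    Exponential,
    Hyperexponential,
    MMWaitingTime,
    WaitingTimeDistribution,
    mm_derive,
    mm_mean_rate,
)
from .sampler import InversionConfig, sample

__all__ = [
    "ConcentrationScale",
    "DistSpec",
    "Reaction",
    "ReactionSystem",
    "SystemState",
    "TrajectoryRecord",
    "Trajectory",
    "StopCriterion",
    "EngineConfig",
    "LiveParameterError",
    "parse_reactions",
    "parse_reaction_line",
    "reaction_to_text",
    "parse_config",
    "fireable",
    "step",
    "simulate",
]


class LiveParameterError(TauraceError):
    """Live distribution parameters are invalid at the current state (e.g. the
    MM substrate amount is 0).  The engine treats such a reaction as not
    fireable for this step."""


@dataclass(frozen=True)
class ConcentrationScale:
    """Multiplies a copy number to give the concentration value fed into
    live distribution parameters.  Default 1.0: counts used directly."""

    scale: float = 1.0

    def __post_init__(self):
        if not (self.scale > 0):
            raise ParameterError(f"concentration scale must be > 0, got {self.scale}")


_KNOWN_FAMILIES = {
    "mm_single_molecule", "exponential", "erlang", "hyperexponential",
    "mass_action", "mm_lumped",
}


@dataclass(frozen=True)
class DistSpec:
    """Waiting-time distribution specification attached to a reaction.

    ``params`` holds family-specific keys; values referencing species are
    resolved against the live state by :meth:`build`.
    """

    family: str
    params: dict

    def __post_init__(self):
        if self.family not in _KNOWN_FAMILIES:
            raise ReactionSyntaxError(
                f"unknown distribution family '{self.family}' "
                f"(known: {', '.join(sorted(_KNOWN_FAMILIES))})"
            )

    def build(self, reaction: "Reaction", state: "SystemState",
              scale: ConcentrationScale) -> WaitingTimeDistribution:
        """Resolve live parameters at the current state and instantiate the law.

        Raises :class:`LiveParameterError` where the state makes the family's
        parameters invalid (substrate exhausted, zero propensity, ...).
        """
        p = self.params
        fam = self.family
        if fam == "mm_single_molecule":
            S = scale.scale * state.count(p["substrate"])
            if S <= 0:
                raise LiveParameterError(f"substrate '{p['substrate']}' exhausted")
            try:
                return MMWaitingTime(mm_derive(p["k1"], p["k2"], p["k_minus1"], S))
            except ParameterError as exc:
                raise LiveParameterError(str(exc)) from exc
        if fam == "exponential":
            if "lam" in p:
                lam = p["lam"]
            else:
                lam = p["lam_coeff"] * scale.scale * state.count(p["species"])
            if lam <= 0:
                raise LiveParameterError("exponential rate is 0 at the current state")
            return Exponential(lam)
        if fam == "erlang":
            return Erlang(k=int(p["k"]), lam=p["lam"])
        if fam == "hyperexponential":
            return Hyperexponential(weights=p["weights"], rates=p["rates"])
        if fam == "mass_action":
            a = mass_action_propensity(reaction, state, p["c"])
            if a <= 0:
                raise LiveParameterError("mass-action propensity is 0")
            return Exponential(a)
        if fam == "mm_lumped":
            S = scale.scale * state.count(p["substrate"])
            if S <= 0:
                raise LiveParameterError(f"substrate '{p['substrate']}' exhausted")
            v = mm_mean_rate(mm_derive(p["k1"], p["k2"], p["k_minus1"], S))
            return Exponential(v)
        raise AssertionError(fam)


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: stoichiometry plus its waiting-time law.

    ``rate_constant`` is the k of the arrow notation; it is carried for
    bookkeeping and used only by distribution specs that need it.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    dist_spec: DistSpec
    rate_constant: float | None = None
    label: str | None = None

    def __post_init__(self):
        if not self.reactants and not self.products:
            raise ReactionSyntaxError("a reaction needs at least one reactant or product")
        for name, coeff in (*self.reactants, *self.products):
            if not name:
                raise ReactionSyntaxError("empty species name")
            if int(coeff) != coeff or coeff < 1:
                raise ReactionSyntaxError(
                    f"stoichiometric coefficient for '{name}' must be a positive "
                    f"integer, got {coeff}"
                )

    def species(self) -> list[str]:
        seen: list[str] = []
        for name, _ in (*self.reactants, *self.products):
            if name not in seen:
                seen.append(name)
        return seen


@dataclass
class ReactionSystem:
    reactions: list[Reaction]

    def species(self) -> list[str]:
        seen: list[str] = []
        for rxn in self.reactions:
            for name in rxn.species():
                if name not in seen:
                    seen.append(name)
        return seen


@dataclass
class SystemState:
    """Species copy numbers plus the simulation clock."""

    counts: dict[str, int]
    time: float = 0.0

    def __post_init__(self):
        for name, n in self.counts.items():
            if n < 0:
                raise ParameterError(f"negative copy number for '{name}': {n}")
        if self.time < 0:
            raise ParameterError(f"negative simulation time: {self.time}")

    def count(self, name: str) -> int:
        # absent species behave as count 0
        return self.counts.get(name, 0)

    def copy(self) -> "SystemState":
        return SystemState(counts=dict(self.counts), time=self.time)


@dataclass(frozen=True)
class TrajectoryRecord:
    time: float
    counts: dict[str, int]
    reaction: int | None  # index into the system's reaction list; None = initial


@dataclass
class Trajectory:
    species: list[str]
    records: list[TrajectoryRecord]

    @property
    def iterations(self) -> int:
        """Number of reaction firings (records minus the initial one)."""
        return len(self.records) - 1

    def final_counts(self) -> dict[str, int]:
        return dict(self.records[-1].counts)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"time": rec.time,
             **{s: rec.counts.get(s, 0) for s in self.species},
             "reaction": "" if rec.reaction is None else rec.reaction + 1}
            for rec in self.records
        ]
        return pd.DataFrame(rows, columns=["time", *self.species, "reaction"])

    def write_csv(self, path) -> None:
        """CSV with header ``time,<species...>,reaction`` (1-based reaction
        index, blank on the initial record)."""
        with open(path, "w", newline="") as fh:
            fh.write(",".join(["time", *self.species, "reaction"]) + "\n")
            for rec in self.records:
                rxn = "" if rec.reaction is None else str(rec.reaction + 1)
                row = [repr(rec.time)] + \
                      [str(rec.counts.get(s, 0)) for s in self.species] + [rxn]
                fh.write(",".join(row) + "\n")


@dataclass(frozen=True)
class StopCriterion:
    """Exactly one of: wall of simulated time, iteration budget, or a target
    copy number of a named species (stop once count ≥ target)."""

    max_time: float | None = None
    max_iterations: int | None = None
    species: str | None = None
    target_count: int | None = None

    def __post_init__(self):
        modes = [self.max_time is not None, self.max_iterations is not None,
                 self.species is not None]
        if not any(modes):
            raise ParameterError("a stop criterion is required")
        if (self.species is None) != (self.target_count is None):
            raise ParameterError("species target needs both species and target_count")

    def reached(self, state: SystemState, iterations: int) -> bool:
        if self.max_time is not None and state.time >= self.max_time:
            return True
        if self.max_iterations is not None and iterations >= self.max_iterations:
            return True
        if self.species is not None and state.count(self.species) >= self.target_count:
            return True
        return False


@dataclass(frozen=True)
class EngineConfig:
    """Engine-level knobs: concentration scale, inversion precision, whether
    analytic quantiles may shortcut the numeric inverter, and the optional
    first-of-n semantics for multi-copy single-molecule channels."""

    scale: ConcentrationScale = ConcentrationScale()
    inversion: InversionConfig = InversionConfig()
    use_analytic: bool = True
    #: when True, a dist spec carrying ``copies=<species>`` samples
    #: min of (live count of that species) i.i.d. draws — the physically
    #: motivated reading of E independent enzymes racing. Off by default:
    #: one draw per reaction channel regardless of copy number.
    first_of_n: bool = False


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+)\s+)?([A-Za-z_][A-Za-z0-9_]*)$")


def _parse_side(side: str, line_number: int | None) -> tuple[tuple[str, int], ...]:
    side = side.strip()
    if not side:
        return ()
    terms = []
    seen = set()
    for chunk in side.split("+"):
        m = _TERM_RE.match(chunk.strip())
        if not m:
            raise ReactionSyntaxError(f"cannot parse species term '{chunk.strip()}'",
                                      line_number)
        coeff = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        if coeff < 1:
            raise ReactionSyntaxError(f"coefficient for '{name}' must be >= 1",
                                      line_number)
        if name in seen:
            raise ReactionSyntaxError(
                f"species '{name}' appears twice on one side; write a single "
                "term with the summed coefficient", line_number)
        seen.add(name)
        terms.append((name, coeff))
    return tuple(terms)


_LIST_KEYS = {"weights", "rates"}
_STR_KEYS = {"dist", "substrate", "species", "copies", "label"}


def _parse_bracket(body: str, line_number: int | None) -> dict:
    out: dict = {}
    for item in body.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ReactionSyntaxError(f"expected key=value, got '{item}'", line_number)
        key, _, value = item.partition("=")
        key, value = key.strip(), value.strip()
        if key in _LIST_KEYS:
            out[key] = tuple(float(v) for v in value.split(","))
        elif key in _STR_KEYS:
            out[key] = value
        else:
            try:
                out[key] = float(value)
            except ValueError:
                raise ReactionSyntaxError(
                    f"value for '{key}' is not numeric: '{value}'", line_number
                ) from None
    return out


def parse_reaction_line(line: str, line_number: int | None = None) -> Reaction:
    text = line.strip()
    bracket = {}
    m = re.search(r"\[(.*)\]\s*$", text)
    if m:
        bracket = _parse_bracket(m.group(1), line_number)
        text = text[: m.start()].strip()
    if "->" not in text:
        raise ReactionSyntaxError("missing '->' arrow", line_number)
    left, _, right = text.partition("->")
    reactants = _parse_side(left, line_number)
    products = _parse_side(right, line_number)
    if "dist" not in bracket:
        raise ReactionSyntaxError("missing 'dist=' distribution family", line_number)
    family = bracket.pop("dist")
    rate_constant = bracket.pop("k", None)
    label = bracket.pop("label", None)
    try:
        spec = DistSpec(family=family, params=bracket)
        return Reaction(reactants=reactants, products=products, dist_spec=spec,
                        rate_constant=rate_constant, label=label)
    except ReactionSyntaxError as exc:
        if exc.line_number is None and line_number is not None:
            raise ReactionSyntaxError(str(exc), line_number) from None
        raise


def parse_reactions(text: str) -> ReactionSystem:
    """Parse a reaction file (one reaction per line; blank lines and ``#``
    comments ignored).  Syntax errors carry the 1-based line number."""
    reactions = []
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        reactions.append(parse_reaction_line(line, line_number=i))
    if not reactions:
        raise ReactionSyntaxError("no reactions found")
    return ReactionSystem(reactions)


def _fmt_num(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() and abs(x) < 1e15 else repr(float(x))


def reaction_to_text(rxn: Reaction) -> str:
    """Serialize a reaction back to the file grammar (round-trips by parse)."""
    def side(terms):
        return " + ".join(f"{c} {s}" if c != 1 else s for s, c in terms)

    items = [f"dist={rxn.dist_spec.family}"]
    for key, val in rxn.dist_spec.params.items():
        if key in _LIST_KEYS:
            items.append(f"{key}={','.join(_fmt_num(v) for v in val)}")
        elif key in _STR_KEYS:
            items.append(f"{key}={val}")
        else:
            items.append(f"{key}={_fmt_num(val)}")
    if rxn.rate_constant is not None:
        items.append(f"k={_fmt_num(rxn.rate_constant)}")
    if rxn.label is not None:
        items.append(f"label={rxn.label}")
    return f"{side(rxn.reactants)} -> {side(rxn.products)} [{'; '.join(items)}]"


def parse_config(text: str) -> dict:
    """Parse the key-value simulation config file.

    Recognised keys: ``init.<species> = <count>``, ``stop.max_time``,
    ``stop.max_iterations``, ``stop.species``, ``stop.count``, ``seed``,
    ``precision``, ``scale``.
    """
    init: dict[str, int] = {}
    stop_kv: dict = {}
    out: dict = {"init": init}
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ReactionSyntaxError(f"expected key = value, got '{line}'", i)
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key.startswith("init."):
            init[key[5:]] = int(value)
        elif key == "stop.max_time":
            stop_kv["max_time"] = float(value)
        elif key == "stop.max_iterations":
            stop_kv["max_iterations"] = int(value)
        elif key == "stop.species":
            stop_kv["species"] = value
        elif key == "stop.count":
            stop_kv["target_count"] = int(value)
        elif key == "seed":
            out["seed"] = int(value)
        elif key == "precision":
            out["precision"] = float(value)
        elif key == "scale":
            out["scale"] = float(value)
        else:
            raise ReactionSyntaxError(f"unknown config key '{key}'", i)
    out["stop"] = StopCriterion(**stop_kv)
    return out


# --------------------------------------------------------------------------
# mass action
# --------------------------------------------------------------------------

def mass_action_propensity(rxn: Reaction, state: SystemState, c: float) -> float:
    """Stochastic mass-action propensity: c × number of distinct reactant
    combinations (n for A, n·m for A+B, n(n−1)/2 for 2A)."""
    a = float(c)
    for name, coeff in rxn.reactants:
        a *= math.comb(state.count(name), coeff)
    return a


# --------------------------------------------------------------------------
# simulation loop
# --------------------------------------------------------------------------

def fireable(rxn: Reaction, state: SystemState) -> bool:
    """True iff every reactant is present at or above its stoichiometry."""
    return all(state.count(name) >= coeff for name, coeff in rxn.reactants)


def _sample_channel(rxn: Reaction, state: SystemState, rng: np.random.Generator,
                    config: EngineConfig) -> float:
    dist = rxn.dist_spec.build(rxn, state, config.scale)
    tau = sample(dist, rng, config.inversion, use_analytic=config.use_analytic)
    if config.first_of_n and "copies" in rxn.dist_spec.params:
        n = state.count(rxn.dist_spec.params["copies"])
        for _ in range(max(n, 1) - 1):
            tau = min(tau, sample(dist, rng, config.inversion,
                                  use_analytic=config.use_analytic))
    return tau


def step(system: ReactionSystem, state: SystemState, rng: np.random.Generator,
         config: EngineConfig | None = None
         ) -> tuple[int, float, SystemState] | None:
    """One race iteration: sample τ per fireable reaction at the *current*
    state, fire the smallest (ties: lowest reaction index), update counts,
    advance the clock.  Returns None (halt) when nothing can fire."""
    if config is None:
        config = EngineConfig()
    best_idx, best_tau = None, None
    for idx, rxn in enumerate(system.reactions):
        if not fireable(rxn, state):
            continue
        try:
            tau = _sample_channel(rxn, state, rng, config)
        except LiveParameterError:
            continue  # invalid live parameters => treated as not fireable
        if best_tau is None or tau < best_tau:
            best_idx, best_tau = idx, tau
    if best_idx is None:
        return None
    new_counts = dict(state.counts)
    for name, coeff in system.reactions[best_idx].reactants:
        new_counts[name] = new_counts.get(name, 0) - coeff
    for name, coeff in system.reactions[best_idx].products:
        new_counts[name] = new_counts.get(name, 0) + coeff
    new_state = SystemState(counts=new_counts, time=state.time + best_tau)
    return best_idx, best_tau, new_state


def simulate(system: ReactionSystem, initial_state: SystemState | dict,
             stop: StopCriterion, rng: np.random.Generator,
             config: EngineConfig | None = None) -> Trajectory:
    """Run the min-τ race until the stop criterion or reactant exhaustion.

    Deterministic for a fixed seed: identical inputs give a byte-identical
    trajectory file.  A ``max_time`` wall is enforced *before* applying a
    step that would overshoot it, so ``max_time=0`` yields only the initial
    record.
    """
    if config is None:
        config = EngineConfig()
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
        result = step(system, state, rng, config)
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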