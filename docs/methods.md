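# Methods

## Model and assumptions

The package simulates discrete-state, continuous-time reaction networks in
which each reaction channel carries its own waiting-time law. The central
law is the exact turnover-time density of a single enzyme following the
Michaelis–Menten (MM) scheme E+S ⇌ ES → E+P:

f(τ) = α(e^{βτ} − e^{γτ}), with B = −(k1[S]+k−1+k2)/2,
A = √(B²−k1k2[S]), α = k1k2[S]/(2A), β = A+B, γ = B−A.

Assumptions inherited from that derivation: a single enzyme molecule (or a
channel treated as one), fixed substrate concentration over one waiting
interval, and no dynamic disorder (no slow conformational modulation of the
rate constants). The density is exact in the sense that it does not invoke
the steady-state approximation; its reciprocal mean is k2[S]/([S]+K_M) with
K_M = (k−1+k2)/k1, so bulk-measured constants parameterise it directly.
The discriminant B²−k1k2[S] is strictly positive for every positive
parameter set except the measure-zero boundary A = 0 (e.g. k1[S] = k2 with
k−1 = 0); that boundary is rejected with a distinct `DegenerateAError`
rather than implementing the confluent α·τ·e^{Bτ} limit, which no realistic
parameter set hits exactly.

A is taken as the *positive square root* of B²−k1k2[S]. This is pinned by
the sign requirements A > 0, B < 0 and verified operationally: the density
then integrates to one and its numerically integrated mean reproduces the
MM rate law to 1e-6 relative (tested for the bundled literature sets and
100 random sets).

Exponential, Erlang and hyperexponential waiting times are provided under
the same interface; the hyperexponential is the standard finite mixture of
exponentials. Units are the caller's responsibility: k1 and [S] must be
mutually consistent (M with M⁻¹s⁻¹, μM with μM⁻¹s⁻¹, or copy numbers with
per-copy rates); nothing is converted internally.

## CDF inversion

Waiting times are drawn by inverse-transform sampling: τ solves F(τ) = r,
r uniform on the *open* interval (0,1) (a drawn 0 is rejected and redrawn;
the generator never returns 1). For every valid MM parameter set β > γ, so
F is strictly increasing and the root is unique.

The inverter isolates the root with an initial bracket [0, mean], doubles
the upper end until F(upper) ≥ r (monotonicity makes this complete: the
bracket eventually covers any quantile), then bisects. The result is an
enclosure [τ_low, τ_high] with cdf(τ_low) ≤ r ≤ cdf(τ_high) and width at
most the configured precision; the reported τ is the midpoint. Default
precision is 1e-9 × mean (relative), floored at 1e-15 absolute; caps are
200 bracket doublings and 20000 bisections. Bisection was chosen over
faster derivative-based root polishing because every iterate keeps the
verified enclosure — the same guarantee an interval-constraint solver
provides — at negligible cost next to CDF evaluation. Families with a
closed-form quantile (exponential; Erlang via the gamma quantile) use it as
a fast path by default; the numeric route remains available and tested for
every family, and both routes consume exactly one uniform per draw so
switching them does not shift the RNG stream.

Accuracy limit: near r → 1 the CDF slope f(τ) underflows relative to
double-precision CDF round-off, so no CDF-based inverter can localise τ
better than ≈ eps/f(τ) there; the closed-form fast path is exact in r.

## Simulation loop

Per iteration the engine samples τ independently for every reaction with
sufficient reactants, evaluating live distribution parameters (the MM
substrate, live exponential rates, mass-action propensities) at the
*current* state, fires the channel with the smallest τ, applies its
stoichiometry, and advances the clock by that τ. All clocks are resampled
at the next iteration; losing draws are discarded. Note this "resampling
race" differs from semi-Markov race semantics with persistent residual
clocks — for exponential waiting times the two coincide (memorylessness),
for general laws they do not, and the resampling loop is the documented
behaviour here.

Other fixed choices: ties in τ (measure zero, but possible in floating
point) go to the lowest reaction index, for determinism; a reaction whose
live parameters are invalid at the current state (e.g. substrate exhausted
while the nominal reactant is present) is treated as not fireable for that
step; a `max_time` wall is enforced before applying a step that would
overshoot it, so a zero budget yields only the initial record; one explicit
`numpy.random.Generator` is threaded through every draw — there is no
global RNG state, and a fixed seed reproduces the trajectory file
byte-for-byte.

A lumped single-molecule MM channel samples *one* τ per iteration
regardless of how many enzyme copies exist — that is the semantics under
which the 500-products benchmark takes exactly 500 iterations. The
physically motivated alternative for E independent enzymes (take the
minimum of E i.i.d. draws) is available by tagging the channel with
`copies=<species>` and enabling `EngineConfig(first_of_n=True)`; it is off
by default.

Copy numbers are mapped to the "concentration" fed into live parameters by
one multiplicative factor (`ConcentrationScale`, default 1.0). The default
means rate constants are interpreted per copy; a molar-units model sets the
factor to the volume-dependent conversion explicitly.

## Markovian reference

`taurace.gillespie` implements the Direct Method: τ ~ Exp(a0), channel j
with probability a_j/a0. Propensities use Gillespie's combinatorial
convention (c·nA·nB for A+B→…, c·nA(nA−1)/2 for 2A→…). Its two modes —
elementary mass action and the lumped Markovian S→P with the MM velocity
as propensity — share the engine's reaction grammar, so the same input
file runs under both simulators. With exponential waiting times the
min-τ engine and the Direct Method sample the same jump process; the test
suite verifies this on a 3-reaction system (2000 runs per simulator,
final-state χ² p > 0.01).

## Synthetic inputs and what they show

No external data are used. Inputs are (i) literature kinetic constants:
three single-molecule sets (k1=1e7 M⁻¹s⁻¹, k2=250 s⁻¹, k−1∈{0,50,2000}
s⁻¹, [S]=5 μM) and three bulk β-lactamase sets in μM units; (ii) a
two-reaction network with live-parameter laws; and (iii) a seeded random
generator of valid MM parameter records, log-uniform over k1∈[1e-2,1e2],
k2∈[1e-2,1e3], k−1∈[1e-3,1e3], S∈[1e-3,1e3] (arbitrary consistent units),
rejecting draws with A < 1e-3·|B| where the two-exponential form loses
floating-point precision. The substrate sweep for the saturation curve is
20 log-spaced points over 0.001–200 μM with 100 draws per point — μM
matching the μM⁻¹s⁻¹ units of the bulk sets, the grid density a choice of
this package. These fixtures exercise distributional correctness,
ergodicity and engine bookkeeping; they do not emulate measurement noise,
dynamic disorder, crowding, or time-varying rate constants, so passing
tests certify the simulator against its own model class, not against any
particular experimental trace.

The Markov-vs-non-Markov transient comparison uses a documented low-copy
regime chosen where theory predicts the largest discrepancy (single
enzyme, 25 substrate copies, k1=1.0, k−1=0.1, k2=10 per-copy units,
k−1 ≪ k2): the exponential lump overweights waiting times near zero, so
its mean product curve overshoots the full elementary model early, while
the non-Markovian lump stays within Monte-Carlo bands (600 runs per
simulator in the test; 200 in the example script). The check is a
qualitative ordering, not a curve match.

## Statistical checks

Goodness of fit uses Pearson χ² over equal-probability bins (20 for n=1000
draws), edges from the analytic quantiles, adjacent bins merged until every
expected count is ≥ 5, dof = bins − 1 (no fitted parameters). A fit
*passes* when p > α with α = 0.01 — the conventional reading of a
goodness-of-fit test. Sampler correctness additionally uses the
Kolmogorov–Smirnov statistic of 1e4 draws against the analytic CDF,
compared with the asymptotic 1% critical value 1.628/√n. Saturation-curve
points carry delta-method standard errors, se(1/τ̄) = √(Var τ / n)/⟨τ⟩²,
from analytic moments.

## Numerical notes

The MM CDF is evaluated with `expm1` to keep precision at small τ.
Quadrature cross-checks in the tests split the integration domain at the
fast-component scale 1/|γ| and truncate at T = (60+log(1+α))/|β|, because
adaptive quadrature on [0, ∞) misses the narrow e^{γτ} component of stiff
sets (|γ|/|β| can exceed 1e7 for random valid parameters). Iteration
budgets in the tests (sample sizes of 1e3–1e4 draws, 600–2000 replicate
trajectories, benchmark runs of 500 firings from 1e6 substrate copies) are
the problem sizes at which the statistical criteria are sharp while the
whole suite stays lightweight.

## Known limitations

- The resampling race (no persistent clocks) is one of several defensible
  non-Markovian race semantics; results for non-exponential laws depend on
  this choice.
- Multi-enzyme lumped channels default to one draw per channel (see above);
  neither default claims to resolve the E > 1 physics.
- No spatial/compartment structure, no tau-leaping or other approximate
  accelerations, no time-varying rate constants, no empirical-histogram
  waiting-time laws.
- Near-degenerate MM parameter sets (A ≲ 1e-3·|B|) are numerically fragile
  in double precision and are rejected by the random generator; `mm_derive`
  itself only rejects the exact boundary.
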