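# Methods

## Model

Agents move in a fully periodic rectangular box (default 20×20×20, all
displacements by the minimum-image convention). The neighborhood of agent
*i* is the open ball of radius r₀ = 3 around it, **including itself**, under
a strict inequality |Δr| < r₀; a tie at exactly r₀ is a non-neighbor
(measure-zero event, chosen for a literal and testable rule). Because the
self term is included, nᵢ ≥ 1 always, ln nᵢ ≥ 0, and an isolated agent has
mean alignment exactly 1 (the self term is accumulated as the constant 1.0,
not as a rounded dot product).

The effective utility is h(n, l) = αn − βn² + γnl − δ ln n with α, β, γ ≥ 0
and δ > 0 (default 1, a pure choice of utility scale). Its stationary points
in n solve 2βn² − (α + γl)n + δ = 0. β = 0 is rejected rather than
special-cased: without a congestion cost there is no finite optimum.
A negative discriminant is reported as a flagged "no real root" result, not
an error, since it is a legitimate parameter regime (alignment too weak to
sustain a flock). Closed-form predictions are evaluated at l = 1: the
equilibrium flocks observed in simulation are near-perfectly aligned, and
only this choice reproduces the reference values (n̂₊ = 73.6, ĥ = 23.8 for
α, β, γ, δ = 0.5, 0.005, 0.25, 1).

## Dynamics

Both models share one integration order per step: neighborhoods → forces →
velocity update v += F·Δt → speed clamp → position update r += v·Δt → wrap.
This makes the speed band [0.5, 1] a hard invariant of every recorded state.

**Boids baseline.** The force is the classic cohesion/separation/alignment
sum with weights a, b, c over the metric neighborhood, plus noise.

**Utility-driven agents.** The force is the sum of two utility-ascent terms:

- *Orientational*: γ Σⱼ nᵢⱼ **s**ⱼ (self included) — the gradient of the
  alignment utility with the neighborhood field held fixed.
- *Positional*: nᵢ is an integer function of position, so no analytic
  gradient exists. We evaluate the agent's full utility h (including the
  alignment and competition terms) for six candidate displacements of
  length `probe` along ± each axis, recomputing the agent's own nᵢ and
  alignment sum per candidate, and composite the per-axis differences into
  a central-difference vector divided by 2·probe. When no candidate
  strictly improves h the force is zero — an agent at a local optimum does
  not jitter deterministically.

The probe length defaults to 0.1·r₀ = 0.3: small against the neighborhood
scale, large enough to move boundary-shell neighbors across the threshold.
The candidate search requires r₀ + 2·probe < min(L)/2 so that no candidate
changes the relevant periodic image; this is validated, not assumed.

Noise is an isotropic unit direction times noise_level·|vᵢ| (default 0.01),
added inside the bracket multiplied by Δt, for both models. The noise
magnitude law is fixed (not Gaussian): the model statement ties it to the
speed, and a fixed magnitude is the minimal reading. Positional and
orientational force components are combined with unit weights and no
per-agent normalization (`normalize_force` exposes the alternative; off by
default). If a velocity update ever cancels a velocity exactly, the agent
is re-drawn with a random orientation at the minimum speed and a warning is
logged; with the default parameters this cannot occur in practice.

## Initialization and protocol

1000 agents start uniformly inside a 10×10×10 block centered in the box,
with orientations uniform on the sphere (normalized Gaussians) and speeds
uniform in [0.5, 1]. Δt defaults to 0.01 (0.1 and 0.5 are the standard
sweep values). One `numpy` Generator seeded from the config drives every
draw in a fixed order, so full runs are bit-reproducible; relabeling agents
permutes a zero-noise trajectory identically.

## Observables

Per step we record population means and population (not sample) standard
deviations of nᵢ, lᵢ, hᵢ — descriptive statistics over the full population.
Window statistics over the trailing 100 steps pool the within-step variance
with the between-step variance of the means, so the reported spread is
comparable to a per-agent standard deviation taken over the whole window.
Percentile bands rank agents descending by utility with ties broken by
agent index and cutoffs at floor(N·p); the default band list intentionally
reports the bottom half both split (50–75%) and whole.

## Stability experiments

A run is taken to equilibrium (default: 100 steps, extended in 50-step
blocks — at most three — while the mean utility of the last 10 steps still
exceeds the window mean by more than half its spread). The equilibrium band
is computed from the flat tail of the pre-run (its last half, capped at
100 steps): mean utility minus twice the pooled spread.

Disturbances randomize velocities (orientation uniform on the sphere, speed
uniform in the configured band — the bounds-respecting reading of "random
orientation and magnitude"), positions, or both. Positions are redrawn
uniformly over the *initial central block*, i.e. the same law as
initialization: this is the reading under which the combined disturbance
reproduces a fresh random start in distribution and the position
disturbance leaves the mean neighbor count roughly unchanged, as the
qualitative description of these experiments requires. The recovery step is
the first post-disturbance step whose population-mean utility re-enters the
band; measured recoveries take ~5–30 steps, comfortably inside the
~100-step scale expected of the model.

The game's potential ϕ is never given explicitly for this utility, so the
Lyapunov diagnostic V = ϕ* − ϕ uses the population-summed effective utility
as an implementable proxy for ϕ. This is a modeling decision, not a
derivation; accordingly the Lyapunov property is asserted only as a trend —
the fraction of consecutive 10-step window means of V that do not increase,
evaluated from the disturbance to the recovery step (beyond recovery V
fluctuates around 0 and successive-window comparisons carry no signal), must
be ≥ 90%. Measured runs give 100%.

## Problem sizes

The test suite and the acceptance script use the full protocol scale
(N = 1000, 1000 steps, Δt = 0.01) for the equilibrium and percentile
checks — the compiled O(N²) kernel makes a full run take seconds — and
three seeds for the stochastic assertions. Unit tests use 2–80 agents with
hand-placed fixtures and brute-force oracles.

## What the simulator does and does not emulate

The agents are ideal, point-like utility maximizers: no body size,
collision avoidance, vision cones, predation, wind, or energetics; the box
is periodic rather than open sky; utility coefficients are homogeneous
across the population. Passing tests therefore certify the internal
consistency of the model and its equilibrium theory — not that real birds
behave this way. Exact trajectories are implementation-sensitive (the
update rule is specified only up to "move along directions of increasing
utility"); only equilibrium-level statistics are expected to be comparable
across implementations, and those are what the acceptance checks assert.

## Known limitations

- The positional force is a finite-difference estimate on an integer-valued
  field; its magnitude depends on the probe length, and very sparse
  configurations produce exactly zero force between shell crossings.
- The Lyapunov proxy is heuristic (see above); V can be slightly negative
  when the population transiently exceeds its pre-disturbance utility.
- The closed-form predictor assumes a homogeneous alignment l for all
  agents; in multi-flock states the global polarization can be low even
  when every local neighborhood is aligned.
- The boids baseline shares the garud protocol (metric neighborhood, speed
  clamp, noise law) and is intended for qualitative comparison, not as a
  faithful reproduction of any particular boids implementation.
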