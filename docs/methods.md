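# Methods

This note documents the model, the estimators, the parameters that matter,
and the choices made where the design was genuinely open.  Nothing here
reports a number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Agents and environment

Agents are circular differential-drive bodies (radius 4 length units) in an
unbounded, obstacle-free plane.  Units are one world length unit and one
simulation second; motor outputs are used unscaled, so speeds are at most
1 unit/s and turning rates at most 1/4 rad/s.  There is no inertia,
friction, or collision handling — bodies may overlap, which is why the
acoustic distance law is clamped (below).

Two acoustic sensors sit on the body perimeter at ±45° from the heading; the
emitter is at the body center.  The intensity a sensor receives from a
partner's emitter is

    I = e · D(d) · S(ψ),

with `e` the partner's emitter output in [0, 1], `d` the emitter-to-sensor
distance, and ψ the angle between the sensor's outward radial direction and
the direction to the source.  Defaults (all configurable through
`AcousticsConfig`):

- `D(d) = 1/max(d, 1)²` — inverse-square attenuation; the clamp at one
  length unit avoids the contact singularity when bodies overlap.  A `1/d`
  law is available as an alternative.
- `S(ψ) = 1` in the sensor's outward half-plane, `0.1` behind it — a hard
  self-shadowing model (the receiver's body blocks sound from behind the
  sensor).  A smooth `(1 + cos ψ)/2` variant is available.

A solitary agent receives identically zero intensity: agents never sense
their own signal.

## Controller

Three fully connected layers.  Sensor nodes apply
`σ(sensor_gain · I + sensor_bias)`; the inner layer is a standard CTRNN
with Euler integration at dt = 0.1 s,

    τᵢ ẏᵢ = −yᵢ + Σⱼ w_rec[j,i] σ(gⱼ(yⱼ + θⱼ)) + Σₖ w_sens[k,i] sₖ,

with neuron output `σ(gᵢ(yᵢ + θᵢ))`; actuator nodes apply
`σ(Σᵢ w_act[i,k] outᵢ + actuator_bias)` with fixed order (left motor, right
motor, emitter).  Conventions chosen where the architecture left room:

- **Gain placement**: inside the output nonlinearity, `σ(g(y + θ))`, one
  gain per neuron (the standard Beer-style convention).
- **Integration**: explicit Euler, matching the fixed 0.1 s step of the
  protocol; the test suite verifies first-order convergence against the
  closed-form linear solution and the closed-form circular trajectory.
- **Update order per step**: (1) sensor intensities from the previous step's
  poses and emitters — synchronous for both agents, so coupling is
  order-independent; (2) sensor nodes; (3) CTRNN step; (4) actuator nodes;
  (5) move bodies, set emitters.  Neuron potentials start at y = 0.
- **Decoupled testing** forces intensity to zero, so sensor nodes still emit
  `σ(sensor_bias)`; a strict variant that zeroes the sensor drive entirely
  is not the default (constant input is dynamically equivalent to a bias
  shift, which the evolved solution has already absorbed).

## Genotype

One agent = `n² + 5n + 6` genes in [−1, 1]: recurrent weights (n²), sensor
weights (2n), actuator weights (3n), and six shared scalars (τ, θ, g,
sensor gain, sensor bias, actuator bias — one value per class, shared
across the units of its layer).  This layout pins the evolvable-parameter
count to exactly 20 (n = 2) and 30 (n = 3).  Genes map linearly to their
class ranges; defaults: weights and biases [−8, 8], time constants [1, 2] s,
gains [1, 5].  A social solution concatenates the pair (2L genes); each
half decodes independently.

## Genetic algorithm

Population 96 for 2000 generations at full scale.  Ranked by fitness, the
top 4 % (ceiling: 4 of 96) pass unchanged; every other slot is filled by
children of two elite parents — drawn uniformly with replacement, distinct
whenever at least two elites exist — via per-gene swap crossover (p = 0.1),
zero-mean Gaussian mutation (variance 0.1) on every gene, and clipping to
[−1, 1].  Clipping preserves the genotype interval the decoder assumes.
At the desk scale (population 24) the 4 % elite rounds up to a single
individual and crossover degenerates to a no-op; the run then behaves as a
(1, 23) evolution strategy, which still optimizes this fitness reliably.

Evaluation is deterministic — the simulation has no noise — so the best
fitness per generation is non-decreasing (elitism) and a run is bit-exactly
reproducible from its seed.  `evolve_runs` stacks several seeded runs into
one simulation batch (a compiled single-threaded kernel integrates the whole
batch); results are identical to running seeds one at a time, which the test
suite asserts.

## Fitness: normalized neural entropy

Neuron-layer outputs (not sensors or actuators) are binned on [0, 1]ⁿ with
B = 50 equal-width bins per dimension; H = −Σ p ln p over occupied cells,
normalized by ln(Bⁿ).  Values exactly at 1.0 fall into the last bin.

- **Trial pooling**: by default one histogram pools the outputs an agent
  produced across its 4 evaluation trials (8000 samples), scored once per
  agent; a per-trial histogram with trial averaging is available
  (`pool_trials=False`).  Pooling treats the recorded outputs of the whole
  evaluation as one sample of the agent's repertoire.
- **Pair fitness** is the arithmetic mean of the two members' entropies —
  not a joint 2n-dimensional entropy — so the measure stays on the same
  scale in both conditions.
- **No burn-in** is discarded by default (`burn_in` exists in config).
- **Known estimator bias**: with 8000 samples, the normalization caps the
  3-neuron model's reachable value at ln 8000 / ln 50³ ≈ 0.77 while the
  2-neuron model can reach 1.0.  Comparisons *across model sizes* therefore
  mix dynamical richness with a sample-size handicap; `study.rescore_entropy`
  re-scores best agents at B ∈ {20, 50, 100} to check how conclusions move
  with the bin count.

## Experimental design

Four cells: condition (IE solitary / SE pair) × model size (2/3 neurons).
Every trial runs 200 s (2000 steps).  The (first) agent starts at the origin
heading +x; in SE the partner starts 20 units away at relative angle
{0, π/2, π, 3π/2} across trials 1–4, also heading +x.  IE trials are
identical by construction and still enumerated four times for structural
parity.  Scale presets: `full` (population 96, 2000 generations, 10 runs
per cell — the published protocol) and `desk` (24, 200, 5 — sized so the
whole 2 × 2 study plus analysis completes in a few minutes on one CPU).

## Time-series analysis

Applied to the neuron-1 *potential* series (y₁, the neural state, not the
sigmoid output; a config switch selects outputs) of trial 1 of each run's
best agent, in coupled and decoupled testing modes.

- **Delay**: histogram mutual information (64 bins), τ at the first strict
  local minimum; fallbacks, logged: first drop below MI(0)/e, then the
  largest lag examined.  For discrete maps, whose MI curves flatten without
  a meaningful minimum, τ can be fixed explicitly (the conventional τ = 1
  is used for the Hénon oracle).
- **Dimension**: false nearest neighbors with the standard thresholds
  Rtol = 10, Atol = 2 (relative to the series' standard deviation), a
  Theiler window of τ, and stop threshold 1 %.  Neighbor search uses a k-d
  tree; a brute-force O(T²) search in the test suite must agree exactly.
  The distance in the Rtol ratio is floored at 1e-12 × std so exactly
  recurring orbits (periodic signals) are not flagged false from rounding
  noise.  A near-constant series is reported as m = 1 with a `degenerate`
  flag; if the fraction never falls below threshold, the dimension at the
  global minimum is returned with a `saturated` flag.

Oracles with known answers pin the estimators: Hénon map → m = 2, Lorenz
system → m = 3, noisy sine → τ near a quarter period and m ≤ 2, white noise
→ never below threshold.  The sine oracle carries small observational noise
(σ = 0.05) because a noiseless sampled sine occupies only ~P distinct values
and its histogram MI curve is flat up to jitter, with spurious early strict
minima.

## Statistics

Best-of-run entropies (best agent for IE, best pair for SE, final
generation) form a balanced table; a fixed-effects two-way ANOVA with
interaction (statsmodels; an explicit sums-of-squares computation serves as
the oracle in the tests) gives residual df = 40 − 4 = 36 at full scale.
The planned post-hoc comparison is a two-sample t-test between (SE,
2-neuron) and (IE, 3-neuron) with a Bonferroni factor (default family size
1, configurable).  Outliers are never removed.  Two identical zero-variance
cells are reported as t = 0, p = 1 (a zero difference), rather than NaN.

## What the reduced-scale runs show — and what they do not

At desk scale the embedding-dimension pattern is reproduced in full:
decoupled best agents stay at or below their network's intrinsic dimension
(20 of 20 in the seed-1 study), coupled social agents exceed their decoupled
dimension, and the coupled 2-neuron social mean exceeds the decoupled
3-neuron solitary mean (3.4 vs 2.2) — interaction adds degrees of freedom
that the isolated network does not have.

The *entropy ordering* between cells does not reproduce at this scale: the
solitary 2-neuron cell attains the highest mean best entropy (seed-1 desk
study: IE2 0.626, IE3 0.455, SE2 0.415, SE3 0.299).  Two mechanisms are
implicated.  First, under the default inverse-square law the signal at the
initial 20-unit separation is at most 2.5 × 10⁻³, so a social genotype pays
double the search dimension for a coupling that only becomes informative
after approach behavior evolves; probes at 800 generations still show the
social cell behind.  Second, the ln(Bⁿ) normalization handicaps the
3-neuron model as described above.  Both the acoustic law and the parameter
ranges are stand-ins exposed through config precisely so this sensitivity
can be studied; the defaults are not tuned to any expected ordering.

More generally, the synthetic setting is an idealization: noiseless
deterministic dynamics, a fixed reliable partner, no task beyond entropy
maximization, and kinematics without physics.  Passing tests show the
estimators and the evolutionary machinery are correct and reproducible; they
do not by themselves license claims about richer environments, larger
groups, or task-constrained behavior.

## Numerical notes

- The simulation inner loop is a compiled (numba) kernel, strict IEEE,
  single-threaded, allocation-free in the time loop; the pure-numpy layer
  operations are the reference implementation and the two are compared on
  full trajectories in the tests.
- Entropy for whole populations is computed by sorting (series, cell) keys
  and run-length counting — identical (to 1e-12) to the per-series
  `numpy.histogramdd` route.
- Every stochastic entry point takes an explicit seed; per-cell run seeds
  derive from one base seed via `numpy.random.SeedSequence`.  Simulation
  itself is deterministic, so traces are bit-reproducible.
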