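# Methods

## The decision model

The package models two-alternative decisions with the standard
drift-diffusion process: evidence `X(t)` starts at `z·a`, drifts at rate `v`
with unit within-trial noise (σ = 1 scaling, so boundary separations near
1.5 and drift rates of 0–2.5 are the natural magnitudes), and terminates at
an upper boundary `a` (correct) or lower boundary 0 (incorrect).  Observed
RT is the first-passage time plus a nondecision latency.  Across trials the
drift is Normal(`v`, `sv²`) and the nondecision time Uniform(`Ter − st/2`,
`Ter + st/2`).  The four-alternative motion task is reduced to binary form
by grouping correct responses at the upper boundary and all incorrect
responses (regardless of which wrong direction was chosen) at the lower
one.  The start point is fixed at `z = 0.5`: with an unpredictable target
direction participants have nothing to be biased toward, and the package
refuses model specifications that ask to estimate it.

### First-passage density

The density is evaluated through the classical pair of series expansions of
the Wiener first-passage distribution on normalized time `u = t/a²`: a
sum-over-image-charges small-time series and a sine large-time series.  The
truncation length of each is computed from the requested error tolerance
(default `1e-7`) and the cheaper series is used per evaluation point.
Across-trial drift variability is integrated analytically — the drift
enters the density only through the factor `exp(−vaw − v²t/2)`, whose
Gaussian mixture has closed form — and nondecision variability by 10-point
Gauss–Legendre quadrature over the uniform window (the integrand is smooth
on a bounded interval, so a fixed low order is ample).  Upper-boundary
densities use the reflection `f_upper(t|v, w) = f_lower(t|−v, 1−w)`.
Unreachable RTs (below `Ter − st/2`) score `−inf` in the log likelihood;
the empty trial list scores 0.

### Simulator

The Euler–Maruyama simulator steps `v·dt + √dt·N(0,1)` (default
`dt = 1e-4` s, hard cap 10 s with a truncation flag) and is vectorized over
trials in blocks.  Discretization only detects crossings at step
boundaries, which biases first-passage times slightly long; at `dt = 1e-4`
the K–S distance to the analytic distribution stays below 0.01 at n = 10⁵
(the acceptance suite verifies this at five parameter sets spanning the
fitted range), and at the coarser `dt = 1e-3` used for bulk cohort
generation it is ~0.03 — small relative to the behavioral effects the
generator needs to carry.  A heterogeneous-parameter variant
(`simulate_trials_mixed`) serves posterior predictive simulation, where
every trial belongs to a different participant × condition cell.

## Hierarchical structure and sampler

Boundary separation, nondecision time and the two variabilities split by
response modality; drift splits by modality × difficulty × direction (16
cells); with `z` fixed this gives 24 group-level means.  `a`, `Ter` and
each drift cell additionally carry participant-level parameters drawn from
Normal group distributions with family-specific SDs.  `sv` and `st` are
estimated at the group level only: with hundreds rather than thousands of
trials per participant, participant-level variabilities are weakly
identified, and the group-level treatment mirrors common practice for this
design.

Priors are weakly informative and chosen to cover the plausible scales with
little information: group means `a ~ N(1.5, 1)` truncated positive (a
truncated-normal reading of a prior centered on the typical boundary
separation), `Ter ~ N(0.5, 0.5)` truncated so the nondecision window stays
non-negative (`Ter ≥ st/2`), `v ~ N(0, 5)`; group-level `sv ~ HalfNormal(2)`
and `st ~ HalfNormal(0.5)`; all group SDs `HalfNormal(1)`.

Sampling is single-chain adaptive Metropolis-within-Gibbs:

- Participant-level families are updated by joint Gaussian random-walk
  proposals with *component-wise* acceptance — the trial likelihood
  factorizes over disjoint scopes (each trial depends on exactly one
  component per family), so one vectorized likelihood evaluation serves all
  components of a family at once.
- Group means are drawn by exact conjugate Gibbs steps (truncated-normal
  draws where the domain requires it), which makes the group-mean chains
  mix nearly as well as independent draws — important because the
  equivalence tests operate on these chains.
- Group SDs, `sv` and `st` use random-walk Metropolis (log scale for SDs),
  with `st` proposals constrained by the nondecision windows of all
  participants and of the group mean.

Proposal scales adapt toward 44% acceptance by Robbins–Monro updates during
burn-in and are frozen afterwards, preserving detailed balance on the
retained samples.  A post-adaptation acceptance rate below 1% in any family
raises an error rather than returning a silently mis-scaled chain.  Chains
are deterministic given the seed.  Defaults follow the reference analysis:
15,000 samples with 7,000 burn-in at full scale; the desk-scale experiments
use 3,000/1,000.

Convergence is monitored with the Geweke diagnostic: the difference between
the means of the first 10% and last 50% of a chain, standardized by
Newey–West (Bartlett-tapered) long-run variance estimates of the two
segments.  On iid chains the statistic is calibrated (|z| < 1.96 about 95%
of the time, verified by simulation in the test suite); trending chains are
reliably flagged.  The slow-mixing `sv`/`st` chains commonly show |z| above
2 at desk scale — their credible intervals still cover the generating
values in the recovery experiments, but the diagnostic output is the
honest place to look before trusting a short chain.

### Posterior predictive checks

For each of `n_sims` (default 500) retained draws, a synthetic dataset
matching the observed trial counts is simulated from that draw's
participant-level parameters; per modality × difficulty × direction cell
the package returns correct/error RT histograms normalized jointly (the two
areas sum to 1) and averaged over draws.  Simulated responses slower than
the 3 s response window are censored, exactly as the task's response window
censors observed data.

## Equivalence testing

For a contrast of one parameter between two conditions, the index-paired
difference of the two chains is formed and its 95% HDI computed (shortest
contiguous window containing ⌈0.95·n⌉ sorted samples; an exhaustive-search
oracle backs this in the tests).  The ROPE is empirical: within each
condition's chain, odd-position minus even-position samples form a
distribution of "the same parameter minus itself", whose 95% HDI brackets
differences attributable to sampling alone; the ROPE takes the widest
bounds of the two chains' intervals.  `P_P|D` is the proportion of the
difference HDI inside the ROPE.

Two definitional choices deserve note.  First, the odd/even differences
are index-paired (s₁−s₂, s₃−s₄, …), not a comparison of half-chain
distributions — this yields n/2 paired differences reflecting within-chain
variability.  Second, the limiting cases are taken from the proportion
formula itself: `P_P|D = 1` exactly when the HDI is *contained in* the
ROPE, and 0 when they are disjoint.  (A rule in which containment of the
ROPE inside the HDI gave `P = 1` would contradict the proportion formula,
which in that configuration yields the ratio of the two widths; the formula
is used universally.)  A zero-width HDI degenerates to a membership
indicator.

Because the ROPE is built from within-chain differences, chain
autocorrelation narrows it: paired differences of adjacent samples have
variance `2σ²(1−ρ₁)` rather than `2σ²`.  The conjugate group-mean updates
keep ρ₁ small for exactly the chains the equivalence tests consume; for
heavily autocorrelated chains (e.g. `sv`) the empirical ROPE is
conservative (narrow), which makes equivalence *harder* to declare — a
deliberate asymmetry that avoids overstating null results.

## Synthetic-data generator

The generator reproduces the study conditions it emulates:

- **Design**: two sessions (joystick, keyboard) of 960 trials in 8 blocks
  of 120; 15 repetitions per direction × difficulty cell per block;
  pseudo-randomized so no identical (direction, difficulty) pair occurs in
  four consecutive trials (rejection-shuffled per block, checked across
  block junctions).  Reduced designs keep per-block balance.
- **Behavior**: group means default to the reference fitted values per
  modality (e.g. joystick `a = 1.508`, `Ter = 0.613`, `sv = 0.992`,
  `st = 0.268`; drift 1.69–2.35 easy, 0.14–0.53 difficult).
  Between-participant SDs are not published for this dataset; the defaults
  `a_sd = 0.15`, `Ter_sd = 0.08`, `v_sd = 0.35` are typical group-level
  spreads for hierarchical DDM fits of comparable tasks, chosen once.
  `shared_across_modalities()` averages the two columns to generate under
  the equivalence null.  Trials slower than the 3 s window are redrawn once
  then clipped (sub-percent occurrence at these parameters).
- **Trajectories**: a raised-cosine radial profile (zero-velocity start and
  end, single interior speed peak — the ballistic movement shape) from the
  neutral position to near-full deflection, placed so the 20% radius is
  crossed at the trial's RT, ending in a plateau of identical samples so
  the stopping rule fires; 85 Hz grid, samples quantized to 4 decimals
  (device-precision stillness is exact equality, avoiding an epsilon).
  Direction-dependent default peak speeds (right 9.5 > left 9.0 > up 8.5 >
  down 8.0 units/s) emulate the ergonomic asymmetry of real joystick
  pushes.
- **Dot stimulus**: per-frame dot count = density × aperture area / refresh
  (≈52 dots for the default geometry) — the conventional reading of
  "dots/deg²/s" at one frame per refresh.  Coherent dots displace by
  speed × 3/refresh ≈ 1.807° relative to three frames earlier (three
  interleaved sequences), live three displacements, then are re-randomized;
  dots leaving the aperture wrap to a random interior position (the
  alternative — deterministic wrap-around — would introduce spatial
  structure the generator has no basis for).

What the generator does *not* emulate: post-decision trajectory corrections
and changes of mind (movements are single-peaked by construction), spatial
noise in movement paths beyond angular jitter, response omissions and
anticipations, session-order and fatigue effects.  Passing recovery tests
on this generator therefore shows that the estimation and inference
machinery is correct under the stated model, not that the model captures
every feature of real joystick data.

## Problem sizes and numerical defaults

The package's own experiments run at a reduced scale chosen to make the
full battery a single-desk job: recovery fits use 8 participants × 240
trials/session/modality with 3,000 MCMC samples (1,000 burn-in), the
simulator/analytic cross-check 10⁵ trials at `dt = 1e-4`, oracle checks 100
replicates, metric closure 1,000 trajectories.  At this scale ≥20 of the 24
group-mean credible intervals cover their generating values, easy drift
exceeds difficult drift in all four directions, modality contrasts under
shared generation give `P_P|D` well above 0.5 for `a` and `Ter`, and the
easy-vs-difficult drift contrasts give `P_P|D = 0` — the same qualitative
pattern as the full-scale analysis.  Paper-scale runs (21 × 960 × 15,000)
are one config flag away (`paper_scale: true`).

Other defaults: density error tolerance `1e-7`; quadrature order 10;
simulator cap 10 s; angular ties at the exact 45° sector boundaries go to
the counter-clockwise direction (a documented deterministic rule; the
measurement convention itself is arbitrary); velocity is computed from raw
finite differences with no smoothing (the most literal "rate of change of
position"; an optional moving-average window exists but defaults to off);
trajectory metrics are computed up to the detected stop index, treating
later samples as padding.

## Known limitations

- Single-chain inference by default (matching the reference analysis);
  between-chain diagnostics like R̂ require multiple runs with different
  seeds.
- `sv` mixes slowly at desk scale; its Geweke scores should be inspected
  before interpreting `sv` contrasts on short chains.
- The sampler is exact but not the fastest possible; paper-scale fits
  (15,000 samples, 21 × 960 × 2 trials) take on the order of an hour on one
  CPU.
- The Euler simulator's first-passage bias, while below the stated
  tolerances, is systematic (RTs slightly long); applications needing
  sub-millisecond simulator accuracy should decrease `dt`.
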