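# Methods

## The assay being modelled

A solitary fly walks in a 48.7 mm linear glass chamber while a linear
optical array records its 1-D position and an infrared laser can raise its
body temperature by ~5 °C (to 26–27 °C, "mild heat"). Five sessions are run
back to back: Pre-test (10 min, no heat), Train 1, Test 1 (10 min, no
heat), Train 2, Test 2 (10 min, no heat). In a Train session the laser in
the train fly's chamber is commanded ON once the fly has walked
continuously for more than 0.5 s, or whenever it occupies the outer 3 mm at
either chamber end, and commanded OFF when it stops walking; the session
ends after 20 laser episodes (maximal ON runs) or after 8 min of one
uninterrupted pause. Each train fly is paired with a yoked fly whose
chamber's laser copies the train fly's channel sample for sample, and with a
blank fly that is never heated. The three run simultaneously, so the train
fly's session termination defines the triplet's Train windows.

## Locomotion and learning model

The simulator is deliberately minimal: a continuous-time two-state
(walk/pause) process sampled at `dt = 0.01 s`, with constant hazards so bout
durations are exponential.

- Pause → walk at baseline rate λ_w = 0.30 s⁻¹; walk → pause at
  λ_p = 0.25 s⁻¹. The stationary walk fraction λ_w/(λ_w+λ_p) ≈ 0.55 and
  mean bout lengths (4 s walks, 3.3 s pauses) match the ~55% baseline
  activity the assay reports for healthy flies.
- Walking moves the fly at 10 mm/s (typical fly walking speed) in a
  persistent heading, reflecting at the walls; the heading re-randomizes at
  each walk-bout onset.
- A suppression variable S ≥ 0 modulates the pause→walk hazard as
  λ_w·exp(−β·S) with β = 1. S integrates the *contingency* of heat on
  walking: heat received while walking adds α·dt (α = 0.02 s⁻¹), heat
  received while pausing subtracts the same amount (floored at 0), and
  without heat S relaxes with a long time constant τ_S = 3600 s, so learned
  suppression persists through a 10-min test session.
- A shared habituation factor exp(−h·t) with h = 1.1·10⁻⁴ s⁻¹ multiplies
  the pause→walk hazard in all flies, heated or not, producing the mild
  non-specific activity decline all groups show between Pre-test and Test 2.

The opponent (subtractive) term is the one place the model is more than the
obvious accumulator, and it is load-bearing. A pure "heat-while-walking"
integrator makes a yoked fly's suppression proportional to its total
heat∧walk time — which tracks *total exposure* (the two are correlated at
r ≈ −0.8 in simulation) and is nearly orthogonal to the exposure
differential ED. That is precisely the pattern the assay rules out: the
reported yoked-fly activity drop does not correlate with total exposure but
does correlate negatively with ED. With the opponent term, net suppression
is α·(T_heat∧walk − T_heat∧pause), which for a yoked fly is approximately
α·ED·T/2 — centred on zero across yoked flies, negligible for blank flies,
and large for train flies (whose heat is concentrated in walking by
construction). One mechanism therefore yields all three group phenotypes
and both correlation results.

Learning couples to the laser flag, not to modelled temperature. Body
temperature is a separate first-order relaxation (τ_heat = 3 s toward
26.5 °C when ON, τ_cool = 5 s toward 21.5 °C when OFF), provided as a
diagnostic trajectory only.

### Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `dt` | 0.01 s | sampling step (the sensor's rate is not documented; 100 Hz resolves the 0.5-s trigger comfortably) |
| `walk_speed` | 10 mm/s | walking speed |
| `pause_to_walk_rate` | 0.30 s⁻¹ | baseline pause→walk hazard |
| `walk_to_pause_rate` | 0.25 s⁻¹ | walk→pause hazard |
| `learning_gain` | 0.02 s⁻¹ | S accrual per second of heated walking |
| `unlearning_gain` | 0.02 s⁻¹ | S erosion per second of heated pausing |
| `suppression_effect` | 1.0 | β in exp(−β·S) |
| `suppression_decay` | 3600 s | forgetting time constant |
| `habituation_rate` | 1.1·10⁻⁴ s⁻¹ | shared non-specific decline |
| `controller_latency` ± jitter | 0.55 ± 0.25 s | operator latency, uniform per commanded switch |
| `max_train_duration` | 3600 s | safety cap on a Train session |

The behavioral defaults were calibrated once against the assay's reported
group magnitudes (baseline activity ~55%; Test-2 activity differences near
−0.37 / −0.11 / −0.06 for train/yoked/blank; a significant negative yoked
ED–AD correlation alongside a null exposure–AD correlation) and then
frozen; they are the package's study conditions, not free dials.

### The virtual operator

The laser is manually operated in the real assay, so the controller applies
a latency to every commanded switch: when the trigger condition (walk run
> 0.5 s, or edge zone) changes state, the laser follows after a delay drawn
uniformly from 0.3–0.8 s, and the command is cancelled if the condition
reverts first. This one ingredient makes the train fly's
P(heated|walking) land near 0.8 rather than 1.0 and gives it a nonzero
P(heated|pause) (laser trailing into pauses), as observed. Edge-zone
heating applies to the train fly only; yoked flies receive exclusively the
mirrored channel. Whether edge-triggered episodes count toward the
20-episode quota is not documented; all maximal ON runs are counted.

### Randomness

One root seed feeds a `SeedSequence` tree: per-triplet, then per-fly child
streams, so enlarging a cohort never perturbs earlier flies, and identical
configurations are bit-identical. The per-sample loop runs in a numba
kernel; `step_fly`/`LaserController` implement the same rules in plain
Python and the test suite cross-checks the kernel against the two-state
theory (stationary walk fraction) and the controller contracts.

## Segmentation

The walking criterion is not documented for the original system, so it is
an explicit, logged parameter pair: a sample is walking when its
first-difference speed |Δx|/dt ≥ 1.0 mm/s (well under real walking speeds,
above sensor jitter), and runs shorter than 0.2 s are merged into their
neighbours (shortest first, ties to pause) to debounce single-sample
flicker. Segmentation is exact by construction: bouts alternate, tile the
trace, and their durations sum to the trace duration; total walk time is
non-increasing in the threshold.

## Metrics

All metrics are sample counts over the walk mask and laser channel.
P(heated|state) is undefined (NaN, never 0) when a state is unoccupied, and
ED for never-heated flies is NaN — the conditional is degenerate and the
contingency analyses concern heated flies. Whole-experiment ED pools
occupancy and heat time across both Train sessions before dividing, since
ED is defined as a fraction of time. The Train-session comparison cut
defaults to the cohort-minimum Train length, recomputed per cohort and
recorded in the run manifest (163 s reproduces the original cohort;
simulated cohorts have their own minimum). AD subtracts the Pre-test level
from a test session's level and is reported as a plain number in [−1, 1].

## Inference

Kruskal–Wallis (midranks, tie correction; exact permutation p additionally
for total n ≤ 10) with pairwise two-sided rank-sum follow-ups: exact
enumeration when both groups have ≤ 8 tie-free observations, otherwise the
continuity-corrected normal approximation with tie-corrected variance, Holm
adjustment by default (togglable off for strict reproduction of unadjusted
output). The "permutation" interval convention in this literature is
ambiguous between two procedures, so both are implemented and labelled:
a with-replacement percentile bootstrap of the median (10 000 resamples,
seeded) for the ± intervals and CI bands, and a two-sided label-permutation
test of the median difference (exact enumeration for total n ≤ 12,
plus-one-corrected Monte Carlo otherwise) for two-group p-values.
Significance tiers: * < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001.

## Curation

A fly is excluded iff it was inactive strictly more than 90% of the
Pre-test (exactly 90% is retained), its attribute record is incomplete, or
it carries the procedure-error flag — one primary reason per exclusion, in
that order. Triplet members are curated independently: the original groups'
unequal sizes (64/125/72) show partners were not dropped together.

## What the simulator does and does not emulate

It reproduces: alternating bouts with realistic durations and speeds, the
closed loop with operator latency and edge rule, laser mirroring and the
never-heated control, both Train-termination rules, contingency-driven
learned suppression that persists into test sessions and scales down under
reduced-learning presets, and a shared mild habituation. It does not
emulate: spatial structure of real trajectories beyond 1-D bouts (no wall
preference, grooming, micro-movements), distance-dependent laser efficacy,
temperature-dependence of learning, inter-fly variability in baseline
parameters (all flies share one parameter set; variability is purely
stochastic), or strong-heat regimes. Passing the simulation-based tests
therefore shows that the pipeline recovers the patterns a
contingency-learning mechanism produces — not that real flies obey this
mechanism.

## Numerical notes and problem sizes

Discrete-time hazards use 1 − exp(−rate·dt), so bouts are exact geometric
approximations of the exponentials; CAD cuts are quantized to the sample
grid (the 1-Lipschitz property holds up to one sample). The main analysis
cohort is 60 triplets (180 flies), matching the original train-group order
of magnitude; the yoked correlation analysis simulates 125 triplets to
match the original yoked sample size; the null-configuration calibration
runs 20 independent 60-triplet cohorts with the learning gains at zero.
Dopamine-receptor-mutant presets scale both learning gains to 25% of wild
type and are illustrative of the simulator's parameter space only.

## Known limitations

- The paper-facing trace format starts at the converted-CSV boundary; the
  original binary TDMS instrument format is out of scope.
- The exact Kruskal–Wallis enumeration is restricted to total n ≤ 10
  (combinatorial growth); beyond that the chi-square approximation is used,
  as in standard practice.
- Bootstrap percentile intervals of a median are slightly conservative at
  small n with heavy ties; the degenerate all-equal sample returns a
  zero-width interval by design.
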