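# Methods

## The generative model

Each simulated decision is a one-dimensional Wiener process with drift `v`
(evidence units·s⁻¹) between absorbing boundaries at 0 and `a` (evidence
units), starting unbiased at `z = a/2`, with intra-trial diffusion
coefficient `s` (evidence units·s⁻½). Crossing the upper boundary is the
correct response; the response time is the first-passage time plus a fixed
non-decision component `Ter`. Inter-trial variability parameters (drift,
start, non-decision time) are fixed at zero and deliberately not modelled.

Two closed forms anchor everything:

- P(correct) = (1 − e^{−2vz/s²}) / (1 − e^{−2va/s²}), which at `z = a/2`
  is the logistic function of `va/s²`;
- E[decision time] = (a/2v)·tanh(va/2s²) for the unbiased start.

### Noise convention

`s = 1` by default. The alternative convention `s = 0.1` merely rescales
`v` and `a`; the knob is exposed (`noise` argument, `--noise-s` flag)
because results such as the accuracy measure's power depend strongly on
where `logistic(va/s²)` sits relative to ceiling. At the default study
conditions (`v = a = 2`, `s = 1`) single-trial accuracy is 0.982 and mean
RT is 0.782 s.

## Samplers

**Exact sampler (default for trial sets and the whole pipeline).**
Rescaling space by `a` and time by `a²/s²` reduces the problem to unit
boundary separation with scaled drift `mu = va/s²`. The choice is drawn
from the closed-form probability. Conditional on the chosen boundary, the
decision time of an unbiased walk has the same distribution at both
boundaries, with CDF (large-time series)

    F(T) = 1 − 2π·cosh(mu/2) · Σ_{k odd} (−1)^{(k−1)/2} k e^{−λ_k T}/λ_k,
    λ_k = (mu² + k²π²)/2,

which depends on `mu` only through `mu²`. A numba kernel inverts `F(T)=u`
per trial by safeguarded Newton iteration inside a bisection bracket
(series truncated when a term falls below 1e−15 of the running sum;
convergence at relative 1e−12). The left tail carries mass ~e^{−1/(8T)},
so the bracket floor `T = 2e−3` (scaled units, i.e. decision times below
~8 ms at `a = 2`, `s = 1`) is unreachable for any representable uniform
draw. Validation: quantiles 0.01–0.99 from 2·10⁵ Euler trials at
dt = 0.5 ms match the exact sampler to <0.5%, and accuracy/mean-RT match
the closed forms within Monte-Carlo error on a 3×3 grid of `(v, a)` at
10⁵ trials (`tests/test_acceptance.py`).

**Euler–Maruyama path simulator.** Increments `v·dt + s·√dt·ε`; the
crossing rule is the first step at or beyond a boundary, with a guard of
10⁶ steps treated as an error, never as a censored trial. Discrete
monitoring of a continuous barrier inflates first-passage times at order
√dt; by default both boundaries are therefore pulled inward by
`0.5826·s·√dt` (the Broadie–Glasserman–Kou continuity correction, on by
default, off via `boundary_correction=False`). Without the correction the
bias in mean RT is ≈0.01 s at dt = 1 ms — larger than the Monte-Carlo
error of any test at 10⁴⁺ trials; with it the residual is O(dt) and
invisible at the trial counts used here. Default dt = 1 ms, usable range
0.2–5 ms; a dt-halving test checks that discretization does not move
accuracy beyond Monte-Carlo noise.

## EZ parameter recovery

Per participant the data reduce to proportion correct `Pc` and the mean
`MRT` and variance `VRT` of correct-trial RTs (correct-only moments are
the default; a flag pools all trials). With `L = logit(Pc)`:

    v̂  = sign(Pc − ½)·s·[L(Pc²L − PcL + Pc − ½)/VRT]^{1/4}
    â  = s²L/v̂
    T̂er = MRT − (â/2v̂)·(1 − e^{−v̂â/s²})/(1 + e^{−v̂â/s²})

Degenerate accuracies are nudged by the half-count rule before the logit:
1 → 1 − 1/(2n), 0 → 1/(2n), ½ → ½ + 1/(2n). At 40 trials and 98%
accuracy roughly half of all participants sit at `Pc = 1`, so the choice
of edge rule is material and is kept visible in the API. A negative `T̂er`
can occur in small samples and is returned unclamped — clamping would
bias group means, and only `v̂` enters the downstream tests. Participants
with fewer than two correct trials or zero RT variance are flagged
unfittable and excluded from the affected measure's test (at the default
conditions this essentially never happens; exclusion counts are reported).

## Cohorts and scenarios

Participants are sampled independently: drift ~ Normal(mean, sd), boundary
~ Normal(mean, sd) with rejection-resampling at boundary ≤ 0 (at mean 2,
SD 0.05 the rejection never fires in practice, so the stated normal
distribution is preserved). Defaults frozen in the bundled presets: base
drift and boundary 2, within-group SDs 0.05, Ter 0.3 s, 40 trials per
participant, α = 0.05. A scenario shifts group B's mean drift up by
`delta_drift` and its mean boundary down by `delta_boundary` (negative =
raised boundary). The declared drift effect size is exactly
`delta_drift / within_sd_drift`; the presets use deltas of 0.1, i.e. a
declared Cohen's d of 2. Presets: `no_sato`, `sato_lowered`,
`sato_raised`, `null`; a scenario's false-alarm counterpart zeroes only
the drift delta, keeping any boundary confound.

## The virtual experiment and power surfaces

Each experiment simulates both groups, reduces every participant to three
measures — mean correct RT, accuracy (raw proportion, untransformed), and
EZ-recovered drift — and applies a pooled-variance (Student) two-sided
two-sample t-test to each at α (Welch available behind a flag; the
simulated groups have equal variances by construction). Observed effect
sizes are pooled-SD Cohen's d.

Hit rate at a design point = rejection frequency under the true scenario;
false-alarm rate = the same under the matched null, on an independent
replication set. Sensitivity combines them as
d′ = Φ⁻¹(HR) − Φ⁻¹(FAR), with rates of exactly 0 or 1 pulled in by
1/(2·n_reps). d′ estimated from finite replication counts is noisy
wherever a rate nears 0 or 1 (the probit derivative blows up), so d′
curves are expected to look kinked; no test asserts smoothness.

Required sample size at a target power is read off the hit-rate curve as
the smallest qualifying grid point; a linear interpolation between the
bracketing points is reported separately. When the target is not reached
on the grid, the acceptance script extrapolates instead of reporting
nothing: each measured hit rate is inverted through
power ≈ Φ(d·√(n/2) − z_{0.975}) to an implied standardized effect, and
the median implied effect is converted back to the n reaching the target.

### Problem sizes (scaled profile)

The full study design (grid to n = 400, 10⁴ replications per point) is a
cluster-scale computation. The scaled profile used by the default tests
and the acceptance script keeps the generative conditions identical and
shrinks only the Monte-Carlo sizes: grid 10–150 in steps of 10 with 1000
replications per point for the no-SATO power sweep; 2000 replications at
n = 100 for null calibration; 500 replications at n = 100 for the
effect-size conversion; 500 replications at n ∈ {50, 100, 150} (hits and
false alarms) for each SATO scenario. `--profile paper` exposes the full
grid and replication count.

## Reproducibility

A single master seed feeds a numpy `SeedSequence` whose spawn key is
(crc32(scenario), n, crc32(role)), so every (scenario, sample-size, role)
cell owns an independent substream and any cell can be regenerated in
isolation. Results are identical under any execution order; hit and
false-alarm replication sets never share a stream. Within a cell,
replications are processed in memory-bounded chunks (≤4·10⁶ trials per
chunk) drawn sequentially from the cell's stream.

## What the generator does and does not emulate

It emulates exactly the stated between-groups design: normal
participant-level parameter distributions, equal group sizes, a fixed
trial count, no starting bias, no inter-trial parameter variability. It
does not emulate contaminant RTs, lapses, fast guesses, unequal group
sizes, within-participant designs, collapsing boundaries, or non-DDM
accumulators. Passing tests therefore certify the statistical machinery
under the idealized generative model, not robustness of EZ recovery to
real-data violations of its assumptions.

## Known limitations and open tensions

- Under the default noise convention the single-trial accuracy (0.982) is
  close to ceiling. Consequently the accuracy measure carries little
  between-group information at 40 trials — its observed effect size for a
  declared drift d of 2 is ≈0.16, bounded above by the binomial noise
  floor √(P(1−P)/40) — and it does not reach 80% power on the scaled
  grid (the acceptance script reports an extrapolated requirement of
  several hundred per group). Lowering the effective `va/s²` moves
  accuracy off ceiling but weakens all three measures at once. Which
  measure wins, and by how much, is regime-dependent; the package
  recomputes rather than assumes the answer.
- The EZ drift estimate at 40 trials has an SD of ≈0.25 at the default
  conditions, so the drift measure's observed effect size is ≈0.4 for a
  declared d of 2; the measured 80%-power requirement is ≈150 per group
  (extrapolated 158), not far below the RT measure's ≈110.
- The d′ dominance of the drift measure under SATO confounds holds across
  the scaled grid, and its false alarms stay near α while the confounded
  raw measure's explode (RT's false-alarm rate reaches ~0.99 at n = 150
  under a lowered boundary). "Near", not "at": with a 0.1 between-group
  boundary shift the EZ drift test's measured false-alarm rate is
  ~0.076–0.086 rather than 0.05 at 500 replications — the EZ drift
  estimate carries a small boundary-dependent bias at ceiling accuracy,
  so a boundary confound leaks slightly into the drift test, and the
  leak grows with n. At small n a strongly confounded raw measure can
  also transiently post a d′ comparable to drift's through its inflated
  hit rate.
- Euler and exact samplers agree to Monte-Carlo precision, but the Euler
  path is ~100× slower and is kept for transparency and validation, not
  production sweeps.
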