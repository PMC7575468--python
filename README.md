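# driftpower

Monte-Carlo power analysis for two-alternative decision experiments:
how much sensitivity does a between-groups study gain by fitting a
decision model to response time (RT) and accuracy data, instead of
testing either raw measure alone — and what happens when the groups sit
at different points of the speed–accuracy trade-off (SATO)?

The package is aimed at experimental psychologists and cognitive
neuroscientists planning group-comparison studies (patients vs controls,
young vs old, intervention vs baseline) whose outcome is speeded binary
decisions.

## The model

Each decision is a drift-diffusion process: evidence `x` accumulates from
`z = a/2` with drift `v` and diffusion coefficient `s` until it hits the
correct boundary `a` or the error boundary 0; RT is the first-passage
time plus a non-decision component `T_er`. For the unbiased start,

- P(correct) = 1 / (1 + exp(−v·a/s²)),
- E[decision time] = (a/2v)·tanh(v·a/2s²).

Participants are drawn from group-level normal distributions of `v` and
`a`. A drift difference between groups is a true sensitivity difference
(declared effect size d = δ_v / SD_within); a boundary difference is a
pure SATO confound. Each simulated participant's 40 trials are reduced
to three competing measures:

1. mean correct RT,
2. accuracy (proportion correct),
3. the drift recovered by the EZ-diffusion closed-form inversion from
   (Pc, MRT, VRT).

Each measure is tested A vs B with a pooled two-sample t-test at
α = 0.05. Over many replications, the rejection rate under a true drift
difference is the hit rate (statistical power) and under the matched
null (no drift difference, any boundary confound retained) the
false-alarm rate; they combine into the bias-free sensitivity
`d′ = Φ⁻¹(HR) − Φ⁻¹(FAR)`. Trial data come from an exact sampler for the
Wiener first-passage problem (series-CDF inversion, numba-accelerated);
an Euler–Maruyama path simulator with continuity correction is kept as a
transparent cross-check. See `docs/methods.md` for details and numerical
choices.

## Worked example

Sweep three sample sizes of the `no_sato` scenario (group B's mean drift
2.1 vs 2.0, within-group SD 0.05 — declared d = 2; no boundary
difference), 300 replications per grid point:

```sh
driftpower power --scenario no_sato --n-grid 40,80,120 --reps 300 --seed 7 --out demo/
```

`demo/power.csv` (abridged):

```
measure,n_per_group,hit_rate,fa_rate,dprime
rt,40,0.357,0.063,1.160
accuracy,40,0.093,0.050,0.324
drift,40,0.263,0.053,0.980
rt,120,0.843,0.060,2.563
accuracy,120,0.220,0.050,0.873
drift,120,0.707,0.030,2.424
```

Reading: with 120 participants per group the RT test detects the group
difference in 84% of experiments, the EZ-drift test in 71%, and the
accuracy test — sitting at its 98% ceiling under these generative
settings — in only 22%; all three false-alarm near the nominal 5%.
`demo/required_n.csv` reads the 80%-power requirement off the curve
(RT: 120 on this coarse grid, 111 interpolated; the other two measures
have not reached 80% by n = 120).

A single confounded experiment shows the SATO danger directly. With a
lowered group-B boundary (faster, sloppier) on top of the same drift
difference:

```sh
driftpower run-experiment --scenario sato_lowered --n-per-group 60 --seed 11 --out demo2/
# p(rt)=0.0000 p(accuracy)=0.6995 p(drift)=0.0460
```

The RT test rejects overwhelmingly — but it would also have rejected
with no drift difference at all, because the boundary shift alone moves
RT. The recovered drift stays interpretable: in the matched null
scenario its false-alarm rate remains close to α while RT's approaches 1
(run the `power` command on `sato_lowered` to see the curves; the
`sato_raised` preset mirrors the confound onto accuracy).

Other subcommands: `simulate-trials` (raw trial dumps),
`sato-sweep` (the curvilinear RT/accuracy trade-off traced by varying
the boundary alone), `effect-curve` (how declared drift differences
convert into the much smaller observed RT/accuracy effect sizes).
Every run writes a `manifest.json` (config snapshot, master seed,
substream scheme) from which it can be reproduced bit-for-bit.

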