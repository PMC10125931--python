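# Methods

This note documents the models, numerical choices and known limitations of
`speedacc`, in the spirit of a model-documentation page: what is computed,
under which assumptions, and what the validation runs do and do not show.

## Diffusion model

Single trials are first-passage times of a scaled Wiener process

X(t) = start + v·t + σ·W(t)

between an absorbing upper boundary *a* (correct response) and a lower
boundary 0 (error), with start = *a*/2 unless overridden. The response time
is the decision time plus a non-decision constant t<sup>ER</sup>. Units:
time in milliseconds; evidence units are arbitrary because only
v·a/σ² and a²/σ² enter any observable. Defaults follow the reference
setup: σ = 4, t<sup>ER</sup> ~ N(300 ms, SD 20 ms) per participant.

Closed forms used as oracles (and available as library functions):

- P(correct) = (1 − e^(−2·v·start/σ²)) / (1 − e^(−2·v·a/σ²)), the logistic
  1/(1 + e^(−v·a/σ²)) at the unbiased start, with limit start/a as v → 0.
- E[decision time] = (a/2v)·tanh(v·a/2σ²) for the unbiased start
  (a²/4σ² at v = 0). Even in the sign of v.

### Integration scheme and its bias

Trials are simulated by Euler–Maruyama with step Δt (default 1 ms,
matching millisecond RT resolution):
X ← X + v·Δt + σ·√Δt·N(0,1), absorbed at X ≥ a or X ≤ 0. A trial that
exhausts `max_steps` (default 20 000 steps) raises an error in library use
and is dropped with a log message in study mode; at the reference
parameters the probability is negligible.

Discrete paths can overshoot a boundary between steps, so first passage is
detected late: each boundary is effectively pushed out by roughly
0.5826·σ·√Δt (the asymptotic overshoot constant for Gaussian increments).
At Δt = 1 ms and the reference parameters this inflates mean decision time
by ≈ +11 ms and accuracy by ≈ +0.008. This is intentional, not corrected:
the reference study's reported condition means (e.g., 487/510 ms against
closed-form values of 476/500 ms) carry exactly this bias, so a 1 ms Euler
scheme *is* the process that generated the numbers being reproduced. The
test suite verifies (a) agreement with the closed forms inside Monte-Carlo
bands at small Δt (0.01 ms for accuracy, 0.002 ms for mean decision time,
the latter with a 2× overshoot-shift allowance on top of the 3-SE band) and
(b) that the bias at Δt = 1 ms is positive and shrinks when Δt is reduced.

The simulation kernel is a numba-compiled sequential loop: a batch of n
trials consumes the random stream exactly as n consecutive single-trial
calls would, so `simulate_trials` and `simulate_trial` are observationally
equivalent by construction (and tested to be).

## Design generator

A two-condition within-participants experiment perturbs one focal
parameter (drift or threshold):

μ<sub>ij</sub> = μ<sub>j</sub> + ε<sub>i</sub><sup>between</sup> + ε<sub>ij</sub><sup>within</sup>,
ε<sup>between</sup> ~ N(0, σ²_B) once per participant,
ε<sup>within</sup> ~ N(0, σ²_W) once per cell.

The shared between-deviation implies a between-condition correlation of the
realized parameter of r = σ²_B/(σ²_B + σ²_W) across participants — 0.80 at
the reference values (σ²_B = 20², σ²_W = 10² for threshold;
0.01², 0.005² for drift). Realizations that would be invalid (non-positive
focal parameter, negative t<sup>ER</sup>) are redrawn for that cell; at the
reference values this essentially never happens, so the marginal stays
Gaussian. The notation N(300, 20) for t<sup>ER</sup> is read as SD = 20 ms
(variances elsewhere in the setup are written as explicit squares); the
knob `t_er_sd` makes the other reading available.

### Shared trial noise (common random numbers)

By default (`shared_trial_noise=True`) the two conditions of a participant
replay the **same** noise substream: trial k of condition 2 starts from the
same generator state trajectory as trial k of condition 1. Because the two
cells' parameters differ only slightly, their trial noise is strongly
positively correlated; it therefore partially cancels in paired condition
differences and adds to the participant-level variance shared between
conditions. Concretely, under the drift design this raises the mean
effect size on mean RT from ≈0.45 (independent trials) to ≈0.65–0.69 and
the between-condition correlation of mean RT from ≈.93 to ≈.975–.98 — the
regime of the reference validation tables, which are not reachable with
independent trial noise at 1000 trials per cell (the trial-level RT SD of
≈150 ms alone would put a floor of ≈7 ms on the paired-difference SD,
versus the ≈3 ms condition effect). The coupling changes power and
correlations, not means. Real experiments have independent trial noise;
set `shared_trial_noise=False` for that regime, and expect lower power and
lower between-condition correlations of the aggregated measures there.

Stream discipline: one master seed per study spawns one child seed per
experiment (each experiment reproducible in isolation); within an
experiment, one substream drives the parameter draws and one is assigned
per participant. Experiments are independent, so scheduling cannot change
results.

## Measures

Aggregation: per participant × condition cell, mean RT over **correct**
trials only, PC over all trials; the LISAS trial SDs pool a participant's
correct-trial RTs (S<sub>i</sub><sup>RT</sup>) and all-trial 0/1 error
indicator (S<sub>i</sub><sup>E</sup>) across that participant's conditions,
with per-cell versions kept for LISAS<sup>cond</sup>. All SDs are sample
SDs (n−1), the default of mainstream statistics software; BIS contrasts are
invariant to that convention while LISAS values shift slightly, and
`aggregate(..., ddof=0)` provides the population convention (under which
the cell error SD equals √(PE·(1−PE)) exactly).

Degenerate cases are defined, not patched: a participant with no errors
anywhere has S<sub>i</sub><sup>E</sup> = 0 together with PE = 0, and the PE
term takes its limit 0, so LISAS reduces to mean RT. A zero across-cell SD
of mean RT or PC makes BIS-standardization impossible and raises an error.
BIS is computed from PC; z(PC) = −z(PE) exactly, so the choice of
orientation is cosmetic. The standardization scope defaults to all cells of
one experiment; callers can build a `MeasureContext` per group when scores
should be equated within groups.

Within one scope, LISAS<sup>BIS</sup> = mean RT + (S^RTbar/S^PE)·PE equals
the RT-scaled BIS plus a constant, so its paired t statistic is BIS's with
the sign flipped — the package treats this identity as a correctness
invariant and tests it to floating-point tolerance.

## Inference and study harness

Per experiment and measure: two-sided paired t test across participants on
condition 1 − condition 2, effect size d_z = t/√n, significance at
α = .05, and the Pearson correlation between the participants' two
condition values. Across experiments the harness reports arithmetic means
of condition means and d_z, the percentage of significant tests, and the
**Fisher-z averaged** correlation with its min/max range (the sampling
distribution of r near 1 is left-skewed; averaging arctanh-transformed
values is the standard remedy and matches how the reference correlations
were evidently summarized). Experiments with a degenerate test or constant
condition (possible only in tiny designs) are logged, excluded for that
measure, and counted.

Partial eta squared (SS_effect/(SS_effect + SS_error)) is provided as a
standalone utility for effect-size reporting; the harness's two-condition
designs do not need it.

## Problem sizes and runtime

The reference study conditions are 20 participants × 2 conditions × 1000
trials per experiment. `scripts/acceptance.py` runs the two headline
designs at the full 1000 replications (a few minutes on one core thanks to
the compiled kernel). The test suite's Monte-Carlo checks use 200
replications with 3-SE tolerances (binomial for percentages, empirical for
means), plus half the printed precision of the value being reproduced; unit
tests run at much smaller desk scales.

## Limitations

- The simulator emulates idealized diffusion behavior: no across-trial
  variability in drift, start or non-decision time (the full Ratcliff
  model's sv/sz/st), no contaminant responses, no sequential effects.
  Passing validation here shows the measures' behavior under controlled
  trade-off vs difficulty manipulations, not under every real-data
  pathology (RT outliers, fast guesses, non-stationarity).
- Exactly two conditions per design; no between-participants group factor
  and no multi-level repeated-measures ANOVA.
- No diffusion-model fitting: the package scores observed or simulated
  trial tables; it does not recover v or a from data.
- The shared-trial-noise default reproduces the reference study's
  correlation/power regime but is an analysis-of-the-simulation choice, not
  a claim about real data (see above).
- The guessing floor of the exponential speed–accuracy curve utility is
  fixed at 50%, i.e., two response alternatives.
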