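# Methods

This note documents the models implemented in `exoresist`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions fixed for reproducibility.

## Proportional resistance control

The device estimates the biological ankle moment from a forefoot force
sensor and commands a resistive plantar-flexion torque proportional to the
instantaneous estimate:

    τ(t) = r · clip( M̂(t) / M_peak, 0, 1 ) · m        [Nm]

with r the prescribed resistance level (Nm/kg), m body mass (kg) and
M_peak the *calibrated* average peak moment, computed as the mean over
stance intervals of the within-interval maximum of M̂. The fraction is
clipped to [0, 1]: strides stronger than calibration saturate at the
prescription, and swing (zero estimated moment) commands exactly zero. The
command at sample k depends only on samples ≤ k.

Design choices, where the underlying control scheme is open:

- **Moment estimation.** How forefoot force maps to ankle moment is not
  fixed by the control law; a single lever-arm proportionality
  M̂ = F · ℓ (default ℓ = 0.15 m, configurable) is used. Because the
  controller consumes only the *ratio* M̂/M_peak, any fixed
  proportionality yields identical behaviour; ℓ only sets the absolute
  scale of logged moments.
- **Stance detection** is a plain force threshold (default 20 N), with a
  100 ms minimum-duration debounce applied to stride segmentation (not to
  the per-sample torque command, which stays causal) to reject sensor
  chatter.
- **Stride "reaching the prescription"** is defined as peak applied torque
  ≥ 95% of r·m; the tolerance is a parameter. The engagement fraction of a
  session is the proportion of gait cycles meeting it.

## Training progression

Ten visits, 20 minutes of resisted walking each. After each visit the
resistance for the next is increased by a fixed increment if and only if
(1) the engagement fraction exceeded 0.5 and (2) reported soreness on the
ordinal scale None < Mild < Moderate < Severe < Very Severe was at most
Moderate. Resistance never decreases. Defaults: starting resistance
0.05 Nm/kg (midpoint of the documented 0.025–0.075 Nm/kg starting range —
values outside it warn but run), increment 0.75 Nm (midpoint of the
allowed 0.5–1 Nm band). Engagement is scored per gait cycle rather than
per unit time; a time-based variant can be obtained by weighting strides
by their duration, but stride counts are the natural unit of the
engagement display the protocol relies on. The increment is applied
identically to both limbs. Rest breaks within a session carry no
information and are ignored.

In `simulate_training_course` a 60-second bout stands in for each
20-minute session: the controller is stationary within a session, so
stride statistics from a shorter bout estimate the same engagement
fraction; only the Monte-Carlo error of engagement (≈ 0.07 at ~100
strides) is affected. The logged `walk_minutes` remains 20.

## Steady-state metabolic analysis

Per-breath metabolic power (W) is computed from V̇O2 and V̇CO2 (ml/min)
with the standard indirect-calorimetry energy equivalents

    P = (16.58 · V̇O2 + 4.51 · V̇CO2) / 60,

i.e. 16.58 kJ per litre O2 and 4.51 kJ per litre CO2.

A sliding window of 20 breaths (default) moves along the power trace; in
each window Kendall's tau-b of power against time is computed with tie
corrections in both variables, with a two-sided p-value from the
tie-adjusted normal approximation of the S statistic (exact permutation
enumeration for windows of ≤ 8 points). A window with p < α (default
0.05) is *rising* (τ > 0) or *falling* (τ < 0); otherwise *stable*. Each
point takes the label of the window centred on it (clipped at the series
edges); steady-state windows are maximal runs of stable points at least
one window long. The centred-window rule is the default because the
alternative — requiring *every* window covering a point to be stable — is
so conservative that a single false-positive trend window (expected at
rate α even on a true plateau) vetoes 2·window−1 points, and on realistic
noisy plateaus frequently leaves no admissible steady window at all; the
strict rule remains available as `rule="all"`. Window length and α are
config keys recorded in output metadata. Tau-b being rank-based, labels
are invariant to affine rescaling of the trace.

When several steady windows exist the longest is used (ties broken toward
the latest, favouring the fully-developed plateau). Breath-by-breath
values enter unsmoothed by default; an odd-width median prefilter is
available. Walking power net of quiet standing (negative nets are flagged,
not rejected), divided by body mass and treadmill speed, gives the cost of
transport in J/(kg·m). Sitting series are processed identically for QC but
only standing enters the net subtraction.

## Outcome statistics

Five measures: plantar-flexor MVC (N/kg; mean of three trials per limb,
limb means averaged, normalised to mass — deviations from the 3-trial
protocol warn and compute on what exists), preferred treadmill speed
(m/s), cost of transport (J/(kg·m)), TUG time (s), 6MWT distance (m).

Per measure: listwise deletion of incomplete pairs; 1.5×IQR fences applied
to pre and post values separately (quartiles by linear interpolation
between order statistics, numpy's default, fixed as the package
convention), flagged participants removed from that measure only;
Lilliefors-corrected Kolmogorov–Smirnov normality reported (not gating) —
the p-value comes from a seeded Monte-Carlo null of ≥10⁴ standard-normal
samples with re-estimated parameters, cached per sample size, rather than
from printed tables; two-tailed paired t-test; Holm–Bonferroni step-down
adjustment across the analysed measures (both raw and adjusted p are
emitted, since published reports are often ambiguous about which they
print); Cohen's d with the difference-score variant d_z = mean(Δ)/SD(Δ) as
default and d_av = mean(Δ)/mean(SD_pre, SD_post) available — with n = 6
the two differ materially and neither is recoverable from group summaries
alone, so the variant is documented, not tuned. Percent change is
summarised as the mean ± SD of per-participant (post−pre)/pre, matching
the "mean ± SD %" reporting style, not the percent change of means.
Degenerate cases (zero-variance differences, zero-variance samples) return
flagged sentinel values rather than raising.

## Synthetic data

The generators define the study conditions under which the pipeline is
exercised; all are pure functions of their arguments and a seed, with one
global seed split into independent substreams per artifact type.

**Gait bouts.** Strides alternate at fixed cadence (default 100 steps/min,
60% stance). Within each stance the moment follows a raised-cosine
single-peak profile peaking at 75% of stance (late stance); any smooth
unimodal shape would serve, and this one is C1 and parameter-free beyond
peak timing. Per-stride peak moments are Gaussian about 0.9 Nm/kg — a
plausible push-off peak for independently ambulant adolescents with CP,
below typically-developing values — with a 10% stride-to-stride CV
(20% during training simulations, where gait is perturbed by the device).
The more-affected limb's peaks are scaled by the profile's asymmetry ratio
(applied to both limbs for bilateral involvement). Forefoot force is
moment/lever-arm, so force and moment are coherent by construction. Not
emulated: double-support timing variation, cadence jitter, EMG,
within-stance shape variability, device dynamics — so passing tests show
the *control and analysis logic* is correct, not that it is robust to
every hardware artifact.

**Breath series.** Expected gas rates follow
rest + (steady − rest)(1 − e^(−t/τ)) with τ = 30 s by default (typical
moderate-intensity on-kinetics), resting rate 35% of steady, additive
Gaussian noise, log-normal inter-breath intervals of mean 3 s (σ = 0.25),
and quantisation at 1 ml/min, the 0.001 L/min reporting resolution of
commercial carts. The quantisation matters conceptually: on a noiseless
exponential the trace is otherwise strictly increasing forever and a
rank-based trend test would never declare steadiness; finite instrument
resolution is what produces the exact ties a real plateau shows. Not
emulated: slow drift components, breath artifacts (cough/swallow), RER
drift within a bout.

**Soreness.** Ordinal response from a cumulative-logistic model on the
latent drive resistance × engagement × propensity (cuts 0.015/0.05/0.11/
0.22 Nm/kg-scale, logistic scale 0.03), chosen once so that mid-protocol
resistance with typical engagement yields mostly Mild–Moderate responses,
Severe rarely, Very Severe exceptionally — the qualitative pattern a
resistance-to-moderate-soreness protocol is designed to produce.

**Cohorts.** Baselines: mass ~ N(52, 12) kg, MVC ~ N(2.0, 0.5) N/kg, speed
~ N(0.9, 0.25) m/s, CoT ~ N(7.0, 1.8) J/(kg·m) (2–3× unimpaired walking
economy), TUG ~ N(8.5, 2.0) s, 6MWT ~ N(450, 80) m, truncated to
physiological ranges. Default pre→post effects (mean, between-participant
SD): MVC +17 ± 8%, speed +39 ± 25%, CoT −33 ± 9%, TUG −11 ± 9%, 6MWT
+13 ± 9%, plus 2% fractional measurement noise. Post = pre × (1 + effect +
participant deviate) + noise. The generator reproduces configured *group*
effects at large n by construction; at n = 6 any single cohort's
statistics scatter widely, which is exactly what the replicate-based tests
quantify.

## Numerical conventions and degenerate inputs

- Kendall tau-b on an entirely tied window returns τ = 0, p = 1 with a
  degenerate flag (and therefore labels the window stable).
- All CSV I/O is RFC-4180, UTF-8, dot decimal, time in seconds; readers
  name the offending column on schema violations and reject comma
  decimals and non-monotone time explicitly.
- Holm adjustment follows the step-down max formulation, capped at 1,
  returned in input order.
- Seeds are split with `numpy.random.SeedSequence`; every simulated
  artifact records its seed in metadata.

## Problem sizes

Defaults used by the test-suite simulations: 60–120 s gait bouts (50–100
strides/limb), 6-minute breath series (~120 breaths), cohorts of n = 6
with 200–500 replicates for calibration checks, 100 seeds for the
metabolic end-to-end check. These sizes give Monte-Carlo error comfortably
below the tolerances asserted while keeping a full run to a few minutes.

## Known limitations

- No hardware dynamics (motor, Bowden-cable compliance, torque-tracking
  error, transmission latency) — the controller is ideal and instantaneous.
- Soreness and engagement are generated from simple stationary models; no
  delayed-onset soreness kinetics, fatigue within a session, or learning
  across sessions.
- The training course does not feed back into the cohort's pre→post
  effects: effect sizes are configured, not emergent, so the package
  validates the measurement and inference chain rather than predicting
  training efficacy.
- The Lilliefors Monte-Carlo null assumes i.i.d. sampling; with n = 6 its
  power is minimal, mirroring the underlying design's limits.
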