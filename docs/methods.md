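# Methods

`beatgain` simulates and analyses a rhythmic auditory attention task: on each
trial a listener hears four reference tones at f0 = 440 Hz establishing a
1.5 Hz beat (inter-stimulus interval 667 ms), followed by an alternation of
eight *target* tones — on the beat in experiments 1 and 2, in anti-phase in
experiment 3 — and eight (nine in experiment 2) *distractor* tones at the
opposite beat phase. Tone frequencies are normal in base-2 log units
(s.d. 0.2); the listener reports whether the targets were on average higher
or lower than f0. In the *motor* condition the listener taps the beat with a
finger; in the *listen* condition they stay still. The package contains a
generative observer that produces taps and choices, and the estimation
pipeline that recovers the observer's sensory gains and their dependence on
tone–tap timing.

## Stimulus model

Times are milliseconds from the first reference onset; every tone lasts
100 ms. Targets and distractors are jittered around the half-beat grid:
Gaussian with s.d. 67 ms, redrawn until strictly inside ±141 ms, in
experiments 1 and 3 (the cap guarantees targets and distractors never swap
order); uniform on ±67 ms in experiment 2, where target and distractor
streams can be jittered independently (conditions TD/Td/tD/td, uppercase =
rhythmic). The exact shape of the "approximately Gaussian" regime is a
modelling choice — s.d. 67 ms truncated at the 141 ms cap matches the stated
dispersion and the stated hard bound — and is recorded in the run
configuration.

Target draws are recentred so the per-trial sample mean equals the titrated
offset ±Δ exactly: Δ *is* the task statistic, so the correct answer is
well defined on every trial. Distractor draws are left at population mean 0
and are *not* recentred per trial. This asymmetry is deliberate: if every
trial's distractor log-frequencies summed to exactly zero, a constant added
to all per-position distractor gains would change nothing — the pooled
distractor gain would be both behaviorally inert in the generator and
structurally unidentifiable in the choice regression. Distractors are
uninformative in expectation, which is what makes their fitted gain an
interference measure.

The sign of Δ is balanced 50/50 within each condition cell (counterbalancing
is a design choice; nothing downstream depends on it).

## Generative observer

Parameters (defaults in parentheses) describe a reasonably attentive adult:

| parameter | default | meaning |
|---|---|---|
| `g_target` | 1.0 | stationary gain per unit log2 frequency, targets |
| `g_distractor` | 0.3 | stationary gain, distractors (imperfect suppression) |
| `bias_b` | 0.0 | additive response bias toward "high" |
| `mod_depth_m` | 0.5 | movement-locked gain swing in the motor condition |
| `pref_phase_rad` | 0.0 | phase of maximal gain in the modulating cycle |
| `listen_mod_depth` | 0.25 | covert beat-locked swing in the listen condition |
| `motor_sd_ms` | 40 | tap timing noise (typical finger-tapping variability) |
| `motor_lag_ms` | −30 | constant tap lead (negative mean asynchrony) |
| `miss_prob` | 0.02 | probability a tap goes unrecorded |

Each target/distractor tone k receives an effective gain
g_k = g_role·(1 + m_eff·cos(φ_k − pref)), the decision variable is
Σ g_k f_k + b, and the choice is Bernoulli with probit probability
Φ(Σ g_k f_k + b). The modulating cycle is the observer's own tap train
(m_eff = `mod_depth_m`) in the motor condition when taps and the attended
stream are aligned (experiments 1–2), and a covert beat-locked oscillation
peaked on the nominal target stream (m_eff = `listen_mod_depth`) otherwise —
including the motor condition of experiment 3, where taps fall in phase with
distractors: the movement-locked boost requires alignment with the attention
cycle, which builds the synergistic-enhancement hypothesis into the
generator. A consequence worth knowing: because the covert oscillation is
beat-locked, a small *negative* tap-referenced modulation survives in
simulated experiment-3 data (cos of the covert cycle projects onto the tap
cycle with sign flipped); tests therefore assert ordering (far below the
experiment-1 value, not significantly positive) rather than exact zero.

Taps are anchored to the beat, never to the jittered tones: one intended tap
per beat from the second reference beat onward, tap = beat + lag + noise.
Misses are recording failures — the movement still happened — so the
generative phase uses the full intended train, and the analysis pipeline's
linear interpolation of missing taps is genuinely being tested against it.

## Staircase

Δ is titrated by a weighted up-down staircase (1-up/1-down, up-step = 3×
down-step), whose asymptote is the level with p(correct)·down =
(1−p)·up, i.e. 75% correct. The run has two phases: coarse steps (4× the
final sizes) until six reversals, then fine steps (0.005/0.015 log2 units),
returning the mean level over all measurement-phase reversals after two
further reversals of settling. The two-phase design keeps the run-to-run
s.d. of the returned threshold near 0.005 log2 units (about 1.5 accuracy
points), which a single-phase, last-eight-reversals rule does not. The rule
itself is a package choice — any rule with a 75% asymptote would do — and is
recorded in the run configuration. An observer near chance drifts upward
(expected step +(up−down)/2 per trial) and is reported as a staircase
divergence rather than a threshold.

## Estimation

The stationary kernel is a probit regression of choice on the per-position
tone frequencies (8 target + 8 or 9 distractor columns + bias). The link is
probit as the model is written; a logit option exists but is off by default,
and no regularization is applied by default (an optional ridge penalty on
the gain coefficients is available for small samples and recorded in the
estimate). Fitting is plain maximum likelihood (Newton); perfect separation
is detected and returned as a flagged estimate with a diagnostic rather
than raised or silently diverged. Pooled gains are arithmetic means over
positions; their standard errors come from the delta method on the
coefficient covariance.

The sensorimotor simultaneity index (SSI) of a tone is its phase in the
cycle spanned by the two flanking taps, φ = 0 at a tap. Before assignment,
(i) one constant per-participant offset — the mean tap-to-nearest-beat
delay — is subtracted from all tap times, making φ = 0 a normalized
reference, and (ii) missing taps are filled by linear interpolation between
the flanking recorded taps (midpoint for an isolated gap; edge gaps are
extrapolated at the beat period and flagged). Because the generative gain
peaks at the *actual* tap while delay correction shifts taps by the mean
asynchrony, the estimand of the fitted preferred phase is
pref + 2π·offset/667 in the corrected frame; recovery tests compare against
that value.

The modulated kernel augments the design with cos(SSI_k)·f_k (and
optionally sin(SSI_k)·f_k) columns, one shared coefficient per role. The
preferred phase is atan2(w_sin, w_cos) of the summed role vectors; the
modulation strength is the cos coefficient (signed) or the cos/sin
amplitude (non-negative, hence upward-biased near zero — null checks use
the cos-only form). "Variability explained" by the SSI is reported as the
likelihood-ratio deviance of the nested fits together with the McFadden
pseudo-R² difference; the metric is a package choice, not a claim about any
particular published figure.

The octile profile reads "64 overlapping octiles" as 64 sliding quantile
windows, each spanning 12.5% of the per-role distribution of the circular
distance of SSI from 0 (so "first octile" = most synchronous eighth
regardless of lead/lag sign), with lower edges evenly stepped so the first
window is exactly the first octile and the last exactly the last. Each
window's probit regression keeps the out-of-window frequency sums per role
as nuisance regressors so in-window gains are not confounded by the rest of
the sequence; windows short of 50 tones per role are widened symmetrically
and logged.

## Group statistics

Analyses are two-stage: per-participant fits first, group tests on the
per-participant estimates second. Provided: paired/one-sample/two-sample t,
Pearson correlation, a 2×2 repeated-measures ANOVA computed exactly from
within-subject contrasts (each effect F(1, n−1) = t² of its contrast; no
sphericity correction is needed at df = 1), a Watson–Williams F test for
equal mean directions (with the von Mises concentration correction
1 + 3/(8κ̂); a mean resultant length below 0.45 sets a validity warning),
and an AIC-based Bayes factor comparing a zero-mean to a free-mean Gaussian
account of the per-participant effects: BF = exp((AIC₀ − AIC₁)/2) =
e⁻¹·(σ̂₀²/σ̂₁²)^{n/2}, with BF > 3 / < 1/3 read as substantial evidence for
the effect / the null. A limitation to note: under this plain-AIC form
σ̂₀² ≥ σ̂₁² always, so BF ≥ e⁻¹ ≈ 0.368 and the < 1/3 region is
unreachable; published values below e⁻¹ imply a small-sample (AICc-style)
correction, which this package does not apply.

## Calibration and problem sizes

All simulations are seeded and bitwise reproducible. Sizes used by the test
suite and acceptance script, chosen as the smallest that make each estimand
well identified:

* design constants and jitter bounds: 1,000–10,000 generated trials;
* staircase calibration: 400 staircase trials, 2,000 evaluation trials;
* kernel/modulation recovery: 4,000 trials per condition;
* type-I calibration: 300 null observers (modulation off, equal condition
  gains), each analysed by a per-observer Wald test of the
  motor-minus-listen pooled target gain at 400 trials per condition;
  measured rejection ≈ 4% at α = .05. Two desk-scale caveats, both
  measured: at 210 trials per condition the Wald test itself over-rejects
  (~7.5%, ML small-sample bias), and a group-level paired t shrunk to
  6 observers per group under-rejects (~3%, heavy-tailed per-observer
  estimates); 400 trials per condition is the scale at which the
  asymptotic per-observer test is accurate.

Phase-resolved checks (octile profile, preferred-phase recovery, the
motor-vs-beat source comparison) use a high-variability tapper
(`motor_sd_ms` = 90, `mod_depth_m` = 0.8): with the default tight tapper,
tone–tap phases cluster at 0/π, the sine regressors are barely identified
and the beat-locked control cycle is nearly collinear with the tap cycle,
so those quantities are only weakly testable — a genuine property of the
design, not of the implementation. The source comparison is asserted as
model fit (the tap-referenced model achieves higher likelihood on identical
trials) rather than as a comparison of raw interaction coefficients, because
regressing on the lower-variance beat-locked proxy can *inflate* its
coefficient even when the generative gain is tap-locked.

## What the synthetic data do and do not show

The generator reproduces the task's trial structure, timing statistics,
tap-train statistics and a choice model that is the exact generative dual of
the estimation model. Passing tests therefore demonstrate correctness and
calibration of the estimation pipeline under its own assumptions
(conjugate recovery), not that the model describes human listeners: real
tapping has drift and error correction rather than i.i.d. timing noise,
real gain dynamics need not be cosine-shaped, lapses and learning are not
modelled, and session structure (blocks, feedback) is ignored. Group-level
human effect sizes are deliberately out of scope; structural mirrors
(orderings and signs on synthetic observers) stand in for them.
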