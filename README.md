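# beatgain

Reverse-correlation analysis of beat-locked sensory gain in rhythmic
auditory attention tasks, with a fully synthetic observer for end-to-end
testing.

## The problem

In temporal-attending paradigms a listener categorizes a rhythmic tone
sequence — four reference tones at f0 = 440 Hz establish a 1.5 Hz beat
(ISI 667 ms), then eight *targets* (on-beat) alternate with eight or nine
*distractors* (anti-phase) — as higher- or lower-pitched on average than
f0. Only targets are informative: their mean log-frequency is offset by a
titrated ±Δ, while distractors average f0. In a *motor-tracking* condition
the listener also taps the beat with a finger. The scientific questions:
how much weight (sensory *gain*) does each tone get in the decision, does
overt motor tracking raise target gain and suppress distractor gain, and
does gain fluctuate within the cycle defined by the listener's own taps?

`beatgain` is aimed at psychophysicists who want to analyse such trial
tables (tones, taps, choices) or to prototype the analysis on synthetic
observers with known ground truth.

## The model

Choices follow a probit observer,

    P(high) = Φ( Σₖ g_tar_k · f_tar_k + Σₖ g_dis_k · f_dis_k + b ),

with tone frequencies f in base-2 log distance from f0, per-position gains
g and response bias b estimated by maximum likelihood across trials
(psychophysical reverse correlation). The sensorimotor simultaneity index
SSI_k is a tone's phase in the cycle spanned by the two flanking taps
(φ = 0 at a tap, after constant-delay correction and linear interpolation
of missing taps). Phase-resolved gain is estimated both nonparametrically
(64 overlapping octile windows over the simultaneity distribution) and
parametrically, by adding interaction regressors cos(SSI_k)·f_k and
sin(SSI_k)·f_k per role; the preferred phase is atan2(w_sin, w_cos).
Group-level tools include t-tests, a 2×2 repeated-measures ANOVA, a
Watson–Williams test for preferred phases, and an AIC-based Bayes factor
e⁻¹·(σ̂₀²/σ̂₁²)^{n/2} for per-participant effects.

The synthetic observer is the generative dual of the estimator: effective
per-tone gain g_role·(1 + m·cos(φ − φ_pref)) locked to its own taps (motor
condition, when taps align with the attended stream) or to a covert
beat-locked cycle (listen condition), plus a weighted up-down staircase
that titrates Δ to 75% correct. See `docs/methods.md` for assumptions,
parameters and limitations.

## Worked example

```python
import beatgain as bg

obs = bg.ObserverParams()          # default synthetic listener
sc = bg.run_staircase(obs, rng_seed=0)
print(f"staircase threshold: delta = {sc.delta:.4f} log2 units")

design = bg.ExperimentDesign(experiment="exp1", delta=sc.delta)
ds = bg.simulate_dataset(obs, design, n_trials_per_condition=1000, rng_seed=1)

listen, motor = ds.subset("listen"), ds.subset("motor")
fit_l = bg.ChoiceKernelModel.from_tables(listen.tones_table(),
                                         listen.choices_table()).fit()
fit_m = bg.ChoiceKernelModel.from_tables(motor.tones_table(),
                                         motor.choices_table()).fit()
print(f"listen : pooled target gain {fit_l.g_target_pooled:.3f}, "
      f"distractor {fit_l.g_distractor_pooled:.3f}")
print(f"motor  : pooled target gain {fit_m.g_target_pooled:.3f}, "
      f"distractor {fit_m.g_distractor_pooled:.3f}")

bmap = {t.trial_id: t.beat_times_ms for t in motor.trials}
traces, offset = bg.correct_delay(list(motor.traces.values()), bmap)
complete = {tr.trial_id: bg.interpolate_missing(tr, bmap[tr.trial_id])
            for tr in traces}
phases = bg.assign_phases(motor.trials, complete, "motor")
est = bg.fit_modulated_probit(motor.tones_table(), motor.choices_table(),
                              phases)
print(est.summary())
```

prints

```
staircase threshold: delta = 0.0706 log2 units
listen : pooled target gain 1.244, distractor 0.281
motor  : pooled target gain 1.337, distractor 0.269
Phase-modulated kernel (SSI x frequency interactions)
  n trials: 1000   loglik base/mod: -525.976 / -521.073
  targets:     w_cos = +0.8388, w_sin = -0.2196
  distractors: w_cos = +0.2459, w_sin = +0.1464
  modulation strength: 0.5766   preferred phase: 6.216 rad
```

Reading the output: the staircase put this observer's 75%-correct offset
near 0.07 log2 units. Target gains are ~4–5× distractor gains in both
conditions (temporal selection), and motor tracking raises the target gain
while slightly lowering the distractor gain. The positive cos coefficients
say gain is highest for tones near a tap; the preferred phase of 6.22 rad
(≈ −0.07 rad) sits just before the corrected tap time, reflecting the
observer's 30 ms tap lead, and the modulated fit improves the
log-likelihood of the choices over the stationary kernel.

The same chain is scriptable: `beatgain simulate | fit | phase | report`
(see `beatgain --help`).

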