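"""Synthetic rhythmic-gain observers: taps, choices, staircase, datasets.

The generative observer implements the hypothesis that motor tracking drives
cyclic fluctuations of sensory gain.  Each target/distractor tone receives an
effective gain

    g_k = g_role * (1 + m_eff * cos(phi_k - pref_phase))

where ``phi_k`` is the tone's phase in the modulating cycle and the decision
is probit: P(high) = Phi( sum_k g_k * f_k + b ), choice ~ Bernoulli.

The modulating cycle depends on the condition:

* motor condition, attention and taps aligned (targets on-beat, experiments
  1 and 2): ``phi_k`` is the tone's phase in the observer's own tap train and
  ``m_eff = mod_depth_m`` — the overt, movement-locked modulation;
* listen condition: a covert oscillation locked to the theoretical beat and
  peaked on the (nominal) target stream, with its own smaller depth
  ``listen_mod_depth``;
* motor condition with taps in phase opposition to the attended stream
  (experiment 3): the covert cycle stays on the targets and the tap-locked
  modulation does not engage (synergy requires alignment), so the effective
  modulation is the covert one.  This builds the synergistic-enhancement
  hypothesis into the generator.

Tapping follows the reference beat, never the jittered tones: one intended
tap per beat from the second reference beat to the end of the sequence, with
a constant lag (negative mean asynchrony) plus Gaussian timing noise, and a
small probability of a missing (unrecorded) tap.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special

from .exceptions import StaircaseError
from .phase import phase_in_tap_cycle
from .sequences import (CONDITIONS, ISI_MS, ROLE_DISTRACTOR, ROLE_TARGET,
                        TrialSpec, generate_trial, nominal_target_phase,
                        _as_rng)

__all__ = [
    "ObserverParams", "MotorTrace", "ChoiceRecord", "ExperimentDesign",
    "SimulatedDataset", "simulate_taps", "simulate_choice", "run_staircase",
    "simulate_dataset", "StaircaseResult",
]

TAP_TABLE_COLUMNS = ["trial_id", "tap_index", "tap_time_ms", "interpolated"]
CHOICE_TABLE_COLUMNS = ["trial_id", "choice", "correct"]


@dataclass(frozen=True)
class ObserverParams:
    """Generative observer parameters.

    Defaults describe a reasonably attentive adult in this task: target
    evidence weighted ~3x distractor leakage, no response bias, a 50%
    movement-locked gain swing with maximal gain at the tap, a weaker covert
    swing in the listen condition, ~40 ms tap timing jitter with the usual
    slight anticipation of the beat, and <2% missing taps.
    """

    g_target: float = 1.0
    g_distractor: float = 0.3
    bias_b: float = 0.0
    mod_depth_m: float = 0.5
    pref_phase_rad: float = 0.0
    listen_mod_depth: float = 0.25
    motor_sd_ms: float = 40.0
    motor_lag_ms: float = -30.0
    miss_prob: float = 0.02

    def __post_init__(self):
        if not (np.isfinite(self.g_target) and np.isfinite(self.g_distractor)):
            raise ValueError("gains must be finite")
        if not 0.0 <= self.mod_depth_m <= 1.0:
            raise ValueError("mod_depth_m must lie in [0, 1]")
        if not 0.0 <= self.listen_mod_depth <= 1.0:
            raise ValueError("listen_mod_depth must lie in [0, 1]")
        if not 0.0 <= self.miss_prob < 1.0:
            raise ValueError("miss_prob must lie in [0, 1)")
        if self.motor_sd_ms < 0:
            raise ValueError("motor_sd_ms must be non-negative")


@dataclass
class MotorTrace:
    """Recorded taps of one trial.

    ``intended_times_ms`` keeps the full pre-miss tap train as simulation
    ground truth (the movement happened even when the press went
    unrecorded); it is not part of the on-disk tables.
    """

    trial_id: int
    tap_times_ms: np.ndarray
    interpolated: np.ndarray
    delay_offset_ms: float = 0.0
    intended_times_ms: np.ndarray | None = None


@dataclass(frozen=True)
class ChoiceRecord:
    trial_id: int
    choice: str  # "high" | "low"
    p_high_true: float
    correct: bool


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of one simulated session.

    ``delta`` is the magnitude of the titrated target-mean offset (its sign
    is balanced 50/50 across trials); ``jitter_conditions`` defaults to the
    experiment's own regime (the single jittered regime for exp1/exp3, all
    four rhythmicity cells for exp2).
    """

    experiment: str = "exp1"
    delta: float = 0.1
    sigma_f: float = 0.2
    jitter_conditions: tuple[str, ...] | None = None

    def resolved_jitter_conditions(self) -> tuple[str, ...]:
        if self.jitter_conditions is not None:
            return tuple(self.jitter_conditions)
        return ("TD", "Td", "tD", "td") if self.experiment == "exp2" else ("td",)


def simulate_taps(trial: TrialSpec, obs: ObserverParams, rng_seed=None) -> MotorTrace:
    """Simulate the tap train of one motor-condition trial.

    One intended tap per beat from the second reference beat to the end of
    the sequence; each tap is the beat time plus the constant lag plus
    Gaussian noise, and is independently unrecorded with ``miss_prob``.
    Taps are anchored to the beat, never to the jittered tone onsets.
    """
    if trial.condition != "motor":
        raise ValueError(f"trial {trial.trial_id} is a {trial.condition!r} "
                         "trial; taps exist only in the motor condition")
    rng = _as_rng(rng_seed)
    beats = trial.beat_times_ms[1:]
    taps = beats + obs.motor_lag_ms + rng.normal(0.0, obs.motor_sd_ms, beats.size)
    taps = np.sort(taps)  # timing noise never swaps taps at a 667 ms period
    recorded = rng.random(beats.size) >= obs.miss_prob
    return MotorTrace(trial_id=trial.trial_id,
                      tap_times_ms=taps[recorded],
                      interpolated=np.zeros(int(recorded.sum()), dtype=bool),
                      intended_times_ms=taps)


def _modulation_cycle(trial: TrialSpec, trace: MotorTrace | None,
                      obs: ObserverParams, onsets: np.ndarray
                      ) -> tuple[np.ndarray, float]:
    """Per-tone phase and effective modulation depth for one trial."""
    attn_phase = nominal_target_phase(trial.experiment)
    synergy = attn_phase == 0.0  # taps and attended stream aligned
    if trial.condition == "motor" and synergy:
        train = (trace.intended_times_ms if trace.intended_times_ms is not None
                 else trace.tap_times_ms)
        phases, _ = phase_in_tap_cycle(onsets, train)
        return phases, obs.mod_depth_m
    # covert beat-locked cycle, peaked on the nominal target stream
    phases = np.mod(2.0 * np.pi * onsets / ISI_MS - attn_phase, 2.0 * np.pi)
    return phases, obs.listen_mod_depth


def choice_probability(trial: TrialSpec, trace: MotorTrace | None,
                       obs: ObserverParams) -> float:
    """Ground-truth P(high) of the generative observer for one trial."""
    if trial.condition == "motor" and trace is None:
        raise ValueError(f"trial {trial.trial_id}: motor-condition choice "
                         "needs the tap trace")
    if trial.condition == "listen" and trace is not None:
        raise ValueError(f"trial {trial.trial_id}: listen-condition choice "
                         "must not receive a tap trace")
    tones = [t for t in trial.tones if t.role in (ROLE_TARGET, ROLE_DISTRACTOR)]
    onsets = np.array([t.onset_ms for t in tones])
    f = np.array([t.f_log2 for t in tones])
    base = np.array([obs.g_target if t.role == ROLE_TARGET else obs.g_distractor
                     for t in tones])
    phases, m_eff = _modulation_cycle(trial, trace, obs, onsets)
    gains = base * (1.0 + m_eff * np.cos(phases - obs.pref_phase_rad))
    dv = float(gains @ f + obs.bias_b)
    return float(scipy.special.ndtr(dv))


def simulate_choice(trial: TrialSpec, trace: MotorTrace | None,
                    obs: ObserverParams, rng_seed=None) -> ChoiceRecord:
    """Draw one choice from the rhythmic-gain observer."""
    rng = _as_rng(rng_seed)
    p = choice_probability(trial, trace, obs)
    high = bool(rng.random() < p)
    correct = high == (trial.f_tar_mean_log2 > 0)
    return ChoiceRecord(trial_id=trial.trial_id,
                        choice="high" if high else "low",
                        p_high_true=p, correct=correct)


# ---------------------------------------------------------------------------
# staircase
# ---------------------------------------------------------------------------

@dataclass
class StaircaseResult:
    delta: float
    n_reversals: int
    levels: np.ndarray  # per-trial delta levels
    n_trials: int


def run_staircase(obs: ObserverParams, design: ExperimentDesign | None = None,
                  rng_seed=None, n_trials: int = 400, delta0: float = 0.4,
                  step_down: float = 0.005, step_up: float = 0.015,
                  coarse_factor: float = 4.0, switch_reversals: int = 6,
                  settle_reversals: int = 2, min_reversals_avg: int = 8,
                  delta_min: float = 0.005,
                  delta_max: float = 1.2) -> StaircaseResult:
    """Weighted up-down staircase titrating the target-mean offset Delta.

    1-up/1-down with asymmetric steps (up = 3x down) on listen-condition
    trials: the asymptote is the level at which p(correct) * step_down =
    (1 - p) * step_up, i.e. 75% correct.  The run has two phases — coarse
    steps (``coarse_factor`` x the final ones) until ``switch_reversals``
    reversals have occurred, then fine steps for the measurement phase —
    and returns the mean level over all measurement-phase reversals (after
    ``settle_reversals`` further reversals of settling), which keeps the
    run-to-run spread of the returned threshold small.  In experiment 2 the
    staircase runs in the fully rhythmic condition.

    Raises
    ------
    StaircaseError
        (with the level trace attached) if Delta escapes past ``delta_max``
        — e.g. for an observer at chance, whose levels drift upward without
        bound — or if too few reversals occur within the trial budget.
    """
    if design is None:
        design = ExperimentDesign()
    rng = _as_rng(rng_seed)
    jc = "TD" if design.experiment == "exp2" else "td"
    delta = float(delta0)
    sd, su = step_down * coarse_factor, step_up * coarse_factor
    levels, measured = [], []
    prev_dir = 0
    n_reversals = 0
    for i in range(n_trials):
        levels.append(delta)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        trial = generate_trial(design.experiment, "listen", jc,
                               sign * delta, design.sigma_f, rng, trial_id=i)
        rec = simulate_choice(trial, None, obs, rng)
        step = -sd if rec.correct else su
        direction = int(np.sign(step))
        if prev_dir and direction != prev_dir:
            n_reversals += 1
            if n_reversals == switch_reversals:
                sd, su = step_down, step_up
            if n_reversals > switch_reversals + settle_reversals:
                measured.append(delta)
        prev_dir = direction
        delta = float(np.clip(delta + step, delta_min, None))
        if delta > delta_max:
            raise StaircaseError(
                f"staircase diverged: Delta exceeded {delta_max} after "
                f"{i + 1} trials (observer near chance?)",
                trace=np.asarray(levels))
    if len(measured) < min_reversals_avg:
        raise StaircaseError(
            f"only {len(measured)} measurement-phase reversals in "
            f"{n_trials} trials (need {min_reversals_avg})",
            trace=np.asarray(levels))
    return StaircaseResult(
        delta=float(np.mean(measured)), n_reversals=n_reversals,
        levels=np.asarray(levels), n_trials=n_trials)


# ---------------------------------------------------------------------------
# full datasets
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """All tables of one simulated session (one observer)."""

    trials: list[TrialSpec]
    traces: dict[int, MotorTrace]
    choices: list[ChoiceRecord]

    def tones_table(self) -> pd.DataFrame:
        from .sequences import trials_to_table
        return trials_to_table(self.trials)

    def beats_table(self) -> pd.DataFrame:
        from .sequences import beats_to_table
        return beats_to_table(self.trials)

    def taps_table(self) -> pd.DataFrame:
        rows = [(tid, i, tr.tap_times_ms[i], bool(tr.interpolated[i]))
                for tid, tr in sorted(self.traces.items())
                for i in range(len(tr.tap_times_ms))]
        return pd.DataFrame(rows, columns=TAP_TABLE_COLUMNS)

    def choices_table(self) -> pd.DataFrame:
        rows = [(c.trial_id, c.choice, c.correct) for c in self.choices]
        return pd.DataFrame(rows, columns=CHOICE_TABLE_COLUMNS)

    def subset(self, condition: str | None = None,
               jitter_condition: str | None = None) -> "SimulatedDataset":
        """Restrict to one condition (and optionally one jitter cell)."""
        keep = [t for t in self.trials
                if (condition is None or t.condition == condition)
                and (jitter_condition is None
                     or t.jitter_condition == jitter_condition)]
        ids = {t.trial_id for t in keep}
        return SimulatedDataset(
            trials=keep,
            traces={k: v for k, v in self.traces.items() if k in ids},
            choices=[c for c in self.choices if c.trial_id in ids])


def simulate_dataset(obs: ObserverParams, design: ExperimentDesign | None = None,
                     n_trials_per_condition: int = 210,
                     rng_seed=None) -> SimulatedDataset:
    """Simulate a complete session: trials, taps and choices.

    ``n_trials_per_condition`` trials are generated for every combination of
    condition (listen, motor) and jitter cell; the sign of the target-mean
    offset is balanced 50/50 within each cell.  Deterministic under a fixed
    seed.
    """
    if design is None:
        design = ExperimentDesign()
    rng = _as_rng(rng_seed)
    trials: list[TrialSpec] = []
    traces: dict[int, MotorTrace] = {}
    choices: list[ChoiceRecord] = []
    tid = 0
    for condition in CONDITIONS:
        for jc in design.resolved_jitter_conditions():
            signs = np.where(np.arange(n_trials_per_condition)
                             < n_trials_per_condition // 2, -1.0, 1.0)
            rng.shuffle(signs)
            for s in signs:
                trial = generate_trial(design.experiment, condition, jc,
                                       s * design.delta, design.sigma_f,
                                       rng, trial_id=tid)
                trace = None
                if condition == "motor":
                    trace = simulate_taps(trial, obs, rng)
                    traces[tid] = trace
                choices.append(simulate_choice(trial, trace, obs, rng))
                trials.append(trial)
                tid += 1
    return SimulatedDataset(trials=trials, traces=traces, choices=choices)
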