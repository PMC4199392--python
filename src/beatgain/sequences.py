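"""Tone-sequence construction for the rhythmic pitch-categorization task.

Each trial is a sequence of pure tones at a 1.5 Hz beat (inter-stimulus
interval 667 ms): four reference tones at the reference frequency f0 = 440 Hz
establish the beat, followed by an alternation of eight target tones (on-beat
in experiments 1 and 2, anti-phase in experiment 3) and eight or nine
distractor tones at the opposite beat phase.  Target and distractor
frequencies are drawn from a normal law with s.d. 0.2 base-2 log units;
target draws are recentred so their per-trial sample mean equals the
titrated offset ``f_tar_mean_log2`` exactly (the offset *is* the task
statistic), while distractors are drawn with population mean 0, i.e. they
are uninformative by design but their per-trial sample mean fluctuates.
Pinning the distractor mean exactly to 0 on every trial would make a
uniform distractor gain behaviorally inert and the pooled distractor gain
unidentifiable in the choice regression, so it is deliberately not done.

Tone onsets are jittered around the nominal half-beat grid: truncated
Gaussian jitter (s.d. 67 ms, hard cap 141 ms, which guarantees targets and
distractors never swap order) in experiments 1 and 3, uniform +/-67 ms jitter
in experiment 2, where target and distractor streams can be jittered
independently (conditions TD / Td / tD / td, uppercase = rhythmic).

All times are milliseconds from the first reference onset.  Frequencies are
stored only as ``f_log2``, the base-2 log distance from f0 (Hz are
recoverable as ``440 * 2**f_log2``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reference frequency in Hz (f_log2 = 0).
F0_HZ = 440.0
#: Beat period (inter-stimulus interval) in ms.
ISI_MS = 667.0
#: Duration of every pure tone in ms.
TONE_DURATION_MS = 100.0
#: Standard deviation of tone frequencies in base-2 log units.
SIGMA_F_DEFAULT = 0.2
#: S.d. of the approximately-Gaussian jitter (experiments 1 and 3), ms.
JITTER_SD_MS = 67.0
#: Hard cap on the absolute jitter, ms (prevents target/distractor overlap).
JITTER_CAP_MS = 141.0
#: Half-width of the uniform jitter (experiment 2), ms.
JITTER_UNIFORM_MS = 67.0
#: Number of reference tones opening every sequence.
N_REFERENCES = 4
#: Number of target tones in every experiment.
N_TARGETS = 8

EXPERIMENTS = ("exp1", "exp2", "exp3")
CONDITIONS = ("listen", "motor")
JITTER_CONDITIONS_EXP2 = ("TD", "Td", "tD", "td")

#: Number of beats spanned by a sequence (beat 0 = first reference; the last
#: tone falls at beat 11.5, so beats 0..12 bracket every tone).
N_BEATS = 13

ROLE_REFERENCE = "reference"
ROLE_TARGET = "target"
ROLE_DISTRACTOR = "distractor"

TONE_TABLE_COLUMNS = [
    "trial_id", "experiment", "condition", "jitter_condition", "role",
    "index_in_role", "nominal_onset_ms", "jitter_ms", "onset_ms", "f_log2",
]


@dataclass(frozen=True)
class ToneEvent:
    """A single tone within a trial.

    ``f_log2_raw`` is the normal draw before the per-trial recentring that
    pins the sample means; it is simulation bookkeeping, not part of the
    on-disk table.
    """

    role: str
    index_in_role: int
    nominal_onset_ms: float
    jitter_ms: float
    f_log2: float
    f_log2_raw: float = 0.0
    duration_ms: float = TONE_DURATION_MS

    @property
    def onset_ms(self) -> float:
        return self.nominal_onset_ms + self.jitter_ms


@dataclass
class TrialSpec:
    """One trial: its design labels, ordered tones and reference beat."""

    trial_id: int
    experiment: str
    condition: str
    jitter_condition: str
    tones: list[ToneEvent]
    beat_times_ms: np.ndarray
    f_tar_mean_log2: float

    def tones_of(self, role: str) -> list[ToneEvent]:
        return [t for t in self.tones if t.role == role]

    @property
    def n_targets(self) -> int:
        return sum(1 for t in self.tones if t.role == ROLE_TARGET)

    @property
    def n_distractors(self) -> int:
        return sum(1 for t in self.tones if t.role == ROLE_DISTRACTOR)

    def to_frame(self) -> pd.DataFrame:
        """One row per tone, in onset order, with the standard columns."""
        rows = [
            (self.trial_id, self.experiment, self.condition,
             self.jitter_condition, t.role, t.index_in_role,
             t.nominal_onset_ms, t.jitter_ms, t.onset_ms, t.f_log2)
            for t in self.tones
        ]
        return pd.DataFrame(rows, columns=TONE_TABLE_COLUMNS)


def make_reference_beat(period_ms: float, n_beats: int, t0: float = 0.0) -> np.ndarray:
    """Arithmetic progression of beat times: t0, t0 + period, ...

    Parameters
    ----------
    period_ms : beat period in ms; must be positive.
    n_beats : number of beats; must be >= 1.
    t0 : time of the first beat.
    """
    if period_ms <= 0:
        raise ValueError(f"beat period must be positive, got {period_ms}")
    if n_beats < 1:
        raise ValueError(f"need at least one beat, got {n_beats}")
    return t0 + period_ms * np.arange(n_beats, dtype=float)


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _truncated_gaussian_jitter(n: int, rng: np.random.Generator) -> np.ndarray:
    """Gaussian(0, 67 ms) jitter redrawn until strictly inside +/-141 ms."""
    out = rng.normal(0.0, JITTER_SD_MS, size=n)
    bad = np.abs(out) >= JITTER_CAP_MS
    while bad.any():
        out[bad] = rng.normal(0.0, JITTER_SD_MS, size=int(bad.sum()))
        bad = np.abs(out) >= JITTER_CAP_MS
    return out


def _recentred_normal(n: int, mean: float, sigma: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Normal draws with the *sample* mean pinned exactly to ``mean``."""
    raw = rng.normal(mean, sigma, size=n)
    return raw - raw.mean() + mean, raw


def _role_layout(experiment: str) -> tuple[np.ndarray, np.ndarray]:
    """Nominal onsets (in beat units) of targets and distractors."""
    on_beat = np.arange(N_REFERENCES, N_REFERENCES + N_TARGETS, dtype=float)
    anti = on_beat + 0.5
    if experiment == "exp1":
        return on_beat, anti
    if experiment == "exp2":
        # extra distractor between the last reference and the first target,
        # so every target is flanked by two distractors
        return on_beat, np.concatenate(([N_REFERENCES - 0.5], anti))
    if experiment == "exp3":
        # roles swapped: targets anti-phase, distractors on-beat
        return anti, on_beat
    raise ValueError(f"unknown experiment {experiment!r}")


def generate_trial(experiment: str, condition: str,
                   jitter_condition: str | None = None,
                   f_tar_mean_log2: float = 0.1,
                   sigma_f: float = SIGMA_F_DEFAULT,
                   rng_seed=None, trial_id: int = 0) -> TrialSpec:
    """Draw one complete trial.

    Parameters
    ----------
    experiment : "exp1", "exp2" or "exp3".
    condition : "listen" or "motor".
    jitter_condition : for exp2 one of "TD", "Td", "tD", "td"
        (uppercase = rhythmic stream, lowercase = jittered); exp1/exp3 have a
        single jittered regime, labelled "td", which is the default.
    f_tar_mean_log2 : the titrated target-mean offset Delta, signed; the sign
        is the trial's correct answer.
    sigma_f : s.d. of the tone-frequency draws in base-2 log units.
    rng_seed : int seed or ``numpy.random.Generator``; a fixed seed gives a
        bitwise-identical trial.
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if sigma_f < 0:
        raise ValueError("sigma_f must be non-negative")
    if abs(f_tar_mean_log2) > 2.0:
        raise ValueError(
            f"|f_tar_mean_log2| = {abs(f_tar_mean_log2)} exceeds 2 octaves; "
            "such frequencies are outside the task's physical range")
    if experiment == "exp2":
        if jitter_condition is None:
            jitter_condition = "td"
        if jitter_condition not in JITTER_CONDITIONS_EXP2:
            raise ValueError(f"exp2 jitter condition must be one of "
                             f"{JITTER_CONDITIONS_EXP2}, got {jitter_condition!r}")
    else:
        if jitter_condition is None:
            jitter_condition = "td"
        if jitter_condition != "td":
            raise ValueError(f"{experiment} has a single jittered regime 'td', "
                             f"got {jitter_condition!r}")
    rng = _as_rng(rng_seed)

    tar_beats, dis_beats = _role_layout(experiment)
    n_dis = len(dis_beats)

    if experiment == "exp2":
        tar_jit = (rng.uniform(-JITTER_UNIFORM_MS, JITTER_UNIFORM_MS, N_TARGETS)
                   if jitter_condition[0] == "t" else np.zeros(N_TARGETS))
        dis_jit = (rng.uniform(-JITTER_UNIFORM_MS, JITTER_UNIFORM_MS, n_dis)
                   if jitter_condition[1] == "d" else np.zeros(n_dis))
    else:
        tar_jit = _truncated_gaussian_jitter(N_TARGETS, rng)
        dis_jit = _truncated_gaussian_jitter(n_dis, rng)

    tar_f, tar_raw = _recentred_normal(N_TARGETS, f_tar_mean_log2, sigma_f, rng)
    dis_raw = rng.normal(0.0, sigma_f, size=n_dis)
    dis_f = dis_raw  # population mean 0; not recentred (see module docstring)

    tones: list[ToneEvent] = []
    for k in range(N_REFERENCES):
        tones.append(ToneEvent(ROLE_REFERENCE, k + 1, k * ISI_MS, 0.0, 0.0, 0.0))
    for k in range(N_TARGETS):
        tones.append(ToneEvent(ROLE_TARGET, k + 1, tar_beats[k] * ISI_MS,
                               float(tar_jit[k]), float(tar_f[k]), float(tar_raw[k])))
    for k in range(n_dis):
        tones.append(ToneEvent(ROLE_DISTRACTOR, k + 1, dis_beats[k] * ISI_MS,
                               float(dis_jit[k]), float(dis_f[k]), float(dis_raw[k])))
    tones.sort(key=lambda t: t.onset_ms)

    return TrialSpec(trial_id=trial_id, experiment=experiment,
                     condition=condition, jitter_condition=jitter_condition,
                     tones=tones,
                     beat_times_ms=make_reference_beat(ISI_MS, N_BEATS),
                     f_tar_mean_log2=float(f_tar_mean_log2))


def nominal_phase(trial: TrialSpec) -> np.ndarray:
    """Phase of each tone's *nominal* onset in the reference-beat cycle.

    Returns one value per tone (in the order of ``trial.tones``) in
    [0, 2*pi): 0 for on-beat roles, pi for anti-phase roles.
    """
    onsets = np.array([t.nominal_onset_ms for t in trial.tones])
    return 2.0 * np.pi * np.mod(onsets / ISI_MS, 1.0)


def nominal_target_phase(experiment: str) -> float:
    """Beat phase of nominal target onsets: 0 (exp1/exp2) or pi (exp3)."""
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    return np.pi if experiment == "exp3" else 0.0


def trials_to_table(trials: list[TrialSpec]) -> pd.DataFrame:
    """Concatenate trials into the standard one-row-per-tone table."""
    if not trials:
        return pd.DataFrame(columns=TONE_TABLE_COLUMNS)
    rows = [
        (tr.trial_id, tr.experiment, tr.condition, tr.jitter_condition,
         t.role, t.index_in_role, t.nominal_onset_ms, t.jitter_ms,
         t.onset_ms, t.f_log2)
        for tr in trials for t in tr.tones
    ]
    return pd.DataFrame(rows, columns=TONE_TABLE_COLUMNS)


def beats_to_table(trials: list[TrialSpec]) -> pd.DataFrame:
    """Companion table of reference-beat times, one row per beat."""
    rows = [(t.trial_id, i, bt)
            for t in trials for i, bt in enumerate(t.beat_times_ms)]
    return pd.DataFrame(rows, columns=["trial_id", "beat_index", "beat_time_ms"])
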