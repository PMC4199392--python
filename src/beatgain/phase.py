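"""Sensorimotor simultaneity: tap-train preprocessing and phase-resolved gain.

A tone's sensorimotor simultaneity index (SSI) is its phase within the cycle
spanned by the two flanking motor acts, with phi = 0 at a tap: for a tone at
time t between taps T_i < t <= T_{i+1},

    SSI = 2*pi * (t - T_i) / (T_{i+1} - T_i).

cos(SSI) therefore runs from +1 (tone simultaneous with a tap) to -1 (tone in
phase opposition to the taps).  A "nonmotor" variant uses the theoretical
reference beats in place of the recorded taps, as a control for influences
not tied to the actual movements.

Before phase assignment, tap trains are (i) shifted by a single constant
per-participant offset that zeroes the mean tap-to-beat delay (so phi = 0 is
a normalized, participant-comparable reference) and (ii) completed by linear
interpolation of occasionally missing taps.

Phase-resolved gain is quantified two ways:

* a sliding-window ("octile") profile: 64 overlapping windows, each covering
  one eighth of the simultaneity distribution, within which per-window target
  and distractor gains are refitted;
* a parametric modulated probit that augments the per-position kernel with
  multiplicative interaction regressors cos(SSI_k) * f_k (and optionally
  sin(SSI_k) * f_k) shared across positions within each role.  The preferred
  phase (gain maximum) is atan2(w_sin, w_cos).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError
from .kernel import (ChoiceKernelModel, ChoiceKernelResults, build_design,
                     _as_choices_table, _as_tones_table)
from .sequences import ISI_MS, ROLE_DISTRACTOR, ROLE_TARGET

__all__ = [
    "phase_in_tap_cycle", "correct_delay", "interpolate_missing",
    "assign_phase", "assign_phases", "octile_profile", "fit_modulated_probit",
    "variability_explained", "PhaseKernelModel", "PhaseKernelResults",
    "ModulationEstimate", "OctileProfile",
]

PHASE_TABLE_COLUMNS = ["trial_id", "role", "index_in_role", "onset_ms",
                       "ssi_rad", "source", "extrapolated"]


def phase_in_tap_cycle(times, taps, period_ms: float = ISI_MS
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Phase of each time point within the tap train, in [0, 2*pi).

    Times outside the tap span are handled by extending the train virtually
    at the beat period; those assignments are flagged.

    Returns (phases, extrapolated_flags).
    """
    times = np.asarray(times, dtype=float)
    taps = np.asarray(taps, dtype=float)
    if taps.size < 2:
        raise InsufficientDataError("need at least two taps to define a cycle")
    if np.any(np.diff(taps) <= 0):
        raise ValueError("tap times must be strictly increasing")
    lo, hi = taps[0], taps[-1]
    extrapolated = (times < lo) | (times > hi)
    n_before = max(0, int(np.ceil((lo - times.min()) / period_ms)) + 1) if times.size else 0
    n_after = max(0, int(np.ceil((times.max() - hi) / period_ms)) + 1) if times.size else 0
    ext = np.concatenate([lo - period_ms * np.arange(n_before, 0, -1),
                          taps,
                          hi + period_ms * np.arange(1, n_after + 1)])
    idx = np.searchsorted(ext, times, side="left")
    at_tap = (idx < ext.size) & np.isclose(ext[np.minimum(idx, ext.size - 1)], times)
    lowi = np.where(at_tap, idx, idx - 1)
    lowi = np.clip(lowi, 0, ext.size - 2)
    frac = (times - ext[lowi]) / (ext[lowi + 1] - ext[lowi])
    phases = np.mod(2.0 * np.pi * frac, 2.0 * np.pi)
    phases[at_tap] = 0.0
    return phases, extrapolated


def correct_delay(traces, beat_times) -> tuple[list, float]:
    """Remove the participant-constant recording/response lag from taps.

    Each tap is matched to its nearest reference beat; the mean tap-to-beat
    delay, pooled over all supplied trials (one participant), is subtracted
    from every tap time.  Returns (corrected traces, offset in ms).

    Raises
    ------
    InsufficientDataError
        if fewer than 10 taps are available for matching.
    """
    traces = list(traces)
    delays = []
    for tr in traces:
        beats = np.asarray(_beats_for(tr, beat_times), dtype=float)
        taps = np.asarray(tr.tap_times_ms, dtype=float)
        if taps.size == 0:
            continue
        nearest = beats[np.argmin(np.abs(taps[:, None] - beats[None, :]), axis=1)]
        delays.append(taps - nearest)
    n = sum(len(d) for d in delays)
    if n < 10:
        raise InsufficientDataError(
            f"only {n} matched taps; need at least 10 to estimate the delay")
    offset = float(np.mean(np.concatenate(delays)))
    corrected = [
        dataclasses.replace(tr, tap_times_ms=np.asarray(tr.tap_times_ms) - offset,
                            delay_offset_ms=offset)
        for tr in traces
    ]
    return corrected, offset


def _beats_for(trace, beat_times):
    """Beat times for one trace: a mapping by trial_id or a shared array."""
    if isinstance(beat_times, dict):
        return beat_times[trace.trial_id]
    return beat_times


def interpolate_missing(trace, beat_times, period_ms: float = ISI_MS):
    """Fill missing taps by linear interpolation between flanking taps.

    Intended taps occupy one slot per beat from the second beat onward; a
    slot with no recorded tap is filled at the linear interpolant of the
    nearest recorded taps on both sides (the midpoint for an isolated gap).
    Missing leading/trailing taps are extrapolated at the beat period.  All
    inserted taps are flagged.
    """
    beats = np.asarray(_beats_for(trace, beat_times), dtype=float)
    slots = beats[1:]
    taps = np.asarray(trace.tap_times_ms, dtype=float)
    if taps.size == 0:
        raise InsufficientDataError(f"trial {trace.trial_id}: no taps to "
                                    "interpolate from")
    filled = np.full(slots.size, np.nan)
    for t in taps:
        j = int(np.clip(np.round((t - slots[0]) / period_ms), 0, slots.size - 1))
        if np.isnan(filled[j]) or abs(t - slots[j]) < abs(filled[j] - slots[j]):
            filled[j] = t
    missing = np.isnan(filled)
    if not missing.any():
        return dataclasses.replace(
            trace, tap_times_ms=filled,
            interpolated=np.zeros(slots.size, dtype=bool))
    runs = _run_lengths(missing)
    if runs and max(runs) > 1:
        warnings.warn(
            f"trial {trace.trial_id}: {max(runs)} consecutive missing taps; "
            "interpolating across the whole gap", stacklevel=2)
    known = np.flatnonzero(~missing)
    out = filled.copy()
    # interior gaps: linear interpolation over slot index
    out[missing] = np.interp(np.flatnonzero(missing), known, filled[known])
    # edge gaps: extrapolate at the beat period from the nearest real tap
    first, last = known[0], known[-1]
    for j in range(first):
        out[j] = filled[first] - period_ms * (first - j)
    for j in range(last + 1, slots.size):
        out[j] = filled[last] + period_ms * (j - last)
    return dataclasses.replace(trace, tap_times_ms=out, interpolated=missing)


def _run_lengths(mask: np.ndarray) -> list[int]:
    runs, count = [], 0
    for m in mask:
        if m:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def assign_phase(trial, trace_or_beats, source: str) -> pd.DataFrame:
    """SSI of every target and distractor tone of one trial.

    ``source`` is "motor" (phases in the recorded, corrected and interpolated
    tap train) or "nonmotor" (phases in the theoretical reference beat, the
    control analysis).  Returns one row per tone with columns
    (trial_id, role, index_in_role, onset_ms, ssi_rad, source, extrapolated).
    """
    if source not in ("motor", "nonmotor"):
        raise ValueError(f"source must be 'motor' or 'nonmotor', got {source!r}")
    if source == "motor":
        taps = np.asarray(trace_or_beats.tap_times_ms, dtype=float)
    else:
        taps = np.asarray(trace_or_beats, dtype=float)
    tones = [t for t in trial.tones if t.role in (ROLE_TARGET, ROLE_DISTRACTOR)]
    onsets = np.array([t.onset_ms for t in tones])
    phases, extrap = phase_in_tap_cycle(onsets, taps)
    return pd.DataFrame({
        "trial_id": trial.trial_id,
        "role": [t.role for t in tones],
        "index_in_role": [t.index_in_role for t in tones],
        "onset_ms": onsets,
        "ssi_rad": phases,
        "source": source,
        "extrapolated": extrap,
    })


def assign_phases(trials, traces_or_beats, source: str) -> pd.DataFrame:
    """Concatenated per-tone phases over many trials.

    For ``source='motor'``, ``traces_or_beats`` maps trial_id -> trace (or is
    a list aligned with ``trials``); for "nonmotor" it may be omitted per
    trial (each trial's own reference beat is used).
    """
    frames = []
    for i, trial in enumerate(trials):
        if source == "motor":
            if isinstance(traces_or_beats, dict):
                tr = traces_or_beats[trial.trial_id]
            else:
                tr = traces_or_beats[i]
            frames.append(assign_phase(trial, tr, source))
        else:
            frames.append(assign_phase(trial, trial.beat_times_ms, source))
    if not frames:
        return pd.DataFrame(columns=PHASE_TABLE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# modulated probit (kernel + cos/sin interaction regressors)
# ---------------------------------------------------------------------------

def _merged(tones, phases) -> pd.DataFrame:
    tones = _as_tones_table(tones)
    tones = tones[tones["role"].isin((ROLE_TARGET, ROLE_DISTRACTOR))]
    merged = tones.merge(phases[["trial_id", "role", "index_in_role", "ssi_rad"]],
                         on=["trial_id", "role", "index_in_role"], how="left")
    if merged["ssi_rad"].isna().any():
        bad = merged.loc[merged["ssi_rad"].isna(), "trial_id"].unique()
        raise InsufficientDataError(
            f"phases missing for tones of trial(s) {bad[:5].tolist()}")
    return merged


class PhaseKernelModel:
    """Choice kernel augmented with SSI interaction terms.

    Adds, per role, a regressor sum_k cos(SSI_k) * f_k (and with
    ``include_sine`` also sum_k sin(SSI_k) * f_k) to the per-position design,
    so the fitted coefficients measure how sensory gain co-varies with
    tone-tap simultaneity.
    """

    def __init__(self, tones, choices, phases, include_sine: bool = True,
                 link: str = "probit"):
        self.include_sine = bool(include_sine)
        self.link = link
        X, y = build_design(tones, choices)
        merged = _merged(tones, phases)
        merged["cos_f"] = np.cos(merged["ssi_rad"]) * merged["f_log2"]
        merged["sin_f"] = np.sin(merged["ssi_rad"]) * merged["f_log2"]
        for role, tag in ((ROLE_TARGET, "tar"), (ROLE_DISTRACTOR, "dis")):
            sub = merged[merged["role"] == role]
            agg = sub.groupby("trial_id")[["cos_f", "sin_f"]].sum().reindex(X.index)
            X[f"w_cos_{tag}"] = agg["cos_f"].fillna(0.0)
            if self.include_sine:
                X[f"w_sin_{tag}"] = agg["sin_f"].fillna(0.0)
        cols = [c for c in X.columns if c != "bias"] + ["bias"]
        self._X, self._y = X[cols], y
        self._base_cols = [c for c in cols if not c.startswith("w_")]

    def fit(self, tol: float = 1e-8) -> "PhaseKernelResults":
        base = ChoiceKernelModel(self._y, self._X[self._base_cols],
                                 link=self.link).fit(tol=tol)
        full = ChoiceKernelModel(self._y, self._X, link=self.link).fit(tol=tol)
        return PhaseKernelResults(model=self, results=full, base_results=base,
                                  include_sine=self.include_sine)


@dataclass
class PhaseKernelResults:
    """Fitted phase-modulated kernel with the nested base fit alongside."""

    model: PhaseKernelModel
    results: ChoiceKernelResults
    base_results: ChoiceKernelResults
    include_sine: bool

    def _w(self, name: str) -> float:
        return float(self.results.params.get(name, 0.0))

    @property
    def w_cos_target(self) -> float:
        return self._w("w_cos_tar")

    @property
    def w_sin_target(self) -> float:
        return self._w("w_sin_tar")

    @property
    def w_cos_distractor(self) -> float:
        return self._w("w_cos_dis")

    @property
    def w_sin_distractor(self) -> float:
        return self._w("w_sin_dis")

    def role_modulation(self, role: str) -> float:
        """Modulation strength for one role: the cos coefficient, or the
        (non-negative) cos/sin amplitude when the sine term is included."""
        wc = self.w_cos_target if role == "target" else self.w_cos_distractor
        ws = self.w_sin_target if role == "target" else self.w_sin_distractor
        return float(np.hypot(wc, ws)) if self.include_sine else wc

    @property
    def mod_strength(self) -> float:
        """Average modulation strength over targets and distractors."""
        return 0.5 * (self.role_modulation("target")
                      + self.role_modulation("distractor"))

    @property
    def pref_phase_rad(self) -> float:
        """Phase of maximal gain, from the summed role vectors, in [0, 2*pi)."""
        wc = self.w_cos_target + self.w_cos_distractor
        ws = self.w_sin_target + self.w_sin_distractor
        return float(np.mod(np.arctan2(ws, wc), 2.0 * np.pi))

    @property
    def loglik_base(self) -> float:
        return self.base_results.llf

    @property
    def loglik_mod(self) -> float:
        return self.results.llf

    @property
    def converged(self) -> bool:
        return self.results.converged and self.base_results.converged

    def to_dict(self) -> dict:
        return {
            "include_sine": self.include_sine,
            "w_cos_target": self.w_cos_target,
            "w_sin_target": self.w_sin_target,
            "w_cos_distractor": self.w_cos_distractor,
            "w_sin_distractor": self.w_sin_distractor,
            "mod_strength": self.mod_strength,
            "pref_phase_rad": self.pref_phase_rad,
            "loglik_base": self.loglik_base,
            "loglik_mod": self.loglik_mod,
            "converged": self.converged,
            "params": self.results.params.to_dict(),
            "bse": self.results.bse.to_dict(),
        }

    def summary(self) -> str:
        lines = [
            "Phase-modulated kernel (SSI x frequency interactions)",
            f"  n trials: {self.results.nobs}   "
            f"loglik base/mod: {self.loglik_base:.3f} / {self.loglik_mod:.3f}",
            f"  targets:     w_cos = {self.w_cos_target:+.4f}"
            + (f", w_sin = {self.w_sin_target:+.4f}" if self.include_sine else ""),
            f"  distractors: w_cos = {self.w_cos_distractor:+.4f}"
            + (f", w_sin = {self.w_sin_distractor:+.4f}" if self.include_sine else ""),
            f"  modulation strength: {self.mod_strength:.4f}   "
            f"preferred phase: {self.pref_phase_rad:.3f} rad",
        ]
        return "\n".join(lines)


#: Domain-named alias.
ModulationEstimate = PhaseKernelResults


def fit_modulated_probit(tones, choices, phases, include_sine: bool = True,
                         link: str = "probit") -> PhaseKernelResults:
    """Fit the SSI-modulated kernel (functional wrapper)."""
    return PhaseKernelModel(tones, choices, phases,
                            include_sine=include_sine, link=link).fit()


def variability_explained(base: ChoiceKernelResults,
                          mod: PhaseKernelResults | ChoiceKernelResults) -> dict:
    """Improvement of the modulated over the base fit on identical data.

    Returns the likelihood-ratio deviance 2*(ll_mod - ll_base) and the
    McFadden pseudo-R^2 delta; both are >= 0 for properly nested fits.
    """
    llf_mod = mod.loglik_mod if isinstance(mod, PhaseKernelResults) else mod.llf
    n_mod = (mod.results.nobs if isinstance(mod, PhaseKernelResults) else mod.nobs)
    k_mod = (len(mod.results.params) if isinstance(mod, PhaseKernelResults)
             else len(mod.params))
    if n_mod != base.nobs:
        raise ValueError("fits are not nested: different numbers of trials")
    if k_mod <= len(base.params):
        raise ValueError("fits are not nested: the modulated model must have "
                         "more parameters than the base model")
    if llf_mod < base.llf - 1e-6:
        raise ValueError("fits are not nested: the larger model has a lower "
                         "log-likelihood")
    deviance = max(0.0, 2.0 * (llf_mod - base.llf))
    y = base.model.endog.to_numpy()
    p = y.mean()
    p = min(max(p, 1e-12), 1 - 1e-12)
    llf_null = len(y) * (p * np.log(p) + (1 - p) * np.log(1 - p))
    return {
        "deviance": deviance,
        "mcfadden_delta": deviance / (-2.0 * llf_null),
        "df": k_mod - len(base.params),
    }


# ---------------------------------------------------------------------------
# octile profile
# ---------------------------------------------------------------------------

@dataclass
class OctileProfile:
    """Sliding-window gain profile over the simultaneity distribution."""

    table: pd.DataFrame  # window, q_lo, q_hi, g_target, g_distractor, se_*
    n_windows: int

    @property
    def contrast_target(self) -> float:
        """First (most synchronous) minus last octile target gain."""
        return float(self.table["g_target"].iloc[0]
                     - self.table["g_target"].iloc[-1])

    @property
    def contrast_distractor(self) -> float:
        return float(self.table["g_distractor"].iloc[0]
                     - self.table["g_distractor"].iloc[-1])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        q = 0.5 * (self.table["q_lo"] + self.table["q_hi"])
        ax.plot(q, self.table["g_target"], label="targets")
        ax.plot(q, self.table["g_distractor"], label="distractors")
        ax.set_xlabel("simultaneity quantile (0 = most synchronous)")
        ax.set_ylabel("sensory gain")
        ax.legend()
        return ax


def octile_profile(tones, choices, phases, n_windows: int = 64,
                   min_tones: int = 50) -> OctileProfile:
    """Gain as a function of tone-tap simultaneity, in sliding windows.

    The simultaneity score of a tone is the circular distance of its SSI
    from 0 (in [0, pi]; equivalently ordering by -cos SSI), so the "first
    octile" is the most synchronous eighth regardless of lead/lag sign.
    ``n_windows`` windows each cover one eighth (12.5%) of each role's score
    distribution, with lower edges evenly stepped so the first window is the
    first octile and the last window the last octile.  Within each window a
    probit regression of choice on (in-window target f-sum, in-window
    distractor f-sum, out-of-window role f-sums as nuisance, intercept)
    yields the windowed gains.  Windows with fewer than ``min_tones`` tones
    in a role are widened symmetrically (and logged).
    """
    merged = _merged(tones, phases)
    ch = _as_choices_table(choices)
    trial_ids = pd.Index(sorted(merged["trial_id"].unique()), name="trial_id")
    y = (ch.set_index("trial_id").loc[trial_ids, "choice"] == "high").astype(int)

    s = np.minimum(merged["ssi_rad"], 2 * np.pi - merged["ssi_rad"])
    merged = merged.assign(sync_score=s)
    # quantile rank of the score within each role
    merged["q"] = merged.groupby("role")["sync_score"].rank(pct=True, method="average")

    width = 1.0 / 8.0
    los = np.linspace(0.0, 1.0 - width, n_windows)
    rows = []
    for w, lo in enumerate(los):
        hi = lo + width
        glo, ghi = lo, hi
        while True:
            inwin = (merged["q"] > glo - 1e-12) & (merged["q"] <= ghi + 1e-12)
            counts = merged.loc[inwin].groupby("role").size()
            if (counts.reindex([ROLE_TARGET, ROLE_DISTRACTOR]).fillna(0)
                    >= min_tones).all() or (glo <= 0 and ghi >= 1):
                break
            glo, ghi = max(0.0, glo - 1 / n_windows), min(1.0, ghi + 1 / n_windows)
        if (glo, ghi) != (lo, hi):
            warnings.warn(f"window {w}: widened to [{glo:.3f}, {ghi:.3f}] to "
                          f"reach {min_tones} tones per role", stacklevel=2)
        cols = {}
        for role, tag in ((ROLE_TARGET, "tar"), (ROLE_DISTRACTOR, "dis")):
            sub = merged[merged["role"] == role]
            m = (sub["q"] > glo - 1e-12) & (sub["q"] <= ghi + 1e-12)
            f_in = sub[m].groupby("trial_id")["f_log2"].sum()
            f_out = sub[~m].groupby("trial_id")["f_log2"].sum()
            cols[f"g_{tag}_in"] = f_in.reindex(trial_ids).fillna(0.0)
            cols[f"g_{tag}_out"] = f_out.reindex(trial_ids).fillna(0.0)
        X = pd.DataFrame(cols, index=trial_ids)
        X["bias"] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ChoiceKernelModel(y, X).fit()
        rows.append((w, glo, ghi,
                     float(res.params["g_tar_in"]), float(res.params["g_dis_in"]),
                     float(res.bse["g_tar_in"]), float(res.bse["g_dis_in"])))
    table = pd.DataFrame(rows, columns=["window", "q_lo", "q_hi", "g_target",
                                        "g_distractor", "se_target",
                                        "se_distractor"])
    return OctileProfile(table=table, n_windows=n_windows)
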