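"""Sensorimotor phase: delay correction, interpolation, SSI, modulation."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

import beatgain as bg
from beatgain.exceptions import InsufficientDataError
from beatgain.observer import MotorTrace
from beatgain.phase import phase_in_tap_cycle
from beatgain.sequences import ISI_MS

from conftest import motor_phase_pipeline


def _trace(times, trial_id=0):
    times = np.asarray(times, dtype=float)
    return MotorTrace(trial_id=trial_id, tap_times_ms=times,
                      interpolated=np.zeros(times.size, dtype=bool))


BEATS = np.arange(13) * ISI_MS


class TestDelayCorrection:
    def test_constant_lag_removed(self):
        traces = [_trace(BEATS[1:] + 30.0, i) for i in range(3)]
        corrected, offset = bg.correct_delay(traces, BEATS)
        assert offset == pytest.approx(30.0, abs=1e-9)
        np.testing.assert_allclose(corrected[0].tap_times_ms, BEATS[1:])
        assert corrected[0].delay_offset_ms == pytest.approx(30.0)

    def test_zero_lag_identity(self):
        corrected, offset = bg.correct_delay([_trace(BEATS[1:])], BEATS)
        assert offset == pytest.approx(0.0, abs=1e-9)

    def test_noisy_lag_estimated_and_residual_zero(self):
        rng = np.random.default_rng(0)
        traces = [_trace(BEATS[1:] - 25.0 + rng.normal(0, 30, 12), i)
                  for i in range(50)]
        corrected, offset = bg.correct_delay(traces, BEATS)
        assert offset == pytest.approx(-25.0, abs=3 * 30 / np.sqrt(600))
        resid = np.concatenate([tr.tap_times_ms - BEATS[1:]
                                for tr in corrected])
        assert np.mean(resid) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_taps(self):
        with pytest.raises(InsufficientDataError):
            bg.correct_delay([_trace(BEATS[1:5])], BEATS)


class TestInterpolation:
    def test_midpoint_fill(self):
        beats = np.array([-667.0, 0.0, 667.0, 1334.0])
        tr = bg.interpolate_missing(_trace([0.0, 1334.0]), beats)
        np.testing.assert_allclose(tr.tap_times_ms, [0.0, 667.0, 1334.0])
        assert list(tr.interpolated) == [False, True, False]

    def test_linear_not_grid_fill(self):
        beats = np.array([-667.0, 0.0, 667.0, 1334.0])
        tr = bg.interpolate_missing(_trace([0.0, 1400.0]), beats)
        assert tr.tap_times_ms[1] == pytest.approx(700.0)

    def test_complete_trace_unchanged(self):
        tr = bg.interpolate_missing(_trace(BEATS[1:] + 5.0), BEATS)
        np.testing.assert_allclose(tr.tap_times_ms, BEATS[1:] + 5.0)
        assert not tr.interpolated.any()

    def test_edge_gap_extrapolated_at_beat_period(self):
        tr = bg.interpolate_missing(_trace(BEATS[2:] + 10.0), BEATS)
        assert tr.tap_times_ms[0] == pytest.approx(BEATS[1] + 10.0)
        assert tr.interpolated[0]

    def test_double_gap_warns_and_chains(self):
        times = np.concatenate([BEATS[1:4], BEATS[6:]])
        with pytest.warns(UserWarning, match="consecutive missing"):
            tr = bg.interpolate_missing(_trace(times), BEATS)
        np.testing.assert_allclose(tr.tap_times_ms, BEATS[1:])


class TestPhaseAssignment:
    def test_tone_at_tap_is_zero(self):
        ph, ex = phase_in_tap_cycle([667.0], BEATS[1:])
        assert ph[0] == 0.0 and not ex[0]

    def test_midpoint_is_pi(self):
        ph, _ = phase_in_tap_cycle([1000.5], BEATS[1:])
        assert ph[0] == pytest.approx(np.pi)

    def test_fractional_phase(self):
        ph, _ = phase_in_tap_cycle([500.0], [0.0, 667.0])
        assert ph[0] == pytest.approx(2 * np.pi * 500 / 667)

    def test_outside_span_extrapolates_and_flags(self):
        ph, ex = phase_in_tap_cycle([-333.5, 8500.0], BEATS[1:])
        assert ex.all()
        assert ph[0] == pytest.approx(np.pi)

    def test_time_translation_invariance(self):
        rng = np.random.default_rng(1)
        taps = np.sort(rng.uniform(0, 8000, 12))
        taps = taps[np.diff(np.concatenate([[-1], taps])) > 1]
        tones = rng.uniform(taps[0] + 1, taps[-1], 20)
        ph0, _ = phase_in_tap_cycle(tones, taps)
        ph1, _ = phase_in_tap_cycle(tones + 1234.5, taps + 1234.5)
        np.testing.assert_allclose(ph0, ph1, atol=1e-9)

    def test_assign_phase_table(self):
        trial = bg.generate_trial("exp1", "motor", rng_seed=2)
        obs = bg.ObserverParams(motor_sd_ms=0.0, motor_lag_ms=0.0,
                                miss_prob=0.0)
        trace = bg.simulate_taps(trial, obs, 3)
        table = bg.assign_phase(trial, trace, "motor")
        assert len(table) == 16
        assert set(table.columns) >= {"trial_id", "role", "index_in_role",
                                      "ssi_rad", "source"}
        assert ((table.ssi_rad >= 0) & (table.ssi_rad < 2 * np.pi)).all()
        # with perfect on-beat taps, on-beat targets sit near phi = 0
        tar = table[table.role == "target"]
        circ = np.minimum(tar.ssi_rad, 2 * np.pi - tar.ssi_rad)
        assert circ.median() < np.pi / 2

    def test_bad_source_rejected(self):
        trial = bg.generate_trial("exp1", "motor", rng_seed=2)
        with pytest.raises(ValueError):
            bg.assign_phase(trial, trial.beat_times_ms, "taps")


class TestModulatedFit:
    def test_null_modulation_recovered_as_zero(self):
        obs = bg.ObserverParams(mod_depth_m=0.0, listen_mod_depth=0.0)
        ds = bg.simulate_dataset(obs, bg.ExperimentDesign(delta=0.1),
                                 1200, rng_seed=4)
        motor, phases, _ = motor_phase_pipeline(ds)
        est = bg.fit_modulated_probit(motor.tones_table(),
                                      motor.choices_table(), phases,
                                      include_sine=False)
        for name in ("w_cos_tar", "w_cos_dis"):
            assert abs(est.results.params[name]) < 3 * est.results.bse[name]

    def test_modulation_recovery(self, mod_dataset, mod_motor_phases,
                                 spread_observer):
        """Cos coefficients recover the generative m*g within their CI and
        the preferred phase lands within 0.3 rad of the corrected-frame
        truth (the generative peak shifted by the delay-corrected lag)."""
        motor, phases, offset = mod_motor_phases
        est = bg.fit_modulated_probit(motor.tones_table(),
                                      motor.choices_table(), phases)
        obs = spread_observer
        truth_t = obs.mod_depth_m * obs.g_target  # 0.8
        truth_d = obs.mod_depth_m * obs.g_distractor  # 0.32
        # delay correction shifts every tap by -offset, so the generative
        # peak (at the actual tap) appears at phase 2*pi*offset/period in
        # the corrected frame
        shift = 2 * np.pi * offset / ISI_MS
        truth_phase = np.mod(obs.pref_phase_rad + shift, 2 * np.pi)
        amp_t = est.role_modulation("target")
        assert abs(amp_t - truth_t) < 2.5 * est.results.bse["w_cos_tar"]
        assert abs(est.role_modulation("distractor") - truth_d) \
            < 2.5 * est.results.bse["w_cos_dis"]
        dphi = np.angle(np.exp(1j * (est.pref_phase_rad - truth_phase)))
        assert abs(dphi) < 0.3

    def test_loglik_nesting(self, exp1_dataset, exp1_motor_phases):
        motor, phases, _ = exp1_motor_phases
        est = bg.fit_modulated_probit(motor.tones_table(),
                                      motor.choices_table(), phases)
        assert est.loglik_mod >= est.loglik_base - 1e-8
        v = bg.variability_explained(est.base_results, est)
        assert v["deviance"] >= 0 and v["mcfadden_delta"] >= 0
        assert v["df"] == 4

    def test_variability_explained_rejects_non_nested(self, exp1_dataset):
        listen = exp1_dataset.subset("listen")
        r = bg.ChoiceKernelModel.from_tables(listen.tones_table(),
                                             listen.choices_table()).fit()
        with pytest.raises(ValueError):
            bg.variability_explained(r, r)

    def test_motor_source_beats_nonmotor(self, mod_dataset,
                                         mod_motor_phases):
        """Tap-locked generative gain shows more strongly through motor-act
        SSI than through the beat-locked control SSI: the motor-source
        model explains the choices decisively better (higher likelihood on
        identical trials with identical df), the model-comparison form of
        the control analysis.  The sources only separate when tapping is
        variable enough to decorrelate the two cycles, hence the
        high-tap-noise observer."""
        motor, phases_m, _ = mod_motor_phases
        phases_n = bg.assign_phases(motor.trials, None, "nonmotor")
        em = bg.fit_modulated_probit(motor.tones_table(),
                                     motor.choices_table(), phases_m)
        en = bg.fit_modulated_probit(motor.tones_table(),
                                     motor.choices_table(), phases_n)
        assert em.loglik_mod > en.loglik_mod + 5.0

    def test_exp3_phase_opposition_abolishes_modulation(self, mod_dataset_exp3,
                                                        mod_motor_phases):
        """With taps in phase with distractors and covert attention on the
        (anti-phase) targets, the tap-locked modulation does not engage:
        the exp3 estimate is far below exp1's and not positive."""
        motor3, phases3, _ = motor_phase_pipeline(mod_dataset_exp3)
        e3 = bg.fit_modulated_probit(motor3.tones_table(),
                                     motor3.choices_table(), phases3,
                                     include_sine=False)
        motor1, phases1, _ = mod_motor_phases
        e1 = bg.fit_modulated_probit(motor1.tones_table(),
                                     motor1.choices_table(), phases1,
                                     include_sine=False)
        assert e1.mod_strength > 0
        assert e3.mod_strength < 0.5 * e1.mod_strength
        # not significantly positive
        se3 = 0.5 * (e3.results.bse["w_cos_tar"] + e3.results.bse["w_cos_dis"])
        assert e3.mod_strength < 2 * se3


class TestOctileProfile:
    def test_window_count_and_coverage(self, mod_dataset, mod_motor_phases):
        motor, phases, _ = mod_motor_phases
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = bg.octile_profile(motor.tones_table(),
                                     motor.choices_table(), phases)
        assert len(prof.table) == 64
        assert prof.table.q_lo.iloc[0] == 0.0
        assert prof.table.q_hi.iloc[-1] == pytest.approx(1.0)
        np.testing.assert_allclose(prof.table.q_hi - prof.table.q_lo, 0.125)

    def test_modulated_profile_decreases(self, mod_dataset,
                                         mod_motor_phases):
        """Most-synchronous window out-gains the least-synchronous one, and
        the pooled stationary gain lies between them (the cyclic-gain
        signature)."""
        motor, phases, _ = mod_motor_phases
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = bg.octile_profile(motor.tones_table(),
                                     motor.choices_table(), phases)
        assert prof.contrast_target > 0
        base = bg.ChoiceKernelModel.from_tables(motor.tones_table(),
                                                motor.choices_table()).fit()
        assert prof.table.g_target.iloc[0] > base.g_target_pooled
        assert prof.table.g_target.iloc[-1] < base.g_target_pooled

    def test_flat_profile_without_modulation(self):
        obs = bg.ObserverParams(mod_depth_m=0.0, listen_mod_depth=0.0)
        ds = bg.simulate_dataset(obs, bg.ExperimentDesign(delta=0.1),
                                 1200, rng_seed=6)
        motor, phases, _ = motor_phase_pipeline(ds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = bg.octile_profile(motor.tones_table(),
                                     motor.choices_table(), phases)
        se = np.hypot(prof.table.se_target.iloc[0],
                      prof.table.se_target.iloc[-1])
        assert abs(prof.contrast_target) < 3 * se
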