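import warnings

import numpy as np
import pytest

import beatgain as bg


@pytest.fixture(autouse=True)
def _quiet_small_sample_warnings():
    """Silence the <10x-trials-per-parameter advisory in deliberately
    small test fits; schema/integrity errors still surface."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="only .* trials for")
        warnings.filterwarnings("ignore", message="trial .*consecutive missing")
        yield


@pytest.fixture(scope="session")
def default_observer():
    return bg.ObserverParams()


@pytest.fixture(scope="session")
def exp1_dataset(default_observer):
    """A large exp1 session shared across estimation tests."""
    return bg.simulate_dataset(default_observer,
                               bg.ExperimentDesign(delta=0.12),
                               n_trials_per_condition=4000, rng_seed=20240101)


@pytest.fixture(scope="session")
def spread_observer():
    """Observer whose noisy tapping (90 ms s.d.) spreads tone-tap phases
    over the whole cycle, making phase-resolved quantities identifiable at
    a few thousand trials; modulation depth at the high end of plausible."""
    return bg.ObserverParams(motor_sd_ms=90.0, mod_depth_m=0.8,
                             g_distractor=0.4)


@pytest.fixture(scope="session")
def mod_dataset(spread_observer):
    """exp1 session of the spread observer, for phase-resolved estimation."""
    return bg.simulate_dataset(spread_observer,
                               bg.ExperimentDesign(delta=0.12),
                               n_trials_per_condition=4000, rng_seed=20240102)


@pytest.fixture(scope="session")
def mod_dataset_exp3(spread_observer):
    """Matched exp3 session (taps in phase with distractors)."""
    return bg.simulate_dataset(spread_observer,
                               bg.ExperimentDesign(experiment="exp3",
                                                   delta=0.12),
                               n_trials_per_condition=4000, rng_seed=20240103)


@pytest.fixture(scope="session")
def mod_motor_phases(mod_dataset):
    """Motor subset + corrected/interpolated SSI phases of ``mod_dataset``."""
    return motor_phase_pipeline(mod_dataset)


@pytest.fixture(scope="session")
def exp1_motor_phases(exp1_dataset):
    """Corrected, interpolated motor-SSI phases for the exp1 dataset."""
    motor = exp1_dataset.subset("motor")
    bmap = {t.trial_id: t.beat_times_ms for t in motor.trials}
    corrected, offset = bg.correct_delay(list(motor.traces.values()), bmap)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        completed = {tr.trial_id: bg.interpolate_missing(tr, bmap[tr.trial_id])
                     for tr in corrected}
    phases = bg.assign_phases(motor.trials, completed, "motor")
    return motor, phases, offset


def motor_phase_pipeline(dataset):
    """Run delay correction + interpolation + SSI assignment on a dataset."""
    motor = dataset.subset("motor")
    bmap = {t.trial_id: t.beat_times_ms for t in motor.trials}
    corrected, offset = bg.correct_delay(list(motor.traces.values()), bmap)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        completed = {tr.trial_id: bg.interpolate_missing(tr, bmap[tr.trial_id])
                     for tr in corrected}
    phases = bg.assign_phases(motor.trials, completed, "motor")
    return motor, phases, offset
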