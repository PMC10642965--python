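"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

from somnoyoke import (EngineConfig, PairedDesign, reference_params,
                       run_inactivity_triggered)


@pytest.fixture(scope="session")
def ref_params():
    return reference_params()


@pytest.fixture(scope="session")
def immobile_params():
    """A fly that falls asleep at the first opportunity and never wakes."""
    from somnoyoke import BoutLengthDist, CircadianPropensity
    return reference_params(
        circadian_propensity=CircadianPropensity(
            baseline=1.0, siesta_amp=0.0, night_amp=0.0),
        onset_cap=1.0, pressure_init=1.0,
        bout_length_dist=BoutLengthDist(day_median_min=1e6, night_median_min=1e6,
                                        day_sigma_log=0.0, night_sigma_log=0.0,
                                        max_min=1e6),
        hyperactivity_gain=0.0)


@pytest.fixture(scope="session")
def sleepless_params():
    """A fly with zero sleep propensity: never immobile."""
    from somnoyoke import CircadianPropensity
    return reference_params(
        circadian_propensity=CircadianPropensity(
            baseline=0.0, siesta_amp=0.0, night_amp=0.0))


@pytest.fixture(scope="session")
def yoked220_run(ref_params):
    """One small closed-loop 220-s deprivation run shared across tests.

    One baseline day, 24-h deprivation on day 2, two recovery days.
    """
    design = PairedDesign.balanced(6, 4)
    cfg = EngineConfig(mode="inactivity_triggered", trigger_threshold_s=220,
                       window_start_h=24.0, window_h=24.0)
    traces, logs = run_inactivity_triggered(design, ref_params, cfg,
                                            n_days=4, seed=101)
    return design, cfg, traces, logs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
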