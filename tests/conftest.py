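"""Shared fixtures: session-scoped synthetic trials and small study tables."""

import numpy as np
import pytest

from equispine import (
    SyntheticStudyConfig,
    compute_all_variables,
    generate_trial,
    run_synthetic_study,
    segment_strides,
)


def noise_free_config(**kwargs) -> SyntheticStudyConfig:
    return SyntheticStudyConfig(noise_sd=0.0, **kwargs)


def static_config(**kwargs) -> SyntheticStudyConfig:
    """No noise, no stride oscillations, no speed wobble: a rigid pose moving
    along the path (the trot bounce stays on so strides remain detectable)."""
    amps = {v: 0.0 for v in (
        "fe_whole_back", "lb_whole_back", "pelvis_roll", "pelvis_pitch",
        "pelvis_yaw", "head_swivel", "body_tracking",
    )}
    amps.update(kwargs.pop("rom_amplitudes", {}))
    return SyntheticStudyConfig(
        noise_sd=0.0, rom_amplitudes=amps, speed_wobble=0.0, **kwargs
    )


@pytest.fixture(scope="session")
def left_trial_noise_free():
    return generate_trial(noise_free_config(), "h1", 1, 1, "left", seed=3)


@pytest.fixture(scope="session")
def left_seg(left_trial_noise_free):
    return segment_strides(left_trial_noise_free)


@pytest.fixture(scope="session")
def left_variables(left_trial_noise_free, left_seg):
    return compute_all_variables(left_trial_noise_free, left_seg)


@pytest.fixture(scope="session")
def noisy_left_trial():
    return generate_trial(SyntheticStudyConfig(), "h1", 1, 1, "left", seed=5)


@pytest.fixture(scope="session")
def small_study_table():
    """A reduced study (4 horses x 1 day x 2 trials x 3 paths, 10 s trials)
    through the complete measurement pipeline."""
    cfg = SyntheticStudyConfig(
        n_horses=4,
        days=1,
        trials_per_day=2,
        trial_duration={"straight": 10.0, "left": 10.0, "right": 10.0},
        seed=7,
    )
    return run_synthetic_study(cfg)


def stride_mean(variables: dict, seg, name: str) -> float:
    """Mean of a per-frame series over the complete strides."""
    vals = np.concatenate([variables[name][s:e] for s, e in seg.strides])
    return float(np.nanmean(vals))
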