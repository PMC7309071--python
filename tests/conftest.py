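import numpy as np
import pytest

from aclgait import synth


def make_spec(**overrides) -> synth.CohortSpec:
    """CohortSpec factory for tests."""
    return synth.CohortSpec(**overrides)


def clean_overrides(**extra) -> dict:
    """Noise-free, clean-clock, no-sidestep generator settings.

    Under these settings the recorded sensor clocks coincide with true
    scenario time, so programmed ground-truth event times can be
    compared directly against detected ones.
    """
    base = dict(
        noise_sd_accel=0.0,
        noise_sd_gyro=0.0,
        base_hf_accel_sd=0.0,
        time_jitter_sd_s=0.0,
        clock_offset_range_s=0.0,
        clock_rate_error=0.0,
        shank_yaw_range_deg=0.0,
        sidestep_stride=None,
        jerk_roughness_scale=1.0,
    )
    base.update(extra)
    return base


def fixed_gait_overrides(gct: float = 0.5, stance_pct: float = 46.0, **extra) -> dict:
    """Deterministic stride timing: every stride has the same GCT/stance."""
    cells = [(c, l) for c in ("acl", "healthy") for l in ("left", "right")]
    base = clean_overrides(
        gct_sd_within=0.0,
        gct_sd_between=0.0,
        stance_sd_within=0.0,
        stance_sd_between=0.0,
        gct_mean={k: gct for k in cells},
        stance_pct_mean={k: stance_pct for k in cells},
    )
    base.update(extra)
    return base


@pytest.fixture
def clean_spec() -> synth.CohortSpec:
    return make_spec(**clean_overrides(seed=7))


@pytest.fixture
def fixed_gait_spec() -> synth.CohortSpec:
    return make_spec(**fixed_gait_overrides(n_strides=6, seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
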