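import numpy as np
import pytest

from kinesig.synth import (
    NoiseConfig,
    SyntheticCohortConfig,
    draw_subject_params,
)


def noiseless(**kw) -> NoiseConfig:
    """Measurement-noise-free settings (between-subject spread retained)."""
    base = dict(
        marker_jitter_sd=0.0,
        angle_jitter_sd=0.0,
        tft_timing_sd=0.0,
        brooke_grader_sd=0.0,
    )
    base.update(kw)
    return NoiseConfig(**base)


@pytest.fixture(scope="session")
def base_config() -> SyntheticCohortConfig:
    return SyntheticCohortConfig(
        n_fshd=1, n_dm=1, n_ctl=1, seed=11, noise=noiseless()
    )


@pytest.fixture()
def subject(base_config):
    """One noiseless control subject's planted parameters."""
    rng = np.random.default_rng(42)
    return draw_subject_params(base_config, "P001", "CTL", "M", rng)


@pytest.fixture()
def fshd_subject(base_config):
    rng = np.random.default_rng(43)
    return draw_subject_params(base_config, "P002", "FSHD", "F", rng)
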