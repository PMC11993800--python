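import numpy as np
import pytest

from paflz.synth import CaseEffect, generate_cohort, generate_record, metadata_frame


@pytest.fixture(scope="session")
def clean_record():
    """Zero-noise, zero-wander 10-s record at 500 Hz with known fiducials."""
    return generate_record(noise_sd=0.0, wander_amplitude=0.0, seed=7)


@pytest.fixture(scope="session")
def effect_cohort():
    """12+12 patient cohort with a doubled RR coefficient of variation."""
    records, metas = generate_cohort(
        n_cases=12,
        n_controls=12,
        case_effect=CaseEffect(rr_cv_scale=2.0),
        seed=11,
    )
    return records, metas, metadata_frame(records, metas)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
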