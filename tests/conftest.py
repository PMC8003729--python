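import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from thermorp.synthetic import (
    CohortSpec,
    CurveProfile,
    generate_cohort,
    generate_rewarming_curve,
)


@pytest.fixture
def logistic_profile():
    """A clean full-information S-shaped profile (no noise, no early stop)."""
    return CurveProfile(
        t_base=34.0,
        t_0=20.0,
        t_end=32.0,
        rate=1.0,
        midpoint=10.0,
        noise_sd=0.0,
        max_duration=40.0,
    )


@pytest.fixture
def logistic_series(logistic_profile):
    return generate_rewarming_curve(logistic_profile, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort used across modules."""
    spec = CohortSpec(n_patients=8, n_controls=12, seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_tables(small_cohort):
    from thermorp import features_frame, reduce_cohort

    series = [s for subj in small_cohort for s in subj.series.values()]
    features = features_frame(series)
    metadata = pd.DataFrame(
        [
            {"subject_id": s.subject_id, "diagnosis": s.diagnosis, "age": s.age}
            for s in small_cohort
        ]
    )
    subjects = reduce_cohort(features, metadata)
    return features, metadata, subjects
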