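import numpy as np
import pytest

from scljoint import (
    Association,
    CohortSpec,
    Dataset,
    JointParams,
    LongFixedEffects,
    LongitudinalRecord,
    SubjectRecord,
    SurvFixedEffects,
    generate_dataset,
    reference_truth_params,
)


def make_subject(subject_id="S1", event_time=24.0, event=1, sex=1, age=40.0,
                 bmi=21.0, ar=0, cmv=0, disease="pulmonary_fibrosis"):
    return SubjectRecord(subject_id, event_time, event, sex, age, bmi, ar,
                         cmv, disease)


def make_dataset(n_subjects=3, n_per_subject=4, seed=0, scale_factor=1000.0):
    """Small hand-rolled valid dataset (not via the generator)."""
    rng = np.random.default_rng(seed)
    subjects, measurements = [], []
    for i in range(n_subjects):
        sid = f"S{i + 1}"
        subjects.append(make_subject(sid, event_time=12.0 + 6.0 * i,
                                     event=i % 2, ar=i % 2))
        for j in range(n_per_subject):
            t = 1.0 + 2.0 * j + 0.1 * i
            measurements.append(LongitudinalRecord(sid, t, 0.3 + 0.05 * rng.standard_normal()))
    return Dataset(tuple(subjects), tuple(measurements), scale_factor).validate()


@pytest.fixture(scope="session")
def truth():
    return reference_truth_params()


@pytest.fixture(scope="session")
def small_cohort(truth):
    """50-subject synthetic cohort under the reference truth."""
    ds, latent = generate_dataset(CohortSpec(50, truth, seed=101))
    return ds, latent


@pytest.fixture()
def simple_params():
    """Easy round-number parameters for closed-form checks."""
    return JointParams(
        long=LongFixedEffects(beta0=0.5, beta1=0.05, beta2=-0.01, beta3=-0.02,
                              knot=10.0, sigma=0.5),
        surv=SurvFixedEffects(gamma0=-1.0, gamma={"ar": 0.4}, p=1.2),
        assoc=Association(-0.5),
        sigma_u=0.8,
    )
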