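import pytest
from hypothesis import HealthCheck, settings

from coroflow.engine import simulate_patient
from coroflow.patients import CohortSpec, generate_synthetic_patient

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def _zero_sd(spec_block):
    return {k: v.model_copy(update={"sd": 0.0}) for k, v in spec_block.items()}


@pytest.fixture(scope="session")
def mean_cohort_spec():
    """Cohort spec with every SD zeroed: the generator becomes the identity on
    the cohort means (severe aortic stenosis pre, post-intervention post)."""
    base = CohortSpec(seed=0)
    return CohortSpec(
        seed=0,
        pre=_zero_sd(base.pre),
        post=_zero_sd(base.post),
        coronary=_zero_sd(base.coronary),
        post_peak_velocity=base.post_peak_velocity.model_copy(update={"sd": 0.0}),
    )


@pytest.fixture(scope="session")
def mean_patient(mean_cohort_spec):
    """(pre, post, anatomy) exactly at the cohort means."""
    return generate_synthetic_patient(mean_cohort_spec, 0)


@pytest.fixture(scope="session")
def tuned_mean(mean_patient):
    """Tuned severe-stenosis patient at cohort means: (waves, result, params)."""
    pre, _, anat = mean_patient
    return simulate_patient(pre, anat)


@pytest.fixture(scope="session")
def tuned_mean_wide_valve(mean_patient):
    """The same patient with only the aortic-valve EOA raised to 1.7 cm^2
    (valve-replacement surrogate), tuned to the same pressure/flow targets."""
    pre, _, anat = mean_patient
    wide = pre.model_copy(update={"EOA_AV": 1.7})
    return simulate_patient(wide, anat)
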