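import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from labrec.records_io import PatientCase, TestUniverse
from labrec.smoothing import SmoothingConfig
from labrec.training import build_training_matrix
from labrec.weighting import WeightConfig


@pytest.fixture
def four_cases():
    """The reference fixture {A,B}, {A,B}, {A,C}, {C}."""
    sets = [{"A", "B"}, {"A", "B"}, {"A", "C"}, {"C"}]
    return [
        PatientCase(case_id=f"c{i}", taken_tests=frozenset(s), patient_id=f"p{i}")
        for i, s in enumerate(sets)
    ]


@pytest.fixture
def four_case_matrix(four_cases):
    return build_training_matrix(four_cases, TestUniverse.from_codes("ABC"))


@pytest.fixture
def raw_config():
    """No smoothing at all: raw count ratios, raw log-odds prior."""
    return WeightConfig(smoothing=SmoothingConfig(method="none", param=0.0, theta=0.0))
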