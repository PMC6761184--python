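import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from infantglioma.fixture import build_paper_fixture, noiseless_assays  # noqa: E402
from infantglioma.pipeline import run_cohort, samples_frame  # noqa: E402


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_paper_fixture()


@pytest.fixture(scope="session")
def fixture_result(fixture_cohort):
    """The reference cohort pushed through the full calling pipeline."""
    bundle = noiseless_assays(fixture_cohort)
    return run_cohort(samples_frame(fixture_cohort), bundle)
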