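import pytest
from hypothesis import settings

from obisenv import fixtures

settings.register_profile("suite", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(params=["sample_based", "ctd", "telemetry", "vpr", "fig1"])
def category_bundle(request):
    """One conformant bundle per dataset category."""
    spec = fixtures.ScenarioSpec(category=request.param, seed=11)
    return fixtures.generate(spec)


@pytest.fixture
def fig1_bundle():
    """The multi-gear scenario: cruise -> station -> gears -> slices."""
    return fixtures.generate(fixtures.ScenarioSpec(category="fig1", seed=5,
                                                   stations=1))
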