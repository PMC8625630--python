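import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_plausibility_warnings():
    # Sweeps and fixtures routinely touch the edges of the modelled
    # parameter box; the warnings are the behaviour under test only in
    # the tests that assert them explicitly.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
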