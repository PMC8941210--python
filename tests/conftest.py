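import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from skipfinder.simulate import make_demo_transcript

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_model():
    """The full-scale demo transcript: 33 exons tiling 3.9 kb, 213 nt exon 20."""
    return make_demo_transcript()


@pytest.fixture(scope="session")
def small_model():
    """A fast transcript for simulation-heavy tests: 8 exons over 1.3 kb,
    213 nt exon 4 (skipping it is in-frame)."""
    return make_demo_transcript(
        n_exons=8, total_length=1299, focus_exon=4, focus_exon_length=213, seed=1,
        name="SMALL_TX",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
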