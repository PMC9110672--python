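import numpy as np
import pytest

from pribin import BinConfig, EventTable
from pribin.synthetic import default_spec, generate_sample


def random_event_table(rng, n_events, markers=("X", "Y", "Z", "W")):
    """Random transformed table with asinh-scale values (may be negative)."""
    values = rng.normal(1.5, 1.2, size=(n_events, len(markers)))
    return EventTable(values=values, channels=list(markers),
                      markers={m: m for m in markers}, transformed=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table(rng):
    return random_event_table(rng, 2000)


@pytest.fixture
def bin_config():
    return BinConfig(x_marker="X", y_marker="Y", z_marker="Z",
                     x_threshold=1.5, y_threshold=1.5, z_threshold=1.5)


@pytest.fixture(scope="session")
def default_sample():
    """One 20k-event sample from the default synthetic cohort (shared)."""
    spec = default_spec(seed=7, n_events=20_000)
    return generate_sample(spec, "effective", 0)
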