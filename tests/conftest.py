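import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_counts():
    """5 OTUs × 10 samples with assorted structure (ints, zeros, ties)."""
    rng = np.random.default_rng(42)
    data = rng.integers(0, 50, size=(5, 10))
    data[2, :4] = 0
    return pd.DataFrame(
        data,
        index=[f"OTU{i}" for i in range(1, 6)],
        columns=[f"S{j}" for j in range(1, 11)],
    )


@pytest.fixture
def toy_table(toy_counts):
    from pomnet.otu_table import OtuTable
    return OtuTable(toy_counts)
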