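import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from epimast.io import CountsMatrix, GenomicRegion, SignalTrack

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def flat_track():
    """Constant value 2.0 over chr1:0-5000."""
    return SignalTrack({"chr1": ([0], [5000], [2.0])})


@pytest.fixture
def half_track():
    """Value 4.0 over chr1:0-2500 only (uncovered to the right)."""
    return SignalTrack({"chr1": ([0], [2500], [4.0])})


@pytest.fixture
def small_counts():
    """6 genes x 4 samples, two conditions."""
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        rng.poisson(50, size=(6, 4)),
        index=[f"g{i}" for i in range(6)],
        columns=["a1", "a2", "b1", "b2"],
    )
    return CountsMatrix(df, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})


def region(start, end, chrom="chr1", name=None):
    return GenomicRegion(chrom, start, end, name)
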