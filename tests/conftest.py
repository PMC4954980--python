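import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20160721)


@pytest.fixture
def toy_alignment():
    """Two groups of two rows, six columns crafted to contain exactly
    2 universal, 1 G1-specific, 1 G2-specific and 2 variable columns."""
    from batglut.promoter_evolution import GroupedAlignment

    #        u u s1 s2 v v
    seqs = {
        "s1": "ACGAAT",
        "s2": "ACGTCC",
        "s3": "ACAGAA",
        "s4": "ACCGCG",
    }
    groups = {"s1": "G1", "s2": "G1", "s3": "G2", "s4": "G2"}
    return GroupedAlignment(list(seqs), list(seqs.values()), groups)
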