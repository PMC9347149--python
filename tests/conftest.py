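import numpy as np
import pytest

from tmbbias.synthetic_data import SimulatedSite, TumourSample


def make_sample(alt_depth_pairs, *, clonal=None, region_size_mb=1.0, purity=1.0):
    """Build a small fixture sample from (alt, depth) pairs."""
    n = len(alt_depth_pairs)
    clonal = clonal or [False] * n
    sites = [
        SimulatedSite(
            site_id=f"site_{i}",
            true_vaf=alt / depth if depth else 0.0,
            depth=depth,
            alt_count=alt,
            is_clonal=flag,
        )
        for i, ((alt, depth), flag) in enumerate(zip(alt_depth_pairs, clonal))
    ]
    return TumourSample(
        sites=sites,
        purity=purity,
        clonal_fraction=sum(clonal) / n,
        region_size_mb=region_size_mb,
        seed=0,
    )


@pytest.fixture
def fixture_sample():
    """Four detected-capable sites with observed VAFs 0.01, 0.049, 0.05, 0.40."""
    return make_sample([(10, 1000), (49, 1000), (50, 1000), (400, 1000)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
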