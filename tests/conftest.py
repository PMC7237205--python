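import numpy as np
import pytest

from meiohot import synthetic as syn


@pytest.fixture(scope="session")
def small_genome():
    """200 kb single-chrom random genome with 10 planted Dom2/Cast hotspots."""
    g = syn.generate_genome(11, {"chr1": 200_000})
    return syn.plant_hotspots(
        g, n=10, allele_mix={"Dom2": 0.5, "Cast": 0.5},
        min_spacing=12_000, seed=12,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
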