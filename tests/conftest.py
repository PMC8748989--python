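import numpy as np
import pytest

from allelescan.atac import Region, local_intensity, make_window_grid
from allelescan.synthetic import AtacSimConfig, simulate_atac


def planted_intensity(seed, n_samples=161, region_length=5000, effect=1.0,
                      planted=(2300, 2700), maf=0.2, background_rate=0.05):
    """Simulate one LD region with a planted allele-dependent interval and
    return (intensity matrix, genotype dosages)."""
    start, end = planted if planted else (None, None)
    config = AtacSimConfig(
        n_samples=n_samples, region_length=region_length, maf=maf,
        background_rate=background_rate, planted_start=start, planted_end=end,
        effect_per_allele=effect if planted else 0.0, seed=seed,
    )
    cut_sites, truth = simulate_atac(config)
    grid = make_window_grid(Region("chr1", 0, region_length))
    matrix = local_intensity(cut_sites, grid)
    return matrix, truth.genotypes.astype(float)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
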