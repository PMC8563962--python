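import numpy as np
import pandas as pd
import pytest

from rockermeth import BetaMatrix, RunConfig


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_beta(chrom_pos, values, samples=None):
    """Build a BetaMatrix from [(chrom, pos), ...] and a value array (percent)."""
    values = np.asarray(values, dtype=float)
    if samples is None:
        samples = [f"s{j}" for j in range(values.shape[1])]
    sites = pd.DataFrame(chrom_pos, columns=["chrom", "pos"])
    return BetaMatrix(sites=sites, samples=list(samples), values=values)


@pytest.fixture
def toy_pair():
    """Tiny matched tumor/normal pair: 6 sites on two chromosomes."""
    coords = [("chr1", 100), ("chr1", 200), ("chr1", 350),
              ("chr2", 50), ("chr2", 80), ("chr2", 9000)]
    tumor = make_beta(coords, [[90, 85, 95], [88, 92, 80], [50, 55, 45],
                               [10, 15, 5], [12, 8, 20], [60, 50, 40]])
    normal = make_beta(coords, [[20, 25, 15], [30, 22, 28], [48, 52, 50],
                                [80, 85, 90], [70, 75, 88], [55, 45, 50]])
    return tumor, normal
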