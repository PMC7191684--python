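import numpy as np
import pytest

from hotcomp.io_formats import GenomeLayout, Interval
from hotcomp.ratemap import RateMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 1_000_000, "chr2": 500_000})


def make_ratemap(
    length=200_000,
    density=1.0 / 200.0,
    rate_shape=2.0,
    rate_mean=1e-3,
    seed=0,
    chrom="chr1",
    population="pop",
):
    """iid-gamma flat-landscape map (matches the caller's null family)."""
    rng = np.random.default_rng(seed)
    n = max(rng.poisson(length * density), 2)
    positions = np.sort(rng.choice(length, size=n, replace=False))
    rates = rng.gamma(rate_shape, rate_mean / rate_shape, size=n - 1)
    return RateMap(chrom=chrom, positions=positions, rates=rates,
                   population=population)


@pytest.fixture
def flat_ratemap():
    return make_ratemap()


def intervals(*triples):
    return [Interval(c, s, e) for c, s, e in triples]
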