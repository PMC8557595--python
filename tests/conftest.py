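import numpy as np
import pytest

from seprog.synthdata import SynthConfig, gen_chipseq_series, gen_expression, gen_qpcr


@pytest.fixture(scope="session")
def default_cfg():
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def chipseq(default_cfg):
    return gen_chipseq_series(default_cfg)


@pytest.fixture(scope="session")
def expression(default_cfg):
    return gen_expression(default_cfg)


@pytest.fixture(scope="session")
def qpcr(default_cfg):
    return gen_qpcr(default_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=5_000):
    """Random validated intervals for oracle comparisons."""
    from seprog.intervals import GenomicInterval

    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out
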