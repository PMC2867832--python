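import numpy as np
import pytest

from acetclust.io import Promoter, PromoterTable
from acetclust.synth import SyntheticConfig, generate_dataset


def make_promoter(
    pid="p1",
    chrom="chr1",
    strand="+",
    rep=10_000,
    level1=None,
    tpm=None,
):
    if level1 is None:
        level1 = ((rep, 10),)
    return Promoter(pid, chrom, strand, rep, tuple(level1), tpm or {"0h": 10.0})


@pytest.fixture(scope="session")
def small_dataset():
    """Noisy dataset with gaps and planted proximal pairs."""
    cfg = SyntheticConfig(
        n_promoters=60,
        genome_length=400_000,
        seed=11,
        proximal_pair_rate=0.1,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noiseless, gap-free dataset: planted structure is exactly recoverable."""
    cfg = SyntheticConfig(
        n_promoters=30,
        genome_length=250_000,
        seed=5,
        noise_sd=0.0,
        gap_rate=0.0,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def promoter_table(*promoters):
    return PromoterTable(tuple(promoters))
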