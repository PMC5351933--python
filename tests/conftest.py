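import numpy as np
import pytest

from haplofoot import SyntheticConfig, generate_dataset
from haplofoot.genome_intervals import GenomicInterval, IntervalSet


@pytest.fixture(scope="session")
def default_dataset():
    """Full-scale dataset at the default study conditions (10^4 sentinels)."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset for module-level behavioural tests."""
    return generate_dataset(
        SyntheticConfig(
            n_chromosomes=1,
            chrom_length_bp=300_000,
            n_dhs=200,
            n_snvs=4000,
            n_haplotypes_in_panel=120,
            n_sentinels=800,
            seed=42,
        )
    )


@pytest.fixture()
def tiny_config():
    """Small enough to write to disk and round-trip quickly."""
    return SyntheticConfig(
        n_chromosomes=1,
        chrom_length_bp=60_000,
        n_dhs=30,
        n_snvs=2000,
        n_haplotypes_in_panel=20,
        ld_block_length_bp=5_000,
        n_sentinels=50,
        seed=7,
    )


def sentinel_intervals(ds) -> IntervalSet:
    """Sentinels as 1-bp query intervals."""
    panel = ds.panel
    out = []
    for s in ds.sentinels:
        i = panel.index_of(s)
        p = int(panel.pos[i])
        out.append(GenomicInterval(str(panel.chrom[i]), p - 1, p, name=s))
    return IntervalSet(out)


def random_interval_set(rng, n, chrom="chr1", max_pos=10_000, max_len=50):
    starts = rng.integers(0, max_pos - max_len, n)
    lengths = rng.integers(1, max_len + 1, n)
    return IntervalSet(
        [GenomicInterval(chrom, int(s), int(s + l)) for s, l in zip(starts, lengths)]
    )
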