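import numpy as np
import pytest

from siddprom import (
    DatasetConfig,
    SynthConfig,
    WindowInstance,
    build_dataset,
    generate,
    split_dataset,
)
from siddprom.sidd_io import NON_PROMOTER, PROMOTER, WINDOW_LENGTH


def make_window(values, label=PROMOTER, origin=1000, strand="forward"):
    return WindowInstance(np.asarray(values, dtype=float), label, origin, strand)


def random_windows(rng, n, label=PROMOTER, loc=10.0, scale=1.5):
    return [
        make_window(rng.normal(loc, scale, WINDOW_LENGTH), label=label, origin=i + 1000)
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def separable_genome():
    """Synthetic genome with strong energy wells: separable by sumG."""
    return generate(SynthConfig(genome_length=30_000, n_promoters=40, seed=11))


@pytest.fixture(scope="session")
def separable_split(separable_genome):
    profile, tss, _ = separable_genome
    cfg = DatasetConfig(exclusion_radius=50, seed=5)
    dataset = build_dataset(profile, tss, cfg)
    train, test = split_dataset(dataset, cfg)
    return train, test


@pytest.fixture(scope="session")
def noisy_split():
    """Shallow wells: classes overlap, so cost settings actually matter."""
    profile, tss, _ = generate(
        SynthConfig(genome_length=40_000, n_promoters=60, well_depth=1.2, seed=23)
    )
    cfg = DatasetConfig(exclusion_radius=50, seed=9)
    dataset = build_dataset(profile, tss, cfg)
    return split_dataset(dataset, cfg)
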