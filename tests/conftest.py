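import numpy as np
import pytest

from recombnet.synthetic import SyntheticConfig, generate_bundle


def tiny_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Down-scaled study conditions for fast unit tests."""
    params = dict(
        seed=seed,
        chrom_lengths={"chr1": 30_000, "chr2": 20_000},
        n_hotspots=12,
        n_coldspots=12,
        interval_length_range=(80, 120),
        n_tfs=6,
        n_hot_tfs=2,
        motif_width=6,
        n_background_nodes=30,
        complex_sizes=(4, 5),
        n_clusters=5,
        go_depth=2,
        go_branching=2,
        bin_length=5_000,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate_bundle(tiny_config(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20140911)
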