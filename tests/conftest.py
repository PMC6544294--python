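import numpy as np
import pytest

import ldtrace as lt


@pytest.fixture(scope="session")
def toy():
    """The deterministic hand-computed 6x5 panel and its expectations."""
    dataset, expected = lt.make_toy_fixture()
    return dataset, expected


@pytest.fixture(scope="session")
def small_sim():
    """A quick single-population Wright-Fisher panel with phased truth."""
    cfg = lt.SimConfig(ne_schedule=((0, 60),), n_chromosomes=2,
                       chromosome_length_bp=2_000_000,
                       snp_density_per_mb=400.0, sample_sizes=(40,), seed=12)
    return lt.simulate_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_dataset(rng, n_samples=20, n_markers=50, n_chrom=2,
                   missing_frac=0.05):
    """Random genotype panel helper used across test modules."""
    g = rng.integers(0, 3, size=(n_samples, n_markers)).astype(np.int8)
    miss = rng.random((n_samples, n_markers)) < missing_frac
    g[miss] = lt.MISSING
    per = n_markers // n_chrom
    chroms, positions = [], []
    for c in range(n_chrom):
        m = per if c < n_chrom - 1 else n_markers - per * (n_chrom - 1)
        chroms += [str(c + 1)] * m
        positions += sorted(rng.choice(
            np.arange(1, 10_000_000), size=m, replace=False).tolist())
    return lt.dataset_from_arrays(
        [f"m{j}" for j in range(n_markers)], chroms, positions,
        ["A"] * n_markers, ["B"] * n_markers,
        [f"s{i}" for i in range(n_samples)], ["p1"] * n_samples, g)
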