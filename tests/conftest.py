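import numpy as np
import pytest

from coldgwas import simulate


@pytest.fixture(scope="session")
def small_pop():
    """A modest two-breed population shared by read-only tests."""
    cfg = simulate.SimulationConfig(
        n_per_breed=50, m_snps=1000, n_chrom=2, fst=0.1, seed=11,
        n_misplaced_low=0, n_misplaced_high=0,
    )
    return simulate.simulate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_genotype_table(rng, n=10, m=50, missing_frac=0.0):
    """A random dosage table with 'A'/'G' alleles on one chromosome."""
    from coldgwas.core import MISSING, GenotypeTable, VariantMap, make_sample_frame

    dos = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_frac > 0:
        dos[rng.random((n, m)) < missing_frac] = MISSING
    variants = VariantMap(
        np.full(m, "1", dtype=object),
        np.arange(1, m + 1) * 100,
        np.array([f"v{i}" for i in range(m)], dtype=object),
        np.stack([np.full(m, "A", dtype=object), np.full(m, "G", dtype=object)], axis=1),
    )
    samples = make_sample_frame(
        [f"s{i}" for i in range(n)],
        sex=rng.integers(1, 3, size=n),
        breed=rng.integers(1, 3, size=n),
    )
    return GenotypeTable(dos, samples, variants)
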