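import numpy as np
import pandas as pd
import pytest

from coredivkit.io import GenotypeMatrix


def make_matrix(dosages, chrom=None, pos=None, ids=None, sample_ids=None,
                a1="A", a2="G"):
    """Build a GenotypeMatrix from a dosage array with minimal metadata."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    variants = pd.DataFrame(
        {
            "id": ids if ids is not None else [f"v{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["Vu01"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
            "a1": a1,
            "a2": a2,
        }
    )
    samples = pd.DataFrame(
        {"id": sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]}
    )
    return GenotypeMatrix(d, variants, samples)


@pytest.fixture
def small_matrix():
    return make_matrix(
        [
            [0, 1, 2, 0],
            [2, 1, 0, -1],
            [1, 2, 2, 0],
        ]
    )


@pytest.fixture(scope="session")
def two_pop_cohort():
    """A moderately sized two-population cohort shared across tests."""
    from coredivkit.simulate import SimulationConfig, simulate_structured_genotypes

    cfg = SimulationConfig(
        n_samples=150,
        n_variants=900,
        n_chromosomes=4,
        chromosome_length_bp=10_000_000,
        f_divergence=0.3,
        admixed_fraction=0.10,
        seed=21,
    )
    g, q = simulate_structured_genotypes(cfg)
    return g, q, cfg
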