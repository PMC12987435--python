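import numpy as np
import pytest

from cgcp import GenotypeMatrix


def random_matrix(rng: np.random.Generator, n_cases: int, n_controls: int,
                  n_variants: int, missing_rate: float = 0.05,
                  maf_range: tuple[float, float] = (0.05, 0.5)) -> GenotypeMatrix:
    """A random case/control matrix with independent binomial genotypes."""
    n = n_cases + n_controls
    mafs = rng.uniform(*maf_range, size=n_variants)
    geno = rng.binomial(2, mafs, size=(n, n_variants)).astype(np.int8)
    if missing_rate > 0:
        geno[rng.uniform(size=geno.shape) < missing_rate] = -1
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        variant_ids=[f"v{j}" for j in range(n_variants)],
        genotypes=geno,
        phenotype=np.array(["case"] * n_cases + ["control"] * n_controls, dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
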