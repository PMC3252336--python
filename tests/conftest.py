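import numpy as np
import pytest

from mbmdr import GenotypeMatrix, Trait


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def make_dataset(rng):
    """Factory for random complete genotype/trait datasets."""

    def _make(n=50, m=4, maf=0.3, effect=None, seed=None):
        local = rng if seed is None else np.random.default_rng(seed)
        geno = local.binomial(2, maf, size=(n, m)).astype(np.int8)
        samples = tuple(f"i{i}" for i in range(n))
        g = GenotypeMatrix(geno, tuple(f"snp{j}" for j in range(m)), samples)
        y = local.normal(size=n)
        if effect is not None:
            y = y + effect(geno)
        return g, Trait(y, samples)

    return _make
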