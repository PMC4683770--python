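import numpy as np
import pytest

from haploblup import (
    BlockPlan,
    LocusSpec,
    ModelSpec,
    PhasedGenotypes,
    RandomTerm,
    load_worked_example,
)

# Frequencies and genotypic values of the four-haplotype example locus.
EXAMPLE_P = np.array([0.4, 0.3, 0.2, 0.1])
EXAMPLE_G = np.array(
    [
        [25.0, 18.0, 15.0, 10.0],
        [18.0, 30.0, 33.0, 40.0],
        [15.0, 33.0, 17.0, 12.0],
        [10.0, 40.0, 12.0, 35.0],
    ]
)


@pytest.fixture(scope="session")
def example_locus() -> LocusSpec:
    return load_worked_example()


def random_locus(h: int, seed: int, missing: bool = False) -> LocusSpec:
    """A random valid locus: Dirichlet frequencies, Gaussian values."""
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(h) * 2)
    g = rng.normal(10, 5, size=(h, h))
    g = (g + g.T) / 2
    if missing and h >= 3:
        g[0, 1] = g[1, 0] = np.nan
    return LocusSpec(p=p, g=g)


@pytest.fixture
def hwe_population() -> tuple[PhasedGenotypes, BlockPlan]:
    """100 individuals in exact HWE proportions for the example locus.

    Haplotype counts are exactly 80/60/40/20 over 200 chromosomes, so sample
    frequencies equal 0.4/0.3/0.2/0.1 and every one of the 10 genotypes of
    the locus is present.
    """
    # 2-SNP haplotype strings sorted canonically: 00 < 01 < 10 < 11
    codes = {0: (0, 0), 1: (0, 1), 2: (1, 0), 3: (1, 1)}
    counts = {
        (0, 0): 16, (1, 1): 9, (2, 2): 4, (3, 3): 1,
        (0, 1): 24, (0, 2): 16, (0, 3): 8,
        (1, 2): 12, (1, 3): 6, (2, 3): 4,
    }
    haps = []
    for (i, j), n in counts.items():
        for _ in range(n):
            haps.append([codes[i], codes[j]])
    hap = np.array(haps, dtype=np.int8).transpose(0, 1, 2)
    geno = PhasedGenotypes(
        haplotypes=hap, samples=tuple(f"s{i}" for i in range(hap.shape[0]))
    )
    plan = BlockPlan(blocks=(np.array([0, 1]),))
    return geno, plan


def random_model(
    seed: int, q: int = 30, n_terms: int = 2, with_signal: bool = True
) -> ModelSpec:
    """A small random mixed model with T matrices and positive components."""
    rng = np.random.default_rng(seed)
    terms = []
    g = np.zeros(q)
    for i in range(n_terms):
        t = rng.integers(4, 12)
        T = rng.normal(size=(q, t))
        sigma2 = float(rng.uniform(0.3, 1.5))
        terms.append(RandomTerm(name=f"term{i}", sigma2=sigma2, T=T))
        if with_signal:
            g = g + T @ rng.normal(0, np.sqrt(sigma2), size=t)
    X = np.column_stack([np.ones(q), rng.normal(size=q)])
    b = np.array([1.0, -0.5])
    y = X @ b + g + rng.normal(0, 1.0, size=q)
    return ModelSpec(y=y, terms=terms, sigma2_e=1.0, X=X)
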