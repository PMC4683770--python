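"""Synthetic populations, pedigrees and phenotypes for the haplotype model.

The generator reproduces the model's own assumptions so that estimator
behaviour can be checked against known truth: haplotypes drawn independently
per individual (Hardy-Weinberg equilibrium by construction), unlinked loci,
Mendelian transmission for pedigree designs, and phenotypes built exactly as
y = X b + Z (sum_i T_i tau_i) + e with iid Gaussian effects of the stated
variances.  Linkage disequilibrium between blocks, selection and
non-Gaussian architectures are deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import PhasedGenotypes

__all__ = [
    "SimulationConfig",
    "simulate_haplotypes",
    "simulate_pedigree",
    "simulate_phenotypes",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Reproducible simulation settings.

    ``spectra`` lists one haplotype-frequency simplex per block;
    ``snps_per_block`` sets the block width in SNPs (wide enough to encode
    the haplotype count).  Variances are per random term; the seed is
    mandatory so every run is reproducible.
    """

    seed: int
    q: int = 200
    spectra: tuple[tuple[float, ...], ...] = ((0.4, 0.3, 0.2, 0.1),)
    snps_per_block: int | None = None
    sigma2: dict[str, float] = field(default_factory=lambda: {"additive": 1.0})
    sigma2_e: float = 1.0
    fixed_effects: tuple[float, ...] = (0.0,)
    pedigree: str = "unrelated"  # unrelated | parent-offspring | full-sib | half-sib

    def __post_init__(self):
        for name, v in self.sigma2.items():
            if v < 0:
                raise ValueError(f"sigma2[{name}] must be nonnegative")
        if self.sigma2_e < 0:
            raise ValueError("sigma2_e must be nonnegative")
        for s in self.spectra:
            arr = np.asarray(s, dtype=float)
            if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-8:
                raise ValueError(f"invalid haplotype frequency simplex {s}")


def _haplotype_strings(h: int, n_snps: int | None) -> np.ndarray:
    """Distinct 0/1 SNP strings for h haplotype alleles."""
    width = max(int(np.ceil(np.log2(max(h, 2)))), 1)
    if n_snps is not None:
        if 2**n_snps < h:
            raise ValueError(f"{n_snps} SNPs cannot encode {h} haplotypes")
        width = n_snps
    codes = np.array(
        [[(a >> b) & 1 for b in range(width - 1, -1, -1)] for a in range(h)],
        dtype=np.int8,
    )
    return codes


def simulate_haplotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[PhasedGenotypes, list[np.ndarray]]:
    """Draw a HWE population from the block haplotype-frequency spectra.

    Every individual receives two haplotypes per block, drawn independently
    from the block spectrum, so genotype frequencies are Hardy-Weinberg
    products by construction.  Returns the phased genotypes and the list of
    per-block SNP index arrays (the matching block plan).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    q = config.q
    blocks, parts = [], []
    start = 0
    for spec in config.spectra:
        p = np.asarray(spec, dtype=float)
        codes = _haplotype_strings(p.size, config.snps_per_block)
        draws = rng.choice(p.size, size=(q, 2), p=p)
        parts.append(codes[draws])  # (q, 2, width)
        blocks.append(np.arange(start, start + codes.shape[1]))
        start += codes.shape[1]
    hap = np.concatenate(parts, axis=2)
    samples = tuple(f"ind{i + 1}" for i in range(q))
    return PhasedGenotypes(haplotypes=hap, samples=samples), blocks


def _mendelian_child(
    father: np.ndarray, mother: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One offspring haplotype pair; unlinked loci, free recombination."""
    m = father.shape[1]
    pick_f = rng.integers(0, 2, size=m)
    pick_m = rng.integers(0, 2, size=m)
    return np.stack(
        [father[pick_f, np.arange(m)], mother[pick_m, np.arange(m)]]
    )


def simulate_pedigree(
    n_families: int,
    n_snps: int,
    design: str,
    seed: int,
    freq_range: tuple[float, float] = (0.1, 0.9),
) -> tuple[PhasedGenotypes, pd.DataFrame, np.ndarray]:
    """Founder couples plus Mendelian offspring at unlinked bi-allelic SNPs.

    Designs: 'parent-offspring' (one child per couple), 'full-sib' (two
    children per couple), 'half-sib' (one sire, two dams, one child each),
    'unrelated' (founders only).  Returns the genotypes, a table of labeled
    pairs (i, j, relation) for relationship averaging, and a boolean founder
    mask (the base population whose allele frequencies are unbiased).
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(*freq_range, size=n_snps)
    founders_per_family = 3 if design == "half-sib" else 2
    n_found = n_families * founders_per_family
    founders = (rng.random((n_found, 2, n_snps)) < p).astype(np.int8)
    haps = [founders]
    pairs = []
    children = []
    offset = n_found
    if design == "unrelated":
        for a in range(min(n_families, n_found - 1)):
            pairs.append((a, a + 1 if a + 1 < n_found else 0, "unrelated"))
    elif design == "parent-offspring":
        for fam in range(n_families):
            f, m = 2 * fam, 2 * fam + 1
            children.append(_mendelian_child(founders[f], founders[m], rng))
            child = offset + fam
            pairs.append((f, child, "parent-offspring"))
            pairs.append((m, child, "parent-offspring"))
    elif design == "full-sib":
        for fam in range(n_families):
            f, m = 2 * fam, 2 * fam + 1
            c1 = offset + 2 * fam
            c2 = offset + 2 * fam + 1
            children.append(_mendelian_child(founders[f], founders[m], rng))
            children.append(_mendelian_child(founders[f], founders[m], rng))
            pairs.append((c1, c2, "full-sib"))
    elif design == "half-sib":
        for fam in range(n_families):
            sire = 3 * fam
            d1, d2 = 3 * fam + 1, 3 * fam + 2
            c1 = offset + 2 * fam
            c2 = offset + 2 * fam + 1
            children.append(_mendelian_child(founders[sire], founders[d1], rng))
            children.append(_mendelian_child(founders[sire], founders[d2], rng))
            pairs.append((c1, c2, "half-sib"))
    else:
        raise ValueError(f"unknown pedigree design {design!r}")
    if children:
        haps.append(np.stack(children))
    hap = np.concatenate(haps, axis=0)
    samples = tuple(f"ind{i + 1}" for i in range(hap.shape[0]))
    founder_mask = np.zeros(hap.shape[0], dtype=bool)
    founder_mask[:n_found] = True
    labels = pd.DataFrame(pairs, columns=["i", "j", "relation"])
    return PhasedGenotypes(haplotypes=hap, samples=samples), labels, founder_mask


def simulate_phenotypes(
    terms: dict[str, np.ndarray],
    sigma2: dict[str, float],
    sigma2_e: float,
    seed: int,
    X: np.ndarray | None = None,
    b: np.ndarray | None = None,
    Z: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Phenotypes under y = X b + Z (sum_i T_i tau_i) + e.

    ``terms`` maps a term name to its scaled coding matrix T_i (q x t_i);
    effects tau_i are iid N(0, sigma2_i) and residuals N(0, sigma2_e).
    Returns (y, true tau per term, true u per term) for recovery scoring.
    """
    rng = np.random.default_rng(seed)
    first = next(iter(terms.values()))
    q = first.shape[0]
    N = q if Z is None else Z.shape[0]
    if X is None:
        X = np.ones((N, 1))
        b = np.zeros(1) if b is None else np.asarray(b, dtype=float)
    elif b is None:
        raise ValueError("b is required when X is supplied")
    genetic = np.zeros(q)
    tau_true: dict[str, np.ndarray] = {}
    u_true: dict[str, np.ndarray] = {}
    for name, T in terms.items():
        tau = rng.normal(0.0, np.sqrt(sigma2[name]), size=T.shape[1])
        tau_true[name] = tau
        u_true[name] = T @ tau
        genetic = genetic + u_true[name]
    g = genetic if Z is None else Z @ genetic
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=N)
    y = X @ np.asarray(b, dtype=float) + g + e
    return y, tau_true, u_true
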