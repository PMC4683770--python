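"""Closed-form genetic partition of a multi-allelic locus.

A haplotype block is treated as one locus whose distinct haplotypes are the
alleles.  Under Hardy-Weinberg equilibrium the genotypic value of every
unordered allele pair splits into a common mean, an additive (breeding) value
and a dominance deviation,

    g_ij = mu + a_ij + d_ij,

where the additive value is a linear function of the h - 1 independent
substitution effects alpha_1k (allele 1 = reference allele) and the dominance
value is a linear function of the up-to h(h-1)/2 heterozygote dominance
effects delta_kf.  This module computes the effects, the values, the
allele-frequency coding matrices W_alpha / W_delta that factorize them
(a = W_alpha @ alpha, d = W_delta @ delta), and the orthogonal variance
partition sigma2_g = sigma2_a + sigma2_d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "LocusSpec",
    "PartitionResult",
    "allele_frequencies",
    "allelic_means",
    "population_mean",
    "additive_effects",
    "dominance_effects",
    "additive_coding",
    "dominance_coding",
    "heterozygote_pairs",
    "genotype_order",
    "locus_coding_matrices",
    "partition_locus",
    "load_worked_example",
]

_SIMPLEX_ATOL = 1e-8


def heterozygote_pairs(h: int) -> list[tuple[int, int]]:
    """Lexicographically ordered unordered heterozygote pairs (k < f)."""
    return [(k, f) for k in range(h - 1) for f in range(k + 1, h)]


def genotype_order(h: int) -> list[tuple[int, int]]:
    """Canonical genotype listing: homozygotes first, then heterozygotes.

    Matches the conventional presentation of the h(h+1)/2 possible genotypes
    of an h-allele locus: (0,0), (1,1), ..., then (0,1), (0,2), ...
    """
    return [(i, i) for i in range(h)] + heterozygote_pairs(h)


@dataclass(frozen=True)
class LocusSpec:
    """One multi-allelic locus: allele frequencies and genotypic values.

    Parameters
    ----------
    p : array of shape (h,)
        Allele frequencies; nonnegative, summing to 1.
    g : array of shape (h, h)
        Genotypic value of each unordered allele pair; must be symmetric.
        ``nan`` marks a missing genotypic value.
    ref_allele : int, optional
        Index of the reference allele.  Defaults to the most frequent allele,
        ties broken by the smallest index.
    labels : sequence of str, optional
        Allele names (e.g. haplotype strings), for reporting only.
    """

    p: np.ndarray
    g: np.ndarray
    ref_allele: int = -1
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("p must be a 1-D frequency vector")
        if np.any(p < -_SIMPLEX_ATOL) or abs(p.sum() - 1.0) > _SIMPLEX_ATOL:
            raise ValueError(
                f"allele frequencies must be nonnegative and sum to 1, got {p}"
            )
        h = p.size
        if g.shape != (h, h):
            raise ValueError(f"g must be {h} x {h}, got {g.shape}")
        both = ~np.isnan(g) & ~np.isnan(g.T)
        if not np.allclose(g[both], g.T[both]):
            raise ValueError("g must be symmetric")
        g = np.where(np.isnan(g), g.T, g)  # symmetrize one-sided entries
        ref = self.ref_allele
        if ref < 0:
            ref = int(np.argmax(p))  # argmax takes the smallest index on ties
        elif ref >= h:
            raise ValueError(f"ref_allele {ref} out of range for h={h}")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "ref_allele", int(ref))

    @property
    def h(self) -> int:
        return self.p.size


def allele_frequencies(genotype_frequencies: np.ndarray) -> np.ndarray:
    """Allele frequencies from a symmetric genotype-frequency table.

    p_i = P_ii + (1/2) * sum_{j != i} P_ij, where ``P`` holds the frequency
    of the unordered genotype A_i A_j split symmetrically across (i, j) and
    (j, i) for heterozygotes (so that ``P`` sums to 1).
    """
    P = np.asarray(genotype_frequencies, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("genotype frequencies must form a square matrix")
    if not np.allclose(P, P.T):
        raise ValueError("genotype frequencies must be symmetric")
    if np.any(P < -_SIMPLEX_ATOL):
        raise ValueError("genotype frequencies must be nonnegative")
    if abs(P.sum() - 1.0) > _SIMPLEX_ATOL:
        raise ValueError(f"genotype frequencies must sum to 1, got {P.sum()}")
    # cell (i,j) holds half the unordered heterozygote frequency, so
    # P_ii + (1/2) sum_{j != i} (unordered P_ij) is exactly the row sum
    return P.sum(axis=1)


def _require_row(spec: LocusSpec, i: int) -> None:
    missing = np.isnan(spec.g[i]) & (spec.p > 0)
    if np.any(missing):
        j = int(np.nonzero(missing)[0][0])
        raise ValueError(
            f"genotypic value g[{i},{j}] is missing but required for the "
            f"allelic mean of allele {i}"
        )


def allelic_means(spec: LocusSpec) -> np.ndarray:
    """HWE allelic means mu_i = sum_j p_j g_ij."""
    out = np.empty(spec.h)
    for i in range(spec.h):
        _require_row(spec, i)
        gi = np.where(spec.p > 0, spec.g[i], 0.0)
        out[i] = float(gi @ spec.p)
    return out


def population_mean(spec: LocusSpec) -> float:
    """HWE population mean mu = sum_ij p_i p_j g_ij = sum_k p_k mu_k."""
    mu_i = allelic_means(spec)
    return float(mu_i @ spec.p)


def additive_effects(spec: LocusSpec) -> np.ndarray:
    """Substitution effects alpha_{ref,k} = mu_ref - mu_k, non-ref k ascending.

    Returns an empty vector for a monomorphic locus (h = 1).  Any other
    substitution effect alpha_ij is recoverable as alpha_{ref,j} - alpha_{ref,i}.
    """
    if spec.h == 1:
        return np.empty(0)
    mu_i = allelic_means(spec)
    others = [k for k in range(spec.h) if k != spec.ref_allele]
    return mu_i[spec.ref_allele] - mu_i[others]


def dominance_effects(spec: LocusSpec) -> np.ndarray:
    """Dominance effects delta_kf = g_kf - (g_kk + g_ff)/2 for pairs k < f.

    A pair with any of the three required genotypic values missing is flagged
    ``nan`` rather than raising: such pairs carry no estimable dominance
    effect and are dropped from dominance coding downstream.
    """
    pairs = heterozygote_pairs(spec.h)
    out = np.full(len(pairs), np.nan)
    g = spec.g
    for idx, (k, f) in enumerate(pairs):
        if not (np.isnan(g[k, f]) or np.isnan(g[k, k]) or np.isnan(g[f, f])):
            out[idx] = g[k, f] - 0.5 * (g[k, k] + g[f, f])
    return out


def additive_coding(i: int, j: int, k: int, p: np.ndarray, ref_allele: int) -> float:
    """Coefficient of substitution effect alpha_{ref,k} for genotype (i, j).

    2 p_k when the genotype does not carry allele k; -(1 - 2 p_k) when the
    heterozygote carries one copy of k; -2 (1 - p_k) for the k homozygote.
    """
    if k == ref_allele:
        raise ValueError("effect allele k must differ from the reference allele")
    pk = float(p[k])
    carries = int(i == k) + int(j == k)  # int(): numpy bools OR under '+'
    if carries == 0:
        return 2.0 * pk
    if carries == 1:
        return -(1.0 - 2.0 * pk)
    return -2.0 * (1.0 - pk)


def dominance_coding(i: int, j: int, k: int, f: int, p: np.ndarray) -> float:
    """Coefficient of dominance effect delta_kf for genotype (i, j).

    Five cases by how many alleles genotype and effect pair share: both
    alleles, one allele (heterozygous or homozygous genotype), or none.
    """
    if k == f:
        raise ValueError("dominance effect requires two distinct alleles k < f")
    shared = {i, j} & {k, f}
    if {i, j} == {k, f}:
        pi, pj = float(p[i]), float(p[j])
        return 1.0 - pi * (1.0 - pj) - pj * (1.0 - pi)
    if len(shared) == 1:
        s = shared.pop()
        non = f if s == k else k
        ps, pn = float(p[s]), float(p[non])
        if i == j:  # homozygote for the shared allele
            return -2.0 * pn * (1.0 - ps)
        return -pn * (1.0 - 2.0 * ps)
    return 2.0 * float(p[k]) * float(p[f])


def locus_coding_matrices(
    spec: LocusSpec, genotypes: list[tuple[int, int]] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """W_alpha and W_delta rows for the given genotypes (default: all).

    Columns of W_alpha follow the non-reference alleles in ascending index
    order; columns of W_delta follow lexicographic heterozygote pairs.
    Dominance columns for pairs whose effect is inestimable (missing
    genotypic value) are still produced here; callers drop them as needed.
    """
    h, p, ref = spec.h, spec.p, spec.ref_allele
    if genotypes is None:
        genotypes = genotype_order(h)
    alpha_cols = [k for k in range(h) if k != ref]
    delta_cols = heterozygote_pairs(h)
    W_a = np.empty((len(genotypes), len(alpha_cols)))
    W_d = np.empty((len(genotypes), len(delta_cols)))
    for r, (i, j) in enumerate(genotypes):
        for c, k in enumerate(alpha_cols):
            W_a[r, c] = additive_coding(i, j, k, p, ref)
        for c, (k, f) in enumerate(delta_cols):
            W_d[r, c] = dominance_coding(i, j, k, f, p)
    return W_a, W_d


@dataclass(frozen=True)
class PartitionResult:
    """Full additive/dominance partition of one locus.

    ``a_values`` and ``d_values`` are symmetric h x h matrices indexed by the
    unordered genotype (i, j); ``alpha`` follows non-reference alleles in
    ascending order and ``delta`` the lexicographic heterozygote pairs (nan
    for pairs with missing genotypic values).
    """

    spec: LocusSpec
    mu: float
    mu_i: np.ndarray
    alpha: np.ndarray
    delta: np.ndarray
    a_values: np.ndarray
    d_values: np.ndarray
    var_g: float
    var_a: float
    var_d: float

    def a_vector(self) -> np.ndarray:
        """Additive values in canonical genotype order (homozygotes first)."""
        return np.array([self.a_values[i, j] for i, j in genotype_order(self.spec.h)])

    def d_vector(self) -> np.ndarray:
        """Dominance values in canonical genotype order (homozygotes first)."""
        return np.array([self.d_values[i, j] for i, j in genotype_order(self.spec.h)])


def partition_locus(spec: LocusSpec, rtol: float = 1e-9) -> PartitionResult:
    """Partition all genotypic values of a locus into mu + a + d.

    The additive and dominance values are computed twice — directly from the
    allelic means (a_ij = (mu_i - mu) + (mu_j - mu), d_ij = g_ij - mu - a_ij)
    and through the factorizations a = W_alpha @ alpha, d = W_delta @ delta —
    and the two routes are required to agree to relative tolerance ``rtol``.
    """
    h = spec.h
    mu_i = allelic_means(spec)
    mu = float(mu_i @ spec.p)
    alpha = additive_effects(spec)
    delta = dominance_effects(spec)

    ai = mu_i - mu  # allelic effects
    a_vals = ai[:, None] + ai[None, :]
    d_vals = spec.g - mu - a_vals

    if h > 1:
        order = genotype_order(h)
        W_a, W_d = locus_coding_matrices(spec, order)
        a_fact = W_a @ alpha
        a_direct = np.array([a_vals[i, j] for i, j in order])
        scale = max(np.max(np.abs(a_direct)), 1.0)
        if not np.allclose(a_fact, a_direct, rtol=rtol, atol=rtol * scale):
            raise AssertionError("additive factorization disagrees with direct values")
        if not np.any(np.isnan(delta)):
            d_fact = W_d @ delta
            d_direct = np.array([d_vals[i, j] for i, j in order])
            scale = max(np.max(np.abs(d_direct)), 1.0)
            if not np.allclose(d_fact, d_direct, rtol=rtol, atol=rtol * scale):
                raise AssertionError(
                    "dominance factorization disagrees with direct values"
                )

    pp = np.outer(spec.p, spec.p)
    valid = ~np.isnan(spec.g)
    if valid.all():
        var_g = float(np.sum(pp * spec.g**2) - mu**2)
        var_d = float(np.sum(pp * d_vals**2))
    else:  # undefined with missing values
        var_g = np.nan
        var_d = np.nan
    var_a = float(np.sum(pp * a_vals**2))
    return PartitionResult(
        spec=spec,
        mu=mu,
        mu_i=mu_i,
        alpha=alpha,
        delta=delta,
        a_values=a_vals,
        d_values=d_vals,
        var_g=var_g,
        var_a=var_a,
        var_d=var_d,
    )


def load_worked_example() -> LocusSpec:
    """The packaged four-haplotype example locus (frequencies + values)."""
    pkg = resources.files("haploblup.data")
    freq_lines = (pkg / "worked_example_frequencies.tsv").read_text().strip().split("\n")
    labels, p = [], []
    for line in freq_lines[1:]:
        name, f = line.split("\t")
        labels.append(name)
        p.append(float(f))
    h = len(p)
    g = np.full((h, h), np.nan)
    value_lines = (pkg / "worked_example_values.tsv").read_text().strip().split("\n")
    for line in value_lines[1:]:
        i, j, v = line.split("\t")
        g[int(i) - 1, int(j) - 1] = float(v)
        g[int(j) - 1, int(i) - 1] = float(v)
    return LocusSpec(p=np.array(p), g=g, labels=tuple(labels))
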