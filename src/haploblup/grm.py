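"""Genome-wide coding matrices and genomic relationship matrices.

Each haplotype block of phased SNPs is one multi-allelic locus.  The
encoders build, for every individual, the allele-frequency coding rows of
the single-locus partition (see :mod:`haploblup.partition`) concatenated
across blocks: W_alpha (q x n_alpha) for additive effects and W_delta
(q x n_delta) for dominance effects.  Scaling T = W / sqrt(k), with k the
average diagonal of W W', yields relationship matrices A = T T' and
D = T T' whose diagonals average exactly 1.

`HaplotypeEncoder` and `SNPEncoder` follow the scikit-learn transformer
protocol: `fit` learns the haplotype catalogs and allele frequencies from a
training population, `transform` codes any population (e.g. a validation
set) against that training catalog — alleles unseen in training are
projected onto the reference allele, which carries zero information.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .partition import additive_coding, dominance_coding

__all__ = [
    "PhasedGenotypes",
    "BlockPlan",
    "BlockCatalog",
    "CodingMatrices",
    "GRMSet",
    "HaplotypeEncoder",
    "SNPEncoder",
    "enumerate_haplotypes",
    "build_W",
    "build_snp_W",
    "relationship_matrix",
    "scale_and_relate",
    "cross_relationship",
]


@dataclass(frozen=True)
class PhasedGenotypes:
    """Phased bi-allelic genotypes: q individuals x 2 haplotypes x m SNPs."""

    haplotypes: np.ndarray  # (q, 2, m) array of 0/1 allele codes
    samples: tuple[str, ...]
    positions: np.ndarray | None = None  # 1-based SNP positions
    chromosomes: tuple[str, ...] | None = None

    def __post_init__(self):
        hap = np.asarray(self.haplotypes, dtype=np.int8)
        if hap.ndim != 3 or hap.shape[1] != 2:
            raise ValueError("haplotypes must have shape (q, 2, m)")
        if not np.isin(hap, (0, 1)).all():
            raise ValueError("haplotype alleles must be coded 0/1 (bi-allelic)")
        if len(self.samples) != hap.shape[0]:
            raise ValueError("sample count does not match haplotype array")
        object.__setattr__(self, "haplotypes", hap)
        object.__setattr__(self, "samples", tuple(self.samples))

    @property
    def q(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def m(self) -> int:
        return self.haplotypes.shape[2]


@dataclass(frozen=True)
class BlockPlan:
    """Haplotype-block definitions: ordered SNP indices per block."""

    blocks: tuple[np.ndarray, ...]
    names: tuple[str, ...] | None = None
    allow_overlap: bool = False

    def __post_init__(self):
        blocks = tuple(np.asarray(b, dtype=np.intp) for b in self.blocks)
        names = self.names or tuple(f"block{i + 1}" for i in range(len(blocks)))
        if len(names) != len(blocks):
            raise ValueError("block names do not match block count")
        if not self.allow_overlap:
            seen: set[int] = set()
            for b in blocks:
                overlap = seen.intersection(b.tolist())
                if overlap:
                    raise ValueError(
                        f"blocks overlap at SNP index {min(overlap)}; "
                        "pass allow_overlap=True to permit this"
                    )
                seen.update(b.tolist())
        object.__setattr__(self, "blocks", blocks)
        object.__setattr__(self, "names", tuple(names))

    @property
    def r(self) -> int:
        return len(self.blocks)

    def validate_for(self, geno: PhasedGenotypes) -> None:
        for name, b in zip(self.names, self.blocks):
            if b.size and (b.min() < 0 or b.max() >= geno.m):
                raise ValueError(f"{name}: SNP index out of range (m={geno.m})")


@dataclass(frozen=True)
class BlockCatalog:
    """Observed alleles of one block with sample frequencies and assignments."""

    name: str
    strings: tuple[str, ...]  # canonical (lexicographic) haplotype strings
    frequencies: np.ndarray  # (h,)
    ref_allele: int  # most frequent; ties -> smallest index
    pairs: np.ndarray  # (q, 2) unordered allele-index pairs, i <= j

    @property
    def h(self) -> int:
        return len(self.strings)


def _block_strings(geno: PhasedGenotypes, snps: np.ndarray) -> np.ndarray:
    """(q, 2) array of haplotype strings over the given SNPs."""
    sub = geno.haplotypes[:, :, snps]  # (q, 2, len)
    flat = sub.reshape(geno.q * 2, -1)
    return np.array(["".join(map(str, row)) for row in flat]).reshape(geno.q, 2)


def enumerate_haplotypes(
    geno: PhasedGenotypes, plan: BlockPlan
) -> list[BlockCatalog]:
    """Catalog the distinct haplotypes of every block.

    Haplotype 'alleles' are ordered by canonical string sort; frequencies are
    haplotype counts over the 2q observed chromosomes; every individual is
    assigned its unordered allele-index pair per block.
    """
    plan.validate_for(geno)
    catalogs = []
    for name, snps in zip(plan.names, plan.blocks):
        strings = _block_strings(geno, snps)
        alleles, counts = np.unique(strings, return_counts=True)
        index = {s: i for i, s in enumerate(alleles)}
        freqs = counts / (2 * geno.q)
        pairs = np.sort(
            np.array(
                [[index[a], index[b]] for a, b in strings], dtype=np.intp
            ),
            axis=1,
        )
        catalogs.append(
            BlockCatalog(
                name=name,
                strings=tuple(alleles),
                frequencies=freqs,
                ref_allele=int(np.argmax(freqs)),
                pairs=pairs,
            )
        )
    return catalogs


@dataclass(frozen=True)
class CodingMatrices:
    """Concatenated coding matrices with per-column provenance.

    ``alpha_columns`` holds (block_name, allele_index) per W_alpha column and
    ``delta_columns`` (block_name, k, f) per W_delta column; ``block_slices``
    maps each block name to its column slice of W_alpha / W_delta, which is
    what per-block heritability partitions consume.
    """

    W_alpha: np.ndarray
    W_delta: np.ndarray
    alpha_columns: tuple[tuple[str, int], ...]
    delta_columns: tuple[tuple[str, int, int], ...]
    samples: tuple[str, ...]
    alpha_slices: dict[str, slice] = field(default_factory=dict)
    delta_slices: dict[str, slice] = field(default_factory=dict)


class HaplotypeEncoder(TransformerMixin, BaseEstimator):
    """Code phased genotypes into haplotype W_alpha / W_delta matrices.

    Parameters
    ----------
    plan : BlockPlan
        Haplotype block definitions over the SNP indices.
    frequencies : dict, optional
        Supplied allele frequencies, mapping block name to a
        {haplotype string: frequency} dict.  Default: estimated from the
        training sample (haplotype counts / 2q).

    Attributes
    ----------
    catalogs_ : list of BlockCatalog
        Training haplotype catalogs (alleles, frequencies, ref allele).
    n_alpha_, n_delta_ : int
        Total additive / dominance column counts across blocks.
    n_projected_ : int
        Alleles in the last `transform` call that were unseen in training
        and projected onto the reference allele.
    """

    def __init__(
        self,
        plan: BlockPlan | None = None,
        frequencies: dict[str, dict[str, float]] | None = None,
    ):
        self.plan = plan
        self.frequencies = frequencies

    def fit(self, X: PhasedGenotypes, y=None):
        if self.plan is None:
            raise ValueError("a BlockPlan is required")
        self.catalogs_ = enumerate_haplotypes(X, self.plan)
        if self.frequencies:
            replaced = []
            for cat in self.catalogs_:
                if cat.name not in self.frequencies:
                    replaced.append(cat)
                    continue
                given = self.frequencies[cat.name]
                unknown = set(given) - set(cat.strings)
                if unknown:
                    raise ValueError(
                        f"{cat.name}: supplied frequency for unobserved "
                        f"haplotype(s) {sorted(unknown)}"
                    )
                freqs = np.array([given.get(s, 0.0) for s in cat.strings])
                if abs(freqs.sum() - 1.0) > 1e-8 or np.any(freqs < 0):
                    raise ValueError(f"{cat.name}: supplied frequencies invalid")
                replaced.append(
                    BlockCatalog(
                        name=cat.name,
                        strings=cat.strings,
                        frequencies=freqs,
                        ref_allele=int(np.argmax(freqs)),
                        pairs=cat.pairs,
                    )
                )
            self.catalogs_ = replaced
        # one dominance column per heterozygote pair observed in training
        self.delta_pairs_ = [
            sorted({(i, j) for i, j in map(tuple, cat.pairs) if i != j})
            for cat in self.catalogs_
        ]
        self.n_alpha_ = sum(max(cat.h - 1, 0) for cat in self.catalogs_)
        self.n_delta_ = sum(len(p) for p in self.delta_pairs_)
        return self

    def _assign(self, cat: BlockCatalog, geno: PhasedGenotypes, snps) -> tuple[np.ndarray, int]:
        strings = _block_strings(geno, snps)
        index = {s: i for i, s in enumerate(cat.strings)}
        projected = 0
        pairs = np.empty((geno.q, 2), dtype=np.intp)
        for r, (a, b) in enumerate(strings):
            ia = index.get(a)
            ib = index.get(b)
            if ia is None:
                ia = cat.ref_allele
                projected += 1
            if ib is None:
                ib = cat.ref_allele
                projected += 1
            pairs[r] = sorted((ia, ib))
        return pairs, projected

    def transform(self, X: PhasedGenotypes) -> CodingMatrices:
        if not hasattr(self, "catalogs_"):
            raise RuntimeError("encoder is not fitted")
        q = X.q
        Wa_parts, Wd_parts = [], []
        alpha_cols: list[tuple[str, int]] = []
        delta_cols: list[tuple[str, int, int]] = []
        alpha_slices, delta_slices = {}, {}
        self.n_projected_ = 0
        for cat, pairs_obs, snps in zip(
            self.catalogs_, self.delta_pairs_, self.plan.blocks
        ):
            assigned, projected = self._assign(cat, X, snps)
            if projected:
                self.n_projected_ += projected
                warnings.warn(
                    f"{cat.name}: {projected} haplotype(s) unseen in training "
                    "projected onto the reference allele",
                    stacklevel=2,
                )
            # coding covers every genotype seen now; only training
            # heterozygote pairs become dominance columns
            h, ref = cat.h, cat.ref_allele
            a_cols = [k for k in range(h) if k != ref]
            W_a = np.empty((q, len(a_cols)))
            W_d = np.empty((q, len(pairs_obs)))
            geno_rows: dict[tuple[int, int], int] = {}
            genos = sorted({tuple(p) for p in map(tuple, assigned)})
            lut_a = np.empty((len(genos), len(a_cols)))
            lut_d = np.empty((len(genos), len(pairs_obs)))
            for r, (i, j) in enumerate(genos):
                geno_rows[(i, j)] = r
                for c, k in enumerate(a_cols):
                    lut_a[r, c] = additive_coding(i, j, k, cat.frequencies, ref)
                for c, (k, f) in enumerate(pairs_obs):
                    lut_d[r, c] = dominance_coding(i, j, k, f, cat.frequencies)
            rows = np.array([geno_rows[tuple(p)] for p in map(tuple, assigned)])
            W_a = lut_a[rows]
            W_d = lut_d[rows]
            alpha_slices[cat.name] = slice(
                len(alpha_cols), len(alpha_cols) + len(a_cols)
            )
            delta_slices[cat.name] = slice(
                len(delta_cols), len(delta_cols) + len(pairs_obs)
            )
            alpha_cols += [(cat.name, k) for k in a_cols]
            delta_cols += [(cat.name, k, f) for k, f in pairs_obs]
            Wa_parts.append(W_a)
            Wd_parts.append(W_d)
        W_alpha = np.hstack(Wa_parts) if Wa_parts else np.empty((q, 0))
        W_delta = np.hstack(Wd_parts) if Wd_parts else np.empty((q, 0))
        return CodingMatrices(
            W_alpha=W_alpha,
            W_delta=W_delta,
            alpha_columns=tuple(alpha_cols),
            delta_columns=tuple(delta_cols),
            samples=X.samples,
            alpha_slices=alpha_slices,
            delta_slices=delta_slices,
        )


class SNPEncoder(TransformerMixin, BaseEstimator):
    """Code phased genotypes into single-SNP W_alpha / W_delta matrices.

    Each SNP is the two-allele special case of the multi-allelic coding: with
    p the frequency of the effect (minor) allele and c its dosage, additive
    codes are {2p, -(1-2p), -2(1-p)} for c = 0, 1, 2 and dominance codes are
    {-2p^2, 2p(1-p), -2(1-p)^2}.  Monomorphic SNPs contribute zero columns.
    """

    def fit(self, X: PhasedGenotypes, y=None):
        dosage_alt = X.haplotypes.sum(axis=1)  # copies of allele '1'
        p_alt = dosage_alt.mean(axis=0) / 2
        # reference allele = the more frequent allele (ties -> allele '0')
        self.effect_is_alt_ = p_alt <= 0.5
        self.p_effect_ = np.where(self.effect_is_alt_, p_alt, 1 - p_alt)
        return self

    def transform(self, X: PhasedGenotypes) -> CodingMatrices:
        if not hasattr(self, "p_effect_"):
            raise RuntimeError("encoder is not fitted")
        dosage_alt = X.haplotypes.sum(axis=1)
        c = np.where(self.effect_is_alt_, dosage_alt, 2 - dosage_alt)
        p = self.p_effect_
        W_a = np.choose(c, [2 * p, -(1 - 2 * p), -2 * (1 - p)])
        W_d = np.choose(c, [-2 * p**2, 2 * p * (1 - p), -2 * (1 - p) ** 2])
        poly = p > 0
        W_a = np.where(poly, W_a, 0.0)
        W_d = np.where(poly, W_d, 0.0)
        names = tuple(f"snp{i + 1}" for i in range(X.m))
        return CodingMatrices(
            W_alpha=W_a.astype(float),
            W_delta=W_d.astype(float),
            alpha_columns=tuple((n, 1) for n in names),
            delta_columns=tuple((n, 0, 1) for n in names),
            samples=X.samples,
            alpha_slices={n: slice(i, i + 1) for i, n in enumerate(names)},
            delta_slices={n: slice(i, i + 1) for i, n in enumerate(names)},
        )


def build_W(geno: PhasedGenotypes, plan: BlockPlan) -> CodingMatrices:
    """Fit a `HaplotypeEncoder` on ``geno`` and code the same population."""
    return HaplotypeEncoder(plan=plan).fit(geno).transform(geno)


def build_snp_W(geno: PhasedGenotypes) -> CodingMatrices:
    """Fit a `SNPEncoder` on ``geno`` and code the same population."""
    return SNPEncoder().fit(geno).transform(geno)


def relationship_matrix(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Scaled relationship matrix T T' with T = W / sqrt(k).

    k is the average diagonal of W W', so the returned matrix has mean
    diagonal exactly 1.  Raises on an all-zero W (no polymorphism).
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] == 0:
        raise ValueError("W must have at least one column")
    k = float(np.mean(np.sum(W**2, axis=1)))
    if k == 0.0:
        raise ValueError("W is all zero: no polymorphism to relate")
    return (W @ W.T) / k, k


@dataclass(frozen=True)
class GRMSet:
    """Genomic relationship matrices with their scale constants."""

    samples: tuple[str, ...]
    A_h: np.ndarray | None = None
    D_h: np.ndarray | None = None
    A_s: np.ndarray | None = None
    D_s: np.ndarray | None = None
    k_alpha_h: float | None = None
    k_delta_h: float | None = None
    k_alpha_s: float | None = None
    k_delta_s: float | None = None
    provenance: str = ""


def _provenance(coding: CodingMatrices) -> str:
    tag = hashlib.sha256(
        repr((coding.alpha_columns, coding.delta_columns)).encode()
    ).hexdigest()[:12]
    return f"columns-sha256:{tag}"


def scale_and_relate(
    coding: CodingMatrices, snp_coding: CodingMatrices | None = None
) -> GRMSet:
    """Relationship matrices from haplotype (and optional SNP) coding."""
    A_h, k_ah = relationship_matrix(coding.W_alpha)
    D_h = k_dh = None
    if coding.W_delta.shape[1] and np.any(coding.W_delta):
        D_h, k_dh = relationship_matrix(coding.W_delta)
    A_s = D_s = k_as = k_ds = None
    if snp_coding is not None:
        A_s, k_as = relationship_matrix(snp_coding.W_alpha)
        if snp_coding.W_delta.shape[1] and np.any(snp_coding.W_delta):
            D_s, k_ds = relationship_matrix(snp_coding.W_delta)
    return GRMSet(
        samples=coding.samples,
        A_h=A_h,
        D_h=D_h,
        A_s=A_s,
        D_s=D_s,
        k_alpha_h=k_ah,
        k_delta_h=k_dh,
        k_alpha_s=k_as,
        k_delta_s=k_ds,
        provenance=_provenance(coding),
    )


def cross_relationship(
    W_validation: np.ndarray, W_training: np.ndarray, k: float
) -> np.ndarray:
    """Training/validation relationship S_01 = T_0 T' using the training k."""
    if W_validation.shape[1] != W_training.shape[1]:
        raise ValueError("validation coding must use the training columns")
    if k <= 0:
        raise ValueError("scale constant k must be positive")
    return (W_validation @ W_training.T) / k
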