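# Methods

## Model and assumptions

A haplotype block is an ordered set of phased bi-allelic SNPs; each distinct
phased allele string observed in the block is one 'allele' of a
multi-allelic locus (exact string identity, no mismatch tolerance).  All
means, effects and variances are defined under Hardy–Weinberg equilibrium:
genotype frequencies are products of allele frequencies, and that product
measure is the weight in every expectation.  The partition of a genotypic
value is

- allelic mean: μ_i = Σ_j p_j g_ij, population mean μ = Σ_i p_i μ_i;
- substitution effects: α_1k = μ_1 − μ_k for k ≠ 1, with allele 1 the
  reference (most frequent) allele; any α_ij = α_1j − α_1i;
- breeding value: a_ij = (μ_i − μ) + (μ_j − μ);
- dominance effect: δ_kf = g_kf − ½(g_kk + g_ff), defined for heterozygote
  pairs only (δ_ii ≡ 0 and is never stored);
- dominance deviation: d_ij = g_ij − μ − a_ij (may be nonzero for
  homozygotes).

Both a and d factorize linearly in the effects.  The additive coefficient
of α_1k for genotype (i,j) is 2p_k (k not carried), −(1 − 2p_k) (one copy)
or −2(1 − p_k) (homozygote kk); the dominance coefficient of δ_kf is one of
five allele-sharing cases ranging from 1 − p_i(1 − p_j) − p_j(1 − p_i)
(same pair) to 2p_k p_f (no shared allele).  `partition_locus` computes the
values by both routes — the allelic-mean definitions and W·effects — and
requires agreement at 1e−9 relative tolerance, so the factorization
identity is asserted on every call, not just in tests.

The single-SNP coding is exactly the h = 2 special case with the minor
allele as effect allele, giving the familiar {2p, −(1−2p), −2(1−p)}
additive and {−2p², 2p(1−p), −2(1−p)²} dominance codes.

## Relationship matrices and the mixed model

With per-individual coding rows concatenated across blocks into W_α
(q × n_α) and W_δ (q × n_δ), the scaling T = W/√k with
k = mean diag(W W′) makes the mean diagonal of A = T_α T_α′ and
D = T_δ T_δ′ exactly 1.  Only this one scaling is implemented.  Frequencies
default to training-sample haplotype counts / 2q; a frequency table may be
supplied instead (e.g. base-population or reference-panel frequencies).
Validation individuals are coded against the training catalog and training
frequencies; a haplotype unseen in training carries no estimable effect and
is projected onto the reference allele with a warning (a zero-information
default).  Dominance columns exist for every heterozygote pair observed in
the training population — the number of dominance effects equals the number
of observed heterozygous genotypes — and pairs whose effect is inestimable
from a genotypic-value table (any missing value among g_kf, g_kk, g_ff) are
flagged missing rather than fatal.

GBLUP is computed by either of two equivalent routes. CE:
b̂ = (X′V⁻¹X)⁻X′V⁻¹y, P = V⁻¹ − V⁻¹X(X′V⁻¹X)⁻X′V⁻¹, ε_i = σ²_i Z′Py,
û_i = S_i ε_i, with validation predictions û_i0 = S_i01 ε_i.  QM: the
Henderson system with ridge blocks λ_i = σ²_e/σ²_i solved for (b̂, τ̂),
û_i = T_i τ̂_i and û_i0 = T_i0 τ̂_i.  Route auto-selection follows the size
of the largest system to factorize: CE when q < c + Σ t_i, QM otherwise.

EM-REML iterates, per term, σ²_i ← σ²_i·y′PZS_iZ′Py / tr(PZS_iZ′) and
σ²_e ← σ²_e·y′PPy / tr(P) (CE), or σ²_i ← τ̂_i′τ̂_i/[t_i − tr(C^ii)λ_i] and
σ²_e ← ê′ê/{N − [r − Σ tr(C^ii)λ_i]} (QM), where C^ii are diagonal blocks
of the inverse absorbed coefficient matrix and r the numerical rank of the
full coefficient matrix.  The two sequences are algebraically identical
(the package tests per-iteration identity), and every update is a product
of nonnegative factors, so estimates never leave the parameter space.  The
REML log-likelihood is computed on the CE route for monitoring and is
non-decreasing across iterations.

## Numerical choices

- Generalized inverses: Moore–Penrose pseudo-inverse with relative cutoff
  1e−10 wherever a g-inverse appears (X′V⁻¹X, the MME coefficient matrix).
- V and the absorbed MME matrix H are solved by Cholesky factorization;
  explicit inversion is avoided except where traces of inverse blocks are
  themselves needed (EM updates).  H is positive definite for λ > 0, and
  using the factorization rather than a spectral pseudo-inverse keeps the
  CE and QM iterate sequences identical even when a component approaches
  the zero boundary and λ becomes very large.
- Convergence: maximum relative change in any component < 1e−8, cap
  10,000 iterations (both configurable); components floored at
  1e−12·var(y) to keep λ finite.  t_i in the QM denominators is the effect
  count of term i (the expression specializes to the SNP count m only for
  SNP terms); the residual-update bracket is used exactly as written and
  validated against the unambiguous CE route.
- Starting values: equal split of the phenotypic variance across all
  components plus residual, unless supplied.
- Single-genetic-term models with one record per individual run the CE
  iteration in the eigenbasis of the term's relationship matrix: one
  symmetric eigendecomposition, O(q) per iteration afterwards.  This is an
  exact reformulation (verified against the dense path to 1e−10), and is
  what makes the q = 500 recovery suite run in seconds.
- Reference allele: most frequent, ties broken by smallest index after
  canonical (lexicographic) haplotype-string sort.  Monomorphic blocks are
  legal and contribute zero columns.
- Coordinates: BED is 0-based half-open, VCF 1-based; a SNP at position P
  falls in [start, end) iff start < P ≤ end.  The conversion lives in one
  routine (`plan_blocks`) with its own tests.
- AI-REML is not implemented: EM only, trading speed for guaranteed
  nonnegative estimates.  No standard errors of components are reported
  (they would require observed-information machinery).

## What the simulator emulates

`simulate_haplotypes` draws two haplotypes per individual independently
from per-block frequency spectra, so Hardy–Weinberg proportions hold by
construction; `simulate_pedigree` adds Mendelian transmission at unlinked
bi-allelic SNPs for parent-offspring, full-sib, half-sib and unrelated
designs; `simulate_phenotypes` builds y = Xb + Z Σ T_i τ_i + e with iid
Gaussian effects at the stated variances.  Defaults mirror the worked
setting: the four-haplotype spectrum (0.4, 0.3, 0.2, 0.1) per block, unit
genetic and residual variances, pedigree SNP frequencies uniform on
0.1–0.9.

Deliberately not emulated: linkage disequilibrium between blocks or a
recombination map (loci are unlinked), selection, inbreeding, genotyping
error, and non-Gaussian effect architectures.  Passing tests therefore
demonstrate correctness of the algebra and the estimators under the model's
own assumptions, not robustness to LD structure or phasing error in real
data.

For the pedigree relationship checks the coding uses founder (base
population) allele frequencies — the convention under which the theoretical
expectations 0.5/0.25/0 (additive) and 0.25 (full-sib dominance) hold;
estimating frequencies from a sample that includes the related offspring
biases the means downward by O(1/q).  Problem sizes in the test suite
(200 founder couples × 5,000 SNPs for relationship expectations; q = 500,
20 replicates per heritability level for EM recovery; q ≤ 50 for the 20
route-equivalence datasets) were chosen as the smallest sizes at which the
Monte-Carlo standard errors make the checks sharp.

## Known limitations

- Input must be pre-phased; no phasing, imputation or LD-based block
  discovery is provided (blocks come from BED, a SNP count or a length).
- Haplotype relationship matrices are prediction devices, not estimates of
  pedigree relatedness: within-block recombination lowers haplotype
  sharing among relatives, so mean relationships shrink as blocks widen
  (the package tests this monotonicity).
- Large blocks make nearly every individual heterozygous, so dominance
  terms lose information (few observations per heterozygote class); block
  size should weigh this.
- Dense linear algebra throughout: practical up to a few thousand
  individuals and a few tens of thousands of effects.
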