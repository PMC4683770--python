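# haploblup

Haplotype-based genomic prediction and variance-component estimation for
quantitative genetics, built on the multi-allelic partition of genotypic
values.

Breeders and geneticists usually run GBLUP (genomic best linear unbiased
prediction) and GREML (genomic REML) on single bi-allelic SNPs. `haploblup`
treats each *haplotype block* of phased SNPs as one multi-allelic locus
whose distinct haplotypes are the alleles, so that blocks defined from
functional annotation (genes, regulatory regions) or simple windowing rules
can carry joint local-allele effects that single-SNP models miss. Haplotype
and single-SNP terms can be fitted jointly in the same mixed model.

## The model

For a locus with h alleles at frequencies p_i and genotypic values g_ij,
every genotypic value partitions orthogonally under Hardy–Weinberg
equilibrium as

    g_ij = μ + a_ij + d_ij ,        σ²_g = σ²_a + σ²_d ,

where the breeding value a_ij = a_i + a_j is a linear function of the h − 1
substitution effects α_1k = μ_1 − μ_k (allele 1 = reference), and the
dominance deviation d_ij is a linear function of the heterozygote dominance
effects δ_kf = g_kf − ½(g_kk + g_ff).  Stacking genotypes gives the
factorizations **a** = W_α **α** and **d** = W_δ **δ**, with W entries that
are simple functions of allele frequencies (e.g. the coefficient of α_1k is
2p_k, −(1 − 2p_k) or −2(1 − p_k) for genotypes carrying 0, 1 or 2 copies of
allele k).  Scaling T = W/√k with k the mean diagonal of WW′ yields genomic
relationship matrices A = T_α T_α′ and D = T_δ T_δ′ with unit mean diagonal.

The mixed model y = Xb + Z Σᵢ Tᵢτᵢ + e is solved two equivalent ways:

* **CE** (conditional expectation): through V = Z(Σ σ²ᵢ Sᵢ)Z′ + σ²_e I and
  the REML projection P; tolerates singular relationship matrices, cheap
  when individuals are few.
* **QM** (mixed-model equations): Henderson system at the effect level with
  ridge blocks λᵢ = σ²_e/σ²ᵢ; cheap when effects are fewer than
  individuals, no relationship-matrix inverse needed.

Both routes give identical GBLUP and identical EM-REML iterate sequences;
the package tests this to 1e−6 and routinely observes machine-precision
agreement.  Heritabilities are h²ᵢ = σ²ᵢ/σ²_y with per-block shares
h²ᵢⱼ = (τ̂ᵢⱼ′τ̂ᵢⱼ/τ̂ᵢ′τ̂ᵢ)·h²ᵢ.

## Worked example

The packaged example locus has four haplotype alleles with frequencies
0.4/0.3/0.2/0.1 and ten genotypic values (g₁₁ = 25, g₁₂ = 18, …, g₄₄ = 35):

```python
from haploblup import load_worked_example, partition_locus

res = partition_locus(load_worked_example())
print(res.mu)          # 22.09
print(res.alpha)       # [-7.4 -1.1 -2.5]
print(res.delta)       # [ -9.5  -6. -20.   9.5   7.5 -14.]
print(res.a_vector())  # [-5.38  9.42 -3.18 -0.38  2.02 -4.28 -2.88  3.12  4.52 -1.78]
print(res.d_vector())  # [ 8.29 -1.51 -1.91 13.29 -6.11 -2.81 -9.21  7.79 13.39 -8.31]
print(res.var_g, res.var_a, res.var_d)  # 71.0419 20.1178 50.9241
```

μ is the population mean; the α vector holds the three substitution effects
of alleles 2–4 against allele 1; the δ vector the six heterozygote
dominance effects; `a_vector`/`d_vector` list breeding values and dominance
deviations per genotype (homozygotes first), which sum with μ back to the
genotypic values exactly; the variances show the orthogonal partition
σ²_g = σ²_a + σ²_d.

The same output prints from the command line with `haploblup partition`.
Other subcommands: `haploblup simulate` (HWE population + phenotypes +
truth), `haploblup grm` (relationship matrices from a phased VCF and a
block rule: `--bed`, `--snps-per-block` or `--block-length`),
`haploblup predict` (GBLUP; individuals with missing phenotype become the
validation set) and `haploblup reml` (EM-GREML components and
heritabilities).

## Library API

Estimators follow scikit-learn conventions: `HaplotypeEncoder` /
`SNPEncoder` are fitted on a training population and `transform` any
population against the training haplotype catalog and frequencies;
`GBLUP(method="auto")` and `EMREML()` fit a `ModelSpec` and expose
`b_`, `u_`, `g_`, `sigma2_`, `h2_`, `converged_`.

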