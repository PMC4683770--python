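"""Haplotype/SNP coding matrices and genomic relationship matrices."""

import numpy as np
import pytest

from haploblup import (
    BlockPlan,
    HaplotypeEncoder,
    LocusSpec,
    PhasedGenotypes,
    SNPEncoder,
    build_snp_W,
    build_W,
    cross_relationship,
    enumerate_haplotypes,
    locus_coding_matrices,
    relationship_matrix,
    scale_and_relate,
)
from haploblup.simulate import simulate_haplotypes, simulate_pedigree
from haploblup import SimulationConfig

from conftest import EXAMPLE_P

# W matrices of the four-haplotype example locus, rows in genotype order
# (homozygotes 11..44, then heterozygotes 12..34).
EXAMPLE_W_ALPHA = np.array(
    [
        [0.6, 0.4, 0.2],
        [-1.4, 0.4, 0.2],
        [0.6, -1.6, 0.2],
        [0.6, 0.4, -1.8],
        [-0.4, 0.4, 0.2],
        [0.6, -0.6, 0.2],
        [0.6, 0.4, -0.8],
        [-0.4, -0.6, 0.2],
        [-0.4, 0.4, -0.8],
        [0.6, -0.6, -0.8],
    ]
)
EXAMPLE_W_DELTA = np.array(
    [
        [-0.36, -0.24, -0.12, 0.12, 0.06, 0.04],
        [-0.56, 0.16, 0.08, -0.28, -0.14, 0.04],
        [0.24, -0.64, 0.08, -0.48, 0.06, -0.16],
        [0.24, 0.16, -0.72, 0.12, -0.54, -0.36],
        [0.54, -0.04, -0.02, -0.08, -0.04, 0.04],
        [-0.06, 0.56, -0.02, -0.18, 0.06, -0.06],
        [-0.06, -0.04, 0.58, 0.12, -0.24, -0.16],
        [-0.16, -0.24, 0.08, 0.62, -0.04, -0.06],
        [-0.16, 0.16, -0.32, -0.08, 0.66, -0.16],
        [0.24, -0.24, -0.32, -0.18, -0.24, 0.74],
    ]
)


def _tiny_population():
    """Four hand-listed individuals over one 2-SNP block."""
    hap = np.array(
        [
            [[0, 0], [0, 1]],
            [[0, 1], [0, 1]],
            [[1, 0], [0, 0]],
            [[0, 0], [0, 0]],
        ],
        dtype=np.int8,
    )
    return PhasedGenotypes(haplotypes=hap, samples=("a", "b", "c", "d"))


class TestEnumeration:
    def test_hand_tally(self):
        geno = _tiny_population()
        plan = BlockPlan(blocks=(np.array([0, 1]),))
        (cat,) = enumerate_haplotypes(geno, plan)
        # canonical sort: 00 < 01 < 10; counts 4, 3, 1 over 8 chromosomes
        assert cat.strings == ("00", "01", "10")
        assert np.allclose(cat.frequencies, [0.5, 0.375, 0.125])
        assert cat.ref_allele == 0
        assert cat.pairs.tolist() == [[0, 1], [1, 1], [0, 2], [0, 0]]

    def test_three_haplotypes_frequencies_sum_to_one(self):
        geno = _tiny_population()
        (cat,) = enumerate_haplotypes(geno, BlockPlan(blocks=(np.array([0, 1]),)))
        assert cat.h == 3 and cat.frequencies.sum() == pytest.approx(1.0)

    def test_monomorphic_block(self):
        hap = np.zeros((5, 2, 3), dtype=np.int8)
        geno = PhasedGenotypes(haplotypes=hap, samples=tuple("abcde"))
        (cat,) = enumerate_haplotypes(geno, BlockPlan(blocks=(np.arange(3),)))
        assert cat.h == 1 and cat.frequencies[0] == 1.0

    def test_out_of_range_block_rejected(self):
        geno = _tiny_population()
        with pytest.raises(ValueError, match="out of range"):
            enumerate_haplotypes(geno, BlockPlan(blocks=(np.array([0, 5]),)))

    def test_overlapping_blocks_need_flag(self):
        with pytest.raises(ValueError, match="overlap"):
            BlockPlan(blocks=(np.array([0, 1]), np.array([1, 2])))
        plan = BlockPlan(
            blocks=(np.array([0, 1]), np.array([1, 2])), allow_overlap=True
        )
        assert plan.r == 2


class TestBuildW:
    def test_exact_hwe_population_reproduces_locus_coding(self, hwe_population):
        """One row per genotype of the worked locus equals the printed W."""
        geno, plan = hwe_population
        coding = build_W(geno, plan)
        # first occurrence of each of the 10 genotypes, in genotype order
        (cat,) = enumerate_haplotypes(geno, plan)
        rows = []
        for gpair in [(0, 0), (1, 1), (2, 2), (3, 3), (0, 1), (0, 2), (0, 3),
                      (1, 2), (1, 3), (2, 3)]:
            rows.append(int(np.nonzero((cat.pairs == gpair).all(axis=1))[0][0]))
        assert np.allclose(cat.frequencies, EXAMPLE_P)
        assert np.allclose(coding.W_alpha[rows], EXAMPLE_W_ALPHA)
        assert np.allclose(coding.W_delta[rows], EXAMPLE_W_DELTA)

    def test_monomorphic_block_contributes_no_columns(self):
        hap = np.zeros((4, 2, 2), dtype=np.int8)
        hap[:, :, 1] = np.array([[0, 1], [1, 1], [0, 0], [0, 1]])
        geno = PhasedGenotypes(haplotypes=hap, samples=tuple("abcd"))
        plan = BlockPlan(blocks=(np.array([0]), np.array([1])))
        coding = build_W(geno, plan)
        assert coding.alpha_slices["block1"] == slice(0, 0)
        assert coding.W_alpha.shape[1] == 1

    def test_dominance_columns_only_for_observed_heterozygotes(self):
        geno = _tiny_population()
        coding = build_W(geno, BlockPlan(blocks=(np.array([0, 1]),)))
        # observed heterozygote pairs: (00,01) and (00,10)
        assert coding.delta_columns == (("block1", 0, 1), ("block1", 0, 2))

    def test_unseen_validation_allele_projected_with_warning(self):
        geno = _tiny_population()
        enc = HaplotypeEncoder(plan=BlockPlan(blocks=(np.array([0, 1]),))).fit(geno)
        novel = PhasedGenotypes(
            haplotypes=np.array([[[1, 1], [0, 0]]], dtype=np.int8), samples=("v",)
        )
        with pytest.warns(UserWarning, match="unseen in training"):
            coding = enc.transform(novel)
        ref_row = enc.transform(
            PhasedGenotypes(
                haplotypes=np.array([[[0, 0], [0, 0]]], dtype=np.int8), samples=("r",)
            )
        )
        assert enc.n_projected_ == 0  # reset by the second transform
        assert np.allclose(coding.W_alpha[0], ref_row.W_alpha[0])

    def test_supplied_frequencies_override_sample_estimates(self):
        geno = _tiny_population()
        plan = BlockPlan(blocks=(np.array([0, 1]),))
        enc = HaplotypeEncoder(
            plan=plan,
            frequencies={"block1": {"00": 0.6, "01": 0.3, "10": 0.1}},
        ).fit(geno)
        assert np.allclose(enc.catalogs_[0].frequencies, [0.6, 0.3, 0.1])
        coding = enc.transform(geno)
        # homozygote 00/00 row: 2p for alleles 01 and 10
        assert np.allclose(coding.W_alpha[3], [0.6, 0.2])


class TestSNPCoding:
    def test_coding_values(self):
        # dosages of allele 1 at p_effect = 0.4: genotypes 0/0, 0/1, 1/1
        hap = np.array(
            [[[0], [0]], [[0], [1]], [[1], [1]], [[0], [1]], [[0], [0]]],
            dtype=np.int8,
        )
        geno = PhasedGenotypes(haplotypes=hap, samples=tuple("abcde"))
        coding = build_snp_W(geno)
        p = 0.4
        assert coding.W_alpha[0, 0] == pytest.approx(2 * p)
        assert coding.W_alpha[1, 0] == pytest.approx(-(1 - 2 * p))
        assert coding.W_alpha[2, 0] == pytest.approx(-2 * (1 - p))

    def test_homozygote_effect_allele_at_half(self):
        hap = np.array([[[1], [1]], [[0], [0]]], dtype=np.int8)
        geno = PhasedGenotypes(haplotypes=hap, samples=("a", "b"))
        coding = build_snp_W(geno)
        assert abs(coding.W_alpha[0, 0]) == pytest.approx(1.0)  # -2(1-0.5)

    def test_matches_partition_coding_on_two_allele_locus(self):
        """SNP coding equals the h = 2 special case of the locus coding."""
        hap = np.array(
            [[[0], [0]]] * 5 + [[[0], [1]]] * 4 + [[[1], [1]]] * 1, dtype=np.int8
        )
        geno = PhasedGenotypes(
            haplotypes=hap, samples=tuple(f"s{i}" for i in range(10))
        )
        coding = build_snp_W(geno)
        p_eff = 6 / 20  # allele '1' frequency
        spec = LocusSpec(
            p=np.array([1 - p_eff, p_eff]), g=np.zeros((2, 2)), ref_allele=0
        )
        W_a, W_d = locus_coding_matrices(spec, [(0, 0), (0, 1), (1, 1)])
        assert coding.W_alpha[0, 0] == pytest.approx(W_a[0, 0])
        assert coding.W_alpha[5, 0] == pytest.approx(W_a[1, 0])
        assert coding.W_alpha[9, 0] == pytest.approx(W_a[2, 0])
        assert coding.W_delta[0, 0] == pytest.approx(W_d[0, 0])
        assert coding.W_delta[5, 0] == pytest.approx(W_d[1, 0])
        assert coding.W_delta[9, 0] == pytest.approx(W_d[2, 0])

    def test_monomorphic_snp_zero_column(self):
        hap = np.zeros((3, 2, 2), dtype=np.int8)
        hap[0, 0, 1] = 1
        geno = PhasedGenotypes(haplotypes=hap, samples=("a", "b", "c"))
        coding = build_snp_W(geno)
        assert np.all(coding.W_alpha[:, 0] == 0)
        assert np.any(coding.W_alpha[:, 1] != 0)


class TestRelationships:
    def test_mean_diagonal_is_one(self):
        rng = np.random.default_rng(2)
        W = rng.normal(size=(7, 11))
        A, k = relationship_matrix(W)
        assert np.mean(np.diag(A)) == pytest.approx(1.0)
        assert k == pytest.approx(np.mean(np.sum(W**2, axis=1)))

    def test_toy_matrix_by_hand(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        A, k = relationship_matrix(W)
        assert k == pytest.approx(4 / 3)
        assert np.allclose(A, W @ W.T / (4 / 3))

    def test_duplicate_individuals_identical_rows(self):
        W = np.array([[0.5, -0.2, 1.0], [0.5, -0.2, 1.0], [0.1, 0.3, -0.4]])
        A, _ = relationship_matrix(W)
        assert np.allclose(A[0], A[1])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="polymorphism"):
            relationship_matrix(np.zeros((4, 3)))

    def test_psd_and_symmetric(self):
        cfg = SimulationConfig(seed=5, q=40, spectra=((0.4, 0.3, 0.2, 0.1),) * 4)
        geno, blocks = simulate_haplotypes(cfg)
        coding = build_W(geno, BlockPlan(blocks=tuple(blocks)))
        grms = scale_and_relate(coding, build_snp_W(geno))
        for M in (grms.A_h, grms.D_h, grms.A_s, grms.D_s):
            assert M is not None
            assert np.allclose(M, M.T)
            ev = np.linalg.eigvalsh(M)
            assert ev.min() >= -1e-8 * np.trace(M)
            assert np.mean(np.diag(M)) == pytest.approx(1.0)

    def test_single_snp_blocks_equal_snp_grm(self):
        """h = 2 one-SNP blocks give the same A as the SNP route."""
        cfg = SimulationConfig(
            seed=9, q=60, spectra=((0.7, 0.3), (0.55, 0.45), (0.9, 0.1)),
            snps_per_block=1,
        )
        geno, blocks = simulate_haplotypes(cfg)
        coding_h = build_W(geno, BlockPlan(blocks=tuple(blocks)))
        coding_s = build_snp_W(geno)
        A_h, _ = relationship_matrix(coding_h.W_alpha)
        A_s, _ = relationship_matrix(coding_s.W_alpha)
        assert np.allclose(A_h, A_s)


class TestCrossRelationship:
    def test_validation_equals_training(self):
        rng = np.random.default_rng(4)
        W = rng.normal(size=(6, 9))
        A, k = relationship_matrix(W)
        S01 = cross_relationship(W, W, k)
        assert np.allclose(S01, A)

    def test_duplicated_individual_row(self):
        rng = np.random.default_rng(5)
        W = rng.normal(size=(6, 9))
        A, k = relationship_matrix(W)
        S01 = cross_relationship(W[[2]], W, k)
        assert np.allclose(S01[0], A[2])

    def test_random_split_matches_direct_product(self):
        cfg = SimulationConfig(seed=13, q=30, spectra=((0.5, 0.3, 0.2),) * 3)
        geno, blocks = simulate_haplotypes(cfg)
        plan = BlockPlan(blocks=tuple(blocks))
        train = np.arange(20)
        val = np.arange(20, 30)
        sub = lambda idx: PhasedGenotypes(
            haplotypes=geno.haplotypes[idx],
            samples=tuple(np.array(geno.samples)[idx]),
        )
        enc = HaplotypeEncoder(plan=plan).fit(sub(train))
        Wt = enc.transform(sub(train)).W_alpha
        Wv = enc.transform(sub(val)).W_alpha
        _, k = relationship_matrix(Wt)
        S01 = cross_relationship(Wv, Wt, k)
        assert np.allclose(S01, Wv @ Wt.T / k)

    def test_column_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_relationship(np.ones((2, 3)), np.ones((4, 5)), 1.0)


class TestPedigreeExpectations:
    def test_block_size_lowers_haplotype_similarity(self):
        """Mean parent-offspring A_h does not increase with block width."""
        geno, pairs, founders = simulate_pedigree(60, 240, "parent-offspring", seed=42)
        means = []
        for width in (1, 2, 4):
            plan = BlockPlan(
                blocks=tuple(
                    np.arange(i, i + width) for i in range(0, 240, width)
                )
            )
            coding = build_W(geno, plan)
            A, _ = relationship_matrix(coding.W_alpha)
            means.append(
                np.mean([A[i, j] for i, j, _ in pairs.itertuples(index=False)])
            )
        assert means[0] >= means[1] - 0.02 >= means[2] - 0.04
        assert means[2] < means[0]
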