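"""F-statistics against direct transcriptions of the published formulas,
bootstrap behaviour, PCA and cluster reassignment."""
import numpy as np
import pytest

from conftest import genotype_matrix_from_dosages
from oracles import matching_beta, nei_stats_one_pop, wc84_components
from plastisel import (
    GenotypeSimConfig,
    assign_clusters,
    basic_stats,
    bootstrap_ci,
    pca_genotypes,
    popgen_report,
    population_specific_fst,
    sim_snp_genotypes,
    wc_pairwise_fst,
)
from plastisel.containers import MISSING
from plastisel.popgen import fst_bootstrap_statistic


def _pairs(dosages):
    return [(1, 1) if d == 2 else (0, 1) if d == 1 else (0, 0) for d in dosages]


class TestBasicStats:
    def test_textbook_single_locus_values(self):
        # {AA, Aa, Aa, aa}: Ho = 0.5, Hs = 7/12, FIS = 1/7
        gm = genotype_matrix_from_dosages([[0], [1], [1], [2]], populations=["p"] * 4)
        bs = basic_stats(gm)
        assert bs.ho[0] == pytest.approx(0.5)
        assert bs.hs[0] == pytest.approx(7 / 12)
        assert bs.fis[0] == pytest.approx(1 / 7)

    def test_all_heterozygotes_give_negative_fis(self):
        gm = genotype_matrix_from_dosages([[1], [1], [1], [1]], populations=["p"] * 4)
        bs = basic_stats(gm)
        assert bs.ho[0] == 1.0
        assert bs.fis[0] < 0

    def test_monomorphic_locus_excluded_from_fis(self):
        gm = genotype_matrix_from_dosages([[0, 1], [0, 1], [0, 0], [0, 2]], populations=["p"] * 4)
        bs = basic_stats(gm)
        # FIS driven by the polymorphic locus only
        ho1, hs1 = nei_stats_one_pop(_pairs([1, 1, 0, 2]))
        assert bs.fis[0] == pytest.approx(1 - ho1 / hs1)

    def test_matches_loop_oracle_with_missing_data(self):
        rng = np.random.default_rng(11)
        dos = rng.integers(0, 3, size=(12, 10))
        dos[rng.random(dos.shape) < 0.15] = MISSING
        gm = genotype_matrix_from_dosages(dos, populations=["p"] * 12)
        bs = basic_stats(gm)
        ho_l, hs_l = [], []
        for j in range(10):
            col = dos[:, j][dos[:, j] != MISSING]
            ho, hs = nei_stats_one_pop(_pairs(col))
            ho_l.append(ho)
            hs_l.append(hs)
        assert bs.ho[0] == pytest.approx(np.mean(ho_l), abs=1e-12)
        assert bs.hs[0] == pytest.approx(np.mean(hs_l), abs=1e-12)

    def test_single_individual_population_errors(self):
        gm = genotype_matrix_from_dosages([[1], [1]], populations=["a", "b"])
        with pytest.raises(ValueError):
            basic_stats(gm)


class TestWcFst:
    def test_fixed_difference_gives_theta_one(self):
        dos = np.array([[0]] * 4 + [[2]] * 4)
        gm = genotype_matrix_from_dosages(dos, populations=["a"] * 4 + ["b"] * 4)
        assert wc_pairwise_fst(gm).theta == pytest.approx(1.0)

    def test_identical_samples_give_nonpositive_theta(self):
        block = np.array([[0], [1], [1], [2]])
        gm = genotype_matrix_from_dosages(np.vstack([block, block]), populations=["a"] * 4 + ["b"] * 4)
        assert wc_pairwise_fst(gm).theta <= 0

    def test_componentwise_equality_with_loop_oracle(self):
        rng = np.random.default_rng(5)
        dos = rng.integers(0, 3, size=(20, 10))
        pops = ["a"] * 12 + ["b"] * 8
        gm = genotype_matrix_from_dosages(dos, populations=pops)
        res = wc_pairwise_fst(gm)
        a_o = abc_o = 0.0
        for j in range(10):
            a, b, c = wc84_components([_pairs(dos[:12, j]), _pairs(dos[12:, j])])
            assert res.a_by_locus[j] == pytest.approx(a, abs=1e-12)
            assert res.abc_by_locus[j] == pytest.approx(a + b + c, abs=1e-12)
            a_o += a
            abc_o += a + b + c
        assert res.theta == pytest.approx(a_o / abc_o, abs=1e-12)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        # one high-information locus (fixed difference), one low-information
        dos = np.array([[0, 1], [0, 1], [0, 0], [0, 1], [2, 1], [2, 0], [2, 1], [2, 1]])
        gm = genotype_matrix_from_dosages(dos, populations=["a"] * 4 + ["b"] * 4)
        res = wc_pairwise_fst(gm)
        per_locus = res.theta_by_locus()
        mean_of_ratios = np.nanmean(per_locus)
        ratio_of_sums = np.nansum(res.a_by_locus) / np.nansum(res.abc_by_locus)
        assert abs(mean_of_ratios - ratio_of_sums) > 1e-3
        assert res.theta == pytest.approx(ratio_of_sums)

    def test_invariance_to_allele_relabeling_and_individual_order(self):
        rng = np.random.default_rng(6)
        dos = rng.integers(0, 3, size=(16, 30))
        pops = np.array(["a"] * 8 + ["b"] * 8)
        gm = genotype_matrix_from_dosages(dos, populations=pops)
        theta = wc_pairwise_fst(gm).theta
        flipped = genotype_matrix_from_dosages(2 - dos, populations=pops)
        assert wc_pairwise_fst(flipped).theta == pytest.approx(theta, abs=1e-12)
        perm = rng.permutation(16)
        shuffled = genotype_matrix_from_dosages(dos[perm], populations=pops[perm])
        assert wc_pairwise_fst(shuffled).theta == pytest.approx(theta, abs=1e-12)

    def test_monomorphic_everywhere_errors(self):
        gm = genotype_matrix_from_dosages(np.zeros((8, 4), dtype=int), populations=["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError):
            wc_pairwise_fst(gm)


class TestPopulationSpecificFst:
    def test_fixed_populations_give_beta_one(self):
        dos = np.array([[0]] * 4 + [[2]] * 4)
        gm = genotype_matrix_from_dosages(dos, populations=["a"] * 4 + ["b"] * 4)
        res = population_specific_fst(gm)
        assert res.beta == pytest.approx([1.0, 1.0])

    def test_identical_populations_give_beta_near_zero(self):
        block = np.array([[0, 1], [1, 2], [1, 0], [2, 1]])
        gm = genotype_matrix_from_dosages(np.vstack([block, block]), populations=["a"] * 4 + ["b"] * 4)
        res = population_specific_fst(gm)
        assert np.all(np.abs(res.beta) < 0.15)

    def test_overall_is_mean_of_per_population_betas(self, two_pop_snps):
        gm, _ = two_pop_snps
        res = population_specific_fst(gm)
        assert res.overall == pytest.approx(res.beta.mean())

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        dos = rng.integers(0, 3, size=(14, 6))
        gm = genotype_matrix_from_dosages(dos, populations=["a"] * 7 + ["b"] * 7)
        res = population_specific_fst(gm)
        loci = [[_pairs(dos[:7, j]), _pairs(dos[7:, j])] for j in range(6)]
        expected = matching_beta(loci)
        assert res.beta == pytest.approx(expected, abs=1e-12)


class TestBootstrap:
    def test_constant_statistic_zero_width_and_seed_determinism(self):
        ci1 = bootstrap_ci(lambda idx: 0.5, 100, n_boot=200, seed=4)
        assert ci1.lower == ci1.upper == 0.5
        stat = lambda idx: float(np.mean(idx))
        a = bootstrap_ci(stat, 100, n_boot=200, seed=4)
        b = bootstrap_ci(stat, 100, n_boot=200, seed=4)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_too_many_undefined_replicates_error(self):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda idx: np.nan, 50, n_boot=100, seed=1)

    def test_snp_scale_fst_ci_is_narrow(self):
        gm, _ = sim_snp_genotypes(GenotypeSimConfig(n_loci=5000, theta_background=0.023, seed=77))
        res = wc_pairwise_fst(gm)
        ci = bootstrap_ci(fst_bootstrap_statistic(res), gm.n_loci, n_boot=300, seed=77)
        assert ci.upper - ci.lower < 0.01
        assert ci.lower < res.theta < ci.upper


class TestPcaAndClusters:
    def test_pc1_separates_diverged_populations(self):
        gm, _ = sim_snp_genotypes(GenotypeSimConfig(n_loci=800, theta_background=0.3, seed=12))
        pca = pca_genotypes(gm)
        pc1 = pca.scores[:, 0]
        assert (pc1[:16].mean() - pc1[16:].mean()) ** 2 > 4 * (pc1[:16].var() + pc1[16:].var())
        assert np.all(np.diff(pca.variance_explained) <= 1e-12)
        assert pca.variance_explained.sum() <= 1 + 1e-9

    def test_duplicated_individual_identical_scores(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(10, 40))
        dos[1] = dos[0]
        gm = genotype_matrix_from_dosages(dos)
        pca = pca_genotypes(gm)
        assert np.allclose(pca.scores[0], pca.scores[1], atol=1e-9)

    def test_kmeans_recovers_truth_and_clamps_pcs(self):
        gm, _ = sim_snp_genotypes(GenotypeSimConfig(n_loci=800, theta_background=0.3, seed=12))
        pca = pca_genotypes(gm)
        labels = assign_clusters(pca, k=2, n_pcs=75, seed=0)  # clamped to available
        first, second = labels[:16], labels[16:]
        assert len(set(first)) == 1 and len(set(second)) == 1 and first[0] != second[0]
        assert assign_clusters(pca, k=1, n_pcs=2, seed=0).tolist() == [1] * 32
        with pytest.raises(ValueError):
            assign_clusters(pca, k=33, n_pcs=2, seed=0)


def test_report_layout_and_ci_order(two_pop_snps):
    gm, _ = two_pop_snps
    rep = popgen_report(gm, n_boot=50, seed=2)
    assert set(rep.statistic) == {"Ho", "Hs", "FIS", "beta_fst", "pairwise_fst"}
    assert (rep.ci_low <= rep.ci_high).all()
    ho = rep[rep.statistic == "Ho"]
    assert ho.estimate.between(0, 1).all()
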