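import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ovinescan as ov
from ovinescan.popstats import wc_components

from conftest import make_dataset
from oracles import wc_anova_oracle


class TestMarkerDiversity:
    @pytest.mark.parametrize(
        "p, expected_gd, expected_pic",
        [
            (0.5, 0.5, 0.375),
            (0.0, 0.0, 0.0),
            (0.1, 0.18, 0.1638),
        ],
    )
    def test_closed_forms(self, p, expected_gd, expected_pic):
        gd, _, pic = ov.marker_diversity(p, n_het=0, n_called=10)
        assert gd == pytest.approx(expected_gd, abs=1e-12)
        assert pic == pytest.approx(expected_pic, abs=1e-12)

    def test_observed_heterozygosity_fraction(self):
        _, het, _ = ov.marker_diversity(0.5, n_het=3, n_called=12)
        assert het == 0.25

    def test_no_calls_rejected(self):
        with pytest.raises(ValueError):
            ov.marker_diversity(0.5, n_het=0, n_called=0)

    @settings(max_examples=200, derandomize=True)
    @given(p=st.floats(0.0, 1.0))
    def test_pic_never_exceeds_gene_diversity(self, p):
        assert ov.pic(p) <= ov.gene_diversity(p) + 1e-15

    def test_report_values_in_unit_interval(self, five_breed_dataset):
        rep = ov.breed_diversity_report(five_breed_dataset)
        assert len(rep) == 5
        for col in ("gene_diversity", "heterozygosity", "pic"):
            assert rep[col].between(0, 1).all()


class TestMafSpectrum:
    def test_identical_counts_give_zero_chisq(self):
        table = pd.DataFrame({"b1": [10, 20], "b2": [10, 20]}).T
        chi2, p = ov.maf_spectrum_chisq(table)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2(self):
        # (10,20 / 20,10): chi2 = 20/3 without continuity correction
        table = pd.DataFrame([[10, 20], [20, 10]], index=["a", "b"])
        chi2, _ = ov.maf_spectrum_chisq(table)
        assert chi2 == pytest.approx(20 / 3, rel=1e-12)

    def test_bins_partition_the_maf_range(self, five_breed_dataset):
        table = ov.maf_bin_counts(five_breed_dataset)
        aut = five_breed_dataset.is_autosomal().sum()
        assert (table.sum(axis=1) == aut).all()

    def test_bad_edges_rejected(self, five_breed_dataset):
        with pytest.raises(ValueError):
            ov.maf_bin_counts(five_breed_dataset, bin_edges=(0.0, 0.6))


class TestWeirCockerham:
    def test_fixed_difference_gives_one(self):
        g = np.vstack([np.full((8, 5), 2), np.zeros((8, 5))]).astype(np.int8)
        ds = make_dataset(g, breeds=["A"] * 8 + ["B"] * 8)
        assert ov.wc_pairwise_fst(ds, "A", "B") == pytest.approx(1.0)

    def test_panmictic_halves_near_zero(self, rng):
        thetas = []
        for _ in range(10):
            g = rng.binomial(2, rng.uniform(0.2, 0.8, 400), size=(40, 400)).astype(np.int8)
            ds = make_dataset(g, breeds=["A"] * 20 + ["B"] * 20)
            thetas.append(ov.wc_pairwise_fst(ds, "A", "B"))
        assert abs(np.mean(thetas)) < 0.01

    def test_components_match_anova_oracle(self, rng):
        for _ in range(25):
            blocks = [
                rng.integers(0, 3, size=int(rng.integers(4, 15)))
                for _ in range(int(rng.integers(2, 5)))
            ]
            a0, b0, c0 = wc_anova_oracle(blocks)
            n = np.array([[len(b)] for b in blocks], dtype=float)
            p = np.array([[b.mean() / 2] for b in blocks])
            h = np.array([[(b == 1).mean()] for b in blocks])
            a1, b1, c1 = wc_components(n, p, h)
            np.testing.assert_allclose([a1[0], b1[0], c1[0]], [a0, b0, c0], atol=1e-12)

    def test_theta_invariant_to_allele_flip_and_marker_order(self, two_breed_dataset):
        ds = two_breed_dataset
        theta = ov.wc_pairwise_fst(ds, "Suffolk", "Rambouillet")
        flipped = ds.genotypes.copy()
        miss = flipped == -1
        flipped = (2 - flipped).astype(np.int8)
        flipped[miss] = -1
        ds_flip = ov.GenotypeDataset(ds.samples, ds.markers, flipped)
        assert ov.wc_pairwise_fst(ds_flip, "Suffolk", "Rambouillet") == pytest.approx(theta)
        perm = np.random.default_rng(0).permutation(ds.n_markers)
        ds_perm = ds.take_markers(perm)
        assert ov.wc_pairwise_fst(ds_perm, "Suffolk", "Rambouillet") == pytest.approx(theta)

    @pytest.mark.parametrize("c", [0.05, 0.0681, 0.1621, 0.3])
    def test_theta_recovers_drift_parameter(self, c):
        thetas = []
        for seed in range(10):
            spec = ov.SimulationSpec(
                chrom_layout=ov.default_chrom_layout(4000, n_autosomes=10),
                populations=[("A", 18, c), ("B", 16, c)],
                seed=1000 + seed,
            )
            ds = ov.simulate(spec)
            thetas.append(ov.wc_pairwise_fst(ds, "A", "B"))
        se = np.std(thetas, ddof=1) / np.sqrt(len(thetas))
        assert abs(np.mean(thetas) - c) < 3 * max(se, 1e-4)


class TestGlobalFStatistics:
    def test_identical_populations_give_near_zero_fst(self, rng):
        # exact copies have zero between-group variance; the unbiased
        # moment estimator then sits slightly below zero (~ -1/(2n-2))
        block = rng.binomial(2, rng.uniform(0.2, 0.8, 300), size=(15, 300)).astype(np.int8)
        g = np.vstack([block, block, block])
        ds = make_dataset(g, breeds=["A"] * 15 + ["B"] * 15 + ["C"] * 15)
        fs = ov.global_f_statistics(ds)
        assert -0.06 < fs.f_st < 0.005

    def test_hwe_conformant_data_gives_near_zero_fis(self, rng):
        g = rng.binomial(2, rng.uniform(0.2, 0.8, 2000), size=(60, 2000)).astype(np.int8)
        ds = make_dataset(g, breeds=["A"] * 30 + ["B"] * 30)
        fs = ov.global_f_statistics(ds)
        assert abs(fs.f_is) < 0.02

    def test_f_statistic_identity_on_components(self, five_breed_dataset):
        fs = ov.global_f_statistics(five_breed_dataset)
        lhs = 1 - fs.f_it
        rhs = (1 - fs.f_is) * (1 - fs.f_st)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_five_breeds_at_study_drift_give_11_percent(self):
        shares = []
        for seed in range(5):
            spec = ov.SimulationSpec(
                chrom_layout=ov.default_chrom_layout(4000, n_autosomes=10),
                populations=[
                    ("Columbia", 19, 0.114), ("Polypay", 19, 0.114),
                    ("Rambouillet", 16, 0.114), ("Suffolk", 18, 0.114),
                    ("Targhee", 22, 0.114),
                ],
                seed=2000 + seed,
            )
            fs = ov.global_f_statistics(ov.simulate(spec))
            shares.append(fs.among_breed_share)
        assert round(100 * np.mean(shares)) == 11

    def test_single_breed_rejected(self, rng):
        ds = make_dataset(rng.integers(0, 3, (5, 10)).astype(np.int8))
        with pytest.raises(ValueError):
            ov.global_f_statistics(ds)


class TestPermutationTest:
    def test_fixed_difference_reaches_floor(self, rng):
        # groups large enough that no permutation reproduces the split
        g = np.vstack([np.full((10, 30), 2), np.zeros((10, 30))]).astype(np.int8)
        ds = make_dataset(g, breeds=["A"] * 10 + ["B"] * 10)
        p = ov.fst_permutation_test(ds, "A", "B", n_perm=199, rng=rng)
        assert p == pytest.approx(1 / 200)

    def test_null_labels_not_significant(self, rng):
        g = rng.binomial(2, rng.uniform(0.2, 0.8, 200), size=(30, 200)).astype(np.int8)
        ds = make_dataset(g, breeds=["A"] * 15 + ["B"] * 15)
        p = ov.fst_permutation_test(ds, "A", "B", n_perm=199, rng=rng)
        assert p > 0.05

    def test_differentiated_breeds_significant(self, two_breed_dataset, rng):
        p = ov.fst_permutation_test(
            two_breed_dataset, "Suffolk", "Rambouillet", n_perm=199, rng=rng
        )
        assert p == pytest.approx(1 / 200)

    def test_too_few_permutations_rejected(self, two_breed_dataset, rng):
        with pytest.raises(ValueError):
            ov.fst_permutation_test(two_breed_dataset, "Suffolk", "Rambouillet",
                                    n_perm=50, rng=rng)
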