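import numpy as np
import pytest
from scipy.optimize import curve_fit

import ovinescan as ov


class TestDrawPopulationFrequencies:
    def test_zero_drift_limit_concentrates_on_pi(self, rng):
        f = ov.draw_population_frequencies(0.5, 1e-6, 4, rng)
        np.testing.assert_allclose(f, 0.5, atol=0.01)

    def test_mean_recovers_pi(self, rng):
        f = ov.draw_population_frequencies(np.full(100_000, 0.3), 0.2, 1, rng)
        se = np.sqrt(0.2 * 0.3 * 0.7 / 100_000)
        assert abs(f.mean() - 0.3) < 3 * se

    def test_variance_recovers_c_pi_q(self, rng):
        c, pi = 0.1621, 0.5
        f = ov.draw_population_frequencies(np.full(100_000, pi), c, 1, rng)
        target = c * pi * (1 - pi)  # = 0.0405
        # SE of a variance estimate ~ sqrt(2/n) * var for near-normal; be generous
        assert abs(f.var() - target) < 0.002
        assert f.min() >= 0.0 and f.max() <= 1.0

    @pytest.mark.parametrize("pi", [0.0, 1.0])
    def test_degenerate_ancestral_frequency_rejected(self, pi, rng):
        with pytest.raises(ValueError):
            ov.draw_population_frequencies(pi, 0.1, 2, rng)


class TestSampleGenotypes:
    def test_fixed_frequencies_give_fixed_genotypes(self, rng):
        g = ov.sample_genotypes(np.ones((2, 5)), [3, 4], rng)
        assert (g == 2).all()
        g = ov.sample_genotypes(np.zeros((2, 5)), [3, 4], rng)
        assert (g == 0).all()

    def test_heterozygote_fraction_at_half(self, rng):
        g = ov.sample_genotypes(np.full((1, 10_000), 0.5), [1], rng)
        frac = (g == 1).mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_male_x_codes_are_hemizygous(self, rng):
        is_x = np.array([True, True, False])
        g = ov.sample_genotypes(
            np.full((1, 3), 0.5), [50], rng, is_x=is_x,
            is_male=np.ones(50, dtype=bool),
        )
        assert set(np.unique(g[:, :2])) <= {0, 2}


class TestLdHaplotypes:
    def test_infinite_decay_length_copies_perfectly(self, rng):
        pos = np.arange(1, 51) * 10_000
        freqs = np.full(50, 0.5)
        haps = ov.simulate_ld_haplotypes(freqs, pos, 2000, 1e15, rng)
        # every haplotype is constant along the chromosome
        assert (haps == haps[:, [0]]).all()

    def test_tiny_decay_length_gives_independence(self, rng):
        pos = np.arange(1, 51) * 10_000
        freqs = np.full(50, 0.5)
        haps = ov.simulate_ld_haplotypes(freqs, pos, 4000, 1e-3, rng)
        r = np.corrcoef(haps[:, 0], haps[:, 1])[0, 1]
        assert abs(r) < 0.05

    def test_marginal_frequencies_preserved(self, rng):
        pos = np.arange(1, 21) * 5_000
        freqs = np.linspace(0.2, 0.8, 20)
        haps = ov.simulate_ld_haplotypes(freqs, pos, 20_000, 50_000, rng)
        np.testing.assert_allclose(haps.mean(axis=0), freqs, atol=0.02)

    def test_fitted_decay_scale_matches_lambda(self, rng):
        # equal-frequency markers: allelic correlation is exactly exp(-d/L),
        # so r^2 between markers at distance d has mean exp(-2d/L)
        lam = 100_000.0
        pos = np.arange(1, 201) * 20_000
        freqs = np.full(200, 0.5)
        haps = ov.simulate_ld_haplotypes(freqs, pos, 30_000, lam, rng)
        dists, r2s = [], []
        for k in range(1, 15):
            r = [
                np.corrcoef(haps[:, i], haps[:, i + k])[0, 1] ** 2
                for i in range(0, 150, 10)
            ]
            dists.append(k * 20_000)
            r2s.append(np.mean(r))
        popt, _ = curve_fit(
            lambda d, scale: np.exp(-2 * d / scale),
            np.array(dists), np.array(r2s), p0=[50_000.0],
        )
        assert abs(popt[0] - lam) / lam < 0.15

    def test_non_positive_decay_length_rejected(self, rng):
        with pytest.raises(ValueError):
            ov.simulate_ld_haplotypes(np.array([0.5]), np.array([1]), 10, 0.0, rng)


class TestQcFixture:
    def test_all_zero_defects_retains_everything(self):
        layout = ov.QcFixtureLayout(n_total=500, n_x_total=50)
        ds = ov.build_qc_fixture(layout, seed=1)
        filtered, report = ov.run_qc(ds)
        assert report.n_removed == 0
        assert filtered.n_markers == 500

    def test_monomorphic_only_layout(self):
        layout = ov.QcFixtureLayout(n_total=100, n_monomorphic=10)
        ds = ov.build_qc_fixture(layout, seed=2)
        filtered, report = ov.run_qc(ds)
        assert report.removed_at("monomorphic") == 10
        assert filtered.n_markers == 90

    def test_infeasible_layout_rejected(self):
        with pytest.raises(ValueError):
            ov.QcFixtureLayout(n_total=10, n_monomorphic=20)
        with pytest.raises(ValueError):
            ov.QcFixtureLayout(n_total=100, n_x_total=5, n_x_male_het=6)

    def test_each_defect_class_lands_at_its_stage(self):
        layout = ov.QcFixtureLayout(
            n_total=600, n_all_missing=7, n_low_callrate=11, n_monomorphic=13,
            n_unmapped=5, n_low_maf=17, n_hwe_fail=19, n_x_total=40,
            n_x_male_het=6,
        )
        ds = ov.build_qc_fixture(layout, seed=3)
        _, report = ov.run_qc(ds)
        expected = {
            "all_missing": 7, "call_rate": 11, "monomorphic": 13,
            "unmapped": 5, "low_maf": 17, "hwe": 19, "x_male_het": 6,
        }
        assert {s: n for s, n, _ in report.stages} == expected


class TestPlantSignal:
    @pytest.fixture
    def base(self):
        spec = ov.SimulationSpec(
            chrom_layout=[("1", 200, 20_000_000), ("2", 200, 20_000_000)],
            populations=[("A", 20, 0.1), ("B", 20, 0.1)],
            seed=7,
        )
        return spec, ov.simulate(spec)

    def test_markers_outside_span_unchanged(self, base, rng):
        spec, ds = base
        sig = ov.PlantedSignal("1", 1_000_000, 3_000_000, elevated_c=0.9)
        planted = ov.plant_signal(ds, sig, spec, rng)
        outside = ~(
            (ds.markers["chrom"] == "1")
            & (ds.markers["pos"] >= 1_000_000)
            & (ds.markers["pos"] <= 3_000_000)
        ).to_numpy()
        np.testing.assert_array_equal(
            planted.genotypes[:, outside], ds.genotypes[:, outside]
        )

    def test_mean_fst_elevated_inside_span(self, base, rng):
        spec, ds = base
        sig = ov.PlantedSignal("1", 1, 20_000_000, elevated_c=0.9)
        inside = (ds.markers["chrom"] == "1").to_numpy()
        fst_in, fst_out = [], []
        for _ in range(5):
            planted = ov.plant_signal(ds, sig, spec, rng)
            track = ov.fst_track(planted, [["A"], ["B"]], with_fisher=False)
            by_chrom = track.groupby("chrom")["fst"].mean()
            fst_in.append(by_chrom["1"])
            fst_out.append(by_chrom["2"])
        assert np.mean(fst_in) > np.mean(fst_out) + 0.2

    def test_absent_chromosome_rejected(self, base, rng):
        spec, ds = base
        sig = ov.PlantedSignal("9", 1, 100, elevated_c=0.9)
        with pytest.raises(ValueError, match="not present"):
            ov.plant_signal(ds, sig, spec, rng)

    def test_elevated_c_not_above_background_rejected(self, base, rng):
        spec, ds = base
        sig = ov.PlantedSignal("1", 1, 20_000_000, elevated_c=0.05)
        with pytest.raises(ValueError, match="background"):
            ov.plant_signal(ds, sig, spec, rng)


class TestDeterminism:
    def test_same_seed_byte_identical_ped_map(self, tmp_path):
        spec = ov.SimulationSpec(
            chrom_layout=ov.default_chrom_layout(300, n_autosomes=3),
            populations=[("A", 5, 0.1), ("B", 6, 0.2)],
            missing_rate=0.02,
            seed=42,
        )
        for d in ("one", "two"):
            ov.write_prefix(ov.simulate(spec), tmp_path / d)
        assert (tmp_path / "one.ped").read_bytes() == (tmp_path / "two.ped").read_bytes()
        assert (tmp_path / "one.map").read_bytes() == (tmp_path / "two.map").read_bytes()
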