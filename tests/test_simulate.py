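"""Generators: ground-truth exactness, determinism, and sampling laws."""

import math

import numpy as np
import pandas as pd
import pytest

from dropscreen import simulate as sim


class TestDropletImage:
    @pytest.mark.parametrize("target", [0.0, 25.0, 84.0, 100.0])
    def test_rendered_occupancy_matches_target(self, spec_clean, target):
        _, truth = sim.generate_droplet_image(spec_clean, target, 8, seed=1)
        assert truth.occupancy_pct == pytest.approx(target, abs=0.5)
        assert truth.a_droplet_px - truth.a_ex_px == pytest.approx(
            target / 100 * truth.a_droplet_px, abs=0.5 / 100 * truth.a_droplet_px
        )

    def test_empty_droplet_has_no_cell_pixels(self, spec_clean):
        img, truth = sim.generate_droplet_image(spec_clean, 0.0, 5, seed=2)
        assert truth.occupancy_pct == 0.0
        assert truth.a_ex_px == truth.a_droplet_px
        # lumen is uniformly at background level
        assert (img.pixels == spec_clean.cell_level).sum() == pytest.approx(
            math.pi * (spec_clean.outer_radius_px**2 - spec_clean.lumen_radius_px**2),
            rel=0.2,
        )

    def test_full_droplet_lumen_all_cells(self, spec_clean):
        img, truth = sim.generate_droplet_image(spec_clean, 100.0, 5, seed=3)
        assert truth.occupancy_pct == 100.0
        assert truth.a_ex_px == 0.0

    def test_same_seed_bit_identical(self, spec_noisy):
        a, _ = sim.generate_droplet_image(spec_noisy, 40.0, 8, seed=9)
        b, _ = sim.generate_droplet_image(spec_noisy, 40.0, 8, seed=9)
        assert np.array_equal(a.pixels, b.pixels)

    def test_unreachable_occupancy_raises(self, spec_clean):
        with pytest.raises(sim.OccupancyUnreachableError):
            sim.generate_droplet_image(spec_clean, 50.0, 0, seed=0)
        # far more blobs than can be placed without overlap
        with pytest.raises(sim.OccupancyUnreachableError):
            sim.generate_droplet_image(spec_clean, 5.0, 500, seed=0)

    def test_target_out_of_range_raises(self, spec_clean):
        with pytest.raises(ValueError):
            sim.generate_droplet_image(spec_clean, 101.0, 5, seed=0)

    def test_droplet_must_fit_in_frame(self):
        with pytest.raises(ValueError, match="fit"):
            sim.ImageSpec(width_px=100, height_px=100, droplet_diameter_um=120)


class TestCalibrationSeries:
    def test_single_zero_od(self, spec_clean):
        series = sim.generate_calibration_series(spec_clean, [0.0], 40.0, seed=0)
        assert len(series) == 1
        assert series[0][1] == 0.0

    def test_occupancy_overflow_raises(self, spec_clean):
        with pytest.raises(ValueError, match="100"):
            sim.generate_calibration_series(spec_clean, [0.5, 3.0], 40.0, seed=0)

    def test_targets_linear_in_od(self, spec_clean):
        ods = [0.0, 0.5, 1.0, 1.5, 2.0]
        series = sim.generate_calibration_series(spec_clean, ods, 40.0, seed=0)
        assert [od for _, od in series] == ods


class TestScreenPopulation:
    def test_all_lambda_zero_all_empty(self, strains):
        scn = sim.ScreenScenario(
            n_droplets=2000, lambdas={"E_coli": 0.0}, seed=1
        )
        table = sim.generate_screen_population(scn, list(strains.values()))
        assert (table["n_E_coli"] == 0).all()
        # intensities are pure baseline draws: positive and right-skewed
        assert (table["intensity"] > 0).all()

    def test_poisson_moments(self, strains):
        lam, n = 0.314, 100_000
        scn = sim.ScreenScenario(
            n_droplets=n, lambdas={"P_mexicana": lam}, seed=4
        )
        counts = sim.generate_screen_population(
            scn, list(strains.values())
        )["n_P_mexicana"].to_numpy()
        se_mean = math.sqrt(lam / n)
        se_var = math.sqrt((lam + 3 * lam**2) / n)
        assert abs(counts.mean() - lam) < 3 * se_mean
        assert abs(counts.var() - lam) < 3 * se_var

    def test_occupied_fraction_at_unit_lambda(self, strains):
        scn = sim.ScreenScenario(
            n_droplets=100_000, lambdas={"E_coli": 1.0}, seed=5
        )
        table = sim.generate_screen_population(scn, list(strains.values()))
        frac = (table["n_E_coli"] >= 1).mean()
        assert frac == pytest.approx(1 - math.exp(-1), abs=0.005)

    def test_two_strain_empty_fraction(self, strains):
        scn = sim.ScreenScenario(
            n_droplets=100_000,
            lambdas={"P_mexicana": 0.250, "E_coli": 0.173},
            seed=6,
        )
        t = sim.generate_screen_population(scn, list(strains.values()))
        neither = ((t["n_P_mexicana"] == 0) & (t["n_E_coli"] == 0)).mean()
        assert neither == pytest.approx(math.exp(-0.423), abs=0.005)

    def test_same_seed_identical_table(self, strains):
        scn = sim.ScreenScenario(n_droplets=500, lambdas={"E_coli": 0.3}, seed=7)
        a = sim.generate_screen_population(scn, list(strains.values()))
        b = sim.generate_screen_population(scn, list(strains.values()))
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_strain_raises(self, strains):
        scn = sim.ScreenScenario(n_droplets=10, lambdas={"nope": 0.1}, seed=0)
        with pytest.raises(ValueError, match="unknown"):
            sim.generate_screen_population(scn, list(strains.values()))


class TestOtuTables:
    def test_column_sums_equal_depths(self):
        scn = sim.enrichment_split_scenario(depth=50_000, seed=3)
        pre, post = sim.generate_otu_tables(scn)
        assert pre.to_numpy().sum() == scn.depth_pre
        assert post.to_numpy().sum() == scn.depth_post

    def test_null_factors_give_unit_ratios_in_expectation(self):
        pre_ab = np.full(10, 0.1)
        scn = sim.EnrichmentScenario(
            pre_abundances=pre_ab, enrichment_factors=np.ones(10), seed=0
        )
        assert np.allclose(scn.expected_post_fractions, pre_ab)

    def test_all_zero_abundance_rejected(self):
        with pytest.raises(ValueError):
            sim.EnrichmentScenario(
                pre_abundances=np.zeros(3), enrichment_factors=np.ones(3)
            )

    def test_split_scenario_weighted_mean_factor_is_one(self):
        scn = sim.enrichment_split_scenario(seed=11)
        assert (scn.pre_abundances * scn.enrichment_factors).sum() == pytest.approx(
            1.0, abs=1e-9
        )
        assert (scn.enrichment_factors > 1).sum() == 45
        assert (scn.enrichment_factors < 1).sum() == 35

    def test_same_seed_identical(self):
        scn = sim.enrichment_split_scenario(depth=10_000, seed=8)
        a = sim.generate_otu_tables(scn)
        b = sim.generate_otu_tables(scn)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestGrowthSeries:
    def test_zero_growth_rate_constant(self):
        p = sim.StrainParams("flat", 0.0, 0.0, 0.5, 1.0, 0.0)
        s = sim.generate_growth_series(p, [0, 2, 4, 6, 8], 0.0, 0)
        assert np.allclose(s.od600, 0.5)

    def test_noise_free_matches_closed_form(self):
        from dropscreen.growth import baranyi_log_od

        p = sim.StrainParams("pm", 8.9, 0.55, 0.005, 2.0, 0.0)
        t = np.arange(0.0, 48.1, 3.0)
        s = sim.generate_growth_series(p, t, 0.0, 0)
        expected = np.exp(
            baranyi_log_od(t, math.log(0.005), math.log(2.0), 0.55, 0.55 * 8.9)
        )
        assert np.allclose(s.od600, expected)

    def test_negative_times_raise(self):
        p = sim.StrainParams("x", 1.0, 0.5, 0.01, 1.0, 0.0)
        with pytest.raises(ValueError):
            sim.generate_growth_series(p, [-1, 0, 1, 2, 3], 0.0, 0)

    def test_strain_invariants_enforced(self):
        with pytest.raises(ValueError):
            sim.StrainParams("bad", -1.0, 0.5, 0.01, 1.0, 0.0)
        with pytest.raises(ValueError):
            sim.StrainParams("bad", 1.0, 0.5, 1.0, 0.5, 0.0)
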