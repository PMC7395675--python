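import warnings
from datetime import date

import numpy as np
import pytest
from scipy.integrate import quad

from oct2vf import synthetic_cohort as sc
from oct2vf.defect_sim import DefectSpec, simulate_defect
from oct2vf.vf_geometry import build_grid_24_2, rnfl_angles


class TestNormativeProfile:
    def test_double_hump_peaks_above_temporal_base(self, gen_cfg):
        assert sc.normative_rnfl_mean(80.0, gen_cfg) > sc.normative_rnfl_mean(0.0, gen_cfg)
        assert sc.normative_rnfl_mean(280.0, gen_cfg) > sc.normative_rnfl_mean(0.0, gen_cfg)

    def test_periodic_at_wrap(self, gen_cfg):
        v0 = sc.normative_rnfl_mean(0.0, gen_cfg)
        v1 = sc.normative_rnfl_mean(359.999, gen_cfg)
        assert abs(v0 - v1) < 1e-2

    def test_sampled_mean_matches_numerical_integral(self, gen_cfg):
        # oracle: numerically integrate the analytic curve over the circle
        true_mean = quad(
            lambda a: sc.normative_rnfl_mean(a % 360.0, gen_cfg), 0, 359.9999,
            limit=200,
        )[0] / 359.9999
        sampled = sc.sampled_healthy_profile(gen_cfg).mean()
        assert abs(sampled - true_mean) < 2.0

    def test_angle_out_of_range_rejected(self, gen_cfg):
        with pytest.raises(ValueError):
            sc.normative_rnfl_mean(360.0, gen_cfg)
        with pytest.raises(ValueError):
            sc.normative_rnfl_mean(-1.0, gen_cfg)


class TestForwardModel:
    def test_healthy_profile_gives_age_corrected_normals(self, gen_cfg, sectors, grid):
        s = sc.forward_sf_model(
            sc.sampled_healthy_profile(gen_cfg), 63.0, gen_cfg, sectors, grid
        )
        assert np.allclose(s, sc.normal_sensitivity(63.0, grid, gen_cfg), atol=1e-9)

    def test_halving_floored_thickness_costs_3_db(self, gen_cfg, sectors, grid):
        b = gen_cfg.residual_base_um
        hp = sc.sampled_healthy_profile(gen_cfg)
        s = sc.forward_sf_model(b + (hp - b) * 0.5, 63.0, gen_cfg, sectors, grid)
        drop = sc.normal_sensitivity(63.0, grid, gen_cfg) - s
        assert np.allclose(drop, 10 * np.log10(2), atol=1e-9)

    def test_profile_at_floor_gives_zero_everywhere(self, gen_cfg, sectors, grid):
        s = sc.forward_sf_model(
            np.full(768, gen_cfg.residual_base_um), 63.0, gen_cfg, sectors, grid
        )
        assert np.all(s == 0.0)

    def test_monotone_in_thickness(self, gen_cfg, sectors, grid, rng):
        hp = sc.sampled_healthy_profile(gen_cfg)
        for _ in range(10):
            a = hp * rng.uniform(0.5, 1.0, size=768)
            b = a * rng.uniform(0.5, 1.0, size=768)  # pointwise <= a
            sa = sc.forward_sf_model(a, 60.0, gen_cfg, sectors, grid)
            sb = sc.forward_sf_model(b, 60.0, gen_cfg, sectors, grid)
            assert np.all(sb <= sa + 1e-12)

    def test_degenerate_floor_rejected(self, sectors, grid):
        cfg = sc.GeneratorConfig()
        cfg.residual_base_um = 200.0  # above the healthy curve everywhere
        with pytest.raises(ValueError, match="floor"):
            sc.forward_sf_model(np.full(768, 90.0), 60.0, cfg, sectors, grid)

    def test_noise_sd_shape(self, gen_cfg):
        s = np.array([40.0, 30.0, 25.0, 20.0, 10.0, 0.0])
        sd = sc.noise_sd(s, gen_cfg)
        assert np.all(np.diff(sd) >= 0)                    # grows as S falls
        assert sd[0] == sd[1] == gen_cfg.noise_sigma0_db   # flat above knee
        assert np.all(sd[s < gen_cfg.noise_knee_db] > gen_cfg.noise_sigma0_db)
        assert np.all(sd <= gen_cfg.noise_cap_db)

    def test_noisy_requires_rng(self, gen_cfg, sectors, grid):
        with pytest.raises(ValueError, match="rng"):
            sc.forward_sf_model(
                sc.sampled_healthy_profile(gen_cfg), 60.0, gen_cfg, sectors, grid,
                noisy=True,
            )


class TestSimulateCohort:
    def test_same_seed_identical_cohorts(self, gen_cfg, small_cohort):
        again = sc.simulate_cohort(sc.GeneratorConfig(n_patients=120, seed=7))
        assert len(again) == len(small_cohort)
        for a, b in zip(small_cohort, again):
            assert np.array_equal(a.rnfl, b.rnfl)
            assert np.array_equal(a.vf, b.vf)
            assert a.test_date_sap == b.test_date_sap

    def test_nonpositive_patients_rejected(self):
        with pytest.raises(ValueError):
            sc.simulate_cohort(sc.GeneratorConfig(n_patients=0))

    def test_healthy_cohort_thicker_than_glaucoma_cohort(self):
        h = sc.simulate_cohort(sc.GeneratorConfig(n_patients=40, fraction_glaucoma=0.0, seed=5))
        g = sc.simulate_cohort(sc.GeneratorConfig(n_patients=40, fraction_glaucoma=1.0, seed=5))
        mean_h = np.mean([e.rnfl.mean() for e in h])
        mean_g = np.mean([e.rnfl.mean() for e in g])
        assert mean_h > mean_g

    def test_ids_nested_and_bounds(self, small_cohort):
        for e in small_cohort[:50]:
            assert e.eye_id.startswith(e.patient_id)
            assert np.all((e.vf >= 0) & (e.vf <= 50))
            assert np.all((e.rnfl >= 0) & (e.rnfl <= 250))

    def test_inferotemporal_defect_hits_superior_hemifield(
        self, gen_cfg, sectors, grid, normative_small
    ):
        """A defect confined to 270-300 deg (inferior retina) must depress
        superior-hemifield points more than inferior ones."""
        hp = sc.sampled_healthy_profile(gen_cfg)
        damaged = simulate_defect(
            hp, DefectSpec(270.0, 300.0, 1), {1: hp * 0.4}
        )
        s_healthy = sc.forward_sf_model(hp, 60.0, gen_cfg, sectors, grid)
        s_damaged = sc.forward_sf_model(damaged, 60.0, gen_cfg, sectors, grid)
        loss = s_healthy - s_damaged
        y = grid.xy()[:, 1]
        assert loss[y > 0].mean() > loss[y < 0].mean()


class TestNormativeTables:
    def test_identical_glaucoma_profiles_degenerate_percentiles(self, gen_cfg):
        h = sc.simulate_cohort(sc.GeneratorConfig(n_patients=30, fraction_glaucoma=0.0, seed=2))
        prof = sc.sampled_healthy_profile(gen_cfg) * 0.6
        glauc = []
        for i, e in enumerate(h[:10]):
            glauc.append(
                sc.PairedExam(
                    patient_id=e.patient_id, eye_id=e.eye_id, laterality="right",
                    test_date_sap=e.test_date_sap, test_date_oct=e.test_date_oct,
                    age_years=e.age_years, rnfl=prof.copy(), vf=e.vf,
                    fixation_loss_frac=0.0, false_positive_frac=0.0,
                    oct_quality_score=30.0, is_glaucoma=True,
                )
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nt = sc.derive_normative_tables(h, glauc, gen_cfg)
        for q in (10, 5, 1):
            assert np.allclose(nt.glaucoma_percentile_profiles[q], prof)

    def test_percentile_profiles_ordered(self, normative_small):
        pp = normative_small.glaucoma_percentile_profiles
        assert np.all(pp[1] <= pp[5] + 1e-12)
        assert np.all(pp[5] <= pp[10] + 1e-12)

    def test_td_pd_percentile_columns_ordered(self, normative_small):
        for tab in (normative_small.td_percentiles, normative_small.pd_percentiles):
            assert np.all(tab[0.5] <= tab[1.0] + 1e-12)
            assert np.all(tab[1.0] <= tab[2.0] + 1e-12)
            assert np.all(tab[2.0] <= tab[5.0] + 1e-12)

    def test_empty_group_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            sc.derive_normative_tables([], small_cohort)

    def test_age_slope_recovery(self, gen_cfg, sectors, grid):
        """Healthy thresholds generated with slope -0.07 dB/yr are recovered."""
        r = np.random.default_rng(99)
        exams = []
        hp = sc.sampled_healthy_profile(gen_cfg)
        for i in range(500):
            age = r.uniform(40.0, 90.0)
            vf = sc.forward_sf_model(hp, age, gen_cfg, sectors, grid,
                                     noisy=True, rng=r)
            exams.append(
                sc.PairedExam(
                    patient_id=f"H{i:04d}", eye_id=f"H{i:04d}-OD", laterality="right",
                    test_date_sap=date(2020, 1, 1), test_date_oct=date(2020, 1, 1),
                    age_years=age, rnfl=hp.copy(), vf=vf,
                    fixation_loss_frac=0.0, false_positive_frac=0.0,
                    oct_quality_score=30.0, is_glaucoma=False,
                )
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nt = sc.derive_normative_tables(exams, exams[:100], gen_cfg)
        # noise sd 1.5 dB, age spread ~14 yr, n=500 -> SE(slope) ~ 0.005/point
        assert abs(nt.normal_slope_db_per_yr.mean() - (-0.07)) < 0.015

    def test_quantile_matches_sort_oracle(self, rng):
        x = rng.normal(size=(9, 4))
        for q in (10, 5, 1):
            got = sc.empirical_percentile(x, q)
            for j in range(4):
                srt = np.sort(x[:, j])
                pos = (q / 100) * (len(srt) - 1)
                lo, hi = int(np.floor(pos)), int(np.ceil(pos))
                expect = srt[lo] + (pos - lo) * (srt[hi] - srt[lo])
                assert got[j] == pytest.approx(expect, abs=1e-12)


class TestCsvRoundTrip:
    def test_cohort_round_trips_through_frames(self, small_cohort):
        meta, wide = sc.cohort_to_frames(small_cohort[:20])
        back = sc.frames_to_cohort(meta, wide)
        for a, b in zip(small_cohort[:20], back):
            assert np.allclose(a.rnfl, b.rnfl)
            assert np.allclose(a.vf, b.vf)
            assert a.patient_id == b.patient_id
            assert a.test_date_sap == b.test_date_sap

    def test_write_and_read_cohort_dir(self, small_cohort, gen_cfg, tmp_path):
        sc.write_cohort(small_cohort[:15], tmp_path, gen_cfg)
        back = sc.read_cohort(tmp_path)
        assert len(back) == 15
        assert np.allclose(back[3].vf, small_cohort[3].vf)
        assert (tmp_path / "manifest.json").exists()
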