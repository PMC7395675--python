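import numpy as np
import pandas as pd
import pytest

from oct2vf import evaluation as ev
from oct2vf.vf_geometry import GH_SECTORS, SectorAssignment


def _pad52(n_exams, rng, base=30.0):
    return base + rng.normal(size=(n_exams, 52))


class TestPointwiseMetrics:
    def test_exact_predictions_zero_mae(self, rng):
        y = _pad52(5, rng)
        m = ev.pointwise_metrics(y, y)
        assert np.all(m.mae == 0) and m.mae_avg == 0

    def test_hand_arithmetic_two_exams(self, rng):
        meas = _pad52(2, rng)
        pred = meas.copy()
        pred[:, 0] = (30.0, 28.0)
        meas[:, 0] = (32.0, 31.0)
        m = ev.pointwise_metrics(pred, meas)
        assert m.mae[0] == pytest.approx(2.5)

    def test_constant_offset_mae_and_perfect_r(self, rng):
        meas = _pad52(20, rng)
        m = ev.pointwise_metrics(meas + 5.0, meas)
        assert np.allclose(m.mae, 5.0)
        assert np.allclose(m.r, 1.0)
        assert m.r_avg == pytest.approx(1.0)

    def test_zero_variance_point_warned_and_excluded(self, rng):
        meas = _pad52(10, rng)
        pred = meas + rng.normal(size=meas.shape)
        pred[:, 3] = 30.0
        with pytest.warns(UserWarning, match="zero variance"):
            m = ev.pointwise_metrics(pred, meas)
        assert np.isnan(m.r[3]) and not np.isnan(m.r_avg)

    def test_exam_order_invariance(self, rng):
        meas = _pad52(15, rng)
        pred = meas + rng.normal(size=meas.shape)
        perm = rng.permutation(15)
        a = ev.pointwise_metrics(pred, meas)
        b = ev.pointwise_metrics(pred[perm], meas[perm])
        assert np.allclose(a.mae, b.mae) and np.allclose(a.r, b.r)

    def test_shape_guards(self, rng):
        with pytest.raises(ValueError):
            ev.pointwise_metrics(np.zeros((3, 52)), np.zeros((4, 52)))
        with pytest.raises(ValueError):
            ev.pointwise_metrics(np.zeros((1, 52)), np.zeros((1, 52)))


class TestBootstrap:
    def test_constant_statistic_zero_width(self, rng):
        ids = np.repeat(np.arange(10), 3)
        lo, hi, _ = ev.bootstrap_cis(lambda idx: 7.0, ids, n_boot=200, seed=0)
        assert lo[0] == hi[0] == 7.0

    def test_seeded_determinism(self, rng):
        vals = rng.normal(size=60)
        ids = np.repeat(np.arange(20), 3)
        stat = lambda idx: vals[idx].mean()
        a = ev.bootstrap_cis(stat, ids, n_boot=300, seed=5)
        b = ev.bootstrap_cis(stat, ids, n_boot=300, seed=5)
        assert a[0] == b[0] and a[1] == b[1]

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            ev.bootstrap_cis(lambda idx: 0.0, np.zeros(5), n_boot=100)

    def test_unequal_cluster_sizes_supported(self, rng):
        vals = rng.normal(size=7)
        ids = np.array([0, 0, 0, 1, 1, 2, 3])
        lo, hi, _ = ev.bootstrap_cis(lambda i: vals[i].mean(), ids, n_boot=200, seed=1)
        assert lo[0] <= hi[0]


class TestSectorMetrics:
    @pytest.fixture()
    def toy_sectors(self):
        labels = np.empty(52, dtype=object)
        for i, s in enumerate(GH_SECTORS):
            labels[i * 8 : (i + 1) * 8] = s
        labels[48:] = GH_SECTORS[0]
        return SectorAssignment(labels=tuple(labels), disc_angle_deg=np.zeros(52))

    def test_constant_sector_average(self, toy_sectors, rng):
        fields = np.zeros((3, 52))
        for i, s in enumerate(GH_SECTORS):
            fields[:, toy_sectors.indices(s)] = i * 10.0
        av = ev.sector_averages(fields, toy_sectors)
        for i, s in enumerate(GH_SECTORS):
            assert np.allclose(av[s], i * 10.0)

    def test_exact_predictions_zero_sector_mae(self, toy_sectors, rng):
        y = _pad52(6, rng)
        tab = ev.sector_metrics(y, y, toy_sectors)
        assert np.allclose(tab["mae"], 0.0)
        assert list(tab["sector"]) == list(GH_SECTORS)

    def test_hand_computed_fixture(self, toy_sectors):
        # 3 exams; point values constant within each sector
        pred = np.zeros((3, 52))
        meas = np.zeros((3, 52))
        idx0 = toy_sectors.indices(GH_SECTORS[0])
        pred[:, idx0] = np.array([10.0, 20.0, 30.0])[:, None]
        meas[:, idx0] = np.array([12.0, 19.0, 26.0])[:, None]
        tab = ev.sector_metrics(pred, meas, toy_sectors).set_index("sector")
        assert tab.loc[GH_SECTORS[0], "mae"] == pytest.approx((2 + 1 + 4) / 3)


class TestModelComparison:
    def test_identical_models_null_difference(self, rng):
        meas = _pad52(40, rng)
        pred = meas + rng.normal(size=meas.shape)
        ids = np.repeat(np.arange(20), 2)
        res = ev.compare_models_correlation(pred, pred, meas, ids, n_boot=200, seed=0)
        assert res["delta_r"] == 0.0 and res["p_bootstrap"] == 1.0

    def test_constructed_separation_significant(self, rng):
        truth = _pad52(300, rng)
        meas = truth + 0.5 * rng.normal(size=truth.shape)
        pred_a = truth + 0.2 * rng.normal(size=truth.shape)
        pred_b = pred_a[rng.permutation(300)]       # shuffled: no association
        ids = np.repeat(np.arange(150), 2)
        res = ev.compare_models_correlation(pred_a, pred_b, meas, ids,
                                            n_boot=500, seed=0)
        assert res["delta_r"] > 0
        assert res["p_bootstrap"] < 0.05
        lo, hi = res["ci"]
        assert lo > 0  # CI excluding 0 consistent with p < 0.05

    def test_mismatched_exam_sets_rejected(self, rng):
        with pytest.raises(ValueError):
            ev.compare_models_correlation(
                np.zeros((5, 52)), np.zeros((6, 52)), np.zeros((5, 52)), np.arange(5)
            )

    def test_equal_errors_zero_coefficient(self, rng):
        err = np.abs(rng.normal(size=40))
        res = ev.compare_models_abs_error(err, err, np.repeat(np.arange(20), 2))
        assert res["coef"] == 0.0 and res["p"] == 1.0

    def test_exact_shift_recovered(self, rng):
        err = np.abs(rng.normal(size=60)) + 1.0
        res = ev.compare_models_abs_error(err, err + 1.0, np.repeat(np.arange(20), 3))
        assert res["coef"] == pytest.approx(1.0, abs=1e-6)

    def test_too_few_participants_rejected(self, rng):
        with pytest.raises(ValueError):
            ev.compare_models_abs_error(np.ones(3), np.ones(3), np.zeros(3))


class TestErrorStructure:
    def test_single_bin_equals_global_mae(self, rng):
        meas = np.full((4, 52), 21.0)
        pred = meas + rng.normal(size=meas.shape)
        tab = ev.mae_by_threshold_bins(pred, meas)
        filled = tab.dropna(subset=["mae"])
        assert len(filled) == 1
        assert filled.iloc[0]["mae"] == pytest.approx(np.mean(np.abs(pred - meas)))

    def test_exact_predictions_zero_in_every_bin(self, rng):
        meas = rng.uniform(0, 40, size=(30, 52))
        tab = ev.mae_by_threshold_bins(meas, meas)
        assert np.all(tab.dropna(subset=["mae"])["mae"] == 0)

    def test_bins_cover_0_to_40(self):
        tab = ev.mae_by_threshold_bins(np.zeros((2, 52)), np.zeros((2, 52)))
        assert tab.iloc[0]["bin_lo"] == 0.0 and tab.iloc[-1]["bin_hi"] == 40.0
        assert len(tab) == 20

    def test_counts_sum_to_n_values(self, rng):
        meas = rng.uniform(0, 39.9, size=(11, 52))
        tab = ev.mae_by_threshold_bins(meas, meas)
        assert tab["count"].sum() == 11 * 52

    def test_correlate_extremes(self, rng):
        err = np.abs(rng.normal(size=50))
        cov = pd.DataFrame({"same": err, "neg": -err})
        tab = ev.error_correlates(err, cov).set_index("covariate")
        assert tab.loc["same", "r"] == pytest.approx(1.0)
        assert tab.loc["neg", "r"] == pytest.approx(-1.0)

    def test_independent_covariate_near_zero(self):
        r = np.random.default_rng(2)
        err = np.abs(r.normal(size=2000))
        cov = pd.DataFrame({"indep": r.normal(size=2000)})
        tab = ev.error_correlates(err, cov)
        assert abs(tab.iloc[0]["r"]) < 0.1

    def test_minimum_sample_rejected(self):
        with pytest.raises(ValueError):
            ev.error_correlates(np.ones(2), pd.DataFrame({"a": [1.0, 2.0]}))
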