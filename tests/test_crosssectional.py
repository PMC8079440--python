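import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cortexeval as ce
from cortexeval.errors import ConfigurationError, SchemaError
from cortexeval.icc import _icc_2k
from cortexeval.regions import REGION_CODES

REGIONS = list(REGION_CODES)


def _cross_table(seed, n, **overrides):
    cfg = ce.CohortConfig(seed=seed, **overrides)
    _, table = ce.generate_cross_sectional(cfg, n)
    return cfg, table


class TestAgePredictionHarness:
    def test_permutation_vector_shape_and_mean(self):
        _, table = _cross_table(31, 60)
        res = ce.run_age_prediction(table, n_permutations=4, n_trees=20, seed=1)
        assert res.rmse_per_permutation.shape == (4,)
        assert res.rmse_mean == pytest.approx(res.rmse_per_permutation.mean())
        assert (res.rmse_per_permutation > 0).all()

    def test_same_seed_same_rmse_and_row_order_invariance(self):
        _, table = _cross_table(32, 60)
        kw = dict(n_permutations=3, n_trees=20, seed=7)
        r1 = ce.run_age_prediction(table, **kw)
        r2 = ce.run_age_prediction(table, **kw)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        r3 = ce.run_age_prediction(shuffled, **kw)
        assert np.array_equal(r1.rmse_per_permutation, r2.rmse_per_permutation)
        assert np.array_equal(r1.rmse_per_permutation, r3.rmse_per_permutation)

    def test_error_contracts(self):
        _, table = _cross_table(33, 30)
        with pytest.raises(ConfigurationError):
            ce.AgePredictionHarness(train_fraction=1.2).fit(table)
        with pytest.raises(ConfigurationError):
            ce.AgePredictionHarness(n_permutations=0).fit(table)
        with pytest.raises(ConfigurationError):
            ce.run_age_prediction(table.head(10), n_permutations=2, n_trees=5)
        with pytest.raises(SchemaError):
            ce.run_age_prediction(table.drop(columns=["icv"]),
                                  n_permutations=2, n_trees=5)

    def test_compare_pipeline_rmse_trivials(self):
        a = ce.age_prediction.AgePredictionResult("d", "A", [3.0, 4.0, 5.0])
        b = ce.age_prediction.AgePredictionResult("d", "B", [3.5, 4.5, 5.5])
        out = ce.compare_pipeline_rmse(a, b)
        assert out["mean_difference"] == pytest.approx(0.5)
        assert np.allclose(out["paired_differences"], 0.5)
        same = ce.compare_pipeline_rmse(a, a)
        assert same["mean_difference"] == 0.0
        with pytest.raises(ConfigurationError):
            ce.compare_pipeline_rmse(
                a, ce.age_prediction.AgePredictionResult("other", "B", [1.0] * 3))
        with pytest.raises(ConfigurationError):
            ce.compare_pipeline_rmse(
                a, ce.age_prediction.AgePredictionResult("d", "B", [1.0, 2.0]))


class TestLifespanModels:
    def test_noiseless_generator_slopes_recovered_exactly(self):
        """With tau = sigma = 0 the OLS coefficients equal the generative
        age slope and gender effect to machine precision."""
        cfg, table = _cross_table(41, 80, tau=0.0, sigma=0.0,
                                  age_slope=-0.004, gender_effect=0.02)
        model = ce.fit_lifespan_models(table)
        assert list(model.coefficients_.index) == REGIONS
        assert np.allclose(model.coefficients_["age"], -0.004, atol=1e-10)
        assert np.allclose(model.coefficients_["gender"], 0.02, atol=1e-10)
        assert np.allclose(model.coefficients_["intercept"], cfg.alpha0,
                           atol=1e-10)

    def test_gender_coefficient_confidence_interval_covers_truth(self):
        _, table = _cross_table(42, 500, gender_effect=0.05)
        model = ce.fit_lifespan_models(table)
        res = model.models_["lh_ENT"]
        lo, hi = res.conf_int()[1]  # gender is the second design column
        assert lo <= 0.05 <= hi

    def test_predict_matches_linear_formula(self):
        _, table = _cross_table(43, 100)
        model = ce.fit_lifespan_models(table)
        c = model.coefficients_.loc["rh_FUS"]
        pred = model.predict(60.0, 1)
        assert pred["rh_FUS"] == pytest.approx(
            c["intercept"] + c["gender"] + c["age"] * 60.0, rel=1e-12)

    def test_extrapolation_warns(self):
        _, table = _cross_table(44, 100)
        model = ce.fit_lifespan_models(table)
        with pytest.warns(UserWarning, match="extrapolat"):
            model.predict(150.0, 0)

    def test_rank_deficient_design_rejected(self):
        _, table = _cross_table(45, 30)
        table["age_baseline"] = 50.0
        table["gender"] = 0
        with pytest.raises(ConfigurationError):
            ce.fit_lifespan_models(table)


class TestRadarTable:
    def test_constant_model_gives_all_relative_values_one(self):
        """If every region has the same flat prediction, all relative values
        are exactly 1 and exactly one cell is the reference."""
        _, table = _cross_table(46, 60, tau=0.0, sigma=0.0, age_slope=0.0,
                                gender_effect=0.0, alpha0=3.0)
        model = ce.fit_lifespan_models(table)
        radar = ce.predict_relative_thickness({"A": model})
        assert len(radar) == 62 * 3 * 2
        assert np.allclose(radar["relative_value"], 1.0, atol=1e-12)
        assert radar["is_reference"].sum() == 1

    def test_two_cell_closed_form(self):
        """Hand-check: thickest region at the youngest age and reference
        ratio computed by hand from the noiseless coefficients."""
        alpha = np.full(62, 2.0)
        alpha[REGIONS.index("rh_ENT")] = 3.6
        _, table = _cross_table(47, 60, tau=0.0, sigma=0.0,
                                age_slope=-0.004, gender_effect=0.02,
                                alpha0=alpha)
        model = ce.fit_lifespan_models(table)
        radar = ce.predict_relative_thickness({"A": model})
        ref = radar[radar["is_reference"]].iloc[0]
        # max prediction: rh_ENT, youngest representative age 25, gender 1
        assert ref["region"] == "rh_ENT"
        assert ref["age"] == 25.0 and ref["gender"] == 1
        ref_mm = 3.6 + 0.02 - 0.004 * 25
        cell = radar[(radar["region"] == "lh_cACC") & (radar["age"] == 75.0)
                     & (radar["gender"] == 0)].iloc[0]
        assert cell["relative_value"] == pytest.approx(
            (2.0 - 0.004 * 75) / ref_mm, rel=1e-9)

    def test_empty_pipeline_dict_rejected(self):
        with pytest.raises(ConfigurationError):
            ce.predict_relative_thickness({})


class TestPairedTTest:
    def _radar(self, shift=0.0, noise=None, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for code in REGIONS:
            for age in (25.0, 50.0, 75.0):
                for g in (0, 1):
                    val = 2.5 + 0.1 * g + shift
                    if noise is not None:
                        val += rng.normal(0, noise)
                    rows.append({"region": code, "age": age, "gender": g,
                                 "predicted_mm": val})
        return pd.DataFrame(rows)

    def test_identical_tables_give_t0_p1(self):
        a = self._radar()
        t, p, df = ce.paired_region_ttest(a, a.copy())
        assert t == 0.0 and p == 1.0 and df == 62 * 6 - 1

    def test_constant_nonzero_shift_degenerates_to_zero_p(self):
        a = self._radar()
        b = self._radar(shift=0.3)
        with pytest.warns(UserWarning):
            t, p, _ = ce.paired_region_ttest(a, b)
        assert np.isinf(t) and p == 0.0

    def test_matches_scipy_ttest_rel(self):
        a = self._radar(noise=0.05, seed=1)
        b = self._radar(shift=0.01, noise=0.05, seed=2)
        t, p, df = ce.paired_region_ttest(a, b)
        merged = a.merge(b, on=["region", "age", "gender"],
                         suffixes=("_a", "_b"))
        ref = stats.ttest_rel(merged["predicted_mm_a"], merged["predicted_mm_b"])
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)
        assert df == len(merged) - 1


class TestICC:
    def test_identical_acquisitions_give_exactly_one(self):
        table = ce.generate_scan_rescan(ce.CohortConfig(seed=51, sigma=0.0), 12)
        for res in ce.compute_icc(table):
            assert res.icc_value == 1.0
            assert res.residual_var == pytest.approx(0.0, abs=1e-25)

    def test_hand_computed_five_by_two_anova(self):
        """ICC(2,k) for a worked 5 x 2 table, mean squares done by hand."""
        matrix = np.array([[2.0, 2.1], [2.4, 2.5], [2.8, 2.7],
                           [3.2, 3.3], [3.6, 3.5]])
        icc, between, resid = _icc_2k(matrix)
        n, k = 5, 2
        grand = matrix.mean()
        msr = k * ((matrix.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((matrix.mean(0) - grand) ** 2).sum() / (k - 1)
        cell = matrix - matrix.mean(1)[:, None] - matrix.mean(0)[None] + grand
        mse = (cell ** 2).sum() / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (msc - mse) / n)
        assert icc == pytest.approx(expected, abs=1e-12)
        assert icc == pytest.approx(0.993103448, abs=1e-9)
        # independent oracle
        pingouin = pytest.importorskip("pingouin")
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "value": matrix.ravel(),
        })
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="value")
        ref_icc2k = ref.loc[ref["Type"] == "ICC(A,k)", "ICC"].iloc[0]
        assert icc == pytest.approx(ref_icc2k, abs=1e-9)

    def test_affine_invariance(self):
        table = ce.generate_scan_rescan(ce.CohortConfig(seed=52), 20)
        base = {r.region: r.icc_value for r in ce.compute_icc(table)}
        scaled = table.copy()
        scaled[REGIONS] = scaled[REGIONS] * 3.0 + 1.0
        for res in ce.compute_icc(scaled):
            assert res.icc_value == pytest.approx(base[res.region], abs=1e-10)

    def test_high_repeatability_regime(self):
        """tau = 0.5, sigma = 0.05, n = 100: component formula gives
        ICC(2,2) approx tau^2/(tau^2 + sigma^2/2) = 0.995; estimate >= 0.97."""
        table = ce.generate_scan_rescan(
            ce.CohortConfig(seed=53, tau=0.5, sigma=0.05), 100)
        values = np.array([r.icc_value for r in ce.compute_icc(table)])
        assert (values >= 0.97).all()

    def test_incomplete_design_and_size_contracts(self):
        table = ce.generate_scan_rescan(ce.CohortConfig(seed=54), 10)
        with pytest.raises(ConfigurationError):
            ce.compute_icc(table.iloc[1:])  # drops one acquisition
        with pytest.raises(ConfigurationError):
            small = ce.generate_scan_rescan(ce.CohortConfig(seed=54), 4)
            ce.compute_icc(small)
        with pytest.raises(SchemaError):
            ce.compute_icc(table.drop(columns=["acquisition"]))
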