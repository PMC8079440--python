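import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import studentized_range

import cortexeval as ce
from cortexeval.contrasts import (
    CONTRASTS,
    benjamini_hochberg,
    fdr_adjust,
    fit_contrast_model,
    prepare_delta,
    tukey_diagnostic_contrasts,
)
from cortexeval.errors import ConfigurationError
from cortexeval.regions import REGION_CODES

REGIONS = list(REGION_CODES)


def _hand_table():
    """Two subjects, three visits each, constant thickness per visit."""
    rows = []
    for sid, site, vals in (("s1", "a", [3.0, 2.9, 2.8]),
                            ("s2", "b", [2.5, 2.45, 2.40])):
        for t, v in zip([0.0, 6.0, 12.0], vals):
            row = {"subject_id": sid, "site": site, "visit_time_months": t,
                   "gender": 0, "age_baseline": 70.0, "icv": 1.5e6,
                   "diagnosis": "CN", "apoe": 0}
            row.update({c: v for c in REGIONS})
            rows.append(row)
    return pd.DataFrame(rows)


class TestPrepareDelta:
    def test_hand_arithmetic(self):
        delta = prepare_delta(_hand_table())
        s1 = delta[(delta["subject_id"] == "s1") & (delta["region"] == "lh_ENT")]
        assert sorted(s1["delta_y"].round(12)) == [-0.2, -0.1]
        assert (s1["y_bl"] == 3.0).all()
        s2 = delta[(delta["subject_id"] == "s2") & (delta["region"] == "rh_INS")]
        assert np.allclose(sorted(s2["delta_y"]), [-0.10, -0.05])

    def test_row_count_is_followups_times_regions(self, small_longitudinal):
        _, _, visits = small_longitudinal
        delta = prepare_delta(visits)
        n_follow = (visits["visit_time_months"] > 0).sum()
        assert len(delta) == n_follow * 62

    def test_subjects_without_baseline_are_excluded_and_counted(self):
        table = _hand_table()
        table = table[~((table["subject_id"] == "s2")
                        & (table["visit_time_months"] == 0))]
        delta = prepare_delta(table)
        assert delta.attrs["n_excluded_no_baseline"] == 1
        assert set(delta["subject_id"]) == {"s1"}

    def test_no_followups_rejected(self):
        table = _hand_table()
        with pytest.raises(ConfigurationError):
            prepare_delta(table[table["visit_time_months"] == 0])


@pytest.fixture(scope="module")
def three_group_delta():
    cfg = ce.adni_like_config(
        seed=61, group_sizes={"CN": 20, "LMCI": 20, "AD": 20}, n_sites=4,
        site_sd=0.0, tau=0.15, rho=0.0015, sigma=0.05)
    _, visits = ce.generate_longitudinal(cfg)
    return prepare_delta(visits)


class TestContrastModel:
    def test_contrast_identity_is_exact(self, three_group_delta):
        """(AD-CN) = (AD-LMCI) + (LMCI-CN) by construction of the L-vectors."""
        sub = three_group_delta[three_group_delta["region"] == "lh_ENT"]
        model = fit_contrast_model(sub, region="lh_ENT")
        est = {r["contrast"]: r["estimate"]
               for r in tukey_diagnostic_contrasts(model)}
        assert est["AD-CN"] == pytest.approx(
            est["AD-LMCI"] + est["LMCI-CN"], abs=1e-12)

    def test_generative_group_difference_recovered(self):
        """AD slope offset -0.004 mm/month vs CN should be estimated within
        50% at this cohort size."""
        cfg = ce.adni_like_config(
            seed=62, group_sizes={"CN": 40, "LMCI": 40, "AD": 40}, n_sites=4,
            site_sd=0.0, tau=0.15, rho=0.001, sigma=0.04,
            diagnosis_slope_offsets={"CN": 0.0, "LMCI": -0.002, "AD": -0.004})
        _, visits = ce.generate_longitudinal(cfg)
        delta = prepare_delta(visits)
        sub = delta[delta["region"] == "rh_PCUN"]
        model = fit_contrast_model(sub, region="rh_PCUN")
        est = {r["contrast"]: r["estimate"]
               for r in tukey_diagnostic_contrasts(model)}
        assert abs(est["AD-CN"] - (-0.004)) < 0.002

    def test_tukey_p_matches_direct_studentized_range(self, three_group_delta):
        """Dual route: rebuild q = |L beta / se| * sqrt(2) from the
        statsmodels t_test machinery and evaluate scipy's SR tail."""
        sub = three_group_delta[three_group_delta["region"] == "lh_FUS"]
        model = fit_contrast_model(sub, region="lh_FUS")
        recs = tukey_diagnostic_contrasts(model)
        res = model.result
        names = list(res.fe_params.index)
        for rec in recs:
            hi, lo = {"LMCI-CN": ("LMCI", "CN"), "AD-LMCI": ("AD", "LMCI"),
                      "AD-CN": ("AD", "CN")}[rec["contrast"]]
            lvec = np.zeros(len(names))
            for c in model.slope_params[hi]:
                lvec[names.index(c)] += 1.0 / len(model.slope_params[hi])
            for c in model.slope_params[lo]:
                lvec[names.index(c)] -= 1.0 / len(model.slope_params[lo])
            tt = res.t_test(lvec.reshape(1, -1))
            q = abs(float(np.ravel(tt.tvalue)[0])) * np.sqrt(2.0)
            p_ref = float(studentized_range.sf(q, 3, model.df_resid))
            assert rec["estimate"] == pytest.approx(
                float(np.ravel(tt.effect)[0]), rel=1e-9)
            assert rec["p_raw"] == pytest.approx(p_ref, rel=1e-9, abs=1e-15)

    def test_missing_level_and_small_design_contracts(self, three_group_delta):
        sub = three_group_delta[three_group_delta["region"] == "lh_ENT"]
        with pytest.raises(ConfigurationError, match="AD"):
            fit_contrast_model(sub[sub["diagnosis_bl"] != "AD"])
        with pytest.raises(ConfigurationError, match="site"):
            fit_contrast_model(sub[sub["site"] == sub["site"].iloc[0]])
        with pytest.raises(ConfigurationError):
            fit_contrast_model(sub, visit="weekly")


class TestFDR:
    def test_bh_closed_form_example(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(adj, [0.03, 0.03, 0.03])
        adj2 = benjamini_hochberg(np.array([0.01, 0.04, 0.9]))
        assert np.allclose(adj2, [0.03, 0.06, 0.9])

    def test_adjusted_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_bruteforce_stepup(self, ps):
        """Library BH equals the textbook step-up computed from scratch."""
        p = np.array(ps)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * n / (np.arange(n) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(ranked, 1.0)
        assert np.allclose(benjamini_hochberg(p), expected, atol=1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ConfigurationError):
            benjamini_hochberg(np.array([0.1, 1.5]))
        frame = pd.DataFrame({"contrast": ["AD-CN"], "p_raw": [-0.2]})
        with pytest.raises(ConfigurationError):
            fdr_adjust(frame)

    def test_contrast_family_adjusts_within_each_contrast(self):
        frame = pd.DataFrame({
            "contrast": np.repeat(list(CONTRASTS), 3),
            "p_raw": [0.01, 0.02, 0.03] * 3,
        })
        per = fdr_adjust(frame, family="contrast")
        # each 3-test family independently gives the 0.03 plateau
        assert np.allclose(per["p_fdr"], 0.03)
        pooled = fdr_adjust(frame, family="global")
        assert np.allclose(pooled["p_fdr"],
                           benjamini_hochberg(frame["p_raw"].to_numpy()))
        assert np.allclose(per["log10_p_fdr"], np.log10(per["p_fdr"]))
        with pytest.raises(ConfigurationError):
            fdr_adjust(frame, family="bonferroni")


class TestFullSweep:
    def test_results_frame_shape_and_flags(self, small_longitudinal):
        _, _, visits = small_longitudinal
        analysis = ce.LongitudinalContrastAnalysis().fit(visits)
        res = analysis.results_
        assert len(res) == 62 * 3
        assert set(res["contrast"]) == set(CONTRASTS)
        assert res["boundary_fit_flag"].dtype == bool
        assert ((res["p_fdr"] >= res["p_raw"] - 1e-15)).all()
        assert np.isfinite(res["log10_p_fdr"]).all()
        assert list(res["region"].unique()) == REGIONS
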