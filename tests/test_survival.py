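"""Cox regression, Kaplan-Meier, ROC/Youden, nomogram and calibration."""

import numpy as np
import pandas as pd
import pytest

from collagenscore.survival import (assign_risk_groups, build_nomogram,
                                    calibration_curve, cox_fit,
                                    feature_os_correlation, km_logrank,
                                    roc_youden)
from collagenscore.synthetic import CohortSpec, generate_cohort


def two_group_cohort(n=2000, hr=2.0, seed=0, censoring=0.0):
    return generate_cohort(CohortSpec(
        n_patients=n, clinical_betas=(("lvi", np.log(hr)),),
        censoring_rate=censoring, seed=seed))


class TestCox:
    def test_hr_two_recovered_with_ci_coverage(self):
        coh = two_group_cohort(seed=7)
        res = cox_fit(coh, ["lvi"], mode="univariate")
        row = res.table.loc["lvi[yes]"]
        assert 1.8 <= row["HR"] <= 2.2
        assert row["CI_lower"] <= 2.0 <= row["CI_upper"]

    def test_null_covariate_ci_covers_one(self):
        coh = generate_cohort(CohortSpec(n_patients=2000, seed=8))
        res = cox_fit(coh, ["sex"], mode="univariate")
        row = res.table.loc["sex[male]"]
        assert row["CI_lower"] <= 1.0 <= row["CI_upper"]

    def test_duplicated_covariate_is_singular(self):
        coh = two_group_cohort(n=300, seed=1)
        coh["lvi2"] = coh["lvi"]
        with pytest.raises(ValueError, match="singular"):
            cox_fit(coh, ["lvi", "lvi2"], mode="multivariate")

    def test_zero_events_rejected(self):
        coh = two_group_cohort(n=100, seed=2)
        coh["event"] = 0
        with pytest.raises(ValueError, match="events"):
            cox_fit(coh, ["lvi"], mode="univariate")

    def test_time_rescaling_invariance(self):
        coh = two_group_cohort(n=500, seed=3)
        days = coh.copy()
        days["os_months"] = days["os_months"] * 30.44
        hr_m = cox_fit(coh, ["lvi"], mode="univariate").table.iloc[0]["HR"]
        hr_d = cox_fit(days, ["lvi"], mode="univariate").table.iloc[0]["HR"]
        assert hr_m == pytest.approx(hr_d, rel=1e-6)

    def test_multivariate_reports_all_terms(self):
        coh = two_group_cohort(n=800, seed=4, censoring=0.2)
        res = cox_fit(coh, ["lvi", "sex", "tnm"], mode="multivariate")
        assert {"lvi[yes]", "sex[male]", "tnm[>=IIB]"} == set(res.table.index)
        assert (res.table["HR"] > 0).all()
        assert (res.table["CI_lower"] <= res.table["HR"]).all()
        assert (res.table["HR"] <= res.table["CI_upper"]).all()


class TestKaplanMeier:
    def test_survival_is_empirical_without_censoring(self):
        df = pd.DataFrame({
            "os_months": [1, 2, 3, 4, 10, 20, 30, 40],
            "event": 1,
        })
        groups = ["a"] * 4 + ["b"] * 4
        km = km_logrank(df, groups)
        at = np.searchsorted(km.times, 2.5, side="right") - 1
        assert km.survival["a"][at] == pytest.approx(0.5)

    def test_km_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, size=100).round(3)
        df = pd.DataFrame({"os_months": t, "event": 1})
        km = km_logrank(df, ["a"] * 50 + ["b"] * 50)
        ta = np.sort(t[:50])
        for i, time in enumerate(km.times):
            expected = 1 - np.searchsorted(ta, time, side="right") / 50
            assert km.survival["a"][i] == pytest.approx(expected, abs=1e-9)

    def test_all_censored_rejected(self):
        df = pd.DataFrame({"os_months": [1, 2, 3, 4], "event": 0})
        with pytest.raises(ValueError, match="events"):
            km_logrank(df, ["a", "a", "b", "b"])

    def test_null_logrank_calibrated(self):
        """Random splits of one distribution: log-rank p is rarely small."""
        ok = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"os_months": rng.exponential(10, 400),
                               "event": 1})
            labels = np.where(rng.random(400) < 0.5, "a", "b")
            if len(set(labels)) < 2:
                continue
            km = km_logrank(df, labels)
            ok += km.logrank_p > 0.01
        assert ok / n_seeds >= 0.9

    def test_separated_groups_detected(self):
        coh = two_group_cohort(n=600, seed=6)
        km = km_logrank(coh, np.where(coh["lvi"] == "yes", "high", "low"),
                        reference="low")
        assert km.logrank_p < 0.01
        assert km.hazard_ratio > 1.4


class TestROCYouden:
    def test_perfect_separation(self):
        r = roc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.youden_j == pytest.approx(1.0)
        assert 3 < r.cutoff < 10

    def test_four_point_case(self):
        r = roc_youden([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert 2 < r.cutoff < 3

    def test_null_score_auc_near_half(self):
        rng = np.random.default_rng(9)
        r = roc_youden(rng.normal(size=2000), rng.integers(0, 2, 2000))
        assert 0.45 <= r.auc <= 0.55
        assert r.auc_ci[0] < r.auc < r.auc_ci[1]

    def test_auc_antisymmetry(self):
        rng = np.random.default_rng(10)
        s = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-s))).astype(int)
        assert roc_youden(s, y).auc == \
            pytest.approx(1 - roc_youden(-s, y).auc, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_youden([1, 2, 3], [1, 1, 1])

    def test_cutoff_transfers_between_splits(self):
        """The Youden cutoff chosen on a training split performs comparably
        on an independent split of the same distribution."""
        rng = np.random.default_rng(11)

        def draw(n):
            y = rng.integers(0, 2, n)
            s = rng.normal(size=n) + 1.2 * y
            return s, y

        s_tr, y_tr = draw(1000)
        s_te, y_te = draw(1000)
        r = roc_youden(s_tr, y_tr)
        pred = s_te > r.cutoff
        j_test = pred[y_te == 1].mean() + (~pred[y_te == 0]).mean() - 1
        assert abs(j_test - r.youden_j) <= 0.15

    def test_risk_group_assignment(self):
        groups = assign_risk_groups([1.0, 3.0], 2.0)
        assert list(groups) == ["low", "high"]


@pytest.fixture(scope="module")
def nomogram_setup():
    spec = CohortSpec(n_patients=800,
                      feature_betas=(0.5, 0, 0, 0, 0, 0, 0, 0),
                      feature_means=(0.0,) * 8, feature_sds=(1.0,) * 8,
                      clinical_betas=(("lvi", 0.8), ("tnm_high", 0.4)),
                      censoring_rate=0.2, seed=12)
    coh = generate_cohort(spec)
    cox = cox_fit(coh, ["fea1", "lvi", "tnm"], mode="multivariate")
    return coh, cox, build_nomogram(cox, coh)


class TestNomogram:
    def test_single_binary_covariate_spans_0_100(self):
        coh = two_group_cohort(n=500, seed=13, censoring=0.1)
        cox = cox_fit(coh, ["lvi"], mode="multivariate")
        nom = build_nomogram(cox, coh)
        pts = sorted(abs(s["per_unit"]) for s in nom.point_scales.values())
        assert pts[-1] == pytest.approx(100.0)

    def test_total_points_increase_with_linear_predictor(self, nomogram_setup):
        coh, cox, nom = nomogram_setup
        lp = cox.design.to_numpy() @ cox.fitter.params_.to_numpy()
        pts = np.array([nom.points_for(cox.design.iloc[i])
                        for i in range(len(coh))])
        order = np.argsort(lp)
        assert (np.diff(pts[order]) >= -1e-9).all()

    def test_reference_profile_matches_baseline_survival(self, nomogram_setup):
        """Cox identity: the zero-point profile's predicted survival is the
        nomogram's own baseline curve."""
        coh, cox, nom = nomogram_setup
        t = np.median(coh["os_months"])
        idx = np.searchsorted(nom.baseline_times, t, side="right") - 1
        s_base = nom.baseline_survival[idx] ** np.exp(
            nom.lp_at_zero_points - nom.lp_center)
        assert nom.predict_survival(0.0, t) == pytest.approx(s_base)

    def test_univariate_model_rejected(self):
        coh = two_group_cohort(n=300, seed=14)
        uni = cox_fit(coh, ["lvi"], mode="univariate")
        with pytest.raises(ValueError, match="multivariate"):
            build_nomogram(uni, coh)

    def test_horizon_beyond_followup_rejected(self, nomogram_setup):
        coh, cox, nom = nomogram_setup
        with pytest.raises(ValueError, match="horizon"):
            nom.predict_survival(0.0, coh["os_months"].max() * 10)


class TestCalibration:
    def test_perfectly_calibrated_model(self):
        """Predictions from the generating exponential model agree with the
        observed Kaplan-Meier estimates within 0.05."""
        rng = np.random.default_rng(15)
        n = 2000
        rate = 0.05 * np.exp(rng.normal(0, 0.6, n))
        t = rng.exponential(1 / rate)
        coh = pd.DataFrame({"os_months": t, "event": 1})
        horizon = 12.0
        pred = np.exp(-rate * horizon)
        cal = calibration_curve(pred, coh, horizon=horizon, n_bins=4)
        assert np.abs(cal["predicted"] - cal["observed"]).mean() <= 0.05

    def test_constant_predictor_single_bin(self):
        coh = generate_cohort(CohortSpec(n_patients=200, seed=16))
        cal = calibration_curve(np.full(200, 0.7), coh, horizon=5.0,
                                n_bins=4)
        assert len(cal) == 1
        from lifelines import KaplanMeierFitter
        kmf = KaplanMeierFitter().fit(coh["os_months"], coh["event"])
        assert cal["observed"].iloc[0] == pytest.approx(
            float(kmf.survival_function_at_times(5.0).iloc[0]))

    def test_one_bin_is_overall_km(self):
        coh = generate_cohort(CohortSpec(n_patients=200, seed=17))
        pred = np.linspace(0.1, 0.9, 200)
        cal = calibration_curve(pred, coh, horizon=5.0, n_bins=1)
        assert len(cal) == 1
        assert cal["predicted"].iloc[0] == pytest.approx(pred.mean())

    def test_horizon_beyond_last_event_rejected(self):
        coh = generate_cohort(CohortSpec(n_patients=100, seed=18))
        with pytest.raises(ValueError, match="horizon"):
            calibration_curve(np.full(100, 0.5), coh,
                              horizon=coh["os_months"].max() + 1)


class TestCorrelations:
    def test_perfect_monotone_relationships(self):
        coh = generate_cohort(CohortSpec(n_patients=50, seed=19))
        coh["fea1"] = coh["os_months"]
        coh["fea2"] = -coh["os_months"]
        res = feature_os_correlation(coh, ["fea1", "fea2"])
        assert res.loc["fea1", "r"] == pytest.approx(1.0)
        assert res.loc["fea2", "r"] == pytest.approx(-1.0)

    def test_null_correlation_concentrates(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            coh = pd.DataFrame({"os_months": rng.exponential(10, 2000),
                                "x": rng.normal(size=2000)})
            r = feature_os_correlation(coh, ["x"]).loc["x", "r"]
            hits += abs(r) <= 0.06
        assert hits >= 95

    def test_zero_variance_rejected(self):
        coh = generate_cohort(CohortSpec(n_patients=50, seed=20))
        coh["fea1"] = 1.0
        with pytest.raises(ValueError, match="variance"):
            feature_os_correlation(coh, ["fea1"])

    def test_pearson_mode(self):
        coh = generate_cohort(CohortSpec(n_patients=50, seed=21))
        res = feature_os_correlation(coh, ["fea1"], method="pearson")
        assert -1 <= res.loc["fea1", "r"] <= 1
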