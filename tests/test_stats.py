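"""Cohort statistics: correlations, dichotomization, KM/Cox, chi-square."""

import numpy as np
import pandas as pd
import pytest

from stromascope import (CohortSimParams, CoxConfig, backward_selection,
                         chi_square_association, cox_fit, dichotomize,
                         generate_cohort, km_logrank, site_concordance,
                         spearman_matrix)
from stromascope.simulate import METRICS


def survival_frame(n, seed, hr_high=1.0, p_high=0.5, rate=0.03, cens=0.015):
    """Minimal two-group exponential PH data set."""
    rng = np.random.default_rng(seed)
    high = rng.random(n) < p_high
    t = rng.exponential(1.0 / (rate * np.where(high, hr_high, 1.0)))
    c = rng.exponential(1.0 / cens, n)
    return pd.DataFrame({
        "metric_high": high.astype(float),
        "os_months": np.minimum(t, c),
        "event": (t <= c).astype(int),
    })


class TestSpearman:
    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((40, 3)), columns=["a", "b", "c"])
        out = spearman_matrix(df, ["a", "b", "c"])
        diag = out[out.metric_a == out.metric_b]
        assert (diag["rho"] == 1.0).all()
        assert (diag["flag"] == "highlighted").all()
        assert out["rho"].abs().max() <= 1.0

    def test_antitone_pair(self):
        df = pd.DataFrame({"x": np.arange(20.0)})
        df["y"] = -df["x"]
        out = spearman_matrix(df, ["x", "y"])
        row = out[(out.metric_a == "x") & (out.metric_b == "y")].iloc[0]
        assert row["rho"] == pytest.approx(-1.0)
        assert row["flag"] == "highlighted"  # |rho| > 0.5 and p < 0.01

    def test_recovers_known_rank_correlation(self):
        rng = np.random.default_rng(42)
        n = 1000
        rho_s = 0.6
        rho = 2 * np.sin(np.pi * rho_s / 6)
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        df = pd.DataFrame({"x": z1, "y": np.exp(z2)})
        out = spearman_matrix(df, ["x", "y"])
        row = out[(out.metric_a == "x") & (out.metric_b == "y")].iloc[0]
        assert row["rho"] == pytest.approx(0.6, abs=0.05)

    def test_constant_metric_reported_missing(self):
        df = pd.DataFrame({"x": np.arange(10.0), "k": np.ones(10)})
        out = spearman_matrix(df, ["x", "k"])
        row = out[(out.metric_a == "x") & (out.metric_b == "k")].iloc[0]
        assert np.isnan(row["rho"]) and row["flag"] == "none"

    def test_pairwise_complete_deletion(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, np.nan, 6.0],
                           "y": [2, 1, 4, 3, 5, np.nan]})
        out = spearman_matrix(df, ["x", "y"])
        assert out[(out.metric_a == "x") & (out.metric_b == "y")].iloc[0]["n"] == 4


class TestConcordance:
    def test_identical_sites_rho_one(self):
        df = pd.DataFrame({f"{m}_primary": np.arange(10.0) for m in METRICS})
        for m in METRICS:
            df[f"{m}_metastasis"] = df[f"{m}_primary"]
        out = site_concordance(df, METRICS)
        np.testing.assert_allclose(out["rho"], 1.0, atol=1e-12)
        assert out["significant"].all()

    def test_too_few_pairs_missing(self):
        df = pd.DataFrame({"vessel_density_primary": [1.0, 2.0],
                           "vessel_density_metastasis": [2.0, 1.0]})
        out = site_concordance(df, ["vessel_density"])
        assert np.isnan(out.iloc[0]["rho"])

    def test_generator_concordance_recovered_at_pair_scale(self):
        conc = dict.fromkeys(METRICS, 0.0)
        conc["pdgfrb_stroma_fraction"] = 0.45
        df = generate_cohort(CohortSimParams(
            n_cases=91, seed=3, primary_metastasis_concordance=conc,
            site_fractions=(1.0, 0.0, 0.0)))
        out = site_concordance(df, METRICS).set_index("metric")
        assert out.loc["pdgfrb_stroma_fraction", "rho"] == pytest.approx(0.45, abs=0.2)
        null_rhos = out.drop(index="pdgfrb_stroma_fraction")["rho"]
        assert null_rhos.abs().max() < 0.35


class TestDichotomize:
    def test_mean_split_example(self):
        labels = dichotomize(np.array([1.0, 2.0, 3.0, 4.0]), "mean_split")
        np.testing.assert_array_equal(labels, [False, False, True, True])

    def test_lowest_quartile_four_points(self):
        # type-7 first quartile of [1,2,3,4] is 1.75 -> exactly one low value
        labels = dichotomize(np.array([1.0, 2.0, 3.0, 4.0]), "lowest_quartile_vs_rest")
        np.testing.assert_array_equal(labels, [False, True, True, True])

    def test_lowest_quartile_monotone_transform_invariant(self):
        rng = np.random.default_rng(1)
        v = rng.random(37)
        a = dichotomize(v, "lowest_quartile_vs_rest")
        b = dichotomize(np.exp(5 * v), "lowest_quartile_vs_rest")
        np.testing.assert_array_equal(a, b)

    def test_degenerate_and_short_inputs_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            dichotomize(np.ones(10))
        with pytest.raises(ValueError, match="at least 4"):
            dichotomize(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="unknown"):
            dichotomize(np.arange(5.0), "median_split")


class TestKaplanMeier:
    def test_identical_groups_logrank_p_near_one(self):
        base = survival_frame(120, 5)
        df = pd.concat([base, base], ignore_index=True)
        high = np.r_[np.zeros(len(base), bool), np.ones(len(base), bool)]
        out = km_logrank(high, df["os_months"], df["event"])
        assert out["logrank_p"] > 0.95

    def test_exponential_median_closed_form(self):
        rng = np.random.default_rng(8)
        lam = 0.05
        t = rng.exponential(1 / lam, 5000)
        high = np.r_[np.ones(2500, bool), np.zeros(2500, bool)]
        out = km_logrank(high, t, np.ones(5000, int))
        for g in ("low", "high"):
            assert out[f"median_{g}"] == pytest.approx(np.log(2) / lam, rel=0.05)

    def test_point_mass_groups_have_their_medians(self):
        t = np.r_[np.ones(30), np.full(30, 2.0)]
        high = np.r_[np.zeros(30, bool), np.ones(30, bool)]
        out = km_logrank(high, t, np.ones(60, int))
        assert out["median_low"] == 1.0 and out["median_high"] == 2.0

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            km_logrank(np.ones(5, bool), np.arange(5.0) + 1, np.ones(5, int))


class TestCox:
    def test_large_n_hr_recovery(self):
        df = survival_frame(2000, 11, hr_high=1.7, rate=0.02, cens=0.009)
        fit = cox_fit(df, "metric_high", "univariate")
        hr = fit.set_index("term").loc["metric_high", "hr"]
        assert 1.5 <= hr <= 1.9

    def test_time_scale_invariance(self):
        df = survival_frame(400, 2, hr_high=2.0)
        fit1 = cox_fit(df, "metric_high", "univariate")
        df2 = df.assign(os_months=2.0 * df["os_months"])
        fit2 = cox_fit(df2, "metric_high", "univariate")
        assert fit1.loc[0, "hr"] == pytest.approx(fit2.loc[0, "hr"], rel=1e-6)

    def test_efron_and_breslow_agree_without_ties(self):
        df = survival_frame(300, 7, hr_high=1.8)
        efron = cox_fit(df, "metric_high", "univariate", config=CoxConfig("efron"))
        breslow = cox_fit(df, "metric_high", "univariate", config=CoxConfig("breslow"))
        # continuous times: no ties, the two partial likelihoods coincide
        assert efron.loc[0, "coef"] == pytest.approx(breslow.loc[0, "coef"], abs=1e-4)

    def test_multivariate_adjusts_for_clinical_design(self):
        df = generate_cohort(CohortSimParams(n_cases=1500, seed=19))
        metric = "pdgfrb_stroma_fraction"
        val = df[f"{metric}_primary"].where(
            df[f"{metric}_primary"].notna(), df[f"{metric}_metastasis"])
        df = df.assign(metric_high=dichotomize(val.to_numpy(), "mean_split").astype(float))
        fit = cox_fit(df, "metric_high", "multivariate").set_index("term")
        assert fit.loc["metric_high", "hr"] == pytest.approx(1.66, rel=0.15)
        assert fit.loc["residual_tumor", "hr"] > 2.5
        assert (fit["ci_low"] <= fit["hr"]).all() and (fit["hr"] <= fit["ci_high"]).all()

    def test_few_events_warns(self):
        df = survival_frame(30, 3, cens=0.2)
        with pytest.warns(UserWarning, match="events"):
            cox_fit(df, "metric_high", "univariate")


class TestBackwardSelection:
    def test_strong_term_retained_null_terms_dropped(self):
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            df = survival_frame(300, 100 + rep, hr_high=3.0)
            rng = np.random.default_rng(1000 + rep)
            df["noise1"] = rng.standard_normal(len(df))
            df["noise2"] = rng.standard_normal(len(df))
            sel = backward_selection(df, "metric_high", covariates=["noise1", "noise2"])
            if sel["metric_retained"] and "noise1" not in sel["retained_terms"] \
                    and "noise2" not in sel["retained_terms"]:
                hits += 1
        assert hits / n_rep >= 0.9

    def test_deterministic_for_fixed_data(self):
        df = survival_frame(200, 4, hr_high=2.0)
        df["noise"] = np.sin(np.arange(len(df)))
        a = backward_selection(df, "metric_high", covariates=["noise"])
        b = backward_selection(df, "metric_high", covariates=["noise"])
        assert a["retained_terms"] == b["retained_terms"]
        assert a["eliminated"] == b["eliminated"]

    def test_empty_covariate_set_is_identity_for_significant_metric(self):
        df = survival_frame(500, 6, hr_high=3.0)
        sel = backward_selection(df, "metric_high", covariates=[])
        assert sel["metric_retained"]
        assert sel["retained_terms"] == ["metric_high"]


class TestChiSquare:
    def test_perfect_independence(self):
        high = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        clinical = pd.DataFrame({"grade": ["1"] * 10 + ["2"] * 10 + ["1"] * 10 + ["2"] * 10})
        out = chi_square_association(high, clinical, ["grade"])
        assert out.iloc[0]["statistic"] == pytest.approx(0.0)
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_perfect_association_statistic_40(self):
        high = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        clinical = pd.DataFrame({"grade": ["1"] * 20 + ["2"] * 20})
        out = chi_square_association(high, clinical, ["grade"])
        assert out.iloc[0]["statistic"] == pytest.approx(40.0)

    def test_transpose_invariance(self):
        from scipy.stats import chi2_contingency
        tab = np.array([[12, 5, 8], [3, 9, 7]])
        s1 = chi2_contingency(tab, correction=False)[0]
        s2 = chi2_contingency(tab.T, correction=False)[0]
        assert s1 == pytest.approx(s2)

    def test_degenerate_table_missing(self):
        high = np.ones(10, bool)
        high[0] = False
        clinical = pd.DataFrame({"grade": ["2"] * 10})
        out = chi_square_association(high, clinical, ["grade"])
        assert np.isnan(out.iloc[0]["statistic"])
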