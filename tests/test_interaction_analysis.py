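"""Regression, moderation, median-split and sensitivity behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import prsmod as pm


def pheno_frame(**cols):
    n = len(next(iter(cols.values())))
    base = {"sample_id": [f"s{i}" for i in range(n)]}
    base.update(cols)
    return pd.DataFrame(base)


class TestDescribePrevalence:
    def test_zero_cases(self):
        p = pheno_frame(hba1c=np.full(50, 40.0), diabetes=np.zeros(50))
        d = pm.describe_prevalence(p)
        assert d["pct_diabetes"] == 0.0 and d["n_above_cutoff"] == 0

    def test_cutoff_is_inclusive(self):
        p = pheno_frame(hba1c=np.array([47.9, 48.0, 48.1]), diabetes=np.zeros(3))
        assert pm.describe_prevalence(p, 48.0)["n_above_cutoff"] == 2

    def test_all_missing_hba1c_rejected(self):
        p = pheno_frame(hba1c=np.full(5, np.nan))
        with pytest.raises(pm.ValidationError):
            pm.describe_prevalence(p)


class TestFitLinear:
    def test_perfect_fit(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        p = pheno_frame(hba1c=s.copy())
        fit = pm.fit_linear(p, s)
        assert fit.standardized_betas["score"] == pytest.approx(1.0, abs=1e-10)

    def test_simple_beta_equals_pearson_r(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=200)
        y = 0.4 * s + rng.normal(size=200)
        p = pheno_frame(hba1c=y)
        fit = pm.fit_linear(p, s)
        r = np.corrcoef(s, y)[0, 1]
        assert fit.standardized_betas["score"] == pytest.approx(r, abs=1e-10)

    def test_constant_predictor_rejected(self):
        p = pheno_frame(hba1c=np.random.default_rng(2).normal(size=20))
        with pytest.raises(pm.ValidationError, match="constant"):
            pm.fit_linear(p, np.ones(20))

    def test_rank_deficient_names_collinear_term(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=30)
        p = pheno_frame(hba1c=rng.normal(size=30), twin=s.copy())
        with pytest.raises(pm.ValidationError, match="twin"):
            pm.fit_linear(p, s, covariates=("twin",))

    def test_too_few_complete_cases(self):
        p = pheno_frame(hba1c=np.r_[np.full(15, np.nan), [1.0, 2.0, 3.0]])
        with pytest.raises(pm.ValidationError, match="complete cases"):
            pm.fit_linear(p, np.arange(18.0))

    def test_listwise_deletion_counts(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=40)
        y[:5] = np.nan
        p = pheno_frame(hba1c=y)
        fit = pm.fit_linear(p, rng.normal(size=40))
        assert fit.n_used == 35


class TestFitLogistic:
    def test_null_association(self):
        rng = np.random.default_rng(5)
        n = 4000
        y = rng.integers(0, 2, n).astype(float)
        s = rng.normal(size=n)
        p = pheno_frame(hba1c=np.full(n, 40.0), diabetes=y)
        fit = pm.fit_logistic(p, s)
        t = fit.term("score")
        assert abs(t.estimate) < 3 * t.std_error

    def test_log_or_recovery(self):
        """ML estimates of a known log-OR of 0.6 are unbiased at n=10,000."""
        ests = []
        for r in range(200):
            rng = np.random.default_rng(600 + r)
            n = 10_000
            x = rng.normal(size=n)
            prob = 1 / (1 + np.exp(-(-2.2 + 0.6 * x)))
            y = (rng.random(n) < prob).astype(float)
            p = pheno_frame(hba1c=np.full(n, 40.0), diabetes=y)
            fit = pm.fit_logistic(p, x, standardize_vars=False)
            ests.append(fit.term("score").estimate)
        assert np.mean(ests) == pytest.approx(0.6, abs=0.05)

    def test_separation_raises(self):
        rng = np.random.default_rng(6)
        x = np.r_[rng.normal(-2, 0.5, 30), rng.normal(2, 0.5, 30)]
        y = (x > 0).astype(float)
        p = pheno_frame(hba1c=np.full(60, 40.0), diabetes=y)
        with pytest.raises(pm.SeparationError):
            pm.fit_logistic(p, x)

    def test_single_class_rejected(self):
        p = pheno_frame(hba1c=np.full(30, 40.0), diabetes=np.zeros(30))
        with pytest.raises(pm.ValidationError, match="single class"):
            pm.fit_logistic(p, np.random.default_rng(7).normal(size=30))

    def test_too_few_events_rejected(self):
        y = np.zeros(100)
        y[:5] = 1
        p = pheno_frame(hba1c=np.full(100, 40.0), diabetes=y)
        with pytest.raises(pm.ValidationError, match="events"):
            pm.fit_logistic(p, np.random.default_rng(8).normal(size=100))


class TestModeration:
    def test_single_threshold_reduces_to_base_fit(self, default_cohort):
        c = default_cohort
        aligned = pm.harmonize(c.summary_stats, c.genotypes)[:2]
        rss = pm.threshold_scores(*aligned, [1.0])
        moder = pm.fit_moderation(c.phenotypes, rss, outcome="hba1c")
        direct = pm.fit_linear(
            c.phenotypes, rss.z[:, 0],
            include_moderator=True, include_interaction=True,
        )
        fit = moder.fits[1.0]
        for name in fit.terms:
            assert fit.term(name).estimate == pytest.approx(
                direct.term(name).estimate, abs=1e-12
            )

    def test_degenerate_column_skipped(self):
        n = 60
        rng = np.random.default_rng(9)
        pheno = pheno_frame(
            hba1c=rng.normal(40, 5, n), moderator=rng.normal(size=n)
        )
        z = rng.normal(size=(n, 2))
        rss = pm.RiskScoreSet(
            sample_ids=np.array(pheno["sample_id"], dtype=object),
            thresholds=np.array([1.0, 0.01]),
            raw=np.zeros((n, 2)),
            z=z,
            n_snps_per_threshold=np.array([10, 0]),
            degenerate=np.array([False, True]),
        )
        moder = pm.fit_moderation(pheno, rss, outcome="hba1c")
        assert list(moder.fits) == [1.0]
        assert len(moder.summary) == 1

    def test_binary_outcome_uses_logistic_family(self, default_cohort):
        c = default_cohort
        aligned = pm.harmonize(c.summary_stats, c.genotypes)[:2]
        rss = pm.threshold_scores(*aligned, [1.0])
        moder = pm.fit_moderation(c.phenotypes, rss, outcome="diabetes")
        assert moder.fits[1.0].family == "logistic"
        assert "interaction_or_per_sd" in moder.summary.columns


class TestMedianSplit:
    def test_even_n_distinct_values_balanced(self):
        rng = np.random.default_rng(10)
        n = 200
        pheno = pheno_frame(
            hba1c=rng.normal(40, 5, n), moderator=rng.permutation(n).astype(float)
        )
        res = pm.median_split_analysis(pheno, rng.normal(size=n))
        assert res.n_low == res.n_high == 100

    def test_effect_r_is_pearson_correlation(self):
        rng = np.random.default_rng(11)
        n = 300
        s = rng.normal(size=n)
        m = rng.normal(size=n)
        y = 40 + 2 * s + rng.normal(size=n)
        pheno = pheno_frame(hba1c=y, moderator=m)
        res = pm.median_split_analysis(pheno, s)
        low = m <= np.median(m)
        r_low = np.corrcoef(s[low], y[low])[0, 1]
        r_high = np.corrcoef(s[~low], y[~low])[0, 1]
        assert res.effect_r_low == pytest.approx(r_low, abs=1e-10)
        assert res.effect_r_high == pytest.approx(r_high, abs=1e-10)

    def test_ties_go_to_low_group(self):
        rng = np.random.default_rng(12)
        n = 21
        m = np.r_[np.zeros(11), np.ones(10)]  # median 0, with ties at 0
        pheno = pheno_frame(hba1c=rng.normal(40, 5, n), moderator=m)
        res = pm.median_split_analysis(pheno, rng.normal(size=n))
        assert res.n_low == 11 and res.n_high == 10

    def test_constant_moderator_rejected(self):
        pheno = pheno_frame(hba1c=np.arange(20.0), moderator=np.ones(20))
        with pytest.raises(pm.ValidationError):
            pm.median_split_analysis(pheno, np.arange(20.0))

    def test_small_stratum_rejected(self):
        rng = np.random.default_rng(13)
        pheno = pheno_frame(hba1c=rng.normal(size=12), moderator=rng.normal(size=12))
        with pytest.raises(pm.ValidationError, match="stratum"):
            pm.median_split_analysis(pheno, rng.normal(size=12))


class TestScaleEquivariance:
    def test_positive_rescaling_leaves_standardized_results_unchanged(
        self, default_cohort
    ):
        c = default_cohort
        s = c.true_score
        for factor in (3.7, 0.002):
            a = pm.fit_linear(c.phenotypes, s, include_moderator=True,
                              include_interaction=True)
            b = pm.fit_linear(c.phenotypes, factor * s, include_moderator=True,
                              include_interaction=True)
            for name in a.terms:
                assert a.term(name).estimate == pytest.approx(
                    b.term(name).estimate, abs=1e-10
                )
                assert a.term(name).p_value == pytest.approx(
                    b.term(name).p_value, abs=1e-10
                )
            la = pm.fit_logistic(c.phenotypes, s, outcome="diabetes")
            lb = pm.fit_logistic(c.phenotypes, factor * s, outcome="diabetes")
            assert la.odds_ratios_per_sd["score"][0] == pytest.approx(
                lb.odds_ratios_per_sd["score"][0], abs=1e-8
            )
            ra = pm.median_split_analysis(c.phenotypes, s)
            rb = pm.median_split_analysis(c.phenotypes, factor * s)
            assert ra.effect_r_low == pytest.approx(rb.effect_r_low, abs=1e-10)


def test_interaction_plot_written(tmp_path, default_cohort):
    out = tmp_path / "interaction.png"
    pm.plot_interaction(default_cohort.phenotypes, default_cohort.true_score, out)
    assert out.exists() and out.stat().st_size > 0


class TestSensitivity:
    def test_empty_exclusion_is_identity(self, default_cohort):
        c = default_cohort
        pheno = c.phenotypes.copy()
        pheno["never"] = 0
        res = pm.sensitivity_refit(
            pheno, c.true_score, outcome="hba1c", exclude_flag="never"
        )
        assert res.delta_score == pytest.approx(0.0, abs=1e-12)
        assert res.delta_interaction == pytest.approx(0.0, abs=1e-12)

    def test_missing_flag_column_rejected(self, default_cohort):
        with pytest.raises(pm.ValidationError, match="nope"):
            pm.sensitivity_refit(
                default_cohort.phenotypes, default_cohort.true_score,
                exclude_flag="nope",
            )

    def test_irrelevant_covariate_changes_little(self):
        c = pm.simulate_cohort(pm.SimulationConfig(n_samples=10_000, n_snps=50, seed=30))
        pheno = c.phenotypes.copy()
        pheno["junk"] = np.random.default_rng(31).normal(size=len(pheno))
        res = pm.sensitivity_refit(
            pheno, c.true_score, outcome="hba1c", add_covariate="junk"
        )
        se = res.baseline.term("score").std_error
        assert abs(res.delta_score) < 2 * se

    def test_null_exclusion_keeps_interaction_p_uniform(self):
        """Excluding a ~1.2%-flagged subgroup under the null interaction
        leaves the interaction p-value distribution uniform."""
        pvals = []
        for r in range(500):
            cfg = pm.SimulationConfig(
                beta_interaction=0.0, n_snps=48, seed=40_000 + r
            )
            c = pm.simulate_cohort(cfg)
            res = pm.sensitivity_refit(
                c.phenotypes, c.true_score, outcome="hba1c",
                exclude_flag="insulin_therapy",
            )
            pvals.append(res.sensitivity.term("score_x_moderator").p_value)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
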