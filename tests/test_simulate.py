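import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from bivpois import (
    SimConfig,
    contamination_scenario,
    default_scenario,
    inject_outliers,
    sample_covariates,
    sample_outcomes,
    simulate,
)
from bivpois.simulate import _linear_predictors


def intercept_config(b1, b2, n=20_000, seed=0, **kw):
    # a single-category covariate contributes no dummy column, leaving an
    # intercept-only design
    return SimConfig(
        n_records=n,
        seed=seed,
        category_probs={"residence": {"rural": 1.0}},
        beta_schooling=np.array([b1]),
        beta_fertility=np.array([b2]),
        include_age=False,
        include_age1stsex=False,
        **kw,
    )


class TestSampleCovariates:
    def test_degenerate_distribution(self):
        cov = sample_covariates(intercept_config(0.0, 0.0, n=5))
        assert (cov["residence"] == "rural").all()

    def test_category_shares_match_probabilities(self):
        cfg = default_scenario(n_records=10_000, seed=3)
        cov = sample_covariates(cfg)
        share = (cov["residence"] == "rural").mean()
        assert abs(share - 10_058 / 11_698) < 0.02  # 3-sigma binomial bound

    def test_seeded_determinism(self):
        cfg = default_scenario(n_records=500, seed=9)
        pd.testing.assert_frame_equal(sample_covariates(cfg), sample_covariates(cfg))

    def test_age_at_first_sex_not_after_age(self):
        cfg = default_scenario(n_records=3000, seed=4)
        cov = sample_covariates(cfg)
        assert (cov["age_first_sex"] <= cov["age"]).all()
        assert cov["age"].between(*cfg.age_range).all()

    def test_invalid_probabilities_named(self):
        with pytest.raises(ValueError, match="residence"):
            SimConfig(
                n_records=10,
                seed=0,
                category_probs={"residence": {"rural": 0.7, "urban": 0.2}},
                beta_schooling=np.zeros(2),
                beta_fertility=np.zeros(2),
                include_age=False,
                include_age1stsex=False,
            )


class TestSampleOutcomes:
    def test_marginal_mean_matches_rate(self):
        cfg = intercept_config(np.log(2.0), 0.0)
        rec = sample_outcomes(sample_covariates(cfg), cfg)
        # 3-sigma Monte-Carlo bound: sd = sqrt(2/20000) ~ 0.01
        assert abs(rec["schooling_years"].mean() - 2.0) < 0.05

    def test_covariance_equals_shock_rate(self):
        cfg = intercept_config(0.0, 0.0, theta3_shared=1.0)
        rec = sample_outcomes(sample_covariates(cfg), cfg)
        cov = np.cov(rec["schooling_years"], rec["children_ever_born"])[0, 1]
        assert abs(cov - 1.0) < 0.1

    def test_opposite_signed_covariate_induces_negative_correlation(self):
        cfg = SimConfig(
            n_records=20_000,
            seed=2,
            category_probs={},
            beta_schooling=np.array([0.7, 0.03]),
            beta_fertility=np.array([0.7, -0.03]),
            include_age=False,
            include_age1stsex=True,
            age1stsex_range=(10, 40),
        )
        rec = sample_outcomes(sample_covariates(cfg), cfg)
        rho = spearmanr(rec["schooling_years"], rec["children_ever_born"]).statistic
        assert rho < 0

    def test_conditional_independence_within_cell_at_zero_shock(self):
        cfg = intercept_config(np.log(3.0), np.log(2.0), n=50_000, seed=7)
        rec = sample_outcomes(sample_covariates(cfg), cfg)
        r = np.corrcoef(rec["schooling_years"], rec["children_ever_born"])[0, 1]
        assert abs(r) < 0.05

    def test_mean_includes_shock(self):
        cfg = intercept_config(0.0, 0.0, theta3_shared=2.0, seed=5)
        rec = sample_outcomes(sample_covariates(cfg), cfg)
        # E[y] = exp(beta0) + theta3 = 3; MC sd = sqrt(3/20000)
        for col in ("schooling_years", "children_ever_born"):
            assert abs(rec[col].mean() - 3.0) < 3 * np.sqrt(3 / 20_000)

    def test_overflow_guard(self):
        cfg = intercept_config(0.0, 0.0, n=10)
        cfg.beta_schooling = np.array([40.0])
        with pytest.raises(FloatingPointError, match="rescal"):
            sample_outcomes(sample_covariates(cfg), cfg)


class TestInjectOutliers:
    def test_zero_fraction_is_noop(self):
        cfg = contamination_scenario(1000, seed=0, contamination_fraction=0.0)
        rec = sample_outcomes(sample_covariates(cfg), cfg)
        out = inject_outliers(rec, cfg)
        pd.testing.assert_frame_equal(out, rec)
        assert not out["is_contaminated"].any()

    def test_exact_count(self):
        cfg = contamination_scenario(10_000, seed=1, contamination_fraction=0.01)
        rec = simulate(cfg)
        assert rec["is_contaminated"].sum() == 100

    def test_swap_rule_direction(self):
        cfg = contamination_scenario(5000, seed=2)
        rec = simulate(cfg)
        eta1, _ = _linear_predictors(rec, cfg)
        pred = np.exp(eta1)
        med = np.median(pred)
        bad = rec["is_contaminated"].to_numpy()
        high = bad & (pred >= med)
        low = bad & (pred < med)
        assert (rec.loc[high, "schooling_years"] == 0).all()
        assert (rec.loc[high, "children_ever_born"] >= 5).all()
        assert (rec.loc[low, "schooling_years"] >= 9).all()
        assert (rec.loc[low, "children_ever_born"] == 0).all()
        untouched = ~bad
        base = sample_outcomes(sample_covariates(cfg), cfg)
        pd.testing.assert_frame_equal(
            rec.loc[untouched].reset_index(drop=True),
            base.loc[untouched].reset_index(drop=True),
        )

    def test_excessive_fraction_rejected(self):
        with pytest.raises(ValueError, match="contamination_fraction"):
            contamination_scenario(100, contamination_fraction=0.6)


class TestEndToEnd:
    def test_bit_reproducible(self):
        cfg = default_scenario(n_records=800, seed=21)
        pd.testing.assert_frame_equal(simulate(cfg), simulate(cfg))

    def test_default_scenario_is_dhs_like(self, default_records):
        cfg, rec = default_records
        assert 3.5 < rec["schooling_years"].mean() < 7.5
        assert 1.5 < rec["children_ever_born"].mean() < 4.5
        rho = spearmanr(rec["schooling_years"], rec["children_ever_born"]).statistic
        assert rho < -0.15  # covariate-induced negative dependence

    def test_config_roundtrip_from_dict(self):
        cfg = default_scenario(n_records=50, seed=1)
        d = dict(
            n_records=50,
            seed=1,
            category_probs=cfg.category_probs,
            beta_schooling=cfg.beta_schooling,
            beta_fertility=cfg.beta_fertility,
            age_range=[15, 49],
            age1stsex_range=[12, 22],
        )
        cfg2 = SimConfig.from_dict(d)
        pd.testing.assert_frame_equal(simulate(cfg), simulate(cfg2))
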