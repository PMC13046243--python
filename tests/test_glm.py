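"""Developmental linear models, FDR, model comparison."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from neolaminar.errors import AlignmentError, CollinearityError, ContractError
from neolaminar.glm import (
    ModelSpec,
    bh_significant,
    build_design,
    compare_models,
    depthwise_age_correlation,
    fit_ols,
    interaction_effects,
    parcelwise_effects,
)
from neolaminar.phantom import simulate_cohort


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(120, seed=5)


class TestFitOls:
    def test_printed_toy_slope(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 4.0])
        res = fit_ols(np.column_stack([np.ones(4), x]), y, ["intercept", "x"])
        assert res.term("x")[0] == pytest.approx(0.9, abs=1e-12)

    def test_constant_response(self):
        x = np.arange(5.0)
        res = fit_ols(np.column_stack([np.ones(5), x]), np.full(5, 3.0))
        coef, _, t, _ = res.coef[1], res.se[1], res.t[1], res.p[1]
        assert coef == pytest.approx(0.0, abs=1e-12)
        assert t == pytest.approx(0.0, abs=1e-6)

    def test_perfect_fit(self):
        x = np.arange(6.0)
        res = fit_ols(np.column_stack([np.ones(6), x]), 2.0 + 3.0 * x)
        assert res.rss == pytest.approx(0.0, abs=1e-18)
        assert res.r2 == pytest.approx(1.0)

    def test_agrees_with_statsmodels(self, cohort):
        # independent oracle for coefficients, SEs, t, p, r2 and AIC
        rng = np.random.default_rng(8)
        X, names = build_design(cohort, ("ga", "pna", "sex"))
        y = 0.3 * cohort["ga_weeks"].to_numpy() + rng.normal(0, 1, len(cohort))
        ours = fit_ols(X, y, names)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(ours.coef, ref.params, rtol=1e-10)
        assert np.allclose(ours.se, ref.bse, rtol=1e-10)
        assert np.allclose(ours.t, ref.tvalues, rtol=1e-10)
        assert np.allclose(ours.p, ref.pvalues, rtol=1e-8)
        assert ours.r2 == pytest.approx(ref.rsquared, rel=1e-10)
        assert ours.aic == pytest.approx(ref.aic, rel=1e-10)

    def test_rank_deficiency_names_columns(self, cohort):
        X, names = build_design(cohort, ("ga", "pna"))
        X = np.column_stack([X, X[:, 1] + X[:, 2]])  # pma duplicate
        with pytest.raises(CollinearityError):
            fit_ols(X, np.zeros(len(X)), names + ["pma"])


class TestModelSpec:
    def test_pma_with_ga_and_pna_rejected(self):
        with pytest.raises(CollinearityError):
            ModelSpec(response="mu1", predictors=("pma", "ga", "pna", "sex"),
                      term_of_interest="pma")

    def test_term_must_be_a_predictor(self):
        with pytest.raises(ContractError):
            ModelSpec(response="mu1", predictors=("ga", "sex"),
                      term_of_interest="pna")


class TestBenjaminiHochberg:
    def test_hand_worked_four_pvalue_example(self):
        # step-up at alpha = 0.025: largest k with p_(k) <= 0.025 k / 4
        # is k = 2, so exactly the two smallest are rejected
        reject, q = bh_significant([0.001, 0.008, 0.039, 0.041], alpha=0.025)
        assert list(reject) == [True, True, False, False]
        assert np.all(q >= [0.001, 0.008, 0.039, 0.041])

    def test_null_fdr_controlled(self, cohort):
        # parcel-wise analysis of pure-noise moments: expected false
        # discovery proportion stays at or below alpha
        rng = np.random.default_rng(77)
        alpha = 0.025
        n_rep, n_parcels = 200, 66
        spec = ModelSpec(response="mu1", predictors=("ga", "pna", "sex"),
                         term_of_interest="ga")
        fdp = np.empty(n_rep)
        for r in range(n_rep):
            Y = rng.normal(size=(n_parcels, len(cohort)))
            eff = parcelwise_effects(Y, cohort, spec, alpha=alpha)
            n_sig = int(eff["significant"].sum())
            fdp[r] = 0.0 if n_sig == 0 else 1.0  # all discoveries false
        se = fdp.std(ddof=1) / np.sqrt(n_rep)
        assert fdp.mean() <= alpha + 2 * se + 0.01


class TestParcelwiseEffects:
    def test_misaligned_subjects_rejected(self, cohort):
        table = pd.DataFrame(np.zeros((3, len(cohort))),
                             columns=[f"other-{i}" for i in range(len(cohort))])
        spec = ModelSpec(response="mu1", predictors=("pma", "sex"),
                         term_of_interest="pma")
        with pytest.raises(AlignmentError):
            parcelwise_effects(table, cohort, spec)

    def test_planted_effect_detected_with_correct_sign(self, cohort):
        rng = np.random.default_rng(2)
        ga = cohort["ga_weeks"].to_numpy()
        affected = 0.1 * ga + rng.normal(0, 0.3, (5, len(cohort)))
        null = rng.normal(0, 0.3, (5, len(cohort)))
        spec = ModelSpec(response="mu1", predictors=("ga", "pna", "sex"),
                         term_of_interest="ga")
        eff = parcelwise_effects(np.vstack([affected, null]), cohort, spec)
        assert eff["t"][:5].min() > 0
        assert eff["significant"][:5].all()
        assert not eff["significant"][5:].any()

    def test_q_at_least_p(self, cohort):
        rng = np.random.default_rng(3)
        spec = ModelSpec(response="mu1", predictors=("pma", "sex"),
                         term_of_interest="pma")
        eff = parcelwise_effects(rng.normal(size=(20, len(cohort))),
                                 cohort, spec)
        assert (eff["q"] >= eff["p"] - 1e-15).all()


class TestInteraction:
    def test_centering_invariance(self, cohort):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(4, len(cohort)))
        base = interaction_effects(Y, cohort)
        shifted = cohort.copy()
        shifted["ga_weeks"] = shifted["ga_weeks"] + 100.0
        shifted["pma_weeks"] = shifted["ga_weeks"] + shifted["pna_weeks"]
        moved = interaction_effects(Y, shifted)
        assert np.allclose(base["t"], moved["t"], atol=1e-8)

    def test_planted_interaction_recovered(self):
        cohort = simulate_cohort(300, seed=9)
        rng = np.random.default_rng(10)
        ga_c = cohort["ga_weeks"] - cohort["ga_weeks"].mean()
        pna_c = cohort["pna_weeks"] - cohort["pna_weeks"].mean()
        y = 0.2 * (ga_c * pna_c).to_numpy() + rng.normal(0, 0.5, len(cohort))
        eff = interaction_effects(y[None, :], cohort)
        assert eff["t"].iloc[0] > 0 and eff["significant"].iloc[0]


class TestCompareModels:
    def test_true_predictor_wins_by_aic(self, cohort):
        rng = np.random.default_rng(12)
        y = 0.5 * cohort["ga_weeks"].to_numpy() + rng.normal(0, 1.0,
                                                             len(cohort))
        fits, ftests = compare_models(y, cohort, [("sex",), ("ga", "sex")])
        assert fits.iloc[0]["model"] == "ga+sex"
        row = ftests.iloc[0]
        assert row["restricted"] == "sex" and row["p"] < 1e-6

    def test_identical_candidates_identical_rows(self, cohort):
        rng = np.random.default_rng(13)
        y = rng.normal(size=len(cohort))
        fits, _ = compare_models(y, cohort, [("ga", "sex"), ("ga", "sex")])
        assert fits.iloc[0].equals(fits.iloc[1])

    def test_f_tests_only_for_nested_pairs(self, cohort):
        rng = np.random.default_rng(14)
        y = rng.normal(size=len(cohort))
        _, ftests = compare_models(y, cohort, [("ga", "sex"), ("pna", "sex")])
        assert len(ftests) == 0


class TestDepthwiseCorrelation:
    def test_perfect_correlation_at_one_depth(self):
        age = np.linspace(30, 44, 20)
        profiles = np.tile(np.ones(12), (20, 1))
        profiles[:, 4] = age
        r, p = depthwise_age_correlation(profiles, age)
        assert r[4] == pytest.approx(1.0)
        assert np.isnan(r[[0, 1, 11]]).all()  # zero-variance depths flagged

    def test_sign_matches_planted_slope(self):
        rng = np.random.default_rng(15)
        age = np.linspace(28, 44, 60)
        slopes = np.linspace(-0.5, 0.5, 12)
        profiles = 5.0 + np.outer(age - 36, slopes)
        profiles += rng.normal(0, 0.1, profiles.shape)
        r, _ = depthwise_age_correlation(profiles, age)
        nonzero = np.abs(slopes) > 0.1
        assert np.all(np.sign(r[nonzero]) == np.sign(slopes[nonzero]))

    def test_too_few_subjects(self):
        with pytest.raises(ContractError):
            depthwise_age_correlation(np.ones((2, 12)), np.array([1.0, 2.0]))
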