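"""Candidate enumeration, AICc ranking, averaging, RVI, VIF, Type-III."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from groomnet import model_inference as mi
from groomnet import synthetic_data as sd
from groomnet.study_data import ValidationError


def toy_fit(terms=(), loglik=-100.0, n=119, k=None, estimates=None,
            ses=None, response="vsc") -> mi.FitResult:
    """Hand-assembled FitResult for the pure bookkeeping operations."""
    spec = mi.ModelSpec(response=response, fixed_terms=tuple(terms))
    names = ["(Intercept)"] + list(terms)
    est = estimates if estimates is not None else [0.0] * len(names)
    se = ses if ses is not None else [1.0] * len(names)
    coef = pd.DataFrame({"estimate": est, "se": se}, index=names)
    return mi.FitResult(spec=spec, n=n,
                        k=k if k is not None else len(names) + 3,
                        loglik=loglik, coefficients=coef, varcomps={},
                        converged=True, core=None)


def manual_ranked(fits, weights, subset=None) -> mi.RankedModelSet:
    """RankedModelSet with externally chosen weights."""
    weights = np.asarray(weights, dtype=float)
    n = len(fits)
    return mi.RankedModelSet(
        fits=fits, aicc=np.zeros(n), delta=np.zeros(n), weight=weights,
        order=np.arange(n),
        subset_mask=np.ones(n, bool) if subset is None
        else np.asarray(subset, bool),
        delta_threshold=10.0)


@pytest.fixture(scope="module")
def sim_measures():
    """Study-scale simulated measure table (18 subjects, 18 periods)."""
    return sd.measures_from_simulation(sd.SimConfig(seed=11))


class TestEnumerate:
    def test_five_factors_give_32_specs_one_null(self):
        specs = mi.enumerate_candidates()
        assert len(specs) == 32
        assert sum(1 for s in specs if not s.fixed_terms) == 1
        sizes = [len(s.fixed_terms) for s in specs]
        assert sizes == sorted(sizes)

    def test_enumeration_is_deterministic(self):
        a = [s.fixed_terms for s in mi.enumerate_candidates()]
        b = [s.fixed_terms for s in mi.enumerate_candidates()]
        assert a == b

    def test_single_factor_gives_two_specs(self):
        specs = mi.enumerate_candidates(("Origin",))
        assert [s.fixed_terms for s in specs] == [(), ("Origin",)]

    def test_no_factors_rejected(self):
        with pytest.raises(ValidationError):
            mi.enumerate_candidates(())

    def test_duplicate_factors_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            mi.enumerate_candidates(("Origin", "Origin"))


class TestAicc:
    def test_hand_computed_value(self):
        fit = toy_fit(loglik=-100.0, n=119, k=4)
        assert mi.aicc(fit) == pytest.approx(208.0 + 40.0 / 114.0,
                                             abs=1e-9)

    def test_large_n_limit_is_aic(self):
        fit = toy_fit(loglik=-100.0, n=10 ** 9, k=4)
        assert mi.aicc(fit) == pytest.approx(208.0, abs=1e-5)

    def test_too_small_n_rejected(self):
        with pytest.raises(ValidationError):
            mi.aicc(toy_fit(loglik=-100.0, n=5, k=4))

    def test_monotone_in_loglik_and_k(self):
        base = mi.aicc(toy_fit(loglik=-100.0, n=119, k=4))
        assert mi.aicc(toy_fit(loglik=-99.0, n=119, k=4)) < base
        assert mi.aicc(toy_fit(loglik=-100.0, n=119, k=5)) > base


class TestRanking:
    def test_equal_aicc_gives_symmetric_weights(self):
        fits = [toy_fit(("Origin",), loglik=-100.0),
                toy_fit(("Sex",), loglik=-100.0)]
        ranked = mi.rank_models(fits)
        np.testing.assert_allclose(ranked.weight, [0.5, 0.5], atol=1e-12)

    def test_delta_two_weights(self):
        # second model exactly 2 AICc units worse
        fits = [toy_fit(("Origin",), loglik=-100.0),
                toy_fit(("Sex",), loglik=-101.0)]
        ranked = mi.rank_models(fits)
        expected = math.exp(-1.0) / (1.0 + math.exp(-1.0))
        np.testing.assert_allclose(ranked.weight,
                                   [1.0 - expected, expected], atol=1e-9)

    def test_single_fit(self):
        ranked = mi.rank_models([toy_fit()])
        assert ranked.delta[0] == 0.0 and ranked.weight[0] == 1.0

    def test_weights_sum_to_one_and_unique_best(self):
        rng = np.random.default_rng(3)
        fits = [toy_fit((), loglik=float(ll))
                for ll in -100 - rng.random(10) * 5]
        ranked = mi.rank_models(fits)
        assert ranked.weight.sum() == pytest.approx(1.0, abs=1e-12)
        assert (ranked.delta >= 0).all()
        assert ranked.delta[ranked.order[0]] == 0.0

    def test_tie_broken_by_fewer_parameters(self):
        # engineer identical AICc for a k=5 and a k=4 model
        f1 = toy_fit(("Origin",), loglik=-100.0, k=5)
        penalty_gap = (mi.aicc(toy_fit((), loglik=0.0, k=4))
                       - mi.aicc(toy_fit((), loglik=0.0, k=5)))
        f0 = toy_fit((), loglik=-100.0 + penalty_gap / 2, k=4)
        ranked = mi.rank_models([f1, f0])
        assert ranked.aicc[0] == pytest.approx(ranked.aicc[1], abs=1e-9)
        assert ranked.best.k == 4

    def test_all_non_converged_rejected(self):
        bad = toy_fit()
        bad.converged = False
        with pytest.raises(ValidationError):
            mi.rank_models([bad])


class TestAveraging:
    def test_single_model_degenerate_average(self):
        fit = toy_fit(("Origin",), estimates=[1.5, -0.7], ses=[0.2, 0.3])
        ranked = manual_ranked([fit], [1.0])
        av = mi.average_conditional(ranked)
        assert av.table.loc["Origin", "estimate"] == pytest.approx(-0.7)
        assert av.table.loc["Origin", "se"] == pytest.approx(0.3)

    def test_weighted_mean_of_two_models(self):
        f1 = toy_fit(("Origin",), estimates=[0.0, 1.0], ses=[1, 0.5])
        f2 = toy_fit(("Origin", "Sex"), estimates=[0.0, 2.0, 0.0],
                     ses=[1, 0.5, 1])
        ranked = manual_ranked([f1, f2], [0.6, 0.4])
        av = mi.average_conditional(ranked)
        assert av.table.loc["Origin", "estimate"] == pytest.approx(1.4)

    def test_identical_estimates_pool_to_weighted_mean_se(self):
        f1 = toy_fit(("Origin",), estimates=[0, 1.0], ses=[1, 0.4])
        f2 = toy_fit(("Origin",), estimates=[0, 1.0], ses=[1, 0.8])
        ranked = manual_ranked([f1, f2], [0.25, 0.75])
        av = mi.average_conditional(ranked)
        assert av.table.loc["Origin", "se"] == pytest.approx(
            0.25 * 0.4 + 0.75 * 0.8)

    def test_term_outside_subset_omitted(self):
        f1 = toy_fit(("Origin",))
        f2 = toy_fit(("Sex",))
        ranked = manual_ranked([f1, f2], [0.9, 0.1], subset=[True, False])
        av = mi.average_conditional(ranked)
        assert "Sex" not in av.table.index
        assert av.rvi.loc["Sex", "n_containing_models"] == 0


class TestRvi:
    def test_weights_sum_for_containing_models(self):
        fits = [toy_fit(("Origin",)), toy_fit(("Origin", "Sex")),
                toy_fit(("Sex",))]
        ranked = manual_ranked(fits, [0.6, 0.3, 0.1])
        assert mi.rvi(ranked, "Origin") == pytest.approx(0.9)
        assert mi.rvi(ranked, "Sex") == pytest.approx(0.4)
        assert mi.rvi(ranked, "PHCinfant") == 0.0

    def test_factor_in_all_models_gives_one(self):
        fits = [toy_fit(("Origin",)), toy_fit(("Origin", "Sex"))]
        ranked = manual_ranked(fits, [0.7, 0.3])
        assert mi.rvi(ranked, "Origin") == pytest.approx(1.0)

    def test_monotone_when_containing_model_added(self):
        fits = [toy_fit(("Origin",)), toy_fit(("Sex",)),
                toy_fit(("Origin", "Sex"))]
        before = mi.rvi(manual_ranked(fits, [0.5, 0.3, 0.2],
                                      subset=[True, True, False]),
                        "Origin")
        after = mi.rvi(manual_ranked(fits, [0.5, 0.3, 0.2]), "Origin")
        assert after >= before

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValidationError):
            mi.rvi(manual_ranked([toy_fit()], [1.0]), "Rank")


class TestFitLmm:
    def test_null_model_intercept_near_grand_mean(self, sim_measures):
        fit = mi.fit_lmm(sim_measures,
                         mi.ModelSpec(response="vsc", fixed_terms=()))
        grand = sim_measures["vsc"].mean()
        assert fit.coefficients.loc["(Intercept)", "estimate"] == (
            pytest.approx(grand, abs=0.5))
        assert fit.k == 4

    def test_matches_statsmodels_crossed_lmm(self, sim_measures):
        smf = pytest.importorskip("statsmodels.formula.api")
        spec = mi.ModelSpec(response="vsc",
                            fixed_terms=("Origin", "Sex", "TPstability"))
        fit = mi.fit_lmm(sim_measures, spec)
        df = sim_measures.assign(
            x_or=(sim_measures["origin"] == "wild").astype(float),
            x_sex=(sim_measures["sex"] == "M").astype(float),
            x_st=(sim_measures["stability"] == "unstable").astype(float),
            one=1)
        res = smf.mixedlm(
            "vsc ~ x_st + x_sex + x_or", df, groups="one",
            vc_formula={"id": "0 + C(individual)",
                        "per": "0 + C(period_code)"}).fit(reml=False)
        assert fit.loglik == pytest.approx(res.llf, abs=1e-4)
        assert fit.coefficients.loc["Origin", "estimate"] == pytest.approx(
            res.params["x_or"], abs=1e-4)
        assert fit.varcomps["individual"] == pytest.approx(
            res.vcomp[0], abs=1e-3)

    def test_zero_random_variance_recovered_at_boundary(self):
        rng = np.random.default_rng(5)
        n = 120
        data = pd.DataFrame({
            "individual": [f"I{i % 15}" for i in range(n)],
            "period_code": [f"P{i % 8}" for i in range(n)],
            "vsc": rng.normal(2.0, 1.0, n), "dewd": 0.1, "n_group": 5,
            "sex": ["F", "M"] * (n // 2),
            "origin": ["wild"] * (n // 2) + ["captive"] * (n // 2),
            "phc_infant": "with_conspecifics",
            "arrival_age_cat": "adult", "stability": "stable"})
        fit = mi.fit_lmm(data, mi.ModelSpec(response="vsc",
                                            fixed_terms=()))
        assert fit.varcomps["individual"] < 0.05
        assert fit.varcomps["period"] < 0.05

    def test_constant_factor_rejected_by_name(self, sim_measures):
        data = sim_measures.copy()
        data["sex"] = "F"
        with pytest.raises(ValidationError, match="Sex"):
            mi.fit_lmm(data, mi.ModelSpec(response="vsc",
                                          fixed_terms=("Sex",)))

    def test_logit_dewd_response_fits(self, sim_measures):
        fit = mi.fit_lmm(sim_measures, mi.ModelSpec(
            response="dewd_logit", fixed_terms=("TPstability",)))
        assert fit.converged
        # concentration is higher in unstable periods by construction
        assert fit.coefficients.loc["TPstability", "estimate"] > 0

    def test_dewd_rows_with_missing_response_dropped(self, sim_measures):
        data = sim_measures.copy()
        data.loc[data.index[:10], "dewd"] = np.nan
        fit = mi.fit_lmm(data, mi.ModelSpec(response="dewd",
                                            fixed_terms=("Origin",)))
        assert fit.n == len(data) - 10


class TestVif:
    @staticmethod
    def frame(origin, sex):
        n = len(origin)
        return pd.DataFrame({
            "origin": origin, "sex": sex,
            "phc_infant": (["with_conspecifics",
                            "without_conspecifics"] * n)[:n],
            "arrival_age_cat": (["adult", "adult", "subadult",
                                 "subadult"] * n)[:n],
            "stability": (["stable", "stable", "stable", "unstable",
                           "unstable", "unstable", "stable",
                           "unstable"] * n)[:n]})

    def test_orthogonal_balanced_predictors_give_one(self):
        # full 2^5 factorial: perfectly balanced, VIF exactly 1
        rows = []
        for bits in range(32):
            rows.append({
                "stability": ["stable", "unstable"][bits & 1],
                "arrival_age_cat": ["subadult", "adult"][(bits >> 1) & 1],
                "sex": ["F", "M"][(bits >> 2) & 1],
                "origin": ["captive", "wild"][(bits >> 3) & 1],
                "phc_infant": ["with_conspecifics",
                               "without_conspecifics"][(bits >> 4) & 1]})
        vifs = mi.vif(pd.DataFrame(rows))
        np.testing.assert_allclose(vifs.to_numpy(), 1.0, atol=1e-10)

    def test_duplicated_predictor_is_infinite(self):
        origin = ["wild", "captive"] * 16
        sex = ["M", "F"] * 16  # sex == origin up to relabeling
        vifs = mi.vif(self.frame(origin, sex))
        assert np.isinf(vifs["Origin"]) and np.isinf(vifs["Sex"])

    def test_confounded_predictors_exceed_one_but_finite(self):
        # origin/arrival-age association like the study population:
        # most wild-caught arrive as adults, most captive-born younger
        rng = np.random.default_rng(0)
        n = 200
        origin = rng.choice(["wild", "captive"], n)
        arrival = np.where(
            rng.random(n) < 0.8,
            np.where(origin == "wild", "adult", "subadult"),
            np.where(origin == "wild", "subadult", "adult"))
        data = pd.DataFrame({
            "origin": origin, "arrival_age_cat": arrival,
            "sex": rng.choice(["F", "M"], n),
            "phc_infant": rng.choice(["with_conspecifics",
                                      "without_conspecifics"], n),
            "stability": rng.choice(["stable", "unstable"], n)})
        vifs = mi.vif(data)
        assert 1.0 < vifs["Origin"] < 10.0
        assert np.isfinite(vifs["Origin"])


class TestAnovaType3:
    def test_degenerate_limit_matches_classical_anova(self):
        # balanced one-factor design, every row its own individual and
        # period: random variances vanish, F and df collapse to one-way
        # ANOVA with residual df n - 2
        rng = np.random.default_rng(42)
        n = 40
        sex = np.array(["F", "M"] * (n // 2))
        y = 1.0 + 0.8 * (sex == "M") + rng.normal(0, 0.5, n)
        data = pd.DataFrame({
            "individual": [f"I{i}" for i in range(n)],
            "period_code": [f"P{i}" for i in range(n)],
            "vsc": y, "dewd": 0.1, "n_group": 5, "sex": sex,
            "origin": ["wild", "captive"] * (n // 2),
            "phc_infant": "with_conspecifics",
            "arrival_age_cat": "adult", "stability": "stable"})
        table = mi.anova_type3(data, mi.ModelSpec(response="vsc",
                                                  fixed_terms=("Sex",)))
        # classical one-way ANOVA F computed directly
        yf, ym = y[sex == "F"], y[sex == "M"]
        ss_between = (len(yf) * (yf.mean() - y.mean()) ** 2
                      + len(ym) * (ym.mean() - y.mean()) ** 2)
        ss_within = ((yf - yf.mean()) ** 2).sum() + (
            (ym - ym.mean()) ** 2).sum()
        f_classical = ss_between / (ss_within / (n - 2))
        assert table.loc["Sex", "F"] == pytest.approx(f_classical,
                                                      abs=1e-3)
        assert table.loc["Sex", "df2"] == pytest.approx(n - 2, abs=0.5)

    def test_term_not_in_model_rejected(self, sim_measures):
        spec = mi.ModelSpec(response="vsc", fixed_terms=("Sex",))
        with pytest.raises(ValidationError, match="Origin"):
            mi.anova_type3(sim_measures, spec, terms=("Origin",))

    def test_full_model_df_plausible(self, sim_measures):
        spec = mi.ModelSpec(response="vsc",
                            fixed_terms=tuple(mi.FACTORS))
        table = mi.anova_type3(sim_measures, spec)
        assert (table["df2"] > 1).all()
        assert (table["df2"] <= len(sim_measures)).all()
        assert set(table["method"]) <= {"satterthwaite", "between_within"}


class TestInteractionModel:
    def test_constructed_interaction_detected(self):
        # explicit response built from a known interaction, tiny noise
        rng = np.random.default_rng(1)
        rows = []
        for i in range(24):
            for p in range(5):
                origin = "wild" if i % 2 else "captive"
                phc = ("without_conspecifics" if (i // 2) % 2
                       else "with_conspecifics")
                x1 = float(origin == "wild")
                x2 = float(phc == "without_conspecifics")
                y = 2.0 - 1.0 * x1 - 0.5 * x2 + 1.5 * x1 * x2 + float(
                    rng.normal(0, 0.3))
                rows.append({
                    "individual": f"I{i}", "period_code": f"P{p}",
                    "vsc": y, "dewd": 0.1, "n_group": 5,
                    "sex": "F" if (i // 4) % 2 else "M", "origin": origin,
                    "phc_infant": phc,
                    "arrival_age_cat": "adult" if (i // 8) % 2 else
                    "subadult",
                    "stability": "stable" if p % 2 else "unstable"})
        data = pd.DataFrame(rows)
        fit, anova, cells = mi.fit_interaction_model(
            data, "vsc", ("Origin", "PHCinfant"))
        assert anova.loc["Origin:PHCinfant", "p"] < 0.05
        assert len(cells) == 4
        assert cells["estimable"].all()
        # cell means reproduce the interaction pattern
        wide = cells.set_index(["Origin", "PHCinfant"])["predicted_mean"]
        observed_gap = (wide[1, 1] - wide[1, 0]) - (wide[0, 1] - wide[0, 0])
        assert observed_gap == pytest.approx(1.5, abs=0.3)

    def test_factor_absent_from_data_rejected(self, sim_measures):
        data = sim_measures.copy()
        data["origin"] = "wild"
        with pytest.raises(ValidationError, match="Origin"):
            mi.fit_interaction_model(data, "vsc", ("Origin", "Sex"))
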