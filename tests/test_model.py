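"""NB fall model: fit recovery, AUC oracle, stability elimination, evaluation."""

import math

import numpy as np
import pandas as pd
import pytest

from stepfall import (
    ModelSpec,
    PRESETS,
    add_group_interactions,
    auc,
    design_matrix,
    evaluate,
    fit_cohort,
    fit_nb,
    nb2_loglikelihood,
    predict_risk,
    select_candidates,
    spearman_matrix,
    stability_elimination,
)
from stepfall.model import (
    DegenerateOutcomeError,
    EmptyModelError,
    SingularDesignError,
    UndefinedAUCError,
    complete_cases,
)
from stepfall.synthetic import parameter_cohort


def brute_force_auc(scores, labels):
    """O(n^2) pairwise comparison with ties counted 0.5."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestFitNB:
    def test_poisson_limit_recovery(self):
        df = parameter_cohort(2000, {"x": 0.5}, nb_dispersion=0.0, seed=101)
        fit, _, _ = fit_cohort(df, ModelSpec(main_effects=("x",)))
        assert fit.coef("x") == pytest.approx(0.5, abs=0.1)
        assert fit.dispersion < 0.05

    def test_nb_recovery(self):
        df = parameter_cohort(
            2000, {"x": 0.4}, nb_intercept=math.log(0.8), nb_dispersion=1.0, seed=102
        )
        fit, _, _ = fit_cohort(df, ModelSpec(main_effects=("x",)))
        assert fit.coef("x") == pytest.approx(0.4, abs=0.1)
        assert fit.coef("const") == pytest.approx(math.log(0.8), abs=0.15)
        assert fit.dispersion == pytest.approx(1.0, abs=0.3)
        assert fit.converged

    def test_all_zero_counts_rejected(self):
        df = parameter_cohort(100, {"x": 0.0}, seed=103)
        df["fall_count"] = 0
        with pytest.raises(DegenerateOutcomeError):
            fit_cohort(df, ModelSpec(main_effects=("x",)))

    def test_collinear_design_names_columns(self):
        df = parameter_cohort(200, {"x": 0.3}, seed=104)
        df["x_copy"] = df["x"]
        spec = ModelSpec(main_effects=("x", "x_copy"))
        with pytest.raises(SingularDesignError, match="x"):
            fit_cohort(df, spec)

    def test_nb_loglik_poisson_limit(self, rng):
        y = rng.poisson(2.0, size=500)
        mu = np.full(500, 2.0)
        pois = np.sum(y * np.log(mu) - mu - [math.lgamma(v + 1) for v in y])
        assert nb2_loglikelihood(y, mu, 1e-13) == pytest.approx(pois, abs=1e-8)
        # the explicit NB form approaches the same limit (gammaln cancellation
        # limits achievable precision at tiny alpha)
        assert nb2_loglikelihood(y, mu, 1e-7) == pytest.approx(pois, abs=1e-2)


class TestPredictRisk:
    def test_intercept_only_at_mean(self):
        df = parameter_cohort(200, {"x": 0.5}, seed=105)
        fit, _, X = fit_cohort(df, ModelSpec(main_effects=("x",)))
        row = np.array([[1.0, 0.0, 0.0]])  # const, group, x at cohort mean
        assert predict_risk(fit, row)[0] == pytest.approx(math.exp(fit.coef("const")))

    def test_monotone_in_positive_coefficient(self):
        df = parameter_cohort(400, {"x": 0.8}, seed=106)
        fit, _, _ = fit_cohort(df, ModelSpec(main_effects=("x",)))
        assert fit.coef("x") > 0
        lo = predict_risk(fit, np.array([[1.0, 0.0, -1.0]]))[0]
        hi = predict_risk(fit, np.array([[1.0, 0.0, 1.0]]))[0]
        assert hi > lo

    def test_dimension_mismatch(self):
        df = parameter_cohort(200, {"x": 0.5}, seed=107)
        fit, _, _ = fit_cohort(df, ModelSpec(main_effects=("x",)))
        with pytest.raises(ValueError):
            predict_risk(fit, np.array([[1.0, 0.0]]))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auc([5.0] * 10, [0, 1] * 5) == 0.5

    def test_oracle_equivalence(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 200))
            scores = rng.choice([0.1, 0.5, 0.9, 1.3], size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-14
            )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.standard_normal(100)
        labels = rng.integers(0, 2, size=100)
        assert auc(scores, labels) == auc(np.exp(scores), labels)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedAUCError):
            auc([1.0, 2.0], [1, 1])


class TestModelSpec:
    def test_interaction_requires_main_effect(self):
        with pytest.raises(ValueError):
            ModelSpec(main_effects=("a",), quantity_interactions=(("a", "b"),))

    def test_drop_main_effect_drops_its_interactions(self):
        spec = ModelSpec(
            main_effects=("q", "a", "b"), quantity_interactions=(("q", "a"), ("q", "b"))
        )
        out = spec.drop("a")
        assert out.main_effects == ("q", "b")
        assert out.quantity_interactions == (("q", "b"),)

    def test_design_matrix_columns(self):
        df = parameter_cohort(50, {"a": 0.0, "b": 0.0}, seed=1)
        from stepfall import Standardizer

        z = Standardizer().fit_transform(df, ["a", "b"])
        spec = ModelSpec(
            main_effects=("a", "b"),
            quantity_interactions=(("a", "b"),),
            group_interactions=("a",),
        )
        X = design_matrix(z, spec)
        assert list(X.columns) == ["const", "group", "a", "b", "a:b", "group:a"]
        np.testing.assert_allclose(X["a:b"], z["a"] * z["b"])


class TestStabilityElimination:
    def test_strong_term_survives(self):
        df = parameter_cohort(400, {"x": 2.0}, nb_dispersion=0.5, seed=108)
        final, hist = stability_elimination(df, ModelSpec(main_effects=("x",)), seed=1)
        assert final.main_effects == ("x",)
        assert hist[-1].mean_p["x"] < 0.001

    def test_noise_term_eliminated(self):
        beta = {"a": 0.8, "b": -0.8, "noise": 0.0}
        df = parameter_cohort(400, beta, seed=109)
        final, hist = stability_elimination(
            df, ModelSpec(main_effects=("a", "b", "noise")), seed=2
        )
        assert "noise" not in final.main_effects
        assert set(final.main_effects) == {"a", "b"}

    def test_group_never_eliminated(self):
        df = parameter_cohort(400, {"x": 1.0}, seed=110)
        final, _ = stability_elimination(df, ModelSpec(main_effects=("x",)), seed=3)
        assert "group" not in final.eliminable_terms

    def test_exhausting_all_terms_is_error(self):
        # pure noise with few observations: nothing can be stable
        df = parameter_cohort(80, {"x": 0.0, "y": 0.0}, nb_dispersion=2.0, seed=111)
        with pytest.raises(EmptyModelError):
            stability_elimination(df, ModelSpec(main_effects=("x", "y")), seed=4)

    def test_deterministic_given_seed(self):
        df = parameter_cohort(300, {"a": 0.6, "b": 0.0}, seed=112)
        spec = ModelSpec(main_effects=("a", "b"))
        f1, h1 = stability_elimination(df, spec, seed=7)
        f2, h2 = stability_elimination(df, spec, seed=7)
        assert f1 == f2
        assert [r.mean_p for r in h1] == [r.mean_p for r in h2]


class TestEvaluate:
    def test_null_cohort_auc_near_half(self):
        df = parameter_cohort(300, {f"p{i}": 0.0 for i in range(4)}, seed=113)
        res = evaluate(df, ModelSpec(main_effects=("p0", "p1", "p2", "p3")), seed=5)
        assert 0.4 <= res.auc_cv_mean <= 0.6

    def test_strong_cohort_discriminates(self):
        df = parameter_cohort(300, {"x": 1.2}, nb_dispersion=0.5, seed=114)
        res = evaluate(df, ModelSpec(main_effects=("x",)), seed=6)
        assert res.auc_insample > 0.65
        assert res.auc_cv_mean > 0.6
        assert len(res.auc_per_split) == 10

    def test_duplicate_rows_leave_auc_unchanged(self):
        df = parameter_cohort(150, {"x": 0.8}, seed=115)
        spec = ModelSpec(main_effects=("x",))
        fit, std, X = fit_cohort(df, spec)
        scores = predict_risk(fit, X)
        labels = df["faller"].to_numpy().astype(bool)
        doubled = auc(np.tile(scores, 2), np.tile(labels, 2))
        assert doubled == pytest.approx(auc(scores, labels), abs=1e-14)

    def test_deterministic_given_seed(self):
        df = parameter_cohort(200, {"x": 0.6}, seed=116)
        spec = ModelSpec(main_effects=("x",))
        r1 = evaluate(df, spec, seed=9)
        r2 = evaluate(df, spec, seed=9)
        assert r1 == r2


class TestCandidateSelection:
    def test_correlated_pair_never_together(self):
        rng = np.random.default_rng(117)
        df = parameter_cohort(250, {"a": 0.8, "c": 0.5}, names=("a", "c"), seed=117)
        df["b"] = df["a"] + 0.05 * rng.standard_normal(len(df))  # |rho| ~ 1 with a
        corr = spearman_matrix(df, columns=("a", "b", "c"))
        spec, board = select_candidates(df, corr, candidates=("a", "b", "c"))
        assert not {"a", "b"} <= set(spec.main_effects)
        assert all(
            not ({"a", "b"} <= set(t)) for t in board["terms"]
        )

    def test_preset_exposes_published_six_terms(self):
        assert PRESETS["paper2023"].main_effects == (
            "total_steps",
            "cadence",
            "cov_stride_time",
            "dfa_step",
            "sampen_step",
            "sampen_stride",
        )

    def test_group_interactions_added_after_selection(self):
        spec = add_group_interactions(ModelSpec(main_effects=("a", "b")))
        assert spec.group_interactions == ("a", "b")
        # still not eliminable
        assert "group:a" not in spec.eliminable_terms


class TestCompleteCases:
    def test_rows_with_missing_params_dropped(self):
        df = parameter_cohort(60, {"x": 0.5, "y": 0.0}, seed=118)
        df.loc[3, "x"] = math.nan
        out = complete_cases(df, ModelSpec(main_effects=("x", "y")))
        assert len(out) == 59
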