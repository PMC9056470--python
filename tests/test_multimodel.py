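import itertools

import numpy as np
import pandas as pd
import pytest

from pollinet import multimodel as mm
from pollinet import synthetic
from pollinet.errors import ModelFitError

MODEL1_TERMS = ("apis", "temp", "fric", "tsim",
                "apis:fric", "apis:tsim", "fric:tsim", "apis:fric:tsim")


def marginality_oracle(terms):
    """Independent exhaustive filter: a subset is admissible iff every
    interaction's lower-order component terms are all present."""
    admissible = []
    for r in range(len(terms) + 1):
        for subset in itertools.combinations(terms, r):
            ok = True
            for t in subset:
                comps = t.split(":")
                if len(comps) < 2:
                    continue
                for size in range(1, len(comps)):
                    for combo in itertools.combinations(comps, size):
                        target = {frozenset(s.split(":")) for s in subset}
                        if frozenset(combo) not in target:
                            ok = False
            if ok:
                admissible.append(frozenset(subset))
    return set(admissible)


class TestScaling:
    def test_three_values_scale_to_unit(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, meta = mm.scale_predictors(df, ["x"])
        assert out["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert meta["x"] == (2.0, 1.0)

    def test_idempotent_on_scaled_column(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=30)})
        once, _ = mm.scale_predictors(df, ["x"])
        twice, _ = mm.scale_predictors(once, ["x"])
        assert np.allclose(once["x"], twice["x"], atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            mm.scale_predictors(pd.DataFrame({"x": [2.0, 2.0]}), ["x"])


class TestResponseTransform:
    def test_ln_of_exponentials(self):
        got, off = mm.transform_response([1.0, np.e, np.e ** 2], "ln")
        assert got == pytest.approx([0.0, 1.0, 2.0])
        assert off == 0.0

    def test_ln_with_zero_raises(self):
        with pytest.raises(ValueError, match="ln_offset"):
            mm.transform_response([0.0, 1.0], "ln")

    def test_ln_offset_uses_half_min_positive(self):
        got, off = mm.transform_response([0.0, 0.2, 0.4], "ln_offset")
        assert off == pytest.approx(0.1)
        assert got == pytest.approx(np.log([0.1, 0.3, 0.5]))


class TestEnumeration:
    def test_two_way_interaction_gives_five_models(self):
        spec = mm.ModelSpec(response="y", terms=("A", "B", "A:B"))
        got = {frozenset(m.terms) for m in mm.enumerate_candidate_models(spec)}
        want = {frozenset(), frozenset({"A"}), frozenset({"B"}),
                frozenset({"A", "B"}), frozenset({"A", "B", "A:B"})}
        assert got == want

    def test_full_three_way_structure_gives_38_models(self):
        spec = mm.ModelSpec(response="y", terms=MODEL1_TERMS)
        cands = mm.enumerate_candidate_models(spec)
        assert len(cands) == 38
        got = {frozenset(m.terms) for m in cands}
        assert got == marginality_oracle(MODEL1_TERMS)

    def test_mains_only_gives_power_set(self):
        spec = mm.ModelSpec(response="y", terms=("a", "b", "c", "d"))
        assert len(mm.enumerate_candidate_models(spec)) == 2 ** 4

    def test_random_intercept_carried_into_every_candidate(self):
        spec = mm.ModelSpec(response="y", terms=("A", "B"), random_intercept="g")
        assert all(m.random_intercept == "g"
                   for m in mm.enumerate_candidate_models(spec))


class TestFitting:
    def test_exact_linear_relation_recovered(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2.0 * df["x"]
        fit = mm.fit_model(mm.ModelSpec(response="y", terms=("x",)), df)
        assert fit.coefficients["x"] == pytest.approx(2.0)
        assert np.allclose(fit.residuals, 0.0)
        assert fit.r2[0] == pytest.approx(1.0)

    def test_ols_loglik_matches_gaussian_closed_form(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=25)})
        df["y"] = 1.0 + 0.5 * df["x"] + rng.normal(0, 0.3, size=25)
        fit = mm.fit_model(mm.ModelSpec(response="y", terms=("x",)), df)
        n = fit.n
        sigma2 = float((fit.residuals ** 2).sum()) / n  # MLE variance
        expected = -n / 2 * (np.log(2 * np.pi * sigma2) + 1)
        assert fit.loglik == pytest.approx(expected, rel=1e-10)

    def test_singular_design_names_aliased_terms(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["z"] = df["x"]
        df["y"] = df["x"] + 1
        with pytest.raises(ModelFitError, match="aliased"):
            mm.fit_model(mm.ModelSpec(response="y", terms=("x", "z")), df)

    def test_mixed_with_no_group_variance_matches_ols_r2(self):
        df, _ = synthetic.simulate_site_level(
            {"apis": 0.5}, 0.3, seed=2, categories=("a", "b", "c"),
            random_intercept_sd=0.0,
        )
        fit = mm.fit_model(
            mm.ModelSpec(response="response", terms=("apis",), random_intercept="site"),
            df,
        )
        marginal, conditional = fit.r2
        assert conditional == pytest.approx(marginal, abs=0.02)

    def test_mixed_k_counts_both_variance_components(self):
        df, _ = synthetic.simulate_site_level(
            {"apis": 0.5}, 0.3, seed=3, categories=("a", "b"), random_intercept_sd=0.5
        )
        fit = mm.fit_model(
            mm.ModelSpec(response="response", terms=("apis",), random_intercept="site"),
            df,
        )
        assert fit.k == 2 + 2  # intercept + slope + two variances


class TestAICcTable:
    def test_closed_form_fixture(self):
        assert mm.aicc(-10.0, 3, 20) == pytest.approx(27.5)
        # plain AIC part: -2*(-10) + 2*3 = 26
        assert mm.aicc(-10.0, 3, 10 ** 9) == pytest.approx(26.0, abs=1e-3)

    def test_weights_from_deltas(self):
        # two models with delta (0, 2): w = (1/(1+e^-1), ...)
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(size=30)})
        df["y"] = rng.normal(size=30)
        m1 = mm.fit_model(mm.ModelSpec(response="y", terms=()), df)
        m2 = mm.fit_model(mm.ModelSpec(response="y", terms=("x",)), df)
        # construct an exact delta of 2 between the two rows
        m2.loglik = (mm.aicc(m1.loglik, m1.k, m1.n) + 2.0 - 2 * m2.k
                     - 2 * m2.k * (m2.k + 1) / (m2.n - m2.k - 1)) / -2.0
        table = mm.aicc_table([m1, m2]).frame
        assert table["delta"].tolist() == pytest.approx([0.0, 2.0], abs=1e-10)
        e = np.exp(-1.0)
        assert table["weight"].tolist() == pytest.approx(
            [1 / (1 + e), e / (1 + e)], abs=1e-10
        )

    def test_equal_models_share_weight(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.normal(size=30)})
        df["y"] = rng.normal(size=30)
        m = mm.fit_model(mm.ModelSpec(response="y", terms=("x",)), df)
        table = mm.aicc_table([m, m]).frame
        assert table["weight"].tolist() == pytest.approx([0.5, 0.5])

    def test_weights_sum_to_one_and_presentation_does_not_renormalize(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({f"x{i}": rng.normal(size=40) for i in range(3)})
        df["y"] = df["x0"] + rng.normal(0, 0.1, size=40)
        spec = mm.ModelSpec(response="y", terms=("x0", "x1", "x2"))
        models = [mm.fit_model(s, df) for s in mm.enumerate_candidate_models(spec)]
        table = mm.aicc_table(models)
        assert table.frame["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        shown = table.presented()
        assert (shown["delta"] < 6).all()
        assert shown["weight"].sum() <= 1.0

    def test_mixed_sample_sizes_rejected(self):
        rng = np.random.default_rng(7)
        d1 = pd.DataFrame({"x": rng.normal(size=30), "y": rng.normal(size=30)})
        d2 = pd.DataFrame({"x": rng.normal(size=25), "y": rng.normal(size=25)})
        m1 = mm.fit_model(mm.ModelSpec(response="y", terms=("x",)), d1)
        m2 = mm.fit_model(mm.ModelSpec(response="y", terms=("x",)), d2)
        with pytest.raises(ValueError):
            mm.aicc_table([m1, m2])


def _fake_model(coefs: dict, ses: dict, n=51):
    fm = mm.FittedModel(
        spec=mm.ModelSpec(response="y", terms=tuple(k for k in coefs if k != "Intercept")),
        coefficients=pd.Series(coefs),
        ses=pd.Series(ses),
        loglik=0.0, k=len(coefs) + 1, n=n,
        residuals=pd.Series(np.zeros(n)), r2=(0.5, None),
    )
    return fm


class TestAveraging:
    def test_single_model_returns_its_own_coefficients(self):
        m = _fake_model({"a": 0.4}, {"a": 0.1})
        out = mm.average_coefficients([m], [1.0])
        assert out.loc["a", "estimate"] == pytest.approx(0.4)
        assert out.loc["a", "unconditional_se"] == pytest.approx(0.1)
        assert out.loc["a", "importance"] == pytest.approx(1.0)

    def test_weighted_mean_of_shared_term(self):
        m1 = _fake_model({"a": 0.2}, {"a": 0.0})
        m2 = _fake_model({"a": 0.4}, {"a": 0.0})
        out = mm.average_coefficients([m1, m2], [0.5, 0.5])
        assert out.loc["a", "estimate"] == pytest.approx(0.3)

    def test_zero_substitution_for_absent_term(self):
        m1 = _fake_model({"a": 0.4}, {"a": 0.0})
        m2 = _fake_model({"b": 1.0}, {"b": 0.0})
        out = mm.average_coefficients([m1, m2], [0.5, 0.5])
        assert out.loc["a", "estimate"] == pytest.approx(0.2)
        assert out.loc["a", "importance"] == pytest.approx(0.5)

    def test_conditional_averaging_ignores_absent_models(self):
        m1 = _fake_model({"a": 0.4}, {"a": 0.0})
        m2 = _fake_model({"b": 1.0}, {"b": 0.0})
        out = mm.average_coefficients([m1, m2], [0.5, 0.5], conditional=True)
        assert out.loc["a", "estimate"] == pytest.approx(0.4)

    def test_ci_brackets_estimate(self):
        m = _fake_model({"a": 0.4}, {"a": 0.1})
        out = mm.average_coefficients([m], [1.0])
        assert out.loc["a", "ci_low"] < 0.4 < out.loc["a", "ci_high"]
        width = out.loc["a", "ci_high"] - out.loc["a", "ci_low"]
        assert width == pytest.approx(2 * 1.959963984540054 * 0.1)


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        df = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        out = mm.vif(df, ["a", "b"])
        assert out["a"] == pytest.approx(1.0)
        assert out["b"] == pytest.approx(1.0)

    def test_closed_form_at_known_correlation(self):
        # two columns with exact sample correlation 0.6 -> VIF 1/(1-0.36)
        rng = np.random.default_rng(8)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        a = (a - a.mean()) / a.std()
        b = b - a * (a @ b) / (a @ a)
        b = (b - b.mean()) / b.std()
        r = 0.6
        c = r * a + np.sqrt(1 - r * r) * b
        out = mm.vif(pd.DataFrame({"a": a, "c": c}), ["a", "c"])
        assert out["a"] == pytest.approx(1.5625, rel=1e-6)
        assert out["c"] == pytest.approx(1.5625, rel=1e-6)

    def test_duplicated_column_reports_infinity(self, caplog):
        rng = np.random.default_rng(9)
        a = rng.normal(size=30)
        with caplog.at_level("WARNING", logger="pollinet.multimodel"):
            out = mm.vif(pd.DataFrame({"a": a, "b": a}), ["a", "b"])
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(60, 3)), columns=["a", "b", "c"])
        df["b"] += 0.7 * df["a"]
        ours = mm.vif(df, ["a", "b", "c"])
        X = sm.add_constant(df[["a", "b", "c"]]).to_numpy()
        for j, col in enumerate(["a", "b", "c"]):
            theirs = variance_inflation_factor(X, j + 1)
            assert ours[col] == pytest.approx(theirs, rel=1e-8)


class TestMoransI:
    def test_expected_value_at_51_sites(self):
        rng = np.random.default_rng(11)
        res = mm.morans_i(rng.normal(size=51), rng.uniform(0, 50, size=(51, 2)))
        assert res.expected == pytest.approx(-1 / 50)

    def test_permutation_null_centres_on_expectation(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 50, size=(30, 2))
        resid = rng.normal(size=30)
        draws = []
        for _ in range(1000):
            draws.append(mm.morans_i(rng.permutation(resid), coords).I)
        mean_i = np.mean(draws)
        mc_err = 3 * np.std(draws) / np.sqrt(len(draws))
        assert abs(mean_i - (-1 / 29)) < mc_err

    def test_spatial_gradient_detected(self):
        x = np.arange(20.0)
        coords = np.column_stack([x, np.zeros(20)])
        res = mm.morans_i(x - x.mean(), coords)
        assert res.I > res.expected
        assert res.p_value < 0.05

    def test_coincident_sites_rejected(self):
        coords = np.zeros((5, 2))
        with pytest.raises(ValueError):
            mm.morans_i(np.arange(5.0), coords)


def test_response_shift_moves_only_the_intercept():
    """Adding a constant to the response shifts the intercept; slopes, AICc
    deltas and weights are unchanged."""
    rng = np.random.default_rng(13)
    df = pd.DataFrame({"x": rng.normal(size=40), "z": rng.normal(size=40)})
    df["y"] = 0.6 * df["x"] + rng.normal(0, 0.4, size=40)
    spec = mm.ModelSpec(response="y", terms=("x", "z"))
    models_a = [mm.fit_model(s, df) for s in mm.enumerate_candidate_models(spec)]
    shifted = df.copy()
    shifted["y"] = shifted["y"] + 5.0
    models_b = [mm.fit_model(s, shifted) for s in mm.enumerate_candidate_models(spec)]
    ta, tb = mm.aicc_table(models_a).frame, mm.aicc_table(models_b).frame
    assert np.allclose(ta["delta"], tb["delta"], atol=1e-8)
    assert np.allclose(ta["weight"], tb["weight"], atol=1e-8)
    for ma, mb in zip(models_a, models_b):
        assert mb.coefficients["Intercept"] == pytest.approx(
            ma.coefficients["Intercept"] + 5.0, abs=1e-8
        )
        for term in ma.coefficients.index:
            if term != "Intercept":
                assert mb.coefficients[term] == pytest.approx(
                    ma.coefficients[term], abs=1e-8
                )
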