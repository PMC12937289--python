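from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from feedval.composition import Basis, IngredientComposition
from feedval.exceptions import (
    CollinearityError,
    ConfigError,
    DegenerateVariableError,
    InsufficientDataError,
    SchemaError,
)
from feedval.regression import (
    PredictionEquation,
    StarConvention,
    fit_linear,
    pearson_matrix,
    predict,
    stepwise_select,
)


@pytest.fixture(scope="module")
def random_table():
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        rng.normal(size=(10, 5)), columns=list("abcde")
    )


class TestPearsonMatrix:
    def test_diagonal_and_symmetry(self, random_table):
        corr = pearson_matrix(random_table)
        assert np.allclose(np.diag(corr.r), 1.0)
        assert np.allclose(corr.r, corr.r.T)
        assert np.allclose(corr.p, corr.p.T)
        assert (np.abs(corr.r.values) <= 1.0 + 1e-12).all()

    def test_p_values_match_t_distribution_oracle(self, random_table):
        """Off-diagonal p must equal 2*P(T_{n-2} > |t|), t = r*sqrt((n-2)/(1-r^2))."""
        corr = pearson_matrix(random_table)
        n = len(random_table)
        for a, b in combinations(random_table.columns, 2):
            r = corr.r.loc[a, b]
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert corr.p.loc[a, b] == pytest.approx(p, rel=1e-9)

    def test_p_value_agrees_with_permutation_oracle(self):
        """At n = 10 the t-based p is close to an exact resampling p."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=10)
        y = 0.6 * x + rng.normal(size=10)
        table = pd.DataFrame({"x": x, "y": y})
        p_t = pearson_matrix(table).p.loc["x", "y"]
        r_obs = abs(np.corrcoef(x, y)[0, 1])
        n_perm = 100_000
        perms = np.array([rng.permutation(y) for _ in range(n_perm)])
        xc = x - x.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        r_perm = (pc @ xc) / np.sqrt((xc**2).sum() * (pc**2).sum(axis=1))
        p_perm = (np.abs(r_perm) >= r_obs - 1e-12).mean()
        assert abs(p_t - p_perm) < 0.02

    def test_survey_composition_energy_correlations(self, ingredient_table):
        corr = pearson_matrix(
            ingredient_table, ["DE", "ME", "CF", "ADF", "Ash", "GE"]
        )
        assert round(corr.r.loc["Ash", "DE"], 2) == -0.75
        assert round(corr.r.loc["CF", "ADF"], 2) == 0.91
        assert round(corr.r.loc["GE", "Ash"], 2) == -0.87
        assert corr.stars.loc["Ash", "DE"] == "*"
        assert corr.stars.loc["CF", "ADF"] == "**"

    def test_star_conventions_differ(self):
        assert StarConvention.ENERGY.star(0.03) == "*"
        assert StarConvention.ENERGY.star(0.005) == "**"
        assert StarConvention.ENERGY.star(0.07) == ""
        assert StarConvention.SID.star(0.07) == "*"
        assert StarConvention.SID.star(0.03) == "**"
        assert StarConvention.SID.star(0.005) == ""

    def test_zero_variance_variable_named_in_error(self, random_table):
        bad = random_table.assign(flat=1.0)
        with pytest.raises(DegenerateVariableError, match="flat"):
            pearson_matrix(bad)

    def test_too_few_rows_rejected(self, random_table):
        with pytest.raises(InsufficientDataError):
            pearson_matrix(random_table.head(2))


class TestFitLinear:
    def test_survey_ash_equation_for_digestible_energy(self, ingredient_table):
        eq = fit_linear(ingredient_table["DE"], ingredient_table[["Ash"]],
                        response="DE")
        assert eq.intercept == pytest.approx(21.71, abs=0.01)
        assert round(eq.coefficients["Ash"], 2) == -0.68
        assert round(eq.r2, 2) == 0.57
        assert round(eq.rmse, 2) == 1.06

    def test_survey_trp_equation_for_total_aa_sid(self, ingredient_table):
        eq = fit_linear(ingredient_table["SID_TAA"], ingredient_table[["Trp"]])
        assert round(eq.r2, 2) == 0.58
        assert eq.rmse == pytest.approx(6.40, abs=0.01)

    def test_exact_affine_relation(self):
        x = pd.DataFrame({"x": np.arange(10.0)})
        y = 2.0 * x["x"] + 1.0
        eq = fit_linear(y, x)
        assert eq.r2 == pytest.approx(1.0)
        assert eq.rmse == pytest.approx(0.0, abs=1e-10)
        assert eq.intercept == pytest.approx(1.0)

    def test_single_predictor_r2_equals_squared_correlation(self, ingredient_table):
        corr = pearson_matrix(ingredient_table, ["DE", "Ash"])
        eq = fit_linear(ingredient_table["DE"], ingredient_table[["Ash"]])
        assert eq.r2 == pytest.approx(corr.r.loc["Ash", "DE"] ** 2, abs=1e-12)

    def test_insufficient_observations_rejected(self):
        x = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            fit_linear(pd.Series([1.0, 2.0]), x)

    def test_collinear_design_rejected(self):
        x = pd.DataFrame({"x": np.arange(10.0)})
        x["y"] = 2 * x["x"]
        with pytest.raises(CollinearityError):
            fit_linear(pd.Series(np.arange(10.0)), x)


class TestStepwiseSelect:
    def test_single_candidate_degenerates_to_fit_linear(self, ingredient_table):
        ranked = stepwise_select(
            ingredient_table["DE"], ingredient_table[["Ash"]], response="DE"
        )
        direct = fit_linear(ingredient_table["DE"], ingredient_table[["Ash"]],
                            response="DE")
        assert ranked[0] == direct

    def test_best_two_term_energy_model_uses_ge_and_cp(self, ingredient_table):
        ranked = stepwise_select(
            ingredient_table["DE"],
            ingredient_table[["GE", "CP", "Ash", "NDF", "CF", "ADF", "EE"]],
        )
        assert set(ranked[0].coefficients) == {"GE", "CP"}
        assert round(ranked[0].r2, 2) == 0.76

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_exhaustive_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(12, 6)), columns=list("abcdef"))
        y = X["a"] - 0.5 * X["c"] + rng.normal(scale=0.5, size=12)
        ranked = stepwise_select(y, X, max_terms=2)
        # independent oracle: enumerate all subsets with plain numpy
        best_r2, best_combo = -np.inf, None
        sst = ((y - y.mean()) ** 2).sum()
        for k in (1, 2):
            for combo in combinations(X.columns, k):
                design = np.column_stack([np.ones(12), X[list(combo)]])
                beta, *_ = np.linalg.lstsq(design, y, rcond=None)
                sse = ((y - design @ beta) ** 2).sum()
                r2 = 1 - sse / sst
                if r2 > best_r2 + 1e-12:
                    best_r2, best_combo = r2, set(combo)
        assert set(ranked[0].coefficients) == best_combo
        assert ranked[0].r2 == pytest.approx(best_r2, abs=1e-9)

    def test_single_term_selection_maximizes_absolute_correlation(
        self, ingredient_table
    ):
        candidates = ingredient_table[["GE", "CP", "Ash", "NDF", "CF", "ADF", "EE"]]
        ranked = stepwise_select(ingredient_table["DE"], candidates, max_terms=1)
        corrs = candidates.corrwith(ingredient_table["DE"]).abs()
        assert next(iter(ranked[0].coefficients)) == corrs.idxmax()

    def test_forward_method_returns_valid_model_first(self, ingredient_table):
        ranked = stepwise_select(
            ingredient_table["DE"],
            ingredient_table[["GE", "CP", "Ash", "NDF", "CF", "ADF", "EE"]],
            method="forward",
        )
        assert isinstance(ranked[0], PredictionEquation)
        assert 0 <= ranked[0].r2 <= 1

    def test_empty_candidates_rejected(self, ingredient_table):
        with pytest.raises(ConfigError):
            stepwise_select(ingredient_table["DE"], ingredient_table[[]])


class TestPredict:
    eq = PredictionEquation("DE", 21.71, {"Ash": -0.68}, 0.57, 1.06, 0.01, 10)

    def test_zero_predictor_returns_intercept(self):
        assert predict(self.eq, {"Ash": 0.0}) == 21.71

    def test_applies_equation_to_new_batch(self):
        assert predict(self.eq, {"Ash": 9.17}) == pytest.approx(15.47, abs=0.005)

    def test_zero_coefficients_return_intercept(self):
        eq = PredictionEquation("y", 3.0, {"a": 0.0, "b": 0.0}, 0, 1, 1, 10)
        assert predict(eq, {"a": 99.0, "b": -4.0}) == 3.0

    def test_missing_predictor_named(self):
        with pytest.raises(SchemaError, match="Ash"):
            predict(self.eq, {"CP": 50.0})

    def test_composition_must_be_dry_matter_basis(self):
        comp = IngredientComposition("x", Basis.AS_FED, 90.0, 18.0, {"Ash": 7.0})
        with pytest.raises(SchemaError):
            predict(self.eq, comp)
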