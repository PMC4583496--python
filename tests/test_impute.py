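"""The five missing-data strategies and Rubin's-rules pooling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from imputebench import (
    CohortTable,
    VariableSpec,
    complete_case,
    conditional_mean_impute,
    mice_impute,
    rubin_pool,
    simple_impute,
    stochastic_regression_impute,
)
from imputebench.impute import ImputationError
from imputebench.synth import apply_missingness, bellville_default_config, generate_complete_cohort

from conftest import build_table, random_mixed_table


def assert_observed_untouched(original, result):
    """No strategy may modify a cell that was observed in the input."""
    in_mask = original.missing_mask()
    for spec in original.variables:
        obs = ~in_mask[spec.name]
        a = original.data.loc[obs, spec.name]
        b = result.table.data.loc[obs, spec.name] if result.table.n == original.n else None
        if b is None:
            return  # deletion: row subset, checked separately
        if spec.kind == "categorical":
            assert (a == b).all()
        else:
            assert np.array_equal(a.to_numpy(), b.to_numpy())


class TestRubinPool:
    def test_degenerate_between_variance(self):
        pooled = rubin_pool([0.6, 0.6, 0.6], [0.1, 0.2, 0.3])
        assert pooled.q_bar == 0.6
        assert pooled.b == 0.0
        assert pooled.t == pooled.w == pytest.approx(0.2)
        assert math.isinf(pooled.df)

    def test_worked_closed_form(self):
        pooled = rubin_pool([0.5, 0.7], [0.04, 0.04])
        assert pooled.q_bar == pytest.approx(0.6)
        assert pooled.w == pytest.approx(0.04)
        assert pooled.b == pytest.approx(0.02)
        assert pooled.t == pytest.approx(0.07)
        assert pooled.df == pytest.approx(1 * (1 + 0.04 / (1.5 * 0.02)) ** 2)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.tuples(st.floats(-10, 10), st.floats(0, 5)),
                 min_size=2, max_size=12)
    )
    def test_total_variance_dominates_within(self, pairs):
        estimates = [p[0] for p in pairs]
        variances = [p[1] for p in pairs]
        pooled = rubin_pool(estimates, variances)
        assert pooled.t >= pooled.w - 1e-12
        assert min(estimates) - 1e-12 <= pooled.q_bar <= max(estimates) + 1e-12

    def test_rejects_single_estimate_and_mismatch(self):
        with pytest.raises(ValueError):
            rubin_pool([0.5], [0.1])
        with pytest.raises(ValueError):
            rubin_pool([0.5, 0.6], [0.1])


class TestCompleteCase:
    def test_complete_table_is_identity(self, mixed_schema):
        table = build_table(
            mixed_schema,
            {"y": [0, 1], "age": [40, 50], "bmi": [22, 30],
             "treated": [0, 1], "smoking": ["no", "past"]}, outcome="y")
        result = complete_case(table)
        assert result.table.equals(table)
        assert result.method == "deletion"

    def test_hand_count(self, small_table):
        result = complete_case(small_table)
        assert result.table.n == 3  # rows 2 and 3 have missing cells
        assert result.n_input == 5

    def test_zero_complete_rows_warns(self, mixed_schema):
        table = build_table(
            mixed_schema,
            {"y": [0, 1], "age": [None, None], "bmi": [22, 30],
             "treated": [0, 1], "smoking": ["no", "past"]})
        result = complete_case(table)
        assert result.table.n == 0
        assert result.warnings

    def test_retained_fraction_matches_independence_product(self):
        # under independent per-variable MCAR the expected complete-case
        # fraction is the product of per-variable completeness
        gen, miss = bellville_default_config(n=1083)
        rates = {k: v.rate for k, v in miss.per_variable.items()}
        expected = np.prod([1 - r for r in rates.values()])
        fractions = []
        for seed in range(60):
            gen, miss = bellville_default_config(n=1083, seed=seed)
            table = apply_missingness(generate_complete_cohort(gen), miss, seed=seed + 10_000)
            fractions.append(complete_case(table).table.n / table.n)
        mc_se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert abs(np.mean(fractions) - expected) < 3 * mc_se + 0.005


class TestSimpleImpute:
    def test_binary_missing_goes_to_majority_class(self):
        # observed 124 yes / 687 no with 272 missing fills to 124 / 959
        schema = [VariableSpec("y", "binary"), VariableSpec("fh", "binary")]
        fh = [1] * 124 + [0] * 687 + [None] * 272
        table = build_table(schema, {"y": [0] * 1083, "fh": fh}, outcome="y")
        result = simple_impute(table)
        filled = result.table.data["fh"]
        assert int((filled == 1).sum()) == 124
        assert int((filled == 0).sum()) == 959

    def test_three_level_missing_goes_to_mode(self):
        # observed 433 current / 105 past / 479 no with 66 missing fills
        # to 433 / 105 / 545
        schema = [VariableSpec("y", "binary"),
                  VariableSpec("smoking", "categorical",
                               categories=("current", "past", "no"))]
        smoking = ["current"] * 433 + ["past"] * 105 + ["no"] * 479 + [None] * 66
        table = build_table(schema, {"y": [0] * 1083, "smoking": smoking}, outcome="y")
        counts = simple_impute(table).table.data["smoking"].value_counts()
        assert counts["current"] == 433
        assert counts["past"] == 105
        assert counts["no"] == 545

    def test_continuous_mean_preserved_sd_never_grows(self):
        rng = np.random.default_rng(23)
        table = random_mixed_table(rng, n=200, missing_rate=0.2)
        result = simple_impute(table)
        for name in ("age", "bmi"):
            before = table.data[name].dropna()
            after = result.table.data[name]
            assert after.mean() == pytest.approx(before.mean())
            assert after.std(ddof=1) <= before.std(ddof=1) + 1e-12

    def test_exact_mean_fill(self):
        schema = [VariableSpec("y", "binary"), VariableSpec("x", "continuous")]
        table = build_table(schema, {"y": [0, 1, 0, 1], "x": [1.0, 2.0, 3.0, None]})
        filled = simple_impute(table).table.data["x"]
        assert filled.iloc[3] == pytest.approx(2.0)

    def test_all_missing_column_is_error(self):
        schema = [VariableSpec("y", "binary"), VariableSpec("x", "continuous")]
        table = build_table(schema, {"y": [0, 1], "x": [None, None]})
        with pytest.raises(ImputationError, match="x"):
            simple_impute(table)

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(31)
        table = random_mixed_table(rng, n=100, missing_rate=0.2)
        assert_observed_untouched(table, simple_impute(table))


def linear_pair_table(n=12, with_doubly_missing=False):
    """z = 2x exactly on complete rows; one row has z missing with x = 5."""
    schema = [VariableSpec("y", "binary"), VariableSpec("x", "continuous"),
              VariableSpec("z", "continuous")]
    x = [float(i) for i in range(1, n + 1)]
    z = [2.0 * v for v in x]
    y = [i % 2 for i in range(n)]
    x.append(5.0)
    z.append(None)
    y.append(1)
    if with_doubly_missing:
        x.append(None)
        z.append(None)
        y.append(0)
    return build_table(schema, {"y": y, "x": x, "z": z}, outcome="y")


class TestConditionalMean:
    def test_exact_linear_relation_filled_exactly(self):
        table = linear_pair_table()
        result = conditional_mean_impute(table)
        assert result.table.data["z"].iloc[-1] == pytest.approx(10.0, abs=1e-8)
        assert result.imputed_mask["z"].iloc[-1]

    def test_row_missing_a_predictor_stays_missing(self):
        table = linear_pair_table(with_doubly_missing=True)
        result = conditional_mean_impute(table)
        assert np.isnan(result.table.data["z"].iloc[-1])
        assert np.isnan(result.table.data["x"].iloc[-1])
        # effective n varies per variable ("varied length")
        assert result.effective_n["z"] == table.n - 1

    def test_beats_unconditional_fill_on_linear_data(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.normal(0, 1, n)
        z_true = 2.0 * x + rng.normal(0, 0.3, n)
        y = (rng.random(n) < 0.3).astype(float)
        miss = rng.random(n) < 0.2
        z = np.where(miss, np.nan, z_true)
        schema = [VariableSpec("y", "binary"), VariableSpec("x", "continuous"),
                  VariableSpec("z", "continuous")]
        table = CohortTable(schema, pd.DataFrame({"y": y, "x": x, "z": z}), "y")
        cond = conditional_mean_impute(table).table.data["z"].to_numpy()
        simp = simple_impute(table).table.data["z"].to_numpy()
        mae_cond = np.abs(cond[miss] - z_true[miss]).mean()
        mae_simp = np.abs(simp[miss] - z_true[miss]).mean()
        assert mae_cond < mae_simp

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(37)
        table = random_mixed_table(rng, n=150, missing_rate=0.15)
        assert_observed_untouched(table, conditional_mean_impute(table))


class TestStochasticRegression:
    def test_zero_residual_variance_reduces_to_conditional(self):
        table = linear_pair_table()
        stoch = stochastic_regression_impute(table, seed=1)
        cond = conditional_mean_impute(table)
        assert stoch.table.data["z"].iloc[-1] == pytest.approx(
            cond.table.data["z"].iloc[-1], abs=1e-6)

    def test_fill_variance_matches_residual_variance(self):
        # many missing cells at the same predictor values: the spread of
        # the fills estimates the residual variance of the fit
        rng = np.random.default_rng(9)
        n_obs, n_miss, sigma = 300, 500, 0.5
        x = np.concatenate([rng.normal(0, 1, n_obs), np.zeros(n_miss)])
        z = np.concatenate([2 * x[:n_obs] + rng.normal(0, sigma, n_obs),
                            np.full(n_miss, np.nan)])
        y = (rng.random(n_obs + n_miss) < 0.3).astype(float)
        schema = [VariableSpec("y", "binary"), VariableSpec("x", "continuous"),
                  VariableSpec("z", "continuous")]
        table = CohortTable(schema, pd.DataFrame({"y": y, "x": x, "z": z}), "y")
        fills = stochastic_regression_impute(table, seed=3).table.data["z"].iloc[n_obs:]
        mc_se = sigma**2 * math.sqrt(2.0 / (n_miss - 1))
        assert fills.var(ddof=1) == pytest.approx(sigma**2, abs=3.5 * mc_se)

    def test_binary_fill_frequency_matches_fitted_probability(self):
        # outcome-independent binary column with observed prevalence 0.3:
        # fills are Bernoulli draws at the fitted probability
        rng = np.random.default_rng(15)
        n_obs, n_miss = 400, 1000
        x = rng.normal(0, 1, n_obs + n_miss)
        b = np.concatenate([(rng.random(n_obs) < 0.3).astype(float),
                            np.full(n_miss, np.nan)])
        y = (rng.random(n_obs + n_miss) < 0.5).astype(float)
        schema = [VariableSpec("y", "binary"), VariableSpec("x", "continuous"),
                  VariableSpec("b", "binary")]
        table = CohortTable(schema, pd.DataFrame({"y": y, "x": x, "b": b}), "y")
        fills = stochastic_regression_impute(table, seed=7).table.data["b"].iloc[n_obs:]
        freq = fills.mean()
        bound = 3 * math.sqrt(0.3 * 0.7 / n_miss) + 0.03  # draw noise + fit noise
        assert abs(freq - 0.3) < bound

    def test_output_fully_observed_even_with_incomplete_predictors(self):
        rng = np.random.default_rng(41)
        table = random_mixed_table(rng, n=120, missing_rate=0.3)
        result = stochastic_regression_impute(table, seed=2)
        assert not result.table.missing_mask().any().any()
        assert_observed_untouched(table, result)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(43)
        table = random_mixed_table(rng, n=80, missing_rate=0.2)
        r1 = stochastic_regression_impute(table, seed=11)
        r2 = stochastic_regression_impute(table, seed=11)
        r3 = stochastic_regression_impute(table, seed=12)
        assert r1.table.equals(r2.table)
        assert not r1.table.equals(r3.table)


class TestMice:
    def test_no_missing_cells_gives_identical_copies(self, mixed_schema):
        table = build_table(
            mixed_schema,
            {"y": [0, 1, 0], "age": [40, 50, 60], "bmi": [22, 30, 27],
             "treated": [0, 1, 0], "smoking": ["no", "past", "current"]},
            outcome="y")
        result = mice_impute(table, m=3, iterations=2, seed=1)
        assert result.m == 3
        for ds in result.datasets:
            assert ds.table.equals(table)

    def test_contract_m_complete_datasets_sharing_observed_cells(self):
        rng = np.random.default_rng(51)
        table = random_mixed_table(rng, n=100, missing_rate=0.2)
        result = mice_impute(table, m=4, iterations=3, seed=5)
        assert len(result.datasets) == 4
        mask = table.missing_mask()
        for ds in result.datasets:
            assert not ds.table.missing_mask().any().any()
            assert (ds.imputed_mask == mask).all().all()
            assert_observed_untouched(table, ds)
        # imputed cells differ between at least some chains
        z = [ds.table.data["age"].to_numpy() for ds in result.datasets]
        assert any(not np.array_equal(z[0], zi) for zi in z[1:])

    def test_bit_identical_under_same_seed(self):
        rng = np.random.default_rng(53)
        table = random_mixed_table(rng, n=60, missing_rate=0.25)
        r1 = mice_impute(table, m=3, iterations=3, seed=99)
        r2 = mice_impute(table, m=3, iterations=3, seed=99)
        for a, b in zip(r1.datasets, r2.datasets):
            assert a.table.equals(b.table)

    def test_m_below_two_rejected(self, small_table):
        with pytest.raises(ValueError):
            mice_impute(small_table, m=1, iterations=2, seed=0)
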