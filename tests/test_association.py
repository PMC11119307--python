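"""Contingency tables, crude ORs, tests, logistic fits, LRT, trend,
interaction and stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aidiet.association import (
    DIET_TERCILE_TERM,
    MODEL_A_COVARIATES,
    ContingencyTable,
    ModelSpec,
    SeparationError,
    Term,
    chi_square_test,
    crosstab,
    crude_or,
    fit_logistic,
    interaction_test,
    likelihood_ratio_test,
    mann_whitney_u,
    stratified_estimates,
    wald_trend_test,
)


def _binary_dataset(a, b, c, d, reps=1):
    """2x2 counts (exposed cases, unexposed cases, exposed controls,
    unexposed controls) expanded to subject rows."""
    rows = (
        [(1, 1)] * a + [(1, 0)] * b + [(0, 1)] * c + [(0, 0)] * d
    ) * reps
    return pd.DataFrame(rows, columns=["status", "exposed"])


class TestCrudeOR:
    def test_childhood_sunburn_counts(self):
        # crude OR from the printed 2x2 counts: (93*176)/(121*58)
        est = crude_or(93, 121, 58, 176)
        assert est.odds_ratio == pytest.approx(93 * 176 / (121 * 58))
        assert est.odds_ratio == pytest.approx(2.332, abs=5e-4)
        assert est.ci_low < est.odds_ratio < est.ci_high
        assert est.p_value < 0.0001

    def test_identity_table(self):
        assert crude_or(1, 1, 1, 1).odds_ratio == pytest.approx(1.0)

    def test_row_column_swap_inverts(self):
        forward = crude_or(93, 121, 58, 176)
        backward = crude_or(58, 176, 93, 121)
        assert backward.odds_ratio == pytest.approx(1 / forward.odds_ratio)

    def test_zero_cell_requires_continuity(self):
        with pytest.raises(ValueError):
            crude_or(0, 5, 5, 5)
        est = crude_or(0, 5, 5, 5, continuity=True)
        assert est.odds_ratio == pytest.approx(0.5 * 5.5 / (5.5 * 5.5))

    def test_woolf_ci_shrinks_with_scale(self):
        small = crude_or(10, 20, 15, 25)
        large = crude_or(40, 80, 60, 100)
        assert large.odds_ratio == pytest.approx(small.odds_ratio)
        assert (np.log(large.ci_high) - np.log(large.ci_low)) < (
            np.log(small.ci_high) - np.log(small.ci_low)
        )


class TestChiSquare:
    def test_perfect_independence(self):
        res = chi_square_test(np.array([[10, 10], [10, 10]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_formula_2x2(self):
        # n(ad-bc)^2 / (r1 r2 c1 c2) = 60*(400-100)^2/30^4
        res = chi_square_test(np.array([[20, 10], [10, 20]]))
        assert res.statistic == pytest.approx(60 * (20 * 20 - 10 * 10) ** 2 / 30**4)
        assert res.df == 1

    def test_identical_columns_3x2(self):
        res = chi_square_test(np.array([[5, 5], [8, 8], [3, 3]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 2


class TestMannWhitney:
    def test_no_overlap(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0

    def test_enumerated_pairs(self):
        assert mann_whitney_u([1, 3], [2]).statistic == 1.0

    def test_identical_samples(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value > 0.9

    def test_all_tied(self):
        assert mann_whitney_u([5, 5], [5, 5, 5]).p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestCrosstab:
    def test_unit_counts(self):
        df = pd.DataFrame({"status": [1, 0], "exposure": ["low", "high"]})
        table = crosstab(df, "exposure", levels=("low", "high"))
        assert table.counts.tolist() == [[1, 0], [0, 1]]

    def test_missing_rows_excluded_and_counted(self):
        df = pd.DataFrame({"status": [1, 0, 1], "exposure": ["a", "b", None]})
        table = crosstab(df, "exposure", levels=("a", "b"))
        assert table.n_missing == 1
        assert table.counts.sum() == 2

    def test_all_missing_is_an_error(self):
        df = pd.DataFrame({"status": [1, 0], "exposure": [None, None]})
        with pytest.raises(ValueError):
            crosstab(df, "exposure")


EXPOSURE_SPEC = ModelSpec("status", (Term("exposed", "binary"),), "exposure only")
NULL_SPEC = ModelSpec("status", (), "intercept only")


class TestLogisticFit:
    def test_saturated_2x2_reproduces_crude_or(self):
        df = _binary_dataset(2, 1, 1, 2, reps=10)
        fit = fit_logistic(df, EXPOSURE_SPEC)
        assert fit.effect("exposed").odds_ratio == pytest.approx(4.0, rel=1e-6)

    def test_matches_crude_or_to_six_significant_digits(self):
        df = _binary_dataset(93, 121, 58, 176)
        fit = fit_logistic(df, EXPOSURE_SPEC)
        crude = crude_or(93, 121, 58, 176)
        assert fit.effect("exposed").odds_ratio == pytest.approx(
            crude.odds_ratio, rel=1e-6
        )
        # Woolf SE equals the Wald SE from the saturated fit
        assert fit.se("exposed") == pytest.approx(
            np.sqrt(1 / 93 + 1 / 121 + 1 / 58 + 1 / 176), rel=1e-6
        )

    def test_null_effect_is_near_zero(self):
        df = _binary_dataset(30, 30, 30, 30)
        fit = fit_logistic(df, EXPOSURE_SPEC)
        assert abs(fit.params["exposed"]) < 1e-8

    def test_perfect_separation_raises(self):
        df = _binary_dataset(20, 0, 0, 20)
        with pytest.raises(SeparationError):
            fit_logistic(df, EXPOSURE_SPEC)

    def test_too_few_rows(self):
        df = _binary_dataset(1, 0, 0, 0)
        with pytest.raises(ValueError):
            fit_logistic(df, EXPOSURE_SPEC)


class TestLikelihoodRatio:
    def test_model_against_itself_is_null(self):
        df = _binary_dataset(20, 15, 10, 25)
        fit = fit_logistic(df, EXPOSURE_SPEC)
        nested = fit_logistic(df, NULL_SPEC)
        res = likelihood_ratio_test(nested, fit)
        assert res.statistic >= 0
        self_res = likelihood_ratio_test(fit, fit)
        assert self_res.statistic == pytest.approx(0.0)
        assert self_res.p_value == pytest.approx(1.0)

    def test_requires_identical_rows(self):
        df = _binary_dataset(20, 15, 10, 25)
        fit_full = fit_logistic(df, EXPOSURE_SPEC)
        fit_null = fit_logistic(df.iloc[:-2], NULL_SPEC)
        with pytest.raises(ValueError, match="identical rows"):
            likelihood_ratio_test(fit_null, fit_full)

    def test_requires_nesting(self):
        df = _binary_dataset(20, 15, 10, 25)
        df["other"] = np.tile([0.0, 1.0], len(df) // 2)
        fit_a = fit_logistic(df, EXPOSURE_SPEC)
        fit_b = fit_logistic(df, ModelSpec("status", (Term("other", "binary"),)))
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(fit_a, fit_b)

    def test_strong_effect_detected(self, rng):
        n = 4000
        x = rng.integers(0, 2, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.0 + 1.5 * x)))).astype(int)
        df = pd.DataFrame({"status": y, "exposed": x})
        res = likelihood_ratio_test(
            fit_logistic(df, NULL_SPEC), fit_logistic(df, EXPOSURE_SPEC)
        )
        assert res.p_value < 0.001


ORDINAL_TERM = Term("tercile", "ordinal", levels=("low", "medium", "high"))


class TestTrend:
    def test_matches_normal_cdf_oracle(self, rng):
        n = 600
        terciles = rng.choice(["low", "medium", "high"], n)
        y = rng.integers(0, 2, n)
        df = pd.DataFrame({"status": y, "tercile": terciles})
        fit = fit_logistic(df, ModelSpec("status", (ORDINAL_TERM,)))
        res = wald_trend_test(fit, "tercile")
        beta, se = fit.params["tercile"], fit.se("tercile")
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(beta / se)))

    def test_monotone_protective_data(self, rng):
        n = 10_000
        code = rng.integers(0, 3, n)
        prob = 1 / (1 + np.exp(-(0.0 + np.log(0.5) * code)))
        y = (rng.random(n) < prob).astype(int)
        df = pd.DataFrame(
            {"status": y, "tercile": np.array(["low", "medium", "high"])[code]}
        )
        fit = fit_logistic(df, ModelSpec("status", (ORDINAL_TERM,)))
        assert wald_trend_test(fit, "tercile").p_value < 0.05

    def test_missing_term_rejected(self, rng):
        df = _binary_dataset(20, 15, 10, 25)
        fit = fit_logistic(df, EXPOSURE_SPEC)
        with pytest.raises(KeyError):
            wald_trend_test(fit, "tercile")


class TestInteraction:
    def test_constant_factor_not_estimable(self, rng):
        df = pd.DataFrame(
            {
                "status": rng.integers(0, 2, 100),
                "tercile": rng.choice(["low", "medium", "high"], 100),
                "genotype_pooled": ["GG"] * 100,
            }
        )
        with pytest.raises(ValueError, match="not estimable"):
            interaction_test(
                df,
                (),
                Term("tercile", "categorical", reference="low",
                     levels=("low", "medium", "high")),
                Term("genotype_pooled", "binary", positive="C_carrier"),
            )

    def test_strong_crossover_detected(self, rng):
        n = 10_000
        x = rng.integers(0, 2, n)
        g = rng.integers(0, 2, n)
        logit = -0.5 + 1.2 * x + 0.2 * g - 2.4 * x * g
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        df = pd.DataFrame(
            {"status": y, "exposed": x, "carrier": np.where(g == 1, "yes", "no")}
        )
        res = interaction_test(
            df, (), Term("exposed", "binary"), Term("carrier", "binary", positive="yes")
        )
        assert res.df == 1
        assert res.p_value < 0.001


class TestStratified:
    def _frame(self, rng, n=400):
        x = rng.choice(["low", "medium", "high"], n)
        y = rng.integers(0, 2, n)
        return pd.DataFrame({"status": y, "tercile": x})

    def test_identical_strata_identical_estimates(self, rng):
        df = self._frame(rng)
        doubled = pd.concat(
            [df.assign(stratum="a"), df.assign(stratum="b")], ignore_index=True
        )
        result = stratified_estimates(
            doubled,
            Term("tercile", "categorical", reference="low",
                 levels=("low", "medium", "high")),
            "stratum",
            (),
        )
        assert len(result) == 2
        assert all(s.available for s in result)
        for e_a, e_b in zip(result[0].estimates, result[1].estimates):
            assert e_a.odds_ratio == pytest.approx(e_b.odds_ratio)

    def test_tiny_stratum_flagged_unavailable(self, rng):
        df = self._frame(rng, n=200).assign(stratum="big")
        tiny = pd.DataFrame(
            {"status": [1, 0, 1], "tercile": ["low", "medium", "high"],
             "stratum": ["small"] * 3}
        )
        result = stratified_estimates(
            pd.concat([df, tiny], ignore_index=True),
            Term("tercile", "categorical", reference="low",
                 levels=("low", "medium", "high")),
            "stratum",
            (),
        )
        by_stratum = {s.stratum: s for s in result}
        assert by_stratum["big"].available
        assert not by_stratum["small"].available
        assert by_stratum["small"].reason

    def test_single_level_stratum_variable_rejected(self, rng):
        df = self._frame(rng).assign(stratum="only")
        with pytest.raises(ValueError, match=">= 2 levels"):
            stratified_estimates(
                df,
                Term("tercile", "categorical", reference="low",
                     levels=("low", "medium", "high")),
                "stratum",
                (),
            )


def test_lrt_invariant_to_categorical_reference(rng):
    n = 500
    x = rng.choice(["low", "medium", "high"], n)
    y = rng.integers(0, 2, n)
    df = pd.DataFrame({"status": y, "tercile": x})
    levels = ("low", "medium", "high")
    stats_by_ref = []
    for ref in levels:
        full = fit_logistic(
            df, ModelSpec("status", (Term("tercile", "categorical", reference=ref,
                                          levels=levels),))
        )
        null = fit_logistic(df, NULL_SPEC)
        stats_by_ref.append(likelihood_ratio_test(null, full).statistic)
    assert stats_by_ref[0] == pytest.approx(stats_by_ref[1], abs=1e-8)
    assert stats_by_ref[0] == pytest.approx(stats_by_ref[2], abs=1e-8)
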