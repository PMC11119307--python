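"""Case-control association statistics.

Implements the statistical toolkit of an unconditional (frequency-matched)
case-control analysis: exposure-by-status contingency tables, crude odds
ratios with Woolf confidence intervals, Pearson chi-square and Mann-Whitney U
tests, multivariable logistic regression with Wald CIs, a Wald test for
linear trend over an ordinal exposure, likelihood-ratio tests for nested
models and for gene-environment interaction, and genotype-stratified effect
estimates.

Maximum-likelihood logistic fits are delegated to statsmodels; the inferential
machinery built on top of them (Woolf intervals, LRT, trend, interaction,
stratification, model presets) is defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "TestResult",
    "EffectEstimate",
    "ContingencyTable",
    "LogisticFit",
    "Term",
    "ModelSpec",
    "SeparationError",
    "ConvergenceError",
    "MODEL_PRESETS",
    "MODEL_A_COVARIATES",
    "crosstab",
    "crude_or",
    "chi_square_test",
    "mann_whitney_u",
    "fit_logistic",
    "wald_trend_test",
    "likelihood_ratio_test",
    "interaction_test",
    "stratified_estimates",
]

Z_95 = float(stats.norm.ppf(0.975))


class SeparationError(RuntimeError):
    """Outcome perfectly (or quasi-) separated by the covariates."""


class ConvergenceError(RuntimeError):
    """Maximum-likelihood iterations failed to converge."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


@dataclass(frozen=True)
class EffectEstimate:
    """Odds ratio with a 95% CI; adjusted_for empty means crude."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted_for: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")


@dataclass(frozen=True)
class ContingencyTable:
    """k exposure levels x 2 status columns (case, control)."""

    counts: np.ndarray  # shape (k, 2): [:, 0] cases, [:, 1] controls
    levels: tuple[str, ...]
    reference: int = 0
    n_missing: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[1] != 2:
            raise ValueError("counts must be k x 2 (case, control)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    def slice_2x2(self, level: int | str) -> tuple[int, int, int, int]:
        """(a, b, c, d) for one exposure level against the reference.

        a = exposed cases, b = unexposed (reference) cases,
        c = exposed controls, d = unexposed controls.
        """
        i = self.levels.index(level) if isinstance(level, str) else int(level)
        r = self.reference
        if i == r:
            raise ValueError("cannot contrast the reference level with itself")
        a, c = self.counts[i]
        b, d = self.counts[r]
        return int(a), int(b), int(c), int(d)


def crosstab(
    subjects: pd.DataFrame,
    exposure: str | Callable[[pd.Series], object],
    status_col: str = "status",
    levels: Sequence[str] | None = None,
    reference: int = 0,
) -> ContingencyTable:
    """Exposure-by-status counts; missing exposure rows are excluded and counted."""
    if callable(exposure):
        values = subjects.apply(exposure, axis=1)
    else:
        values = subjects[exposure]
    status = subjects[status_col]
    keep = values.notna() & status.notna()
    n_missing = int((~keep).sum())
    values, status = values[keep], status[keep].astype(int)
    if len(values) == 0:
        raise ValueError("no usable subjects: exposure missing for everyone")
    if levels is None:
        if isinstance(values.dtype, pd.CategoricalDtype):
            levels = tuple(values.cat.categories)
        else:
            levels = tuple(pd.unique(values))
    counts = np.zeros((len(levels), 2), dtype=int)
    for i, lev in enumerate(levels):
        at = values == lev
        counts[i, 0] = int((at & (status == 1)).sum())
        counts[i, 1] = int((at & (status == 0)).sum())
    return ContingencyTable(
        counts=counts, levels=tuple(str(l) for l in levels), reference=reference,
        n_missing=n_missing,
    )


def crude_or(
    a: int, b: int, c: int, d: int, continuity: bool = False
) -> EffectEstimate:
    """Crude odds ratio ad/bc with the Woolf (log-scale Wald) 95% CI.

    Cells: a exposed cases, b unexposed cases, c exposed controls,
    d unexposed controls. With ``continuity`` a 0.5 correction is added to
    every cell when any cell is zero; otherwise a zero cell is an error.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (cells == 0).any():
        if not continuity:
            raise ValueError("zero cell; pass continuity=True for the 0.5 correction")
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    log_or = np.log(a_ * d_) - np.log(b_ * c_)
    se = float(np.sqrt((1 / cells).sum()))
    z = log_or / se
    return EffectEstimate(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z_95 * se)),
        ci_high=float(np.exp(log_or + Z_95 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
    )


def chi_square_test(table: ContingencyTable | np.ndarray) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    res = stats.chi2_contingency(counts, correction=False)
    if np.any(res.expected_freq == 0):
        raise ValueError("expected count of zero; table degenerate")
    return TestResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        test_name="Pearson chi-square",
    )


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test (midranks for ties).

    Uses exact enumeration when both samples have fewer than 8 observations
    and no ties are present, and the tie-corrected normal approximation
    otherwise. The reported statistic is U for the first sample.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # Degenerate: every observation identical; no evidence either way.
        return TestResult(
            statistic=float(x.size * y.size / 2), df=None, p_value=1.0,
            test_name="Mann-Whitney U",
        )
    method = "exact" if (max(x.size, y.size) < 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic), df=None,
        p_value=float(min(res.pvalue, 1.0)), test_name="Mann-Whitney U",
    )


# ---------------------------------------------------------------------------
# Logistic model specification and fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """One model term with its coding.

    kind:
      continuous  -- the column enters as-is
      binary      -- indicator of ``positive`` (column may be 0/1 or labelled)
      categorical -- dummy indicators for every level except ``reference``
      ordinal     -- integer codes 0..k-1 following ``levels`` order
    """

    name: str
    kind: str = "continuous"
    reference: str | None = None
    levels: tuple[str, ...] | None = None
    positive: object = 1

    def columns(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.name not in df.columns:
            raise KeyError(f"term {self.name!r} not in the subject table")
        col = df[self.name]
        missing = col.isna()
        if self.kind == "continuous":
            out = pd.DataFrame({self.name: pd.to_numeric(col, errors="raise")})
        elif self.kind == "binary":
            vals = (col == self.positive).astype(float)
            vals[missing] = np.nan
            out = pd.DataFrame({self.name: vals})
        elif self.kind == "categorical":
            levels = self.levels or tuple(
                col.cat.categories
                if isinstance(col.dtype, pd.CategoricalDtype)
                else pd.unique(col.dropna())
            )
            ref = self.reference if self.reference is not None else levels[0]
            if ref not in levels:
                raise ValueError(f"reference {ref!r} not among levels {levels}")
            out = {}
            for lev in levels:
                if lev == ref:
                    continue
                ind = (col == lev).astype(float)
                ind[missing] = np.nan
                out[f"{self.name}[{lev}]"] = ind
            if not out:
                raise ValueError(f"term {self.name!r} has a single level; not estimable")
            out = pd.DataFrame(out)
        elif self.kind == "ordinal":
            if self.levels is None:
                raise ValueError("ordinal term requires an explicit level order")
            codes = {lev: i for i, lev in enumerate(self.levels)}
            vals = col.map(codes).astype(float)
            out = pd.DataFrame({self.name: vals})
        else:
            raise ValueError(f"unknown term kind: {self.kind!r}")
        out.index = df.index
        return out


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    terms: tuple[Term, ...]
    name: str = ""

    def with_terms(self, *extra: Term, name: str = "") -> "ModelSpec":
        return ModelSpec(self.outcome, self.terms + tuple(extra), name or self.name)


@dataclass(frozen=True)
class LogisticFit:
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    nobs: int
    converged: bool
    spec: ModelSpec
    row_index: pd.Index

    def se(self, term: str) -> float:
        return float(np.sqrt(self.cov.loc[term, term]))

    def effect(self, term: str, adjusted_for: tuple[str, ...] = ()) -> EffectEstimate:
        """exp(beta) with the Wald 95% CI for one design column."""
        beta = float(self.params[term])
        se = self.se(term)
        z = beta / se if se > 0 else np.inf
        return EffectEstimate(
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - Z_95 * se)),
            ci_high=float(np.exp(beta + Z_95 * se)),
            p_value=float(2 * stats.norm.sf(abs(z))),
            adjusted_for=adjusted_for,
            label=term,
        )

    def coefficient_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov.values))
        beta = self.params.values
        return pd.DataFrame(
            {
                "beta": beta,
                "se": se,
                "odds_ratio": np.exp(beta),
                "ci_low": np.exp(beta - Z_95 * se),
                "ci_high": np.exp(beta + Z_95 * se),
                "p_value": 2 * stats.norm.sf(np.abs(beta / se)),
            },
            index=self.params.index,
        )


def build_design(
    subjects: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.Series, pd.DataFrame]:
    """Outcome vector and design matrix (with intercept), complete cases only."""
    pieces = [term.columns(subjects) for term in spec.terms]
    X = (
        pd.concat(pieces, axis=1)
        if pieces
        else pd.DataFrame(index=subjects.index)  # intercept-only model
    )
    y = pd.to_numeric(subjects[spec.outcome], errors="raise")
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X[keep], y[keep].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    X.insert(0, "const", 1.0)
    return y, X


_MAX_ABS_BETA = 20.0  # |log-odds| beyond this on a fitted scale implies separation


def _fit_design(y: pd.Series, X: pd.DataFrame, spec: ModelSpec) -> LogisticFit:
    if len(y) < X.shape[1]:
        raise ValueError(
            f"{len(y)} complete-case rows is fewer than {X.shape[1]} parameters"
        )
    model = sm.Logit(np.asarray(y), np.asarray(X))
    try:
        res = model.fit(disp=0, maxiter=100, tol=1e-10, method="newton")
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"model {spec.name or spec.outcome}: {exc}") from exc
    params = pd.Series(res.params, index=X.columns)
    if np.abs(params).max() > _MAX_ABS_BETA:
        raise SeparationError(
            f"model {spec.name or spec.outcome}: diverging coefficients "
            f"(max |beta| = {np.abs(params).max():.1f}); outcome likely separated"
        )
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(f"model {spec.name or spec.outcome} did not converge")
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return LogisticFit(
        params=params,
        cov=cov,
        llf=float(res.llf),
        nobs=int(res.nobs),
        converged=True,
        spec=spec,
        row_index=y.index,
    )


def fit_logistic(subjects: pd.DataFrame, spec: ModelSpec) -> LogisticFit:
    """Maximum-likelihood logistic regression on complete cases.

    Raises :class:`SeparationError` on perfect/quasi separation and
    :class:`ConvergenceError` if Newton iterations do not converge.
    """
    y, X = build_design(subjects, spec)
    return _fit_design(y, X, spec)


def wald_trend_test(fit: LogisticFit, ordinal_term: str) -> TestResult:
    """Two-sided Wald z-test of a single ordinal-coded coefficient."""
    if ordinal_term not in fit.params.index:
        raise KeyError(f"term {ordinal_term!r} not in the fitted model")
    beta = float(fit.params[ordinal_term])
    se = fit.se(ordinal_term)
    z = beta / se if se > 0 else np.inf
    return TestResult(
        statistic=float(z), df=None,
        p_value=float(2 * stats.norm.sf(abs(z))),
        test_name="Wald trend test",
    )


def likelihood_ratio_test(fit_null: LogisticFit, fit_full: LogisticFit) -> TestResult:
    """LRT of nested logistic models fitted on identical rows."""
    if not fit_null.row_index.equals(fit_full.row_index):
        raise ValueError("LRT requires both models fitted on identical rows")
    null_cols = set(fit_null.params.index)
    full_cols = set(fit_full.params.index)
    if not null_cols <= full_cols:
        raise ValueError("models are not nested (null design not contained in full)")
    df = len(full_cols) - len(null_cols)
    statistic = max(0.0, 2.0 * (fit_full.llf - fit_null.llf))
    p_value = 1.0 if df == 0 else float(stats.chi2.sf(statistic, df=df))
    return TestResult(
        statistic=float(statistic), df=df, p_value=p_value,
        test_name="likelihood-ratio test",
    )


def interaction_test(
    subjects: pd.DataFrame,
    base_terms: Sequence[Term],
    factor_a: Term,
    factor_b: Term,
    outcome: str = "status",
) -> TestResult:
    """LRT for interaction between two categorical/binary factors.

    Compares the model with all pairwise product terms of the two factors'
    indicator columns against the main-effects model, fitted on the same
    complete-case rows; df = (levels_a - 1) * (levels_b - 1). Empty cross
    cells are tolerated (the fit proceeds on the available data); a factor
    observed at a single level is not estimable and raises ValueError.
    """
    cols_a = factor_a.columns(subjects)
    cols_b = factor_b.columns(subjects)
    for fac, cols in ((factor_a, cols_a), (factor_b, cols_b)):
        observed = subjects[fac.name].dropna()
        if observed.nunique() < 2:
            raise ValueError(f"interaction not estimable: {fac.name!r} is constant")
    spec_null = ModelSpec(outcome, tuple(base_terms) + (factor_a, factor_b), "main effects")
    y, X = build_design(subjects, spec_null)
    products = {}
    for ca in cols_a.columns:
        for cb in cols_b.columns:
            products[f"{ca}:{cb}"] = cols_a[ca] * cols_b[cb]
    X_full = pd.concat([X, pd.DataFrame(products, index=subjects.index).loc[X.index]], axis=1)
    keep = X_full.notna().all(axis=1)
    y, X, X_full = y[keep], X[keep], X_full[keep]
    fit_null = _fit_design(y, X, spec_null)
    fit_full = _fit_design(y, X_full, replace(spec_null, name="with interaction"))
    result = likelihood_ratio_test(fit_null, fit_full)
    return TestResult(
        statistic=result.statistic, df=result.df, p_value=result.p_value,
        test_name=f"LRT interaction {factor_a.name} x {factor_b.name}",
    )


@dataclass(frozen=True)
class StratumEstimate:
    stratum: str
    n: int
    available: bool
    estimates: tuple[EffectEstimate, ...] = ()
    trend: TestResult | None = None
    reason: str = ""


def stratified_estimates(
    subjects: pd.DataFrame,
    exposure: Term,
    stratum_col: str,
    adjustment_terms: Sequence[Term],
    outcome: str = "status",
) -> list[StratumEstimate]:
    """Adjusted exposure effects within each level of a stratifying variable.

    Each stratum gets its own logistic fit (exposure + adjustment terms).
    Strata too small to fit, or where the fit fails, are flagged unavailable
    with the reason, never silently dropped.
    """
    strata = subjects[stratum_col].dropna()
    levels = (
        tuple(strata.cat.categories)
        if isinstance(strata.dtype, pd.CategoricalDtype)
        else tuple(pd.unique(strata))
    )
    if len(levels) < 2:
        raise ValueError(f"stratum variable {stratum_col!r} must have >= 2 levels")
    spec = ModelSpec(outcome, (exposure,) + tuple(adjustment_terms), "stratified")
    adjusted_for = tuple(t.name for t in adjustment_terms)
    out: list[StratumEstimate] = []
    for lev in levels:
        rows = subjects[subjects[stratum_col] == lev]
        try:
            fit = fit_logistic(rows, spec)
        except (ValueError, KeyError, SeparationError, ConvergenceError) as exc:
            out.append(
                StratumEstimate(stratum=str(lev), n=len(rows), available=False,
                                reason=str(exc))
            )
            continue
        exp_cols = [c for c in fit.params.index if c.startswith(f"{exposure.name}[") or c == exposure.name]
        estimates = tuple(fit.effect(c, adjusted_for=adjusted_for) for c in exp_cols)
        out.append(
            StratumEstimate(
                stratum=str(lev), n=fit.nobs, available=True, estimates=estimates
            )
        )
    return out


# ---------------------------------------------------------------------------
# Model presets mirroring the study's multivariable models A-H
# ---------------------------------------------------------------------------

DIET_TERCILE_TERM = Term(
    "diet_tercile", "categorical", reference="low", levels=("low", "medium", "high")
)
DIET_ORDINAL_TERM = Term("diet_tercile", "ordinal", levels=("low", "medium", "high"))

#: Model A covariates: sex, age, education, number of nevi, skin photo-type,
#: solar lentigines and sunburns in childhood.
MODEL_A_COVARIATES: tuple[Term, ...] = (
    Term("sex", "binary", positive="male"),
    Term("age", "continuous"),
    Term("education", "categorical", reference="<8", levels=("<8", "8-13", ">13")),
    Term("nevi", "binary", positive=">=60"),
    Term("photo_type", "binary", positive="I-II"),
    Term("lentigines", "binary", positive="high"),
    Term("sunburn_childhood", "binary", positive=1),
)

_EXTRA_TERMS: dict[str, tuple[Term, ...]] = {
    "A": (),
    "B": (Term("bmi", "categorical", reference="<=24.9",
               levels=("<=24.9", "25.0-29.9", ">=30")),),
    "C": (Term("cox2_inhibitor", "binary", positive=1),),
    "D": (Term("aspirin", "binary", positive=1),),
    "E": (Term("genotype_pooled", "binary", positive="C_carrier"),),
    "F": (Term("smoking", "categorical", reference="never",
               levels=("never", "current", "ex")),),
    "G": (Term("chronic_ex_cvd", "binary", positive=1),),
    "H": (Term("chronic_incl_cvd", "binary", positive=1),),
}

#: Presets A-H: model A is the core covariate set; B-H add one robustness
#: covariate each (BMI, COX-2 inhibitor use, aspirin, -765G>C genotype,
#: smoking, chronic disease excluding / including CVDs).
MODEL_PRESETS: dict[str, ModelSpec] = {
    key: ModelSpec(
        outcome="status",
        terms=(DIET_TERCILE_TERM,) + MODEL_A_COVARIATES + extra,
        name=f"model_{key}",
    )
    for key, extra in _EXTRA_TERMS.items()
}


def trend_spec(preset: ModelSpec) -> ModelSpec:
    """The preset with the diet tercile recoded as an ordinal 0/1/2 term."""
    terms = tuple(
        DIET_ORDINAL_TERM if (t.name == "diet_tercile") else t for t in preset.terms
    )
    return ModelSpec(preset.outcome, terms, preset.name + "_trend")
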