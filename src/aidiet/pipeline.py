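"""End-to-end study analysis: descriptive tables, multivariable models A-H,
trend tests, gene-environment interaction and genotype-stratified estimates.

The entry point is :func:`analyze`, which takes a subject table (one row per
subject with the standard column schema produced by ``simulate``/``score``)
and returns a nested report dict that serializes to JSON, with CSV renderings
of each table available through :func:`write_report`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .association import (
    MODEL_A_COVARIATES,
    MODEL_PRESETS,
    ConvergenceError,
    DIET_TERCILE_TERM,
    SeparationError,
    Term,
    chi_square_test,
    crosstab,
    crude_or,
    fit_logistic,
    interaction_test,
    mann_whitney_u,
    stratified_estimates,
    trend_spec,
    wald_trend_test,
)

logger = logging.getLogger("aidiet")

__all__ = ["run_descriptives", "run_models", "run_gene_environment", "analyze", "write_report"]

#: (column, level order, reference index) for the categorical descriptive rows.
DESCRIPTIVE_VARIABLES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("sex", ("female", "male")),
    ("education", ("<8", "8-13", ">13")),
    ("hair_colour", ("dark", "light_brown", "fair")),
    ("photo_type", ("III-IV", "I-II")),
    ("skin_colour", ("dark", "fair")),
    ("freckles", ("0", "1")),
    ("nevi", ("0-59", ">=60")),
    ("lentigines", ("none/few/moderate", "high")),
    ("family_history", ("0", "1")),
    ("chronic_ex_cvd", ("0", "1")),
    ("chronic_incl_cvd", ("0", "1")),
    ("genotype", ("GG", "GC", "CC")),
    ("sun_hours", ("<=26", "27-36", ">=37")),
    ("sunburn_childhood", ("0", "1")),
    ("bmi", ("<=24.9", "25.0-29.9", ">=30")),
    ("smoking", ("never", "current", "ex")),
    ("cox2_inhibitor", ("0", "1")),
    ("aspirin", ("0", "1")),
    ("diet_tercile", ("low", "medium", "high")),
)


def _effect_dict(e) -> dict:
    return {
        "odds_ratio": e.odds_ratio,
        "ci_low": e.ci_low,
        "ci_high": e.ci_high,
        "p_value": e.p_value,
        "adjusted_for": list(e.adjusted_for),
    }


def run_descriptives(subjects: pd.DataFrame) -> dict:
    """Per-variable counts/percentages by status, chi-square p (Mann-Whitney
    for age) and crude level-vs-reference odds ratios."""
    out: dict = {"variables": {}}
    status = subjects["status"].astype(int)
    n_cases = int((status == 1).sum())
    n_controls = int((status == 0).sum())
    out["n_cases"] = n_cases
    out["n_controls"] = n_controls

    if "age" in subjects.columns and subjects["age"].notna().any():
        cases_age = subjects.loc[status == 1, "age"].dropna()
        controls_age = subjects.loc[status == 0, "age"].dropna()
        mw = mann_whitney_u(cases_age, controls_age)
        out["age"] = {
            "case_mean": float(cases_age.mean()),
            "case_sd": float(cases_age.std()),
            "control_mean": float(controls_age.mean()),
            "control_sd": float(controls_age.std()),
            "test": mw.test_name,
            "p_value": mw.p_value,
        }

    for column, levels in DESCRIPTIVE_VARIABLES:
        if column not in subjects.columns:
            continue
        values = subjects[column].astype(object).where(subjects[column].notna())
        values = values.map(lambda v: str(int(v)) if isinstance(v, (int, np.integer, float)) and not pd.isna(v) else v)
        if values.notna().sum() == 0:
            out["variables"][column] = {"flag": "all missing; skipped"}
            logger.warning("descriptives: %s all missing, skipped", column)
            continue
        frame = pd.DataFrame({"status": status, column: values})
        table = crosstab(frame, column, levels=levels)
        entry: dict = {
            "levels": list(levels),
            "case_counts": table.counts[:, 0].tolist(),
            "control_counts": table.counts[:, 1].tolist(),
            "n_missing": table.n_missing,
        }
        try:
            entry["chi_square_p"] = chi_square_test(table).p_value
        except ValueError as exc:
            entry["chi_square_p"] = None
            entry["flag"] = f"chi-square unavailable: {exc}"
        ors = {}
        for i, lev in enumerate(levels):
            if i == table.reference:
                continue
            try:
                ors[lev] = _effect_dict(crude_or(*table.slice_2x2(i)))
            except ValueError as exc:
                ors[lev] = {"flag": str(exc)}
        entry["crude_or_vs_reference"] = ors
        out["variables"][column] = entry

    if "diet_score" in subjects.columns:
        for label, mask in (("case", status == 1), ("control", status == 0)):
            scores = subjects.loc[mask, "diet_score"].dropna()
            out[f"{label}_diet_score_mean"] = float(scores.mean())
            out[f"{label}_diet_score_sd"] = float(scores.std())
    return out


def run_models(subjects: pd.DataFrame, presets: Sequence[str] = tuple("ABCDEFGH")) -> dict:
    """Tercile odds ratios (T2, T3 vs T1), Wald 95% CIs and trend p per preset."""
    out: dict = {}
    for key in presets:
        if key not in MODEL_PRESETS:
            raise KeyError(f"unknown model preset {key!r}; available: A-H")
        spec = MODEL_PRESETS[key]
        missing = [t.name for t in spec.terms if t.name not in subjects.columns]
        if missing:
            raise KeyError(f"model {key}: dataset lacks covariates {missing}")
        fit = fit_logistic(subjects, spec)
        adjusted_for = tuple(t.name for t in spec.terms if t.name != "diet_tercile")
        trend_fit = fit_logistic(subjects, trend_spec(spec))
        trend = wald_trend_test(trend_fit, "diet_tercile")
        out[key] = {
            "n": fit.nobs,
            "covariates": list(adjusted_for),
            "or_t2": _effect_dict(fit.effect("diet_tercile[medium]", adjusted_for)),
            "or_t3": _effect_dict(fit.effect("diet_tercile[high]", adjusted_for)),
            "p_trend": trend.p_value,
        }
    return out


def run_gene_environment(subjects: pd.DataFrame, min_genotyped: int = 50) -> dict:
    """Interaction LRT (diet tercile x pooled genotype) and per-stratum
    adjusted tercile estimates; skipped with a warning without genotype data."""
    if "genotype_pooled" not in subjects.columns or subjects["genotype_pooled"].notna().sum() < min_genotyped:
        logger.warning("gene-environment section skipped: insufficient genotype data")
        return {"flag": "skipped: insufficient genotype data"}
    genotyped = subjects[subjects["genotype_pooled"].notna()]
    factor_b = Term("genotype_pooled", "binary", positive="C_carrier")
    result = interaction_test(
        genotyped, MODEL_A_COVARIATES, DIET_TERCILE_TERM, factor_b
    )
    strata = stratified_estimates(
        genotyped, DIET_TERCILE_TERM, "genotype_pooled", MODEL_A_COVARIATES
    )
    return {
        "interaction": {
            "statistic": result.statistic,
            "df": result.df,
            "p_value": result.p_value,
        },
        "n_genotyped": int(len(genotyped)),
        "strata": [
            {
                "stratum": s.stratum,
                "n": s.n,
                "available": s.available,
                "reason": s.reason,
                "estimates": {e.label: _effect_dict(e) for e in s.estimates},
            }
            for s in strata
        ],
    }


def analyze(
    subjects: pd.DataFrame,
    presets: Sequence[str] = tuple("ABCDEFGH"),
    metadata: Mapping | None = None,
) -> dict:
    """Full analysis report: descriptives, models A-H, gene-environment."""
    report = {
        "metadata": {
            "software": f"aidiet {_version}",
            "n_rows": int(len(subjects)),
            **(dict(metadata) if metadata else {}),
        },
        "descriptives": run_descriptives(subjects),
        "models": run_models(subjects, presets),
        "gene_environment": run_gene_environment(subjects),
    }
    return report


def write_report(report: Mapping, out_dir: str | Path) -> None:
    """Write the JSON report plus per-table CSV renderings."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)

    rows = []
    for var, entry in report["descriptives"]["variables"].items():
        if "levels" not in entry:
            continue
        for i, lev in enumerate(entry["levels"]):
            est = entry["crude_or_vs_reference"].get(lev, {})
            rows.append(
                {
                    "variable": var,
                    "level": lev,
                    "cases": entry["case_counts"][i],
                    "controls": entry["control_counts"][i],
                    "chi_square_p": entry["chi_square_p"],
                    "crude_or": est.get("odds_ratio"),
                    "ci_low": est.get("ci_low"),
                    "ci_high": est.get("ci_high"),
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "descriptives.csv", index=False)

    rows = []
    for key, entry in report["models"].items():
        for tercile, field in (("medium", "or_t2"), ("high", "or_t3")):
            est = entry[field]
            rows.append(
                {
                    "model": key,
                    "tercile": tercile,
                    "n": entry["n"],
                    "odds_ratio": est["odds_ratio"],
                    "ci_low": est["ci_low"],
                    "ci_high": est["ci_high"],
                    "p_trend": entry["p_trend"],
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "models.csv", index=False)

    ge = report["gene_environment"]
    if "strata" in ge:
        rows = []
        for s in ge["strata"]:
            for label, est in s["estimates"].items():
                rows.append(
                    {
                        "stratum": s["stratum"],
                        "n": s["n"],
                        "term": label,
                        "odds_ratio": est["odds_ratio"],
                        "ci_low": est["ci_low"],
                        "ci_high": est["ci_high"],
                        "interaction_p": ge["interaction"]["p_value"],
                    }
                )
        pd.DataFrame(rows).to_csv(out_dir / "gene_environment.csv", index=False)
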