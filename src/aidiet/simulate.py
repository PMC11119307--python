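"""Synthetic case-control data with the structure the analysis assumes.

The generator draws a source population with independently distributed
covariates (prevalences set to the study's control marginals), Hardy-Weinberg
genotypes, and FFQ items with configurable high-consumption probabilities;
assigns disease from a logistic model that is linear in the diet score/terciles
and the model-A covariates; then samples cases and frequency-matched controls
(sex 1:1, 5-year age strata). Everything is deterministic given the seed.

The packaged default calibration reproduces, in expectation, the original
study's mean diet scores (controls 6.2, cases 5.5) at 10% population
prevalence; the calibration constants were solved exactly on the
Bernoulli-sum score distribution (see docs/methods.md).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .diet_score import ITEM_MIN_LEVEL, PUBLISHED_CUTPOINTS, categorize_score

__all__ = [
    "GeneratorConfig",
    "StudyDataset",
    "MatchingError",
    "sample_population",
    "assign_disease",
    "draw_case_control",
    "simulate_study",
    "calibration_default",
    "tercile_recovery_config",
    "interaction_recovery_config",
    "DEFAULT_SEED",
]

#: Fallback seed for test fixtures (the study's publication date).
DEFAULT_SEED = 20240523

#: Calibrated per-item high-consumption probabilities (CSV column names).
#: Solved so the control mean score is 6.2 under the default disease model.
ITEM_PROBS_CALIBRATED: dict[str, float] = {
    "green_leafy": 0.632460,
    "salad": 0.729762,
    "veg_general": 0.583810,
    "citrus": 0.437857,
    "fruits": 0.681111,
    "nuts": 0.340556,
    "coffee": 0.778413,
    "fish_n3": 0.389206,
    "olive_oil": 0.827063,
    "rosemary": 0.437857,
    "salvia": 0.291905,
}

#: CSV column -> scored-item threshold (frequency items only).
_FREQ_THRESHOLDS = {
    "green_leafy": ITEM_MIN_LEVEL["green_leafy_vegetables"],
    "salad": ITEM_MIN_LEVEL["salad"],
    "veg_general": ITEM_MIN_LEVEL["vegetables_general"],
    "citrus": ITEM_MIN_LEVEL["citrus_fruits"],
    "fruits": ITEM_MIN_LEVEL["fruits_general"],
    "nuts": ITEM_MIN_LEVEL["nuts"],
    "coffee": ITEM_MIN_LEVEL["coffee"],
    "fish_n3": ITEM_MIN_LEVEL["fish_n3"],
}
_BINARY_COLS = ("olive_oil", "rosemary", "salvia")

# Calibrated disease-model constants (exact solve; per-point score OR 0.707).
_CAL_INTERCEPT = -2.5533605594
_CAL_BETA_SCORE = -0.3464168814


class MatchingError(RuntimeError):
    """A sex-by-age matching cell cannot be filled from the population."""


@dataclass(frozen=True)
class GeneratorConfig:
    """All simulation parameters; fully determines a dataset given the seed."""

    seed: int
    population_n: int = 20_000
    n_cases: int = 273
    n_controls: int = 269
    matching: str = "frequency"  # 'frequency' or 'exact'

    # covariate marginals (study control distributions)
    sex_male_p: float = 0.435
    age_mean: float = 51.9
    age_sd: float = 15.6
    age_min: float = 18.0
    age_max: float = 90.0
    education_p: tuple[float, float, float] = (0.219, 0.666, 0.115)  # <8, 8-13, >13
    hair_p: tuple[float, float, float] = (0.665, 0.253, 0.082)  # dark, light brown, fair
    skin_fair_p: float = 0.587
    freckles_p: float = 0.187
    photo_i_ii_p: float = 0.422
    nevi_high_p: float = 0.130
    lentigines_high_p: float = 0.588
    family_history_p: float = 0.034
    chronic_ex_cvd_p: float = 0.297
    chronic_incl_cvd_p: float = 0.320
    sunburn_childhood_p: float = 0.248
    bmi_p: tuple[float, float, float] = (0.493, 0.388, 0.119)
    smoking_p: tuple[float, float, float] = (0.468, 0.368, 0.164)  # never, current, ex
    cox2_inhibitor_p: float = 0.108
    aspirin_p: float = 0.037
    sun_hours_p: tuple[float, float, float] = (0.341, 0.345, 0.314)
    allele_c_freq: float = 0.2244

    # FFQ item high-consumption probabilities (CSV column names)
    item_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(ITEM_PROBS_CALIBRATED)
    )

    # disease model (log-odds)
    intercept: float = _CAL_INTERCEPT
    beta_score: float = _CAL_BETA_SCORE  # per score point
    beta_t2: float = 0.0  # medium vs low tercile
    beta_t3: float = 0.0  # high vs low tercile
    beta_sex_male: float = 0.0
    beta_age: float = 0.0  # per year
    beta_education_mid: float = math.log(1.43)
    beta_education_high: float = math.log(2.87)
    beta_photo: float = math.log(2.80)
    beta_nevi: float = math.log(5.41)
    beta_lentigines: float = math.log(3.60)
    beta_sunburn: float = math.log(2.50)
    beta_c_carrier: float = math.log(0.85)
    beta_t2_x_c: float = 0.0  # tercile-by-genotype interaction
    beta_t3_x_c: float = 0.0

    # per-column missingness rates applied to the drawn dataset
    missing_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        probs = [
            self.sex_male_p, self.skin_fair_p, self.freckles_p, self.photo_i_ii_p,
            self.nevi_high_p, self.lentigines_high_p, self.family_history_p,
            self.chronic_ex_cvd_p, self.chronic_incl_cvd_p, self.sunburn_childhood_p,
            self.cox2_inhibitor_p, self.aspirin_p, self.allele_c_freq,
            *self.education_p, *self.hair_p, *self.bmi_p, *self.smoking_p,
            *self.sun_hours_p, *self.item_probs.values(), *self.missing_rates.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.matching not in ("frequency", "exact"):
            raise ValueError(f"unknown matching mode: {self.matching!r}")
        if self.matching == "exact" and self.n_cases != self.n_controls:
            raise ValueError("exact matching requires n_cases == n_controls")
        missing_items = set(ITEM_PROBS_CALIBRATED) - set(self.item_probs)
        if missing_items:
            raise ValueError(f"item_probs lacks items: {sorted(missing_items)}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class StudyDataset:
    data: pd.DataFrame
    config: GeneratorConfig
    provenance: dict

    @property
    def n_cases(self) -> int:
        return int((self.data["status"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.data["status"] == 0).sum())


def _categorical(rng, n, probs, labels):
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(labels), size=n, p=p)
    return np.asarray(labels, dtype=object)[idx]


def age_stratum(age: np.ndarray, width: int = 5, start: int = 18) -> np.ndarray:
    """5-year stratum label for each age: [18-22], [23-27], ..."""
    lo = start + width * np.floor((np.asarray(age) - start) / width).astype(int)
    return np.array([f"{l}-{l + width - 1}" for l in lo], dtype=object)


def sample_population(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the source population: covariates, HWE genotypes, FFQ items, score."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.population_n

    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )

    q = config.allele_c_freq
    p = 1 - q
    genotype = _categorical(rng, n, (p * p, 2 * p * q, q * q), ("GG", "GC", "CC"))

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": np.where(rng.random(n) < config.sex_male_p, "male", "female"),
            "age": age,
            "education": _categorical(rng, n, config.education_p, ("<8", "8-13", ">13")),
            "hair_colour": _categorical(
                rng, n, config.hair_p, ("dark", "light_brown", "fair")
            ),
            "skin_colour": np.where(rng.random(n) < config.skin_fair_p, "fair", "dark"),
            "freckles": (rng.random(n) < config.freckles_p).astype(int),
            "photo_type": np.where(
                rng.random(n) < config.photo_i_ii_p, "I-II", "III-IV"
            ),
            "nevi": np.where(rng.random(n) < config.nevi_high_p, ">=60", "0-59"),
            "lentigines": np.where(
                rng.random(n) < config.lentigines_high_p, "high", "none/few/moderate"
            ),
            "family_history": (rng.random(n) < config.family_history_p).astype(int),
            "chronic_ex_cvd": (rng.random(n) < config.chronic_ex_cvd_p).astype(int),
            "chronic_incl_cvd": (rng.random(n) < config.chronic_incl_cvd_p).astype(int),
            "sunburn_childhood": (rng.random(n) < config.sunburn_childhood_p).astype(int),
            "bmi": _categorical(rng, n, config.bmi_p, ("<=24.9", "25.0-29.9", ">=30")),
            "smoking": _categorical(rng, n, config.smoking_p, ("never", "current", "ex")),
            "cox2_inhibitor": (rng.random(n) < config.cox2_inhibitor_p).astype(int),
            "aspirin": (rng.random(n) < config.aspirin_p).astype(int),
            "sun_hours": _categorical(
                rng, n, config.sun_hours_p, ("<=26", "27-36", ">=37")
            ),
            "genotype": genotype,
        }
    )
    df["genotype_pooled"] = np.where(df["genotype"] == "GG", "GG", "C_carrier")
    df["age_stratum"] = age_stratum(df["age"].to_numpy())

    # FFQ items: a Bernoulli "high consumption" hit per item; frequency items
    # then get a level uniform on the high (>= threshold) or low (< threshold)
    # side, so the item indicator probability equals the configured one.
    score = np.zeros(n, dtype=int)
    for col, thr in _FREQ_THRESHOLDS.items():
        hit = rng.random(n) < config.item_probs[col]
        high = rng.integers(thr, 7, size=n)
        low = rng.integers(0, thr, size=n)
        df[col] = np.where(hit, high, low)
        score += hit.astype(int)
    for col in _BINARY_COLS:
        hit = rng.random(n) < config.item_probs[col]
        df[col] = hit.astype(int)
        score += hit.astype(int)
    df["diet_score"] = score
    df["diet_tercile"] = pd.Categorical(
        [categorize_score(s, PUBLISHED_CUTPOINTS).value for s in score],
        categories=["low", "medium", "high"],
    )
    return df


def disease_logit(population: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """Linear predictor of the disease model for each subject."""
    t2 = (population["diet_tercile"] == "medium").to_numpy(dtype=float)
    t3 = (population["diet_tercile"] == "high").to_numpy(dtype=float)
    carrier = (population["genotype_pooled"] == "C_carrier").to_numpy(dtype=float)
    logit = (
        config.intercept
        + config.beta_score * population["diet_score"].to_numpy(dtype=float)
        + config.beta_t2 * t2
        + config.beta_t3 * t3
        + config.beta_sex_male * (population["sex"] == "male").to_numpy(dtype=float)
        + config.beta_age * population["age"].to_numpy(dtype=float)
        + config.beta_education_mid * (population["education"] == "8-13").to_numpy(dtype=float)
        + config.beta_education_high * (population["education"] == ">13").to_numpy(dtype=float)
        + config.beta_photo * (population["photo_type"] == "I-II").to_numpy(dtype=float)
        + config.beta_nevi * (population["nevi"] == ">=60").to_numpy(dtype=float)
        + config.beta_lentigines * (population["lentigines"] == "high").to_numpy(dtype=float)
        + config.beta_sunburn * population["sunburn_childhood"].to_numpy(dtype=float)
        + config.beta_c_carrier * carrier
        + config.beta_t2_x_c * t2 * carrier
        + config.beta_t3_x_c * t3 * carrier
    )
    return logit


def assign_disease(
    population: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw disease status from the logistic model; adds a 'diseased' column."""
    out = population.copy()
    prob = expit(disease_logit(population, config))
    out["diseased"] = (rng.random(len(out)) < prob).astype(int)
    return out


def _allocate_controls(case_counts: pd.Series, n_controls: int) -> pd.Series:
    """Largest-remainder allocation of controls proportional to case cells."""
    target = case_counts * n_controls / case_counts.sum()
    floor = np.floor(target).astype(int)
    shortfall = n_controls - int(floor.sum())
    remainders = (target - floor).sort_values(ascending=False)
    extra = pd.Series(0, index=case_counts.index)
    if shortfall > 0:
        extra[remainders.index[:shortfall]] = 1
    return floor + extra


def draw_case_control(
    population: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> StudyDataset:
    """Sample cases and sex/age frequency-matched controls; apply missingness."""
    if "diseased" not in population.columns:
        raise ValueError("population lacks disease status; run assign_disease first")
    diseased = population[population["diseased"] == 1]
    healthy = population[population["diseased"] == 0]
    if len(diseased) < config.n_cases:
        raise MatchingError(
            f"population has {len(diseased)} diseased subjects; {config.n_cases} cases requested"
        )
    case_idx = rng.choice(diseased.index.to_numpy(), size=config.n_cases, replace=False)
    cases = population.loc[case_idx]

    cells = cases.groupby(["sex", "age_stratum"], observed=True).size()
    if config.matching == "exact":
        control_counts = cells.copy()
    else:
        control_counts = _allocate_controls(cells, config.n_controls)

    control_rows = []
    healthy_cells = dict(tuple(healthy.groupby(["sex", "age_stratum"], observed=True)))
    for cell, k in control_counts.items():
        if k == 0:
            continue
        pool = healthy_cells.get(cell)
        if pool is None or len(pool) < k:
            have = 0 if pool is None else len(pool)
            raise MatchingError(
                f"matching cell sex={cell[0]}, age={cell[1]}: need {k} controls, "
                f"population has {have} non-diseased subjects"
            )
        chosen = rng.choice(pool.index.to_numpy(), size=int(k), replace=False)
        control_rows.append(population.loc[chosen])
    controls = pd.concat(control_rows)

    data = pd.concat([cases.assign(status=1), controls.assign(status=0)])
    data = data.drop(columns=["diseased"]).reset_index(drop=True)
    data["id"] = np.arange(len(data))

    for col, rate in config.missing_rates.items():
        if rate <= 0:
            continue
        mask = rng.random(len(data)) < rate
        data[col] = data[col].astype(object)
        data.loc[mask, col] = np.nan
    if "genotype" in config.missing_rates and "genotype_pooled" in data.columns:
        data["genotype_pooled"] = data["genotype_pooled"].astype(object)
        data.loc[data["genotype"].isna(), "genotype_pooled"] = np.nan

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_cases": int((data["status"] == 1).sum()),
        "n_controls": int((data["status"] == 0).sum()),
        "matching": config.matching,
    }
    return StudyDataset(data=data, config=config, provenance=provenance)


def simulate_study(config: GeneratorConfig) -> StudyDataset:
    """population -> disease -> case-control sampling, one RNG stream from the seed."""
    rng = np.random.default_rng(config.seed)
    population = sample_population(config, rng)
    population = assign_disease(population, config, rng)
    return draw_case_control(population, config, rng)


def calibration_default(seed: int = DEFAULT_SEED, **overrides) -> GeneratorConfig:
    """The packaged calibration: reproduces the study's mean diet scores.

    Under this config the expected control mean score is 6.2 and the case
    mean 5.5 (exact solve on the score distribution); genotypes follow HWE at
    allele-C frequency 0.2244; covariate prevalences are the study's control
    marginals; the study's genotyping coverage (303/542) is emulated as a
    genotype missingness rate.
    """
    base = dict(
        seed=seed,
        population_n=20_000,
        n_cases=273,
        n_controls=269,
        missing_rates={"genotype": 1 - 303 / 542},
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def tercile_recovery_config(
    seed: int,
    or_t2: float = 0.83,
    or_t3: float = 0.29,
    n_cases: int = 5_000,
    n_controls: int = 5_000,
    population_n: int = 130_000,
    **overrides,
) -> GeneratorConfig:
    """Config whose diet effect is purely tercile-coded (the model-A truths).

    The per-point score effect is switched off so that exp(beta_t3) is the
    true adjusted high-vs-low odds ratio a correctly specified logistic fit
    should recover.
    """
    base = dict(
        seed=seed,
        population_n=population_n,
        n_cases=n_cases,
        n_controls=n_controls,
        beta_score=0.0,
        beta_t2=math.log(or_t2),
        beta_t3=math.log(or_t3),
        intercept=-2.2,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def interaction_recovery_config(
    seed: int,
    or_t3_gg: float = 0.17,
    or_t3_carrier: float = 0.21,
    or_t2: float = 0.83,
    n_cases: int = 10_000,
    n_controls: int = 10_000,
    population_n: int = 260_000,
    **overrides,
) -> GeneratorConfig:
    """Config with a genotype-by-tercile interaction: stratum-specific truths.

    GG is the reference stratum, so beta_t3 = ln(or_t3_gg) and the
    interaction term shifts C carriers to ln(or_t3_carrier).
    """
    base = dict(
        seed=seed,
        population_n=population_n,
        n_cases=n_cases,
        n_controls=n_controls,
        beta_score=0.0,
        beta_t2=math.log(or_t2),
        beta_t3=math.log(or_t3_gg),
        beta_t3_x_c=math.log(or_t3_carrier) - math.log(or_t3_gg),
        intercept=-2.2,
    )
    base.update(overrides)
    return GeneratorConfig(**base)
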