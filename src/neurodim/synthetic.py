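"""Synthetic participant cohorts with a latent internalising/externalising structure.

The generator emulates a community-sample data table: age, gender, eight
neurocognitive task scores, and nine symptom/substance-use domain scores
(six symptom-inventory domains plus alcohol, cannabis, and other-substance
involvement).  The nine domains are driven by two correlated latent factors
(internalising, externalising) through a fixed loading pattern, and the
latent factors in turn depend on the task scores through a switchable
ground-truth link:

``linear``
    factors are additive weighted sums of (negated) task z-scores plus
    demographic effects;
``interactive``
    the task contribution is carried by pairwise products of task z-scores,
    a signal invisible to main-effects regression;
``compensatory``
    latent burden follows the worst deficit over a task pair,
    ``max(deficit_a, deficit_b)``, so a preserved ability caps the benefit
    of the other;
``null``
    factors are pure correlated noise, independent of tasks and demographics.

All task scores are standard-normal z-scores; domain scores are unit-variance
with ``domain = loading * factor + sqrt(1 - loading^2) * uniqueness``.
Under ``null`` the population covariance of the nine domains is exactly
``Lambda Phi Lambda' + Psi`` with ``Phi = [[1, rho], [rho, 1]]``.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .errors import CohortDataError, ConfigError, EmptyFileError, SchemaError

TASK_COLUMNS = [
    "digit_span",
    "visual_wm",
    "inferring_relevance",
    "shape_number",
    "stroop",
    "go_nogo",
    "simple_rt",
    "inspection_time",
]

DOMAIN_COLUMNS = [
    "depression",
    "agoraphobia",
    "hostility",
    "mental_fog",
    "interpersonal_anxiety",
    "somatisation",
    "alcohol",
    "cannabis",
    "other_substances",
]

FACTOR_COLUMNS = ["internalising", "externalising", "p"]

CSV_COLUMNS = ["age", "gender"] + TASK_COLUMNS + DOMAIN_COLUMNS

#: gender coding used throughout: 0 = male, 1 = female.
GENDER_FEMALE = 1

# Task pairs that carry the latent "cognitive burden" signal for each factor.
# Speed-of-processing tasks drive internalising; inhibition/shifting tasks
# drive externalising.  Pairs are disjoint so the two factors' task signals
# are uncorrelated and the implied moments stay closed-form.
INT_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("simple_rt", "inspection_time"),
    ("digit_span", "stroop"),
)
EXT_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("go_nogo", "shape_number"),
    ("visual_wm", "inferring_relevance"),
)

# Standardised demographic effects on the latent factors (non-null modes):
# older age lowers burden scores' drivers... sign convention: negative age
# effect (younger adults report more symptoms), women slightly higher
# internalising and lower externalising.
AGE_BETA = {"internalising": -0.35, "externalising": -0.30}
GENDER_BETA = {"internalising": 0.15, "externalising": -0.15}

EFFECT_MODES = ("linear", "interactive", "compensatory", "null")

# max of two iid standard normals: mean 1/sqrt(pi), variance 1 - 1/pi
_MAX2_MEAN = 1.0 / math.sqrt(math.pi)
_MAX2_SD = math.sqrt(1.0 - 1.0 / math.pi)


def default_loading_pattern() -> Dict[str, Tuple[str, float]]:
    """Default domain -> (factor, loading) map.

    Magnitudes are typical of symptom-inventory CFA solutions (0.55-0.75);
    symptom domains load internalising except hostility, which joins the
    substance-use domains on externalising.
    """
    return {
        "depression": ("internalising", 0.75),
        "agoraphobia": ("internalising", 0.65),
        "mental_fog": ("internalising", 0.75),
        "interpersonal_anxiety": ("internalising", 0.70),
        "somatisation": ("internalising", 0.70),
        "hostility": ("externalising", 0.60),
        "alcohol": ("externalising", 0.55),
        "cannabis": ("externalising", 0.60),
        "other_substances": ("externalising", 0.55),
    }


@dataclass
class CohortConfig:
    """Generation parameters for one synthetic cohort.

    Defaults reproduce the reference sample's demographics (n = 400, age
    mean 44.47, SD 16.35, 51.5% female) with effect sizes chosen to land
    domain-level linear R-squared in the 0.1-0.2 range.
    """

    n_cases: int = 400
    seed: int = 0
    age_mean: float = 44.47
    age_sd: float = 16.35
    prop_female: float = 0.515
    effect_mode: str = "linear"
    effect_size: float = 0.35
    noise_sd: float = 0.7
    factor_corr: float = 0.6
    loading_pattern: Dict[str, Tuple[str, float]] = field(
        default_factory=default_loading_pattern
    )

    def validate(self) -> None:
        if self.effect_mode not in EFFECT_MODES:
            raise ConfigError(
                f"effect_mode must be one of {EFFECT_MODES}, got {self.effect_mode!r}"
            )
        if self.n_cases < 20:
            raise ConfigError("n_cases must be >= 20")
        if not (0.0 <= self.prop_female <= 1.0):
            raise ConfigError("prop_female must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not (-1.0 < self.factor_corr < 1.0):
            raise ConfigError("factor_corr must lie in (-1, 1)")
        if set(self.loading_pattern) != set(DOMAIN_COLUMNS):
            missing = set(DOMAIN_COLUMNS) - set(self.loading_pattern)
            extra = set(self.loading_pattern) - set(DOMAIN_COLUMNS)
            raise ConfigError(
                f"loading_pattern must cover the 9 domains exactly "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        for dom, (fac, lam) in self.loading_pattern.items():
            if not (0.0 < lam < 1.0):
                raise ConfigError(f"loading for {dom} must lie in (0, 1), got {lam}")
            if fac not in ("internalising", "externalising"):
                raise ConfigError(f"unknown factor {fac!r} for domain {dom!r}")


@dataclass
class Cohort:
    """A generated (or loaded) participant table.

    ``data`` holds the observable columns (age, gender, tasks, domains);
    ``latents`` — present only for generated cohorts — holds the true
    internalising/externalising/p factor scores for recovery tests;
    ``meta`` echoes the generating configuration and derived truths.
    """

    data: pd.DataFrame
    latents: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return len(self.data)

    def tasks(self) -> pd.DataFrame:
        return self.data[TASK_COLUMNS]

    def domains(self) -> pd.DataFrame:
        return self.data[DOMAIN_COLUMNS]

    def predictors(self) -> pd.DataFrame:
        """The 10 model inputs: age, gender, and the 8 task scores."""
        return self.data[["age", "gender"] + TASK_COLUMNS]


def _task_signal(mode: str, z: pd.DataFrame, pairs, effect_size: float) -> np.ndarray:
    """Unit-variance task-driven component of one latent factor, times effect_size."""
    n = len(z)
    if mode == "null" or effect_size == 0.0:
        return np.zeros(n)
    cols = [z[a].to_numpy() for pair in pairs for a in pair]
    a1, b1, a2, b2 = cols
    if mode == "linear":
        raw = -(a1 + b1 + a2 + b2) / 2.0
    elif mode == "interactive":
        raw = (a1 * b1 + a2 * b2) / math.sqrt(2.0)
    elif mode == "compensatory":
        m1 = (np.maximum(-a1, -b1) - _MAX2_MEAN) / _MAX2_SD
        m2 = (np.maximum(-a2, -b2) - _MAX2_MEAN) / _MAX2_SD
        raw = (m1 + m2) / math.sqrt(2.0)
    else:  # pragma: no cover - guarded by validate()
        raise ConfigError(f"unknown effect_mode {mode!r}")
    return effect_size * raw


def _factor_variances(config: CohortConfig) -> Dict[str, float]:
    """Population variance of each raw (pre-standardisation) latent factor."""
    out = {}
    for fac in ("internalising", "externalising"):
        if config.effect_mode == "null":
            v_demo = 0.0
            v_sig = 0.0
        else:
            v_demo = AGE_BETA[fac] ** 2 + GENDER_BETA[fac] ** 2
            v_sig = config.effect_size**2
        out[fac] = v_demo + v_sig + config.noise_sd**2
    return out


def analytic_factor_r2(config: CohortConfig) -> Dict[str, float]:
    """Population R-squared of the best predictor of each latent factor.

    For ``linear`` mode this is attainable by a linear model; for
    ``interactive``/``compensatory`` it is the share of factor variance
    carried by tasks + demographics (attainable only by a model that can
    represent the nonlinearity).
    """
    config.validate()
    var = _factor_variances(config)
    out = {}
    for fac, v_tot in var.items():
        out[fac] = (v_tot - config.noise_sd**2) / v_tot
    return out


def true_factor_correlation(config: CohortConfig) -> float:
    """Population correlation of the two standardised latent factors."""
    config.validate()
    if config.effect_mode == "null":
        return config.factor_corr
    var = _factor_variances(config)
    cov_demo = (
        AGE_BETA["internalising"] * AGE_BETA["externalising"]
        + GENDER_BETA["internalising"] * GENDER_BETA["externalising"]
    )
    cov = cov_demo + config.factor_corr * config.noise_sd**2
    return cov / math.sqrt(var["internalising"] * var["externalising"])


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one cohort. Deterministic for a given config (including seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    age = rng.normal(config.age_mean, config.age_sd, size=n)
    age = np.clip(age, 18.0, 90.0)  # adult community sample
    gender = (rng.random(n) < config.prop_female).astype(int)

    z_tasks = pd.DataFrame(
        rng.standard_normal((n, len(TASK_COLUMNS))), columns=TASK_COLUMNS
    )

    # correlated residual component of the two factors
    rho = config.factor_corr
    cov = config.noise_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    eps = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")

    var = _factor_variances(config)
    factors = {}
    p_female = config.prop_female
    g_sd = math.sqrt(max(p_female * (1 - p_female), 1e-12))
    z_age = (age - config.age_mean) / config.age_sd
    z_gender = (gender - p_female) / g_sd
    pairs = {"internalising": INT_PAIRS, "externalising": EXT_PAIRS}
    for idx, fac in enumerate(("internalising", "externalising")):
        sig = _task_signal(config.effect_mode, z_tasks, pairs[fac], config.effect_size)
        if config.effect_mode == "null":
            demo = 0.0
        else:
            demo = AGE_BETA[fac] * z_age + GENDER_BETA[fac] * z_gender
        factors[fac] = (demo + sig + eps[:, idx]) / math.sqrt(var[fac])

    rho_true = true_factor_correlation(config)
    p_factor = (factors["internalising"] + factors["externalising"]) / math.sqrt(
        2.0 * (1.0 + rho_true)
    )

    domains = {}
    for dom in DOMAIN_COLUMNS:
        fac, lam = config.loading_pattern[dom]
        unique = rng.standard_normal(n)
        domains[dom] = lam * factors[fac] + math.sqrt(1.0 - lam**2) * unique

    data = pd.DataFrame({"age": age, "gender": gender})
    for col in TASK_COLUMNS:
        data[col] = z_tasks[col]
    for col in DOMAIN_COLUMNS:
        data[col] = domains[col]

    latents = pd.DataFrame(
        {
            "internalising": factors["internalising"],
            "externalising": factors["externalising"],
            "p": p_factor,
        }
    )
    meta = {
        "config": _config_to_jsonable(config),
        "true_factor_correlation": rho_true,
        "analytic_factor_r2": analytic_factor_r2(config),
    }
    return Cohort(data=data, latents=latents, meta=meta)


def _config_to_jsonable(config: CohortConfig) -> dict:
    d = asdict(config)
    d["loading_pattern"] = {
        k: [fac, lam] for k, (fac, lam) in config.loading_pattern.items()
    }
    return d


def interaction_terms(cohort: Cohort) -> pd.DataFrame:
    """The generating pairwise product terms, one column per task pair.

    Used to check that linear-fit residuals under ``interactive`` truth
    still carry the interaction signal.
    """
    z = cohort.tasks()
    out = {}
    for a, b in INT_PAIRS + EXT_PAIRS:
        out[f"{a}*{b}"] = z[a] * z[b]
    return pd.DataFrame(out)


def write_cohort(cohort: Cohort, path, meta_path=None) -> None:
    """Write the cohort table as CSV (full float precision, fixed header).

    If ``meta_path`` is given, generation metadata (config echo plus any
    recorded true latent parameters) is written there as JSON.
    """
    path = Path(path)
    cohort.data.to_csv(path, index=False, columns=CSV_COLUMNS)
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps(cohort.meta, indent=2, sort_keys=True))


def read_cohort(path) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-made).

    Raises
    ------
    EmptyFileError
        if the file has no data rows;
    SchemaError
        if any required column is missing (named in the message);
    CohortDataError
        if any cell is missing or non-numeric.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyFileError(f"{path} is empty")
    try:
        # round_trip parser: values written by write_cohort reparse exactly
        df = pd.read_csv(io.StringIO(text), float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyFileError(f"{path} has no parseable content") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is missing required columns: {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyFileError(f"{path} has a header but no data rows")
    df = df[CSV_COLUMNS]
    for col in CSV_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            bad = int(values.isna().sum())
            raise CohortDataError(
                f"column {col!r} has {bad} missing or non-numeric value(s)"
            )
        df[col] = values
    df["gender"] = df["gender"].astype(int)
    return Cohort(data=df.reset_index(drop=True), latents=None, meta={"source": str(path)})
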