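"""Predicted-vs-actual correlations and Fisher r-to-z model comparisons.

The comparison protocol: Pearson correlations between each model family's
predictions and the observed outcomes; the nine lower-level (domain)
correlations are averaged on the raw r scale to a single accuracy figure;
the linear-vs-network contrast is tested with the two-independent-samples
Fisher transformation statistic

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))

with a two-tailed normal p, Bonferroni-controlled over the family of four
contrasts (lower-level average + three higher-level factors).  Note the
two correlations are computed on the same cases, so the independent-samples
test is approximate; it is kept for protocol fidelity and a dependent-
correlation variant is deliberately out of scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantVectorError, SchemaError
from .synthetic import DOMAIN_COLUMNS, FACTOR_COLUMNS


@dataclass
class CorrelationRecord:
    outcome: str
    model: str  # "LM" or "ANN"
    r: float
    n: int
    one_tailed_p: float


@dataclass
class ComparisonResult:
    label: str
    r_lm: float
    r_ann: float
    n_lm: int
    n_ann: int
    z: float
    p: float
    alpha_adjusted: float
    significant: bool


def pearson(pred, actual, model: str = "", outcome: str = "") -> CorrelationRecord:
    """Sample Pearson r with a one-tailed (r > 0) p from the t distribution."""
    x = np.asarray(pred, dtype=float)
    y = np.asarray(actual, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SchemaError("pearson expects two equal-length 1-d vectors")
    n = x.size
    if n < 4:
        raise SchemaError("need at least 4 cases for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ConstantVectorError(
            f"correlation undefined for constant vector (outcome={outcome or '?'})"
        )
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p_one = 0.0 if r > 0 else 1.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p_one = float(stats.t.sf(t, n - 2))
    return CorrelationRecord(outcome=outcome, model=model, r=r, n=n, one_tailed_p=p_one)


def average_correlations(records: Sequence[CorrelationRecord] | Sequence[float]) -> float:
    """Arithmetic mean of raw r values (not Fisher-z averaged)."""
    if len(records) == 0:
        raise ValueError("cannot average an empty list of correlations")
    rs = [rec.r if isinstance(rec, CorrelationRecord) else float(rec) for rec in records]
    return float(np.mean(rs))


def fisher_z_compare(
    r1: float,
    n1: int,
    r2: float,
    n2: int,
    *,
    label: str = "",
    alpha_adjusted: float = 0.05,
) -> ComparisonResult:
    """Two-correlation Fisher-transformation test (independent-samples form)."""
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1 for the Fisher transformation")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(
        label=label,
        r_lm=r1,
        r_ann=r2,
        n_lm=n1,
        n_ann=n2,
        z=float(z),
        p=p,
        alpha_adjusted=alpha_adjusted,
        significant=bool(p < alpha_adjusted),
    )


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 < family_alpha < 1.0):
        raise ValueError("family_alpha must lie in (0, 1)")
    return family_alpha / m


@dataclass
class ComparisonReport:
    records: List[CorrelationRecord]
    comparisons: List[ComparisonResult]
    lower_average_lm: float
    lower_average_ann: float
    family_alpha: float
    alpha_adjusted: float

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": c.label,
                "r_lm": c.r_lm,
                "r_ann": c.r_ann,
                "Z": c.z,
                "p": c.p,
                "alpha_adjusted": c.alpha_adjusted,
                "significant": c.significant,
            }
            for c in self.comparisons
        ]
        return pd.DataFrame(rows)

    def correlations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "outcome": r.outcome,
                    "model": r.model,
                    "r": r.r,
                    "n": r.n,
                    "one_tailed_p": r.one_tailed_p,
                }
                for r in self.records
            ]
        )

    def to_markdown(self) -> str:
        lines = ["# Linear vs. network predictive accuracy", ""]
        lines.append("## Predicted-vs-actual correlations")
        lines.append("")
        lines.append("| outcome | r (LM) | r (ANN) |")
        lines.append("|---|---|---|")
        by_outcome: Dict[str, Dict[str, float]] = {}
        for rec in self.records:
            by_outcome.setdefault(rec.outcome, {})[rec.model] = rec.r
        for outcome, d in by_outcome.items():
            lines.append(
                f"| {outcome} | {d.get('LM', float('nan')):.3f} "
                f"| {d.get('ANN', float('nan')):.3f} |"
            )
        lines.append("")
        lines.append(
            f"Lower-level average r: LM = {self.lower_average_lm:.3f}, "
            f"ANN = {self.lower_average_ann:.3f}"
        )
        lines.append("")
        lines.append("## Fisher-transformation comparisons")
        lines.append("")
        lines.append("| contrast | r (LM) | r (ANN) | Z | p | significant |")
        lines.append("|---|---|---|---|---|---|")
        for c in self.comparisons:
            lines.append(
                f"| {c.label} | {c.r_lm:.3f} | {c.r_ann:.3f} | {c.z:.3f} "
                f"| {c.p:.4f} | {'yes' if c.significant else 'no'} |"
            )
        lines.append("")
        lines.append(
            f"Bonferroni-adjusted alpha: {self.alpha_adjusted:.4f} "
            f"(family alpha {self.family_alpha}, {len(self.comparisons)} contrasts)"
        )
        return "\n".join(lines) + "\n"


def run_comparison_suite(
    lm_predictions: pd.DataFrame,
    ann_predictions: pd.DataFrame,
    actuals: pd.DataFrame,
    n: int | None = None,
    *,
    lower_outcomes: Sequence[str] = tuple(DOMAIN_COLUMNS),
    higher_outcomes: Sequence[str] = tuple(FACTOR_COLUMNS),
    family_alpha: float = 0.05,
) -> ComparisonReport:
    """Per-outcome correlations plus the four Bonferroni-controlled contrasts.

    ``lm_predictions``/``ann_predictions``/``actuals`` must share the outcome
    columns (lower-level domains and/or higher-level factors).  The contrast
    family is: the lower-level average correlation, plus one contrast per
    higher-level factor present.
    """
    outcomes = [c for c in list(lower_outcomes) + list(higher_outcomes) if c in actuals.columns]
    for df, name in ((lm_predictions, "lm_predictions"), (ann_predictions, "ann_predictions")):
        missing = [c for c in outcomes if c not in df.columns]
        if missing:
            raise SchemaError(f"{name} missing outcome columns: {', '.join(missing)}")
    if n is None:
        n = len(actuals)

    records: List[CorrelationRecord] = []
    for outcome in outcomes:
        records.append(
            pearson(lm_predictions[outcome], actuals[outcome], "LM", outcome)
        )
        records.append(
            pearson(ann_predictions[outcome], actuals[outcome], "ANN", outcome)
        )

    lower_present = [o for o in lower_outcomes if o in actuals.columns]
    higher_present = [o for o in higher_outcomes if o in actuals.columns]
    n_contrasts = (1 if lower_present else 0) + len(higher_present)
    alpha_adj = bonferroni_alpha(family_alpha, max(n_contrasts, 1))

    by = {(r.outcome, r.model): r for r in records}
    comparisons: List[ComparisonResult] = []
    avg_lm = avg_ann = float("nan")
    if lower_present:
        avg_lm = average_correlations([by[(o, "LM")] for o in lower_present])
        avg_ann = average_correlations([by[(o, "ANN")] for o in lower_present])
        comparisons.append(
            fisher_z_compare(
                avg_lm, n, avg_ann, n,
                label="lower_level_average", alpha_adjusted=alpha_adj,
            )
        )
    for o in higher_present:
        comparisons.append(
            fisher_z_compare(
                by[(o, "LM")].r, n, by[(o, "ANN")].r, n,
                label=o, alpha_adjusted=alpha_adj,
            )
        )
    return ComparisonReport(
        records=records,
        comparisons=comparisons,
        lower_average_lm=avg_lm,
        lower_average_ann=avg_ann,
        family_alpha=family_alpha,
        alpha_adjusted=alpha_adj,
    )
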