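"""Cohort-level diagnostic evaluation of the OCT burn score.

Given per-wound records (grades from one or two observers, clinical
judgment, healing outcome) this module builds 2x2 confusion tables at a
score threshold, computes predictive values / sensitivity / specificity /
agreement with 95% confidence intervals, sweeps the threshold over 0-6,
summarises a cohort, and quantifies inter-observer agreement (percent
agreement and Cohen's kappa per item and for the total score).

The unit of analysis is the hand (one row per burned hand), since
bilateral injuries occur; ``patient_id`` groups hands.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from statistics import median
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import CohortValidationError, EmptyCohortError
from .score import (
    DEFAULT_THRESHOLD,
    DepthClass,
    FeatureGrades,
    ManagementPrediction,
    SkinType,
    classify_depth,
    compute_score,
    predict_management,
)

__all__ = [
    "Outcome",
    "ClinicalJudgment",
    "WoundRecord",
    "ConfusionTable",
    "ProportionEstimate",
    "DiagnosticStats",
    "build_confusion",
    "diagnostic_stats",
    "threshold_sweep",
    "cohort_summary",
    "interobserver_agreement",
    "cohen_kappa",
    "round_percent",
]

CIMethod = Literal["wilson", "exact"]
DeepOutcomeRule = Literal["grafted_or_refused", "grafted_only"]
ObserverMode = Literal["obs1", "consensus"]


class Outcome(enum.Enum):
    """Healing course of a wound."""

    HEALED_SPONTANEOUSLY = "healed_spontaneously"
    GRAFTED = "grafted"
    # clinically deep wound whose family declined grafting (healed with
    # hypertrophic scarring); deep by healing course, not grafted
    DEEP_REFUSED_GRAFT = "deep_refused_graft"


class ClinicalJudgment(enum.Enum):
    """Bedside depth call at initial debridement."""

    SUPERFICIAL = "superficial"
    DEEP = "deep"


@dataclass(frozen=True)
class WoundRecord:
    """One burned hand: identifiers, grades, judgment and outcome."""

    wound_id: str
    patient_id: str
    skin_type: SkinType
    grades_obs1: FeatureGrades
    outcome: Outcome
    grades_obs2: Optional[FeatureGrades] = None
    clinical_judgment: Optional[ClinicalJudgment] = None
    days_to_graft: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.outcome is Outcome.GRAFTED) != (self.days_to_graft is not None):
            raise CohortValidationError(
                f"wound {self.wound_id!r}: days_to_graft must be present "
                f"iff outcome is grafted (outcome={self.outcome.value}, "
                f"days_to_graft={self.days_to_graft!r})"
            )
        if self.days_to_graft is not None and self.days_to_graft < 0:
            raise CohortValidationError(
                f"wound {self.wound_id!r}: days_to_graft must be >= 0"
            )

    @property
    def score(self) -> int:
        """Observer-1 burn score."""
        return compute_score(self.grades_obs1)


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts: predicted deep/superficial vs actually deep/healed.

    a: predicted deep, actually deep; b: predicted deep, healed;
    c: predicted superficial, actually deep; d: predicted superficial, healed.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise CohortValidationError(f"confusion count {name} < 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ConfusionTable":
        """Table with the positive class relabelled on both axes.

        Exchanges PPV with NPV and sensitivity with specificity while
        leaving the agreement unchanged.
        """
        return ConfusionTable(a=self.d, b=self.c, c=self.b, d=self.a)


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its numerator/denominator and 95% CI."""

    estimate: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int

    def percent(self, decimals: int = 0) -> str:
        return round_percent(self.estimate, decimals)


@dataclass(frozen=True)
class DiagnosticStats:
    """Point estimates and 95% CIs for a confusion table.

    Metrics whose denominator is zero are ``None`` (absent), never 0.
    """

    ppv: Optional[ProportionEstimate]
    npv: Optional[ProportionEstimate]
    sensitivity: Optional[ProportionEstimate]
    specificity: Optional[ProportionEstimate]
    agreement: ProportionEstimate
    ci_method: str = "wilson"


def round_percent(p: float, decimals: int = 0) -> str:
    """Format a proportion as a percent string, round-half-up.

    ``round_percent(9/17)`` is ``"53%"``; one-decimal mode gives
    ``round_percent(171/461, 1) == "37.1%"``.
    """
    q = Decimal(1).scaleb(-decimals)
    val = (Decimal(repr(p)) * 100).quantize(q, rounding=ROUND_HALF_UP)
    return f"{val}%"


def is_actually_deep(
    record: WoundRecord, rule: DeepOutcomeRule = "grafted_or_refused"
) -> bool:
    """Reference-standard depth of a wound under the chosen rule."""
    if rule == "grafted_only":
        return record.outcome is Outcome.GRAFTED
    if rule == "grafted_or_refused":
        return record.outcome in (Outcome.GRAFTED, Outcome.DEEP_REFUSED_GRAFT)
    raise CohortValidationError(f"unknown deep_outcome_rule {rule!r}")


def _select_records(
    records: Sequence[WoundRecord], observer: ObserverMode
) -> list[WoundRecord]:
    if observer == "obs1":
        return list(records)
    if observer == "consensus":
        return [
            r
            for r in records
            if r.grades_obs2 is not None
            and r.grades_obs2.as_dict() == r.grades_obs1.as_dict()
        ]
    raise CohortValidationError(f"unknown observer mode {observer!r}")


def build_confusion(
    records: Sequence[WoundRecord],
    threshold: int = DEFAULT_THRESHOLD,
    deep_outcome_rule: DeepOutcomeRule = "grafted_or_refused",
    observer: ObserverMode = "obs1",
) -> ConfusionTable:
    """Count predicted-deep (score > threshold) vs actual depth.

    ``deep_outcome_rule`` chooses the reference standard: grafted wounds
    only, or grafted plus the deep-but-graft-refused course (default).
    """
    selected = _select_records(records, observer)
    if not selected:
        raise EmptyCohortError("empty cohort: no records to evaluate")
    a = b = c = d = 0
    for r in selected:
        predicted_deep = (
            predict_management(r.score, threshold)
            is ManagementPrediction.GRAFT_CANDIDATE
        )
        deep = is_actually_deep(r, deep_outcome_rule)
        if predicted_deep and deep:
            a += 1
        elif predicted_deep:
            b += 1
        elif deep:
            c += 1
        else:
            d += 1
    return ConfusionTable(a, b, c, d)


def _proportion(
    numer: int, denom: int, ci_method: CIMethod
) -> Optional[ProportionEstimate]:
    if denom == 0:
        return None
    method = {"wilson": "wilson", "exact": "beta"}[ci_method]
    lo, hi = proportion_confint(numer, denom, alpha=0.05, method=method)
    return ProportionEstimate(
        estimate=numer / denom,
        ci_low=float(lo),
        ci_high=float(hi),
        numerator=numer,
        denominator=denom,
    )


def diagnostic_stats(
    table: ConfusionTable, ci_method: CIMethod = "wilson"
) -> DiagnosticStats:
    """PPV, NPV, sensitivity, specificity and agreement with 95% CIs.

    PPV = a/(a+b), NPV = d/(c+d), sensitivity = a/(a+c),
    specificity = d/(b+d), agreement = (a+d)/total. Wilson intervals by
    default; ``exact`` selects Clopper-Pearson tail inversion.
    """
    if ci_method not in ("wilson", "exact"):
        raise CohortValidationError(f"unknown ci_method {ci_method!r}")
    if table.total == 0:
        raise EmptyCohortError("all-zero confusion table")
    return DiagnosticStats(
        ppv=_proportion(table.a, table.a + table.b, ci_method),
        npv=_proportion(table.d, table.c + table.d, ci_method),
        sensitivity=_proportion(table.a, table.a + table.c, ci_method),
        specificity=_proportion(table.d, table.b + table.d, ci_method),
        agreement=_proportion(table.a + table.d, table.total, ci_method),
        ci_method=ci_method,
    )


def threshold_sweep(
    records: Sequence[WoundRecord],
    deep_outcome_rule: DeepOutcomeRule = "grafted_or_refused",
    ci_method: CIMethod = "wilson",
    observer: ObserverMode = "obs1",
) -> pd.DataFrame:
    """Diagnostic statistics at every threshold 0-6, one row per threshold."""
    rows = []
    for t in range(0, 7):
        table = build_confusion(
            records, threshold=t, deep_outcome_rule=deep_outcome_rule,
            observer=observer,
        )
        stats = diagnostic_stats(table, ci_method=ci_method)
        row: dict[str, object] = {
            "threshold": t,
            "a": table.a,
            "b": table.b,
            "c": table.c,
            "d": table.d,
        }
        for name in ("ppv", "npv", "sensitivity", "specificity", "agreement"):
            est: Optional[ProportionEstimate] = getattr(stats, name)
            row[name] = est.estimate if est else np.nan
            row[f"{name}_ci_low"] = est.ci_low if est else np.nan
            row[f"{name}_ci_high"] = est.ci_high if est else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("threshold")


def cohort_summary(
    records: Sequence[WoundRecord],
    admissions_total: Optional[int] = None,
) -> dict[str, object]:
    """Descriptive counts: per score, depth class, outcome; graft timing.

    With ``admissions_total`` given, also the proportion of hand-injury
    patients among admissions (one-decimal percent, round-half-up).
    """
    if not records:
        raise EmptyCohortError("empty cohort: nothing to summarise")
    patients = {r.patient_id for r in records}
    score_counts = {s: 0 for s in range(7)}
    depth_counts = {cls: 0 for cls in DepthClass}
    outcome_counts = {out: 0 for out in Outcome}
    for r in records:
        score_counts[r.score] += 1
        depth_counts[classify_depth(r.score)] += 1
        outcome_counts[r.outcome] += 1
    graft_days = [r.days_to_graft for r in records if r.days_to_graft is not None]
    summary: dict[str, object] = {
        "n_wounds": len(records),
        "n_patients": len(patients),
        "score_counts": score_counts,
        "depth_class_counts": {c.value: n for c, n in depth_counts.items()},
        "outcome_counts": {o.value: n for o, n in outcome_counts.items()},
        "n_grafted": outcome_counts[Outcome.GRAFTED],
        "median_days_to_graft": median(graft_days) if graft_days else None,
    }
    if admissions_total is not None:
        if admissions_total < len(patients):
            raise CohortValidationError(
                f"admissions_total {admissions_total} < number of patients "
                f"{len(patients)}"
            )
        frac = len(patients) / admissions_total
        summary["hand_injury_fraction"] = frac
        summary["hand_injury_percent"] = round_percent(frac, 1)
    return summary


def cohen_kappa(table: np.ndarray) -> Optional[float]:
    """Cohen's kappa from a square rater-1 x rater-2 contingency table.

    kappa = (p_o - p_e) / (1 - p_e) with p_e the chance agreement from the
    marginal frequencies. Returns ``None`` when p_e = 1 (both raters
    constant), where kappa is undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise CohortValidationError("kappa needs a square contingency table")
    n = t.sum()
    if n == 0:
        raise CohortValidationError("kappa needs a non-empty table")
    p_o = np.trace(t) / n
    p_e = float((t.sum(axis=1) / n) @ (t.sum(axis=0) / n))
    if np.isclose(p_e, 1.0):
        return None
    return float((p_o - p_e) / (1.0 - p_e))


def _pair_table(
    pairs: list[tuple[int, int]], n_levels: int
) -> np.ndarray:
    table = np.zeros((n_levels, n_levels), dtype=int)
    for g1, g2 in pairs:
        table[g1, g2] += 1
    return table


def interobserver_agreement(
    records: Sequence[WoundRecord],
) -> dict[str, object]:
    """Two-observer agreement per item and on the total score.

    Records without observer-2 grades are excluded (their count is
    reported). For each item: observed percent agreement and Cohen's
    kappa from the 2-observer contingency table; kappa is absent when the
    marginals are degenerate.
    """
    dual = [r for r in records if r.grades_obs2 is not None]
    excluded = len(records) - len(dual)
    if len(dual) < 2:
        raise EmptyCohortError(
            "inter-observer agreement needs >= 2 dual-graded records "
            f"(found {len(dual)})"
        )
    from .score import ITEM_RANGES  # local to avoid polluting module top

    result: dict[str, object] = {"n_dual": len(dual), "n_excluded": excluded}
    items: dict[str, Mapping[str, object]] = {}
    for item, (lo, hi) in ITEM_RANGES.items():
        pairs = [
            (getattr(r.grades_obs1, item), getattr(r.grades_obs2, item))
            for r in dual
        ]
        table = _pair_table(pairs, hi - lo + 1)
        p_o = float(np.trace(table) / table.sum())
        items[item] = {
            "percent_agreement": p_o,
            "kappa": cohen_kappa(table),
            "table": table,
        }
    result["items"] = items
    score_pairs = [
        (compute_score(r.grades_obs1), compute_score(r.grades_obs2))  # type: ignore[arg-type]
        for r in dual
    ]
    score_table = _pair_table(score_pairs, 7)
    result["total_score"] = {
        "percent_agreement": float(np.trace(score_table) / score_table.sum()),
        "kappa": cohen_kappa(score_table),
        "table": score_table,
    }
    return result
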