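"""The additive OCT burn score for pediatric hand burns.

Four en-face/cross-sectional OCT features are graded per wound and summed
into a 0-6 score:

====================================  =====  ==========================
item                                  range  meaning of the maximum
====================================  =====  ==========================
surface irregularity                  0-1    irregular wound surface
loss of epidermis                     0-1    dark epidermal band absent
dermal pattern (site-specific)        0-2    pattern completely lost
perfusion / microvascular network     0-2    network truncated/absent
====================================  =====  ==========================

The dermal item is read as *skin lines* on glabrous skin (palm) and as the
*papillary spot pattern* on hair-bearing skin (dorsum); a wound carries
exactly one of the two, selected by skin type. Score 0 is healthy skin and
6 a deep burn with destroyed dermal structure and absent papillary plexus.

Score bands: 0-2 healthy skin or epidermal injury, 3-4 partial-thickness
burn expected to heal spontaneously, 5-6 full-thickness burn needing
grafting. The management threshold is 4, inclusive on the healing side.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from numbers import Integral
from typing import Mapping

from .errors import GradeRangeError, IncompleteGradingError, InvalidScoreError

__all__ = [
    "SkinType",
    "FeatureGrades",
    "DepthClass",
    "ManagementPrediction",
    "ITEM_RANGES",
    "ITEM_NAMES",
    "DEFAULT_THRESHOLD",
    "MAX_SCORE",
    "validate_grades",
    "compute_score",
    "classify_depth",
    "predict_management",
    "all_grade_combinations",
]

#: Inclusive (min, max) grade range per score item.
ITEM_RANGES: dict[str, tuple[int, int]] = {
    "surface_irregularity": (0, 1),
    "epidermal_loss": (0, 1),
    "dermal_pattern": (0, 2),
    "vascular_network": (0, 2),
}

ITEM_NAMES: tuple[str, ...] = tuple(ITEM_RANGES)

MAX_SCORE: int = 6

#: Scores <= threshold predict spontaneous healing ("4 or less healed").
DEFAULT_THRESHOLD: int = 4


class SkinType(enum.Enum):
    """Skin site of the graded wound; selects the dermal-pattern item."""

    GLABROUS = "glabrous"  # palms and soles: skin lines
    HAIR_BEARING = "hair_bearing"  # dorsum of the hand: papillary spots


class DepthClass(enum.Enum):
    """Burn-depth band implied by the total score."""

    HEALTHY_OR_EPIDERMAL = "healthy_or_epidermal"  # scores 0-2
    PARTIAL_SPONTANEOUS = "partial_spontaneous"  # scores 3-4
    DEEP_GRAFT = "deep_graft"  # scores 5-6


class ManagementPrediction(enum.Enum):
    """Management implied by the score relative to the threshold."""

    SPONTANEOUS_HEALING = "spontaneous_healing"
    GRAFT_CANDIDATE = "graft_candidate"


def _check_item(item: str, value: object) -> int:
    lo, hi = ITEM_RANGES[item]
    # bool is Integral but a grade of True/False is almost certainly a bug
    if isinstance(value, bool) or not isinstance(value, Integral):
        raise GradeRangeError(
            f"grade out of range: item {item!r} must be an integer in "
            f"[{lo}, {hi}], got {value!r} (fractional or averaged grades "
            f"are not accepted)"
        )
    v = int(value)
    if not lo <= v <= hi:
        raise GradeRangeError(
            f"grade out of range: item {item!r} value {v} outside [{lo}, {hi}]"
        )
    return v


@dataclass(frozen=True)
class FeatureGrades:
    """Validated per-item grades for one wound.

    ``dermal_pattern`` means skin lines on glabrous skin and papillary
    pattern on hair-bearing skin; ``skin_type`` records which reading
    applies.
    """

    surface_irregularity: int
    epidermal_loss: int
    dermal_pattern: int
    vascular_network: int
    skin_type: SkinType

    def __post_init__(self) -> None:
        if not isinstance(self.skin_type, SkinType):
            raise GradeRangeError(
                f"skin_type must be a SkinType, got {self.skin_type!r}"
            )
        for item in ITEM_NAMES:
            object.__setattr__(self, item, _check_item(item, getattr(self, item)))

    def as_dict(self) -> dict[str, int]:
        """Item name -> grade mapping (skin type excluded)."""
        return {item: getattr(self, item) for item in ITEM_NAMES}


def validate_grades(
    raw: Mapping[str, object], skin_type: SkinType
) -> FeatureGrades:
    """Validate a raw item-name -> value mapping into :class:`FeatureGrades`.

    All four items must be present; values must be integers within the
    item's range. Values are never clamped or rounded.

    Raises
    ------
    IncompleteGradingError
        If any item key is missing.
    GradeRangeError
        If any value is non-integer or out of range.
    """
    missing = [item for item in ITEM_NAMES if item not in raw]
    if missing:
        raise IncompleteGradingError(
            f"incomplete grading: missing item(s) {', '.join(missing)}"
        )
    return FeatureGrades(
        surface_irregularity=raw["surface_irregularity"],  # type: ignore[arg-type]
        epidermal_loss=raw["epidermal_loss"],  # type: ignore[arg-type]
        dermal_pattern=raw["dermal_pattern"],  # type: ignore[arg-type]
        vascular_network=raw["vascular_network"],  # type: ignore[arg-type]
        skin_type=skin_type,
    )


def compute_score(grades: FeatureGrades) -> int:
    """Additive burn score: the sum of the four item grades (0-6)."""
    return (
        grades.surface_irregularity
        + grades.epidermal_loss
        + grades.dermal_pattern
        + grades.vascular_network
    )


def _check_score(score: object) -> int:
    if isinstance(score, bool) or not isinstance(score, Integral):
        raise InvalidScoreError(f"invalid score: {score!r} is not an integer")
    s = int(score)
    if not 0 <= s <= MAX_SCORE:
        raise InvalidScoreError(f"invalid score: {s} outside [0, {MAX_SCORE}]")
    return s


def classify_depth(score: int) -> DepthClass:
    """Map a 0-6 score onto its depth band.

    0-2 healthy skin or epidermal injury; 3-4 partial-thickness burn with
    spontaneous healing; 5-6 full-thickness burn needing grafting.
    """
    s = _check_score(score)
    if s <= 2:
        return DepthClass.HEALTHY_OR_EPIDERMAL
    if s <= 4:
        return DepthClass.PARTIAL_SPONTANEOUS
    return DepthClass.DEEP_GRAFT


def predict_management(
    score: int, threshold: int = DEFAULT_THRESHOLD
) -> ManagementPrediction:
    """Predict management from the score: heal if ``score <= threshold``.

    The default threshold of 4 encodes the observed rule that wounds
    scoring 4 or less healed spontaneously under dressing while scores of
    5 or more marked deeper wounds.
    """
    s = _check_score(score)
    if isinstance(threshold, bool) or not isinstance(threshold, Integral):
        raise InvalidScoreError(f"invalid threshold: {threshold!r}")
    t = int(threshold)
    if not 0 <= t <= MAX_SCORE:
        raise InvalidScoreError(f"invalid threshold: {t} outside [0, {MAX_SCORE}]")
    if s <= t:
        return ManagementPrediction.SPONTANEOUS_HEALING
    return ManagementPrediction.GRAFT_CANDIDATE


def all_grade_combinations(
    skin_type: SkinType = SkinType.GLABROUS,
) -> list[FeatureGrades]:
    """Every valid grade combination (2*2*3*3 = 36) for one skin type."""
    ranges = [range(lo, hi + 1) for lo, hi in ITEM_RANGES.values()]
    return [
        FeatureGrades(s, e, d, v, skin_type)
        for s, e, d, v in itertools.product(*ranges)
    ]
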