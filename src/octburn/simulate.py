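"""Synthetic cohorts with the statistical structure of the study cohort.

The generator draws, per wound: a total score from the printed score
distribution (counts 2/15/29/12/5 for scores 2-6), a grade combination
uniformly among all combinations summing to that score, a latent
deep/superficial status from a score-conditional probability, a grafting
decision for deep wounds, a noisy second-observer grading, and a clinical
depth judgment. The defaults emulate the study conditions; the
score-conditional outcome probabilities are calibration choices (the
study reports outcomes only at the band level) and are configuration,
not constants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import ClinicalJudgment, Outcome, WoundRecord
from .errors import ConfigError
from .score import ITEM_RANGES, FeatureGrades, SkinType, compute_score

__all__ = ["CohortConfig", "sample_grades_for_score", "generate_cohort"]

#: Printed per-score wound counts for scores 0..6 (none observed below 2).
STUDY_SCORE_COUNTS: tuple[int, ...] = (0, 0, 2, 15, 29, 12, 5)


def _default_p_deep() -> dict[int, float]:
    # Calibrated so band-level predictive values land near the reported
    # ones: essentially no deep wounds at <=3, rare at 4, frequent at 5-6.
    return {0: 0.0, 1: 0.0, 2: 0.0, 3: 0.0, 4: 0.03, 5: 0.5, 6: 0.9}


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic wound cohort."""

    n_wounds: int = 63
    score_weights: tuple[float, ...] = STUDY_SCORE_COUNTS
    p_deep_given_score: dict[int, float] = field(default_factory=_default_p_deep)
    p_graft_given_deep: float = 0.9
    skin_type_mix: float = 0.5  # probability of glabrous
    observer_flip_prob: float = 0.1  # per-item one-step deviation of obs2
    # bedside judgment tends to over-call depth
    p_judged_deep_given_deep: float = 0.95
    p_judged_deep_given_superficial: float = 0.17
    median_days_to_graft: int = 9
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if self.n_wounds < 1:
            raise ConfigError("n_wounds must be >= 1")
        if len(self.score_weights) != 7:
            raise ConfigError("score_weights must have 7 entries (scores 0-6)")
        if any(w < 0 for w in self.score_weights):
            raise ConfigError("score_weights must be nonnegative")
        if sum(self.score_weights) <= 0:
            raise ConfigError("score_weights must sum to > 0")
        if sorted(self.p_deep_given_score) != list(range(7)):
            raise ConfigError("p_deep_given_score must map every score 0-6")
        probs = list(self.p_deep_given_score.values()) + [
            self.p_graft_given_deep,
            self.skin_type_mix,
            self.observer_flip_prob,
            self.p_judged_deep_given_deep,
            self.p_judged_deep_given_superficial,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if self.median_days_to_graft < 1:
            raise ConfigError("median_days_to_graft must be >= 1")
        return self


def _combinations_by_score() -> dict[int, list[tuple[int, int, int, int]]]:
    ranges = [range(lo, hi + 1) for lo, hi in ITEM_RANGES.values()]
    by_score: dict[int, list[tuple[int, int, int, int]]] = {
        s: [] for s in range(7)
    }
    for combo in itertools.product(*ranges):
        by_score[sum(combo)].append(combo)
    return by_score


_COMBOS_BY_SCORE = _combinations_by_score()


def sample_grades_for_score(
    target_score: int, skin_type: SkinType, rng: np.random.Generator
) -> FeatureGrades:
    """Draw grades uniformly among all combinations summing to the target.

    Every score 0-6 is attainable; scores 0 and 6 have a unique
    combination ((0,0,0,0) and (1,1,2,2)).
    """
    if not 0 <= target_score <= 6:
        raise ConfigError(f"target_score {target_score} outside [0, 6]")
    combos = _COMBOS_BY_SCORE[target_score]
    s, e, d, v = combos[rng.integers(len(combos))]
    return FeatureGrades(s, e, d, v, skin_type)


def _perturb_item(value: int, lo: int, hi: int, rng: np.random.Generator,
                  flip_prob: float) -> int:
    # symmetric one-step perturbation, clipped to the item's range
    if rng.random() < flip_prob:
        step = 1 if rng.random() < 0.5 else -1
        return int(np.clip(value + step, lo, hi))
    return value


def _observer2_grades(
    grades: FeatureGrades, rng: np.random.Generator, flip_prob: float
) -> FeatureGrades:
    values = {}
    for item, (lo, hi) in ITEM_RANGES.items():
        values[item] = _perturb_item(getattr(grades, item), lo, hi, rng, flip_prob)
    return FeatureGrades(skin_type=grades.skin_type, **values)


def generate_cohort(config: Optional[CohortConfig] = None) -> list[WoundRecord]:
    """Generate a reproducible synthetic cohort of wound records.

    One child stream per record (spawned from the cohort seed in record
    order) makes the draws stable under partial regeneration.
    """
    config = (config or CohortConfig()).validate()
    weights = np.asarray(config.score_weights, dtype=float)
    weights = weights / weights.sum()
    streams = np.random.SeedSequence(config.seed).spawn(config.n_wounds)
    records: list[WoundRecord] = []
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        skin = SkinType.GLABROUS if rng.random() < config.skin_type_mix \
            else SkinType.HAIR_BEARING
        target = int(rng.choice(7, p=weights))
        grades1 = sample_grades_for_score(target, skin, rng)
        assert compute_score(grades1) == target
        grades2 = _observer2_grades(grades1, rng, config.observer_flip_prob)
        deep = rng.random() < config.p_deep_given_score[target]
        if deep:
            grafted = rng.random() < config.p_graft_given_deep
            outcome = Outcome.GRAFTED if grafted else Outcome.DEEP_REFUSED_GRAFT
            p_judged = config.p_judged_deep_given_deep
        else:
            outcome = Outcome.HEALED_SPONTANEOUSLY
            p_judged = config.p_judged_deep_given_superficial
        judgment = (
            ClinicalJudgment.DEEP
            if rng.random() < p_judged
            else ClinicalJudgment.SUPERFICIAL
        )
        days = None
        if outcome is Outcome.GRAFTED:
            # Poisson with the configured median; >= 1 day post-injury
            days = max(1, int(rng.poisson(config.median_days_to_graft)))
        records.append(
            WoundRecord(
                wound_id=f"W{i:05d}",
                patient_id=f"P{i:05d}",
                skin_type=skin,
                grades_obs1=grades1,
                grades_obs2=grades2,
                clinical_judgment=judgment,
                outcome=outcome,
                days_to_graft=days,
            )
        )
    return records


def implied_band_probabilities(config: CohortConfig) -> dict[str, float]:
    """Config-implied reference probabilities at the default threshold.

    ``p_deep_given_high`` is the weighted mean of P(deep | score) over
    scores 5-6 (the expected PPV for depth of a score >= 5 call) and
    ``p_superficial_given_low`` its complement over scores <= 4 (the
    expected predictive value of a score <= 4 call for healing).
    """
    w = np.asarray(config.score_weights, dtype=float)
    p = np.array([config.p_deep_given_score[s] for s in range(7)])
    low, high = w[:5], w[5:]
    p_low, p_high = p[:5], p[5:]
    return {
        "p_deep_given_high": float((high * p_high).sum() / high.sum()),
        "p_superficial_given_low": float(1.0 - (low * p_low).sum() / low.sum()),
        "p_grafted_given_high": float(
            (high * p_high).sum() / high.sum() * config.p_graft_given_deep
        ),
    }
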