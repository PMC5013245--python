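"""Questionnaire scoring for the KNW screening battery.

The baseline screening of the Kanker Nazorg Wijzer (KNW, "Cancer Aftercare
Guide") collects a set of validated patient-reported-outcome instruments and
lifestyle questions.  This module turns raw item responses into the subscale
scores and behavioural conditions consumed by the traffic-light referral
engine:

* CIS subjective fatigue — 8 items, 7-point Likert, sum 8–56 (higher = worse).
* HADS anxiety / depression — 7 items each, 0–3, sums 0–21.
* MAC negative adjustment to cancer — 16 items, 1–4, sum 16–64.
* SSL-D social-support discrepancy — 6 items, 1–4, sum 6–24.
* Work-related needs (extended CaSUN) — 4 items, 0–5, total 0–20.
* Physical activity — weekly moderate-to-vigorous minutes and number of days
  with ≥30 min moderate activity, compared against the two public-health
  guideline conditions (≥150 min/week; ≥30 min on ≥5 days/week).
* Diet — five food-group quantities compared against the WCRF/ACS-style
  recommendations (≥200 g vegetables/day, ≥2 pieces of fruit/day, ≥2 fish
  servings/week, ≥15 g whole grains/day, ≥4 starch servings/day).
* Smoking status — never / quit before diagnosis / quit after diagnosis /
  current.

All scores are plain sums and all lifestyle thresholds are boundary-inclusive.
Item-level input is optional: a :class:`ScreeningProfile` can be built
directly from subscale scores, which is what the referral engine consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

__all__ = [
    "ItemValidationError",
    "CISFatigueItems",
    "HADSItems",
    "MACNegativeItems",
    "SSLDItems",
    "WorkNeedsItems",
    "PAProfile",
    "DietProfile",
    "SmokingStatus",
    "ScreeningProfile",
    "DietThresholds",
    "score_cis_fatigue",
    "score_hads",
    "score_mac_negative",
    "score_ssl_discrepancy",
    "score_work_needs",
    "evaluate_pa_conditions",
    "evaluate_diet_conditions",
]


class ItemValidationError(ValueError):
    """Raised when item responses or scores fall outside their instrument range."""


def _check_items(name: str, items: Sequence[int], n: int, lo: int, hi: int) -> None:
    if len(items) != n:
        raise ItemValidationError(
            f"{name}: expected {n} items, got {len(items)}"
        )
    for i, v in enumerate(items):
        if not isinstance(v, (int,)) or isinstance(v, bool):
            raise ItemValidationError(f"{name}: item {i} is not an integer ({v!r})")
        if not lo <= v <= hi:
            raise ItemValidationError(
                f"{name}: item {i} = {v} outside allowed range {lo}..{hi}"
            )


def _check_score(name: str, value: int, lo: int, hi: int) -> None:
    if isinstance(value, bool) or not isinstance(value, int):
        raise ItemValidationError(f"{name} must be an integer, got {value!r}")
    if not lo <= value <= hi:
        raise ItemValidationError(f"{name} = {value} outside allowed range {lo}..{hi}")


@dataclass(frozen=True)
class CISFatigueItems:
    """Checklist Individual Strength, subjective-fatigue subscale (8 items, 1–7)."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        _check_items("CIS fatigue", self.items, 8, 1, 7)


@dataclass(frozen=True)
class HADSItems:
    """Hospital Anxiety and Depression Scale items (7 + 7 items, each 0–3)."""

    anxiety_items: tuple[int, ...]
    depression_items: tuple[int, ...]

    def __post_init__(self) -> None:
        _check_items("HADS-A", self.anxiety_items, 7, 0, 3)
        _check_items("HADS-D", self.depression_items, 7, 0, 3)


@dataclass(frozen=True)
class MACNegativeItems:
    """Mental Adjustment to Cancer, negative-adjustment dimension (16 items, 1–4)."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        _check_items("MAC negative adjustment", self.items, 16, 1, 4)


@dataclass(frozen=True)
class SSLDItems:
    """Social Support List, discrepancy subscale (6 items, 1–4)."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        _check_items("SSL-D", self.items, 6, 1, 4)


@dataclass(frozen=True)
class WorkNeedsItems:
    """Extended-CaSUN work-related needs: four items, each 0–5."""

    need_adjust_job: int
    need_financial: int
    need_support_return: int
    need_legal: int

    def __post_init__(self) -> None:
        _check_items(
            "work needs",
            (
                self.need_adjust_job,
                self.need_financial,
                self.need_support_return,
                self.need_legal,
            ),
            4,
            0,
            5,
        )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.need_adjust_job,
            self.need_financial,
            self.need_support_return,
            self.need_legal,
        )


@dataclass(frozen=True)
class PAProfile:
    """Derived physical-activity quantities (SQUASH-style weekly summary)."""

    weekly_mvpa_minutes: float
    days_with_30min_moderate: int

    def __post_init__(self) -> None:
        if self.weekly_mvpa_minutes < 0:
            raise ItemValidationError(
                f"weekly_mvpa_minutes must be >= 0, got {self.weekly_mvpa_minutes}"
            )
        if isinstance(self.days_with_30min_moderate, bool) or not isinstance(
            self.days_with_30min_moderate, int
        ):
            raise ItemValidationError("days_with_30min_moderate must be an integer")
        if not 0 <= self.days_with_30min_moderate <= 7:
            raise ItemValidationError(
                f"days_with_30min_moderate = {self.days_with_30min_moderate} "
                "outside 0..7"
            )


@dataclass(frozen=True)
class DietProfile:
    """Daily/weekly food-group quantities for the five dietary conditions."""

    vegetables_g_per_day: float
    fruit_pieces_per_day: float
    fish_servings_per_week: float
    wholegrain_g_per_day: float
    starch_servings_per_day: float

    def __post_init__(self) -> None:
        for name in (
            "vegetables_g_per_day",
            "fruit_pieces_per_day",
            "fish_servings_per_week",
            "wholegrain_g_per_day",
            "starch_servings_per_day",
        ):
            if getattr(self, name) < 0:
                raise ItemValidationError(f"{name} must be >= 0")


class SmokingStatus(str, Enum):
    NEVER = "never"
    FORMER_QUIT_BEFORE_DIAGNOSIS = "former_quit_before_diagnosis"
    FORMER_QUIT_AFTER_DIAGNOSIS = "former_quit_after_diagnosis"
    CURRENT = "current"


@dataclass(frozen=True)
class DietThresholds:
    """Boundary-inclusive cut-offs of the five dietary recommendations."""

    vegetables_g_per_day: float = 200.0
    fruit_pieces_per_day: float = 2.0
    fish_servings_per_week: float = 2.0
    wholegrain_g_per_day: float = 15.0
    starch_servings_per_day: float = 4.0


def score_cis_fatigue(items: CISFatigueItems) -> int:
    """Sum of the 8 subjective-fatigue items; range 8–56."""
    return sum(items.items)


def score_hads(items: HADSItems) -> tuple[int, int]:
    """(HADS-A, HADS-D) subscale sums, each 0–21."""
    return sum(items.anxiety_items), sum(items.depression_items)


def score_mac_negative(items: MACNegativeItems) -> int:
    """Sum of the 16 negative-adjustment items; range 16–64."""
    return sum(items.items)


def score_ssl_discrepancy(items: SSLDItems) -> int:
    """Sum of the 6 support-discrepancy items; range 6–24."""
    return sum(items.items)


def score_work_needs(items: WorkNeedsItems) -> tuple[int, bool]:
    """(total, no_needs): total of the four work-needs items and whether all are 0."""
    total = sum(items.as_tuple())
    return total, all(v == 0 for v in items.as_tuple())


def evaluate_pa_conditions(
    pa: PAProfile,
    weekly_minutes_threshold: float = 150.0,
    days_threshold: int = 5,
) -> tuple[bool, bool]:
    """Evaluate the two physical-activity guideline conditions.

    Returns ``(meets_weekly_150, meets_5x30)``; both comparisons are
    boundary-inclusive.
    """
    return (
        pa.weekly_mvpa_minutes >= weekly_minutes_threshold,
        pa.days_with_30min_moderate >= days_threshold,
    )


def evaluate_diet_conditions(
    diet: DietProfile, thresholds: DietThresholds | None = None
) -> tuple[int, tuple[bool, bool, bool, bool, bool]]:
    """Evaluate the five dietary recommendations.

    Returns ``(met_count, flags)`` where flags are in the order vegetables,
    fruit, fish, whole grains, starches and every comparison is
    boundary-inclusive (e.g. exactly 200 g vegetables meets the condition).
    """
    t = thresholds or DietThresholds()
    flags = (
        diet.vegetables_g_per_day >= t.vegetables_g_per_day,
        diet.fruit_pieces_per_day >= t.fruit_pieces_per_day,
        diet.fish_servings_per_week >= t.fish_servings_per_week,
        diet.wholegrain_g_per_day >= t.wholegrain_g_per_day,
        diet.starch_servings_per_day >= t.starch_servings_per_day,
    )
    return sum(flags), flags


@dataclass(frozen=True)
class ScreeningProfile:
    """One participant's scored screening battery.

    This is the input of the referral engine.  Scores may come from
    :func:`score_cis_fatigue` and friends or be supplied directly (the
    deployed system stores subscale scores, not items).

    ``cis_fatigue`` accepts 1–56: item-level scoring always yields 8–56, but
    externally supplied scores in the instrument's conventionally printed
    1–56 range are not rejected.
    """

    cis_fatigue: int
    hads_a: int
    hads_d: int
    mac_neg: int
    ssl_d: int
    casun_relationship_needs: bool
    work_needs_total: int
    work_no_needs: bool
    pa: PAProfile
    diet: DietProfile
    smoking: SmokingStatus

    def __post_init__(self) -> None:
        _check_score("cis_fatigue", self.cis_fatigue, 1, 56)
        _check_score("hads_a", self.hads_a, 0, 21)
        _check_score("hads_d", self.hads_d, 0, 21)
        _check_score("mac_neg", self.mac_neg, 16, 64)
        _check_score("ssl_d", self.ssl_d, 6, 24)
        _check_score("work_needs_total", self.work_needs_total, 0, 20)
        if self.work_no_needs and self.work_needs_total != 0:
            raise ItemValidationError(
                "work_no_needs is true but work_needs_total = "
                f"{self.work_needs_total} (must be 0)"
            )
        if not isinstance(self.smoking, SmokingStatus):
            raise ItemValidationError(f"invalid smoking status {self.smoking!r}")
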