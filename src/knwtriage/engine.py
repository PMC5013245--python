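"""Traffic-light Module Referral Advice (MRA) engine.

Maps a scored :class:`~knwtriage.instruments.ScreeningProfile` to a
green / orange / red advice color for each of the seven referable topics of
the KNW intervention (fatigue, return to work, mood, relationships, physical
activity, diet, smoking).  Green means no or minor complaints — following the
corresponding self-management module is not a priority; orange flags elevated
but not severe complaints or partial adherence to lifestyle recommendations;
red flags severe complaints or no adherence, with a strong recommendation to
follow the module.  The eighth KNW module (residual symptoms) carries no
referral advice.

Two situations the published cut-off table leaves open are resolved
explicitly and conservatively (both documented in the package methods note):

* work-needs totals of 1–2 sit between "no needs" (green) and the 3–12 orange
  band — classified green, since green covers "no or minor" needs;
* an SSL-D score ≥ 8 without CaSUN relationship needs — classified green,
  since both the orange and red rows require the needs flag.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .instruments import (
    DietThresholds,
    ItemValidationError,
    ScreeningProfile,
    SmokingStatus,
    evaluate_diet_conditions,
    evaluate_pa_conditions,
)

__all__ = [
    "Topic",
    "TOPICS",
    "MODULES",
    "RESIDUAL_MODULE",
    "MRAColor",
    "MRACutoffs",
    "MRAProfile",
    "classify_fatigue",
    "classify_return_to_work",
    "classify_mood",
    "classify_relationships",
    "classify_physical_activity",
    "classify_diet",
    "classify_smoking",
    "classify_all",
]


class Topic(str, Enum):
    """The seven topics that can receive a referral advice."""

    FATIGUE = "fatigue"
    RETURN_TO_WORK = "return_to_work"
    MOOD = "mood"
    RELATIONSHIPS = "relationships"
    PHYSICAL_ACTIVITY = "physical_activity"
    DIET = "diet"
    SMOKING = "smoking"


TOPICS: tuple[Topic, ...] = tuple(Topic)

#: Module that exists in the intervention but has no referral advice.
RESIDUAL_MODULE = "residual_symptoms"

#: The eight KNW modules (seven referable topics + residual symptoms).
MODULES: tuple[str, ...] = tuple(t.value for t in TOPICS) + (RESIDUAL_MODULE,)


class MRAColor(str, Enum):
    """Traffic-light advice color, ordered green < orange < red for reports."""

    GREEN = "green"
    ORANGE = "orange"
    RED = "red"

    @property
    def severity(self) -> int:
        return {"green": 0, "orange": 1, "red": 2}[self.value]

    def __lt__(self, other: "MRAColor") -> bool:  # type: ignore[override]
        return self.severity < other.severity


@dataclass(frozen=True)
class MRACutoffs:
    """Every classification threshold, overridable via a JSON config file.

    Defaults are the deployed KNW cut-offs.  ``*_red_min`` style fields are
    inclusive lower bounds of the red band; all comparisons elsewhere are
    boundary-inclusive as printed.
    """

    fatigue_orange_min: int = 27          # green below; 27..35 orange
    fatigue_red_min: int = 36             # >35 red
    work_orange_min: int = 3              # totals 3..12 orange (1-2 -> green)
    work_red_min: int = 13                # >=13 red
    hads_elevated_min: int = 8            # 8..15 elevated
    hads_severe_min: int = 16             # >15 severe (red)
    mac_elevated_min: int = 37            # >36 elevated
    ssl_green_max: int = 7                # <=7 green regardless of needs
    ssl_red_min: int = 10                 # >=10 & CaSUN needs -> red
    pa_weekly_minutes_min: float = 150.0
    pa_days_min: int = 5
    diet_green_min_conditions: int = 4    # >=4 of 5 -> green
    diet_red_max_conditions: int = 1      # <=1 of 5 -> red
    diet_thresholds: DietThresholds = field(default_factory=DietThresholds)

    @classmethod
    def from_json(cls, path: str | Path) -> "MRACutoffs":
        raw = json.loads(Path(path).read_text())
        diet = raw.pop("diet_thresholds", None)
        kwargs = dict(raw)
        if diet is not None:
            kwargs["diet_thresholds"] = DietThresholds(**diet)
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


_DEFAULT_CUTOFFS = MRACutoffs()


@dataclass(frozen=True)
class MRAProfile:
    """Per-topic advice colors for one participant."""

    colors: dict[Topic, MRAColor]

    def __post_init__(self) -> None:
        missing = [t for t in TOPICS if t not in self.colors]
        if missing:
            raise ValueError(f"MRAProfile missing topics: {missing}")
        extra = [t for t in self.colors if t not in TOPICS]
        if extra:
            raise ValueError(f"MRAProfile has unknown topics: {extra}")

    @property
    def n_red(self) -> int:
        return sum(1 for c in self.colors.values() if c is MRAColor.RED)

    @property
    def n_orange(self) -> int:
        return sum(1 for c in self.colors.values() if c is MRAColor.ORANGE)

    @property
    def n_referrals(self) -> int:
        """Number of topics with a red or orange advice (modules referred to)."""
        return self.n_red + self.n_orange

    def as_dict(self) -> dict[str, str]:
        return {t.value: self.colors[t].value for t in TOPICS}


def classify_fatigue(
    cis_fatigue: int, cutoffs: MRACutoffs = _DEFAULT_CUTOFFS
) -> MRAColor:
    """Fatigue advice from the CIS subjective-fatigue score (<27 / 27–35 / >35)."""
    if not 1 <= cis_fatigue <= 56:
        raise ItemValidationError(f"cis_fatigue = {cis_fatigue} outside 1..56")
    if cis_fatigue >= cutoffs.fatigue_red_min:
        return MRAColor.RED
    if cis_fatigue >= cutoffs.fatigue_orange_min:
        return MRAColor.ORANGE
    return MRAColor.GREEN


def classify_return_to_work(
    total: int, no_needs: bool, cutoffs: MRACutoffs = _DEFAULT_CUTOFFS
) -> MRAColor:
    """Return-to-work advice from the work-needs total (no needs / 3–12 / ≥13)."""
    if not 0 <= total <= 20:
        raise ItemValidationError(f"work needs total = {total} outside 0..20")
    if no_needs and total != 0:
        raise ItemValidationError(
            f"no_needs is true but work needs total = {total}"
        )
    if total >= cutoffs.work_red_min:
        return MRAColor.RED
    if total >= cutoffs.work_orange_min:
        return MRAColor.ORANGE
    # no needs, or minor needs (total 1-2) below the orange band
    return MRAColor.GREEN


def classify_mood(
    hads_a: int, hads_d: int, mac_neg: int, cutoffs: MRACutoffs = _DEFAULT_CUTOFFS
) -> MRAColor:
    """Mood advice from HADS-A, HADS-D and MAC negative adjustment.

    Red when either HADS subscale is severe (>15); otherwise orange when
    either subscale is elevated (8–15) or MAC negative adjustment exceeds 36;
    green when both subscales are below 8 and MAC is at most 36.
    """
    if not 0 <= hads_a <= 21:
        raise ItemValidationError(f"hads_a = {hads_a} outside 0..21")
    if not 0 <= hads_d <= 21:
        raise ItemValidationError(f"hads_d = {hads_d} outside 0..21")
    if not 16 <= mac_neg <= 64:
        raise ItemValidationError(f"mac_neg = {mac_neg} outside 16..64")
    if hads_a >= cutoffs.hads_severe_min or hads_d >= cutoffs.hads_severe_min:
        return MRAColor.RED
    if (
        hads_a >= cutoffs.hads_elevated_min
        or hads_d >= cutoffs.hads_elevated_min
        or mac_neg >= cutoffs.mac_elevated_min
    ):
        return MRAColor.ORANGE
    return MRAColor.GREEN


def classify_relationships(
    ssl_d: int, casun_needs: bool, cutoffs: MRACutoffs = _DEFAULT_CUTOFFS
) -> MRAColor:
    """Relationships advice from SSL-D and the CaSUN sexuality/fertility needs flag.

    Orange and red both require reported needs; a high support discrepancy
    without needs stays green.
    """
    if not 6 <= ssl_d <= 24:
        raise ItemValidationError(f"ssl_d = {ssl_d} outside 6..24")
    if ssl_d <= cutoffs.ssl_green_max or not casun_needs:
        return MRAColor.GREEN
    if ssl_d >= cutoffs.ssl_red_min:
        return MRAColor.RED
    return MRAColor.ORANGE


def classify_physical_activity(
    meets_weekly_150: bool, meets_5x30: bool
) -> MRAColor:
    """PA advice: both guideline conditions met → green, one → orange, none → red."""
    n = int(meets_weekly_150) + int(meets_5x30)
    return (MRAColor.RED, MRAColor.ORANGE, MRAColor.GREEN)[n]


def classify_diet(met_count: int, cutoffs: MRACutoffs = _DEFAULT_CUTOFFS) -> MRAColor:
    """Diet advice from the number of dietary recommendations met (of 5)."""
    if not 0 <= met_count <= 5:
        raise ItemValidationError(f"diet met_count = {met_count} outside 0..5")
    if met_count >= cutoffs.diet_green_min_conditions:
        return MRAColor.GREEN
    if met_count <= cutoffs.diet_red_max_conditions:
        return MRAColor.RED
    return MRAColor.ORANGE


def classify_smoking(status: SmokingStatus) -> MRAColor:
    """Smoking advice: never/quit-before-diagnosis green, quit-after orange, current red."""
    if not isinstance(status, SmokingStatus):
        raise ItemValidationError(f"invalid smoking status {status!r}")
    if status is SmokingStatus.CURRENT:
        return MRAColor.RED
    if status is SmokingStatus.FORMER_QUIT_AFTER_DIAGNOSIS:
        return MRAColor.ORANGE
    return MRAColor.GREEN


def classify_all(
    profile: ScreeningProfile, cutoffs: MRACutoffs = _DEFAULT_CUTOFFS
) -> MRAProfile:
    """Apply all seven topic classifiers to a screening profile."""
    colors: dict[Topic, MRAColor] = {}
    steps = {
        Topic.FATIGUE: lambda: classify_fatigue(profile.cis_fatigue, cutoffs),
        Topic.RETURN_TO_WORK: lambda: classify_return_to_work(
            profile.work_needs_total, profile.work_no_needs, cutoffs
        ),
        Topic.MOOD: lambda: classify_mood(
            profile.hads_a, profile.hads_d, profile.mac_neg, cutoffs
        ),
        Topic.RELATIONSHIPS: lambda: classify_relationships(
            profile.ssl_d, profile.casun_relationship_needs, cutoffs
        ),
        Topic.PHYSICAL_ACTIVITY: lambda: classify_physical_activity(
            *evaluate_pa_conditions(
                profile.pa, cutoffs.pa_weekly_minutes_min, cutoffs.pa_days_min
            )
        ),
        Topic.DIET: lambda: classify_diet(
            evaluate_diet_conditions(profile.diet, cutoffs.diet_thresholds)[0],
            cutoffs,
        ),
        Topic.SMOKING: lambda: classify_smoking(profile.smoking),
    }
    for topic, step in steps.items():
        try:
            colors[topic] = step()
        except ItemValidationError as exc:
            raise ItemValidationError(f"[{topic.value}] {exc}") from exc
    return MRAProfile(colors=colors)
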