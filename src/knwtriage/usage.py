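"""Module-use outcomes and appreciation descriptives from page-visit logs.

A module counts as *used* when at least its first three pages were visited —
these pages carry the key information after which participants branch into
personalised pathways.  "First three pages" is read strictly: pages 1, 2 and
3 must each appear in the log (visiting pages 1, 3 and 7 does not qualify).

Week stamps are integer weeks since the participant first got access to the
intervention (week 0 = access week).  Appreciation ratings collected at
follow-up may be missing due to dropout; missing values are excluded
pairwise and never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import MODULES

__all__ = [
    "UsageEvent",
    "ModuleUsageLog",
    "UsageSummary",
    "AppreciationRecord",
    "NoModuleUsersError",
    "FIRST_PAGES_REQUIRED",
    "derive_module_use",
    "UsageDistribution",
    "usage_distribution",
    "distribution_mean_sd",
    "engagement_within_weeks",
    "appreciation_summary",
]

#: Number of leading pages that must all be visited for a module to count as used.
FIRST_PAGES_REQUIRED = 3

SUBQUESTIONS = ("understandable", "useful", "personal_relevance", "recommendable")


class NoModuleUsersError(ValueError):
    """Raised when a users-only metric is requested for a cohort with no users."""


@dataclass(frozen=True)
class UsageEvent:
    module: str
    page: int
    week: int

    def __post_init__(self) -> None:
        if self.module not in MODULES:
            raise ValueError(f"unknown module {self.module!r}")
        if self.page < 1:
            raise ValueError(f"page index must be >= 1, got {self.page}")
        if self.week < 0:
            raise ValueError(f"week stamp must be >= 0, got {self.week}")


@dataclass(frozen=True)
class ModuleUsageLog:
    """All page-visit events of one participant."""

    participant_id: str
    events: tuple[UsageEvent, ...]


@dataclass(frozen=True)
class UsageSummary:
    """Dichotomised module use for one participant."""

    participant_id: str
    used: dict[str, bool]
    last_week_per_module: dict[str, int | None]

    @property
    def n_modules_used(self) -> int:
        return sum(self.used.values())

    @property
    def any_module_used(self) -> bool:
        return self.n_modules_used > 0

    @property
    def last_week_overall(self) -> int | None:
        weeks = [w for w in self.last_week_per_module.values() if w is not None]
        return max(weeks) if weeks else None


@dataclass(frozen=True)
class AppreciationRecord:
    """6-month appreciation ratings; ``None`` marks a missing answer."""

    participant_id: str
    overall_rating: int | None
    module_ratings: dict[str, int | None]
    understandable: int | None
    useful: int | None
    personal_relevance: int | None
    recommendable: int | None

    def __post_init__(self) -> None:
        def _chk(name: str, v: int | None, lo: int, hi: int) -> None:
            if v is not None and not lo <= v <= hi:
                raise ValueError(f"{name} = {v} outside {lo}..{hi}")

        _chk("overall_rating", self.overall_rating, 1, 10)
        for m, v in self.module_ratings.items():
            if m not in MODULES:
                raise ValueError(f"unknown module {m!r} in module_ratings")
            _chk(f"module rating [{m}]", v, 1, 10)
        for q in SUBQUESTIONS:
            _chk(q, getattr(self, q), 1, 5)

    @property
    def responded(self) -> bool:
        return self.overall_rating is not None


def derive_module_use(
    log: ModuleUsageLog, first_pages: int = FIRST_PAGES_REQUIRED
) -> UsageSummary:
    """Dichotomise module use from a page-visit log.

    A module is used iff each of pages ``1..first_pages`` appears among its
    events (in any order, any number of times).  The result is independent of
    event order and of duplicated events.
    """
    pages_seen: dict[str, set[int]] = {m: set() for m in MODULES}
    max_week: dict[str, int] = {}
    for ev in log.events:
        pages_seen[ev.module].add(ev.page)
        max_week[ev.module] = max(max_week.get(ev.module, 0), ev.week)
    required = set(range(1, first_pages + 1))
    used = {m: required <= pages_seen[m] for m in MODULES}
    last_week = {m: (max_week[m] if used[m] else None) for m in MODULES}
    return UsageSummary(
        participant_id=log.participant_id,
        used=used,
        last_week_per_module=last_week,
    )


@dataclass(frozen=True)
class UsageDistribution:
    """Histogram of modules used per participant, top-coded at "six or more"."""

    counts: dict[str, int]          # keys "0".."5", "6+"
    percentages: dict[str, float]
    mean: float
    sd: float
    n: int


def distribution_mean_sd(
    histogram: Mapping[int, int], topcode_value: int = 6
) -> tuple[float, float]:
    """Mean and sample SD of a module-count histogram.

    ``histogram`` maps a module count to the number of participants; the
    largest key is the top-coded "six or more" bin and is valued at
    ``topcode_value`` (the within-bin split is not published, so the SD is a
    lower bound).  SD uses the n-1 denominator; a single participant yields
    SD 0 by convention.
    """
    values = np.repeat(list(histogram.keys()), list(histogram.values())).astype(float)
    values[values >= topcode_value] = topcode_value
    if values.size == 0:
        raise ValueError("empty histogram")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd


def usage_distribution(summaries: Sequence[UsageSummary]) -> UsageDistribution:
    """Distribution of n_modules_used across a cohort (bins 0..5, 6+)."""
    if not summaries:
        raise ValueError("empty cohort")
    n = len(summaries)
    counts_raw = [s.n_modules_used for s in summaries]
    hist: dict[int, int] = {}
    for c in counts_raw:
        hist[c] = hist.get(c, 0) + 1
    bins = [str(i) for i in range(6)] + ["6+"]
    binned = {b: 0 for b in bins}
    for c, k in hist.items():
        binned["6+" if c >= 6 else str(c)] += k
    percentages = {b: 100.0 * k / n for b, k in binned.items()}
    arr = np.asarray(counts_raw, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    return UsageDistribution(
        counts=binned, percentages=percentages, mean=mean, sd=sd, n=n
    )


def engagement_within_weeks(
    summaries: Sequence[UsageSummary], horizon_weeks: int
) -> float:
    """Proportion of module users whose last module activity is within the horizon.

    The denominator is the number of participants who used at least one
    module; raises :class:`NoModuleUsersError` when there are none.
    """
    if horizon_weeks < 0:
        raise ValueError("horizon_weeks must be >= 0")
    users = [s for s in summaries if s.any_module_used]
    if not users:
        raise NoModuleUsersError("no participant used any module")
    within = sum(1 for s in users if s.last_week_overall <= horizon_weeks)
    return within / len(users)


def _mean_sd_n(values: list[float]) -> tuple[float, float, int]:
    n = len(values)
    if n == 0:
        return math.nan, math.nan, 0
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    return float(arr.mean()), sd, n


def appreciation_summary(
    records: Sequence[AppreciationRecord],
    summaries: Sequence[UsageSummary],
) -> pd.DataFrame:
    """Mean/SD/n of every appreciation scale, overall and split by module use.

    Returns a tidy frame with columns ``scale``, ``group``, ``mean``, ``sd``,
    ``n``.  Groups are ``all``, ``module_users`` and ``non_users`` for the
    overall rating and the four content subquestions, plus per-module groups
    (users of that module) for the module-specific ratings.  Missing answers
    are dropped pairwise; an all-missing cell keeps NaN statistics with
    ``n = 0``.
    """
    if len(records) != len(summaries):
        raise ValueError("records and summaries must have equal length")
    by_id = {s.participant_id: s for s in summaries}
    rows = []

    def collect(scale: str, group: str, values: list[float]) -> None:
        mean, sd, n = _mean_sd_n(values)
        rows.append({"scale": scale, "group": group, "mean": mean, "sd": sd, "n": n})

    user_split = {
        "all": lambda s: True,
        "module_users": lambda s: s.any_module_used,
        "non_users": lambda s: not s.any_module_used,
    }
    for scale in ("overall_rating",) + SUBQUESTIONS:
        for group, pred in user_split.items():
            vals = [
                getattr(r, scale)
                for r in records
                if getattr(r, scale) is not None and pred(by_id[r.participant_id])
            ]
            collect(scale, group, vals)
    for module in MODULES:
        vals = [
            r.module_ratings.get(module)
            for r in records
            if r.module_ratings.get(module) is not None
            and by_id[r.participant_id].used[module]
        ]
        collect(f"module_rating_{module}", f"{module}_users", vals)
    return pd.DataFrame(rows)
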