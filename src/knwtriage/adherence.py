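"""Adherence to the Module Referral Advice: 2x2 contingency statistics.

Adherence is quantified by cross-tabulating the binary module-use outcome
against the advice color for every pair of colors (red/orange, red/green,
orange/green) within a topic, then testing the association with an
uncorrected Pearson chi-square (df=1) and summarising its strength with the
odds ratio and a Woolf (log-normal) 95% confidence interval.

The published association table can be rebuilt from aggregate data alone:
with the cohort size N and the printed percentages (share of each color,
share of module users within each color), nearest-integer reconstruction of
the cell counts reproduces the published chi-square statistics and odds
ratios — :func:`reproduce_published_adherence` does exactly that and flags
any entry that disagrees with the published value by more than 0.01.

No continuity correction is applied anywhere: the published statistics are
only recovered by the uncorrected Pearson formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from . import reference
from .engine import MRAColor, MRAProfile, Topic

__all__ = [
    "ContingencyTable2x2",
    "ChiSquareResult",
    "OddsRatioResult",
    "MarginError",
    "pearson_chi_square",
    "odds_ratio",
    "round_half_away",
    "reconstruct_counts",
    "build_color_pair_table",
    "reproduce_published_adherence",
    "format_p_value",
]


class MarginError(ValueError):
    """Raised when a contingency-table margin is zero and the test is undefined."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Used/not-used counts for two advice-color groups.

    ``a``/``b`` are the used/not-used counts of the first group,
    ``c``/``d`` of the second.
    """

    a: int
    b: int
    c: int
    d: int
    group1_empty: bool = False
    group2_empty: bool = False

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} = {v} must be a non-negative integer")
        if self.total < 1:
            raise ValueError("contingency table must contain at least one count")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    ci_method: str
    zero_cell: bool = False


def pearson_chi_square(t: ContingencyTable2x2) -> ChiSquareResult:
    """Uncorrected Pearson chi-square test of association (df=1).

    The statistic is the sum over the four cells of
    (observed - expected)^2 / expected with expected counts computed from
    the margins; the p-value is the upper tail of the chi-square(1)
    distribution.  Raises :class:`MarginError` if any row or column margin
    is zero (expected counts would vanish).
    """
    a, b, c, d = t.cells
    n = t.total
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    for name, margin in (
        ("group 1 (row 1)", row1),
        ("group 2 (row 2)", row2),
        ("used (column 1)", col1),
        ("not used (column 2)", col2),
    ):
        if margin == 0:
            raise MarginError(f"margin {name} is zero; chi-square undefined")
    # closed form for 2x2: n (ad - bc)^2 / (row1 row2 col1 col2)
    statistic = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    p = float(stats.chi2.sf(statistic, df=1))
    return ChiSquareResult(statistic=float(statistic), df=1, p_value=p)


def odds_ratio(
    t: ContingencyTable2x2, ci_method: str = "woolf", alpha: float = 0.05
) -> OddsRatioResult:
    """Odds ratio (a*d)/(b*c) with a Woolf log-normal confidence interval.

    A zero cell makes the point estimate 0 or infinite; it is returned as
    such with ``zero_cell=True`` and NaN confidence limits rather than
    raising.
    """
    if ci_method != "woolf":
        raise ValueError(f"unknown ci_method {ci_method!r}")
    a, b, c, d = t.cells
    if b * c == 0 or a * d == 0:
        or_point = math.inf if b * c == 0 and a * d > 0 else 0.0
        return OddsRatioResult(
            odds_ratio=or_point,
            ci_low=math.nan,
            ci_high=math.nan,
            ci_method=ci_method,
            zero_cell=True,
        )
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(stats.norm.ppf(1 - alpha / 2))
    return OddsRatioResult(
        odds_ratio=or_point,
        ci_low=math.exp(math.log(or_point) - z * se),
        ci_high=math.exp(math.log(or_point) + z * se),
        ci_method=ci_method,
    )


def round_half_away(x: float) -> int:
    """Nearest integer, halves rounded away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def reconstruct_counts(
    n_total: int, pct_color: float, pct_used: float
) -> tuple[int, int]:
    """Rebuild (group size, users in group) from printed percentages.

    ``n_color = round(n_total * pct_color/100)`` and
    ``n_used = round(n_color * pct_used/100)`` with nearest-integer rounding
    (half away from zero).
    """
    if not 0 <= pct_color <= 100 or not 0 <= pct_used <= 100:
        raise ValueError("percentages must lie in [0, 100]")
    n_color = round_half_away(n_total * pct_color / 100.0)
    n_used = round_half_away(n_color * pct_used / 100.0)
    return n_color, n_used


def build_color_pair_table(
    mra_profiles: Sequence[MRAProfile],
    used: Sequence[Mapping[str, bool]],
    topic: Topic,
    color1: MRAColor,
    color2: MRAColor,
) -> ContingencyTable2x2:
    """Cross-tabulate use of a topic's module for two advice colors.

    ``used[i]`` maps module name -> used flag for participant ``i`` (e.g. the
    ``used`` field of a :class:`~knwtriage.usage.UsageSummary`).  Participants
    whose advice color for the topic is neither ``color1`` nor ``color2`` are
    excluded.  An empty color group yields a zero row, flagged on the table.
    """
    if color1 == color2:
        raise ValueError("color1 and color2 must differ")
    if len(mra_profiles) != len(used):
        raise ValueError("mra_profiles and used must have equal length")
    counts = {color1: [0, 0], color2: [0, 0]}
    module = topic.value
    for mra, u in zip(mra_profiles, used):
        color = mra.colors[topic]
        if color in counts:
            counts[color][0 if u[module] else 1] += 1
    (a, b), (c, d) = counts[color1], counts[color2]
    return ContingencyTable2x2(
        a=a,
        b=b,
        c=c,
        d=d,
        group1_empty=(a + b == 0),
        group2_empty=(c + d == 0),
    )


def format_p_value(p: float) -> str:
    """Three-decimal p-value display; values below 0.0005 shown as ``<.001``."""
    if p < 0.0005:
        return "<.001"
    return f"{p:.3f}".lstrip("0")


def reproduce_published_adherence(
    n_total: int = reference.N_PARTICIPANTS,
    flag_tolerance: float = 0.01,
) -> pd.DataFrame:
    """Rebuild all 21 published adherence entries from aggregate percentages.

    For every topic and color pair the cell counts are reconstructed with
    :func:`reconstruct_counts` from the published color shares and
    conditional-use percentages, then the uncorrected chi-square and odds
    ratio are computed.  Entries whose chi-square or odds ratio differ from
    the published value by more than ``flag_tolerance`` are flagged (the
    published PA red/orange odds ratio is the one known flagged entry).
    """
    rows = []
    for topic in Topic:
        color_pct = reference.MRA_COLOR_PCT[topic]
        use_pct = reference.MODULE_USE_GIVEN_COLOR_PCT[topic]
        for c1, c2 in reference.COLOR_PAIRS:
            n1, a = reconstruct_counts(n_total, color_pct[c1], use_pct[c1])
            n2, c = reconstruct_counts(n_total, color_pct[c2], use_pct[c2])
            table = ContingencyTable2x2(a=a, b=n1 - a, c=c, d=n2 - c)
            chi = pearson_chi_square(table)
            orr = odds_ratio(table)
            pub_chi, pub_p, pub_or, pub_lo, pub_hi = reference.PUBLISHED_ADHERENCE[
                topic
            ][(c1, c2)]
            rows.append(
                {
                    "topic": topic.value,
                    "pair": f"{c1}_vs_{c2}",
                    "a": a,
                    "b": n1 - a,
                    "c": c,
                    "d": n2 - c,
                    "chi_square": chi.statistic,
                    "p_value": chi.p_value,
                    "p_display": format_p_value(chi.p_value),
                    "odds_ratio": orr.odds_ratio,
                    "ci_low": orr.ci_low,
                    "ci_high": orr.ci_high,
                    "published_chi_square": pub_chi,
                    "published_p": pub_p,
                    "published_odds_ratio": pub_or,
                    "published_ci": f"{pub_lo}-{pub_hi}",
                    "chi_square_match": abs(chi.statistic - pub_chi) <= flag_tolerance,
                    "odds_ratio_match": abs(orr.odds_ratio - pub_or)
                    <= flag_tolerance,
                }
            )
    return pd.DataFrame(rows)
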