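"""Contingency statistics: published-value reproduction and oracle equivalence."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from knwtriage.adherence import (
    ContingencyTable2x2,
    MarginError,
    build_color_pair_table,
    format_p_value,
    odds_ratio,
    pearson_chi_square,
    reconstruct_counts,
    reproduce_published_adherence,
    round_half_away,
)
from knwtriage.engine import MRAColor, MRAProfile, Topic, TOPICS


@pytest.mark.parametrize(
    "cells, expected_chi2",
    [
        ((47, 33, 17, 27), 4.5985),    # fatigue red vs orange
        ((10, 10, 10, 10), 0.0),
        ((13, 14, 7, 190), 58.075),    # smoking red vs green
    ],
)
def test_uncorrected_chi_square_values(cells, expected_chi2):
    res = pearson_chi_square(ContingencyTable2x2(*cells))
    assert res.statistic == pytest.approx(expected_chi2, abs=5e-4)
    assert res.df == 1
    assert 0.0 <= res.p_value <= 1.0


@pytest.mark.parametrize(
    "cells, expected_or",
    [
        ((47, 33, 17, 27), 2.262),
        ((12, 32, 19, 141), 2.783),    # relationships orange vs green
        ((6, 3, 8, 4), 1.0),           # a*d == b*c
    ],
)
def test_odds_ratio_values(cells, expected_or):
    res = odds_ratio(ContingencyTable2x2(*cells))
    assert res.odds_ratio == pytest.approx(expected_or, abs=5e-4)
    assert res.ci_low <= res.odds_ratio <= res.ci_high


def test_chi_square_matches_scipy_without_correction():
    rng = np.random.default_rng(2)
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(1, 80, size=4))
        t = ContingencyTable2x2(a, b, c, d)
        ours = pearson_chi_square(t)
        ref = chi2_contingency([[a, b], [c, d]], correction=False)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12, abs=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10, abs=1e-12)


def test_odds_ratio_and_ci_match_statsmodels():
    sm = pytest.importorskip("statsmodels.stats.contingency_tables")
    for cells in [(47, 33, 17, 27), (22, 20, 26, 154), (3, 9, 31, 52)]:
        table = sm.Table2x2(np.array(cells).reshape(2, 2), shift_zeros=False)
        ours = odds_ratio(ContingencyTable2x2(*cells))
        assert ours.odds_ratio == pytest.approx(table.oddsratio, rel=1e-12)
        lo, hi = table.oddsratio_confint()
        assert ours.ci_low == pytest.approx(lo, rel=1e-9)
        assert ours.ci_high == pytest.approx(hi, rel=1e-9)


def test_chi_square_exact_against_rational_arithmetic_oracle():
    """All tables with total <= 40 and positive margins: the closed-form
    statistic equals the expected-count definition computed with exact
    rational arithmetic, to 1e-9."""
    checked = 0
    for total in range(2, 41):
        for a in range(total + 1):
            for b in range(total + 1 - a):
                for c in range(total + 1 - a - b):
                    d = total - a - b - c
                    if min(a + b, c + d, a + c, b + d) == 0:
                        continue
                    n = Fraction(total)
                    exact = Fraction(0)
                    for obs, r, col in (
                        (a, a + b, a + c),
                        (b, a + b, b + d),
                        (c, c + d, a + c),
                        (d, c + d, b + d),
                    ):
                        e = Fraction(r * col, total)
                        exact += (obs - e) ** 2 / e
                    ours = pearson_chi_square(ContingencyTable2x2(a, b, c, d))
                    assert abs(ours.statistic - float(exact)) < 1e-9
                    checked += 1
    assert checked > 50_000


@given(st.tuples(*[st.integers(1, 200)] * 4))
@settings(derandomize=True, max_examples=100)
def test_invariances_and_reciprocal(cells):
    a, b, c, d = cells
    t = ContingencyTable2x2(a, b, c, d)
    swapped_groups = ContingencyTable2x2(c, d, a, b)
    swapped_outcome = ContingencyTable2x2(b, a, d, c)
    s = pearson_chi_square(t).statistic
    assert pearson_chi_square(swapped_groups).statistic == pytest.approx(s, rel=1e-12)
    assert pearson_chi_square(swapped_outcome).statistic == pytest.approx(s, rel=1e-12)
    assert odds_ratio(swapped_groups).odds_ratio == pytest.approx(
        1.0 / odds_ratio(t).odds_ratio, rel=1e-12
    )


def test_zero_margin_raises_named_error():
    with pytest.raises(MarginError, match="column 1"):
        pearson_chi_square(ContingencyTable2x2(0, 5, 0, 5))
    with pytest.raises(MarginError, match="row 1"):
        pearson_chi_square(ContingencyTable2x2(0, 0, 3, 5))


def test_zero_cell_odds_ratio_flagged_not_raised():
    res = odds_ratio(ContingencyTable2x2(5, 0, 3, 4))
    assert res.zero_cell and res.odds_ratio == float("inf")
    res0 = odds_ratio(ContingencyTable2x2(0, 5, 3, 4))
    assert res0.zero_cell and res0.odds_ratio == 0.0


@pytest.mark.parametrize(
    "args, expected",
    [
        ((231, 34.6, 58.8), (80, 47)),
        ((231, 0.0, 50.0), (0, 0)),
        ((231, 77.9, 14.4), (180, 26)),
    ],
)
def test_count_reconstruction(args, expected):
    assert reconstruct_counts(*args) == expected


def test_round_half_away_from_zero():
    assert round_half_away(2.5) == 3
    assert round_half_away(-2.5) == -3
    assert round_half_away(2.4) == 2


def _mra(colors: dict[Topic, MRAColor]) -> MRAProfile:
    full = dict.fromkeys(TOPICS, MRAColor.GREEN)
    full.update(colors)
    return MRAProfile(colors=full)


def test_build_color_pair_table_toy_cohort():
    profiles = [
        _mra({Topic.FATIGUE: MRAColor.RED}),
        _mra({Topic.FATIGUE: MRAColor.ORANGE}),
        _mra({Topic.FATIGUE: MRAColor.GREEN}),  # excluded from red-vs-orange
    ]
    used = [{"fatigue": True}, {"fatigue": False}, {"fatigue": True}]
    t = build_color_pair_table(
        profiles, used, Topic.FATIGUE, MRAColor.RED, MRAColor.ORANGE
    )
    assert t.cells == (1, 0, 0, 1)
    assert not t.group1_empty and not t.group2_empty


def test_build_color_pair_table_flags_empty_group():
    profiles = [_mra({Topic.DIET: MRAColor.GREEN})]
    t = build_color_pair_table(
        profiles, [{"diet": False}], Topic.DIET, MRAColor.RED, MRAColor.GREEN
    )
    assert t.group1_empty and t.cells == (0, 0, 0, 1)


def test_reconstructed_fatigue_cohort_reproduces_counts():
    """Build an individual-level cohort from the reconstructed counts and
    cross-tabulate it back."""
    profiles, used = [], []
    for color, n_used, n_not in [
        (MRAColor.RED, 47, 33),
        (MRAColor.ORANGE, 17, 27),
    ]:
        for flag, k in ((True, n_used), (False, n_not)):
            for _ in range(k):
                profiles.append(_mra({Topic.FATIGUE: color}))
                used.append({"fatigue": flag})
    t = build_color_pair_table(
        profiles, used, Topic.FATIGUE, MRAColor.RED, MRAColor.ORANGE
    )
    assert t.cells == (47, 33, 17, 27)


def test_published_adherence_reproduction_report():
    df = reproduce_published_adherence()
    assert len(df) == 21
    # every chi-square entry reproduces within 0.01 of the published value
    assert df.chi_square_match.all()
    # the single known discrepancy: the published PA red/orange odds ratio
    mismatches = df[~df.odds_ratio_match]
    assert list(mismatches.topic) == ["physical_activity"]
    assert list(mismatches.pair) == ["red_vs_orange"]


def test_p_value_display_convention():
    assert format_p_value(0.0312) == ".031"
    assert format_p_value(0.0004) == "<.001"
    assert format_p_value(0.863) == ".863"
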