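"""Referral-advice rules: examples, exhaustive completeness, oracle agreement."""

import json

import numpy as np
import pytest

from knwtriage.engine import (
    TOPICS,
    MRAColor,
    MRACutoffs,
    Topic,
    classify_all,
    classify_diet,
    classify_fatigue,
    classify_mood,
    classify_physical_activity,
    classify_relationships,
    classify_return_to_work,
    classify_smoking,
)
from knwtriage.instruments import (
    DietProfile,
    ItemValidationError,
    PAProfile,
    SmokingStatus,
)
from conftest import healthy_profile, worst_profile

G, O, R = MRAColor.GREEN, MRAColor.ORANGE, MRAColor.RED


# ---------------------------------------------------------------------------
# straight-line re-implementations of the cut-off table, used as oracles
# ---------------------------------------------------------------------------

def mood_oracle(a: int, d: int, mac: int) -> MRAColor:
    if a > 15:
        return R
    if d > 15:
        return R
    if 8 <= a <= 15:
        return O
    if 8 <= d <= 15:
        return O
    if mac > 36:
        return O
    return G


def relationships_oracle(ssl: int, needs: bool) -> MRAColor:
    if ssl <= 7:
        return G
    if not needs:
        return G
    if ssl >= 10:
        return R
    return O


@pytest.mark.parametrize(
    "score, expected", [(26, G), (27, O), (35, O), (36, R), (1, G), (56, R)]
)
def test_fatigue_cutoffs(score, expected):
    assert classify_fatigue(score) == expected


@pytest.mark.parametrize(
    "total, no_needs, expected",
    [(0, True, G), (1, False, G), (2, False, G), (3, False, O), (12, False, O),
     (13, False, R), (20, False, R)],
)
def test_return_to_work_cutoffs(total, no_needs, expected):
    assert classify_return_to_work(total, no_needs) == expected


@pytest.mark.parametrize(
    "a, d, mac, expected",
    [(5, 5, 30, G), (5, 5, 36, G), (5, 5, 40, O), (5, 5, 37, O),
     (8, 0, 16, O), (0, 8, 16, O), (3, 16, 20, R), (16, 0, 16, R),
     (15, 15, 64, O), (21, 21, 64, R)],
)
def test_mood_cutoffs(a, d, mac, expected):
    assert classify_mood(a, d, mac) == expected


@pytest.mark.parametrize(
    "ssl, needs, expected",
    [(7, True, G), (6, False, G), (8, True, O), (9, True, O),
     (10, True, R), (24, True, R), (10, False, G), (24, False, G)],
)
def test_relationships_cutoffs(ssl, needs, expected):
    assert classify_relationships(ssl, needs) == expected


@pytest.mark.parametrize(
    "both, expected",
    [((True, True), G), ((True, False), O), ((False, True), O), ((False, False), R)],
)
def test_physical_activity_conditions(both, expected):
    assert classify_physical_activity(*both) == expected


@pytest.mark.parametrize(
    "count, expected", [(5, G), (4, G), (3, O), (2, O), (1, R), (0, R)]
)
def test_diet_conditions_met(count, expected):
    assert classify_diet(count) == expected


@pytest.mark.parametrize(
    "status, expected",
    [
        (SmokingStatus.NEVER, G),
        (SmokingStatus.FORMER_QUIT_BEFORE_DIAGNOSIS, G),
        (SmokingStatus.FORMER_QUIT_AFTER_DIAGNOSIS, O),
        (SmokingStatus.CURRENT, R),
    ],
)
def test_smoking_categories(status, expected):
    assert classify_smoking(status) == expected


def test_mood_grid_matches_straight_line_oracle():
    """Exhaustive sweep of HADS-A x HADS-D x MAC against an independent
    nested-conditional reading of the rule table."""
    for a in range(22):
        for d in range(22):
            for mac in range(16, 65):
                assert classify_mood(a, d, mac) == mood_oracle(a, d, mac)


def test_every_scalar_input_gets_exactly_one_color():
    """Exhaustive enumeration over full ranges: the rules partition each
    input space (no gaps, no overlaps — each call returns exactly one color)."""
    fatigue_colors = [classify_fatigue(s) for s in range(1, 57)]
    assert {c for c in fatigue_colors} == {G, O, R}
    work_colors = [classify_return_to_work(t, t == 0) for t in range(21)]
    assert {c for c in work_colors} == {G, O, R}
    rel = [
        classify_relationships(s, needs)
        for s in range(6, 25)
        for needs in (False, True)
    ]
    assert rel.count(O) == 2 and rel.count(R) == 15 and rel.count(G) == 21
    assert {classify_diet(k) for k in range(6)} == {G, O, R}
    for s, needs in [(6, False), (24, True)]:
        assert isinstance(classify_relationships(s, needs), MRAColor)
    for ssl in range(6, 25):
        for needs in (False, True):
            assert classify_relationships(ssl, needs) == relationships_oracle(
                ssl, needs
            )


@pytest.mark.parametrize(
    "classifier, worsening_inputs",
    [
        (classify_fatigue, [1, 10, 26, 27, 30, 35, 36, 45, 56]),
        (classify_diet, [5, 4, 3, 2, 1, 0]),
        (lambda t: classify_return_to_work(t, t == 0), list(range(21))),
    ],
)
def test_monotone_in_severity(classifier, worsening_inputs):
    severities = [classifier(x).severity for x in worsening_inputs]
    assert severities == sorted(severities)


def test_classify_all_composition():
    all_green = classify_all(healthy_profile())
    assert set(all_green.colors.values()) == {G}
    assert all_green.n_referrals == 0

    all_red = classify_all(worst_profile())
    assert set(all_red.colors.values()) == {R}
    assert all_red.n_red == 7 and all_red.n_referrals == 7

    one_orange = classify_all(healthy_profile(cis_fatigue=30))
    assert one_orange.colors[Topic.FATIGUE] == O
    assert one_orange.n_referrals == 1 and one_orange.n_orange == 1


def test_n_referrals_counts_non_green_topics():
    rng = np.random.default_rng(11)
    for _ in range(200):
        profile = healthy_profile(
            cis_fatigue=int(rng.integers(1, 57)),
            hads_a=int(rng.integers(0, 22)),
            hads_d=int(rng.integers(0, 22)),
            mac_neg=int(rng.integers(16, 65)),
            ssl_d=int(rng.integers(6, 25)),
            casun_relationship_needs=bool(rng.random() < 0.5),
            work_needs_total=int(rng.integers(0, 21)),
            work_no_needs=False,
            smoking=list(SmokingStatus)[int(rng.integers(0, 4))],
        )
        # work_no_needs must stay consistent
        if profile.work_needs_total == 0:
            profile = healthy_profile(
                cis_fatigue=profile.cis_fatigue, work_needs_total=0, work_no_needs=True
            )
        mra = classify_all(profile)
        non_green = sum(1 for c in mra.colors.values() if c != G)
        assert mra.n_referrals == non_green == mra.n_red + mra.n_orange


def test_classifier_errors_carry_topic_name():
    bad = healthy_profile()
    object.__setattr__(bad, "cis_fatigue", 99)  # bypass constructor validation
    with pytest.raises(ItemValidationError, match=r"\[fatigue\]"):
        classify_all(bad)


def test_cutoffs_json_round_trip_and_override(tmp_path):
    path = tmp_path / "cutoffs.json"
    MRACutoffs().to_json(path)
    assert MRACutoffs.from_json(path) == MRACutoffs()
    raw = json.loads(path.read_text())
    raw["fatigue_orange_min"] = 20
    path.write_text(json.dumps(raw))
    custom = MRACutoffs.from_json(path)
    assert classify_fatigue(25, custom) == O
    assert classify_fatigue(25) == G
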