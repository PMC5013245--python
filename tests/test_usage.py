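"""Module-use derivation, usage distribution and appreciation descriptives."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from knwtriage.engine import MODULES
from knwtriage.reference import MODULE_COUNT_DISTRIBUTION
from knwtriage.usage import (
    AppreciationRecord,
    ModuleUsageLog,
    NoModuleUsersError,
    UsageEvent,
    UsageSummary,
    appreciation_summary,
    derive_module_use,
    distribution_mean_sd,
    engagement_within_weeks,
    usage_distribution,
)


def log_of(pid: str, *events: tuple[str, int, int]) -> ModuleUsageLog:
    return ModuleUsageLog(
        participant_id=pid,
        events=tuple(UsageEvent(module=m, page=p, week=w) for m, p, w in events),
    )


def summary_of(pid: str, n_used: int, week: int = 1) -> UsageSummary:
    used = {m: i < n_used for i, m in enumerate(MODULES)}
    return UsageSummary(
        participant_id=pid,
        used=used,
        last_week_per_module={m: (week if used[m] else None) for m in MODULES},
    )


@pytest.mark.parametrize(
    "pages, used",
    [
        ((1, 2, 3), True),
        ((1, 2), False),
        ((1, 3, 7), False),   # page 2 never visited: strict first-three reading
        ((3, 1, 2, 9), True),  # order does not matter
    ],
)
def test_first_three_pages_rule(pages, used):
    log = log_of("p1", *[("diet", p, 0) for p in pages])
    assert derive_module_use(log).used["diet"] is used


def test_unknown_module_rejected():
    with pytest.raises(ValueError, match="unknown module"):
        UsageEvent(module="yoga", page=1, week=0)


def test_last_week_is_max_event_week_of_used_modules():
    log = log_of("p1", ("mood", 1, 0), ("mood", 2, 3), ("mood", 3, 1), ("diet", 1, 9))
    s = derive_module_use(log)
    assert s.last_week_per_module["mood"] == 3
    assert s.last_week_per_module["diet"] is None  # not used
    assert s.last_week_overall == 3
    assert s.n_modules_used == 1


@given(
    events=st.lists(
        st.tuples(
            st.sampled_from(MODULES), st.integers(1, 12), st.integers(0, 30)
        ),
        max_size=30,
    ),
)
@settings(derandomize=True, max_examples=80)
def test_module_use_order_insensitive_and_idempotent(events):
    log = log_of("p", *events)
    shuffled = log_of("p", *list(reversed(events)))
    doubled = log_of("p", *(events + events))
    base = derive_module_use(log)
    assert derive_module_use(shuffled).used == base.used
    assert derive_module_use(doubled).used == base.used


def test_published_usage_histogram_mean():
    """The published module-count distribution, with the open top bin valued
    at 6, has mean 2.1 (matching the published mean; the SD depends on the
    unpublished >=6 split)."""
    mean, sd = distribution_mean_sd(MODULE_COUNT_DISTRIBUTION)
    assert round(mean, 1) == 2.1
    assert sd > 0


def test_usage_distribution_edge_cases():
    one = usage_distribution([summary_of("a", 0)])
    assert one.percentages["0"] == 100.0 and one.mean == 0.0 and one.sd == 0.0
    same = usage_distribution([summary_of(str(i), 2) for i in range(5)])
    assert same.sd == 0.0 and same.mean == 2.0
    with pytest.raises(ValueError, match="empty"):
        usage_distribution([])


def test_usage_distribution_percentages_sum_to_100(small_cohort):
    from knwtriage.usage import derive_module_use as dmu

    dist = usage_distribution([dmu(p.usage) for p in small_cohort])
    assert sum(dist.percentages.values()) == pytest.approx(100.0, abs=0.1)
    assert sum(dist.counts.values()) == dist.n


def test_engagement_proportion():
    all_week1 = [summary_of(str(i), 1, week=1) for i in range(10)]
    assert engagement_within_weeks(all_week1, 16) == 1.0
    late = [summary_of("a", 1, week=20), summary_of("b", 1, week=2)]
    assert engagement_within_weeks(late, 16) == 0.5
    nonusers = [summary_of("a", 0)]
    with pytest.raises(NoModuleUsersError):
        engagement_within_weeks(nonusers, 16)


def record_of(pid, overall=None, module=None, rating=None, **subs):
    ratings = {m: None for m in MODULES}
    if module is not None:
        ratings[module] = rating
    return AppreciationRecord(
        participant_id=pid,
        overall_rating=overall,
        module_ratings=ratings,
        understandable=subs.get("understandable"),
        useful=subs.get("useful"),
        personal_relevance=subs.get("personal_relevance"),
        recommendable=subs.get("recommendable"),
    )


def test_appreciation_constant_ratings():
    records = [record_of(str(i), overall=7) for i in range(4)]
    summaries = [summary_of(str(i), 1) for i in range(4)]
    table = appreciation_summary(records, summaries)
    row = table[(table.scale == "overall_rating") & (table.group == "all")].iloc[0]
    assert row["mean"] == 7.0 and row["sd"] == 0.0 and row["n"] == 4


def test_appreciation_single_record_sd_zero_by_convention():
    table = appreciation_summary([record_of("a", overall=9)], [summary_of("a", 1)])
    row = table[(table.scale == "overall_rating") & (table.group == "all")].iloc[0]
    assert row["n"] == 1 and row["sd"] == 0.0


def test_appreciation_missing_never_imputed_and_counts_conserved():
    records = [
        record_of("a", overall=8),
        record_of("b"),                       # dropout: everything missing
        record_of("c", overall=6),
    ]
    summaries = [summary_of("a", 1), summary_of("b", 0), summary_of("c", 0)]
    table = appreciation_summary(records, summaries)
    overall = table[table.scale == "overall_rating"].set_index("group")
    assert overall.loc["all", "n"] == 2
    assert overall.loc["all", "mean"] == 7.0
    # split counts add up to the total responder count
    assert overall.loc["module_users", "n"] + overall.loc["non_users", "n"] == 2
    # an all-missing scale is reported as unavailable, not imputed
    useful = table[(table.scale == "useful") & (table.group == "all")].iloc[0]
    assert useful["n"] == 0 and math.isnan(useful["mean"])


def test_module_rating_restricted_to_module_users():
    records = [
        record_of("a", overall=8, module="diet", rating=9),
        record_of("b", overall=7, module="diet", rating=3),
    ]
    # participant b rated diet but did not use it (below three pages):
    # the rating is excluded from the diet users' summary
    summaries = [summary_of("a", 8), summary_of("b", 0)]
    table = appreciation_summary(records, summaries)
    row = table[table.scale == "module_rating_diet"].iloc[0]
    assert row["n"] == 1 and row["mean"] == 9.0
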