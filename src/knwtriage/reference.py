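"""Published summary statistics of the KNW process-evaluation cohort (N=231).

These constants are the printed aggregate results of the KNW intervention
arm: the per-topic distribution of referral-advice colors, the probability of
using each module conditional on the received color, the published adherence
chi-square/odds-ratio entries, the module-count usage distribution, the
appreciation rating summaries and the baseline demographic marginals.

They serve two purposes: (1) default calibration of the synthetic-cohort
generator, and (2) inputs/benchmarks for the adherence reconstruction, which
rebuilds the 2x2 contingency tables behind the published association
statistics from these percentages alone.
"""

from __future__ import annotations

from .engine import RESIDUAL_MODULE, Topic

#: Size of the intervention cohort.
N_PARTICIPANTS = 231

#: Per-topic referral-color distribution, in percent of the cohort,
#: as printed (some triples sum to 100.1 due to rounding of each entry).
MRA_COLOR_PCT: dict[Topic, dict[str, float]] = {
    Topic.FATIGUE: {"red": 34.6, "orange": 19.1, "green": 46.3},
    Topic.RETURN_TO_WORK: {"red": 3.9, "orange": 18.2, "green": 77.9},
    Topic.MOOD: {"red": 1.7, "orange": 28.6, "green": 69.7},
    Topic.RELATIONSHIPS: {"red": 11.7, "orange": 19.1, "green": 69.3},
    Topic.PHYSICAL_ACTIVITY: {"red": 5.2, "orange": 35.9, "green": 58.9},
    Topic.DIET: {"red": 53.3, "orange": 42.9, "green": 3.9},
    Topic.SMOKING: {"red": 11.7, "orange": 3.1, "green": 85.3},
}

#: Percent of participants who used the topic's module, conditional on the
#: advice color they received.
MODULE_USE_GIVEN_COLOR_PCT: dict[Topic, dict[str, float]] = {
    Topic.FATIGUE: {"red": 58.8, "orange": 38.6, "green": 16.8},
    Topic.RETURN_TO_WORK: {"red": 55.6, "orange": 52.4, "green": 14.4},
    Topic.MOOD: {"red": 25.0, "orange": 30.3, "green": 17.4},
    Topic.RELATIONSHIPS: {"red": 25.9, "orange": 27.3, "green": 11.8},
    Topic.PHYSICAL_ACTIVITY: {"red": 25.0, "orange": 37.4, "green": 12.5},
    Topic.DIET: {"red": 50.4, "orange": 68.7, "green": 44.4},
    Topic.SMOKING: {"red": 48.2, "orange": 42.9, "green": 3.6},
}

#: Fraction of the cohort that used the residual-symptoms module (47/231).
RESIDUAL_MODULE_USE_PROB = 0.204

#: Published adherence statistics per topic and color pair:
#: (chi_square, p_display, odds_ratio, ci_low, ci_high).
COLOR_PAIRS: tuple[tuple[str, str], ...] = (
    ("red", "orange"),
    ("red", "green"),
    ("orange", "green"),
)

PUBLISHED_ADHERENCE: dict[Topic, dict[tuple[str, str], tuple[float, str, float, float, float]]] = {
    Topic.FATIGUE: {
        ("red", "orange"): (4.599, ".032", 2.262, 0.99, 5.16),
        ("red", "green"): (35.485, "<.001", 7.042, 3.12, 14.69),
        ("orange", "green"): (8.332, ".004", 3.113, 1.30, 7.37),
    },
    Topic.RETURN_TO_WORK: {
        ("red", "orange"): (0.030, ".863", 1.136, 0.21, 6.56),
        ("red", "green"): (10.565, ".001", 7.404, 1.46, 39.25),
        ("orange", "green"): (28.920, "<.001", 6.515, 2.92, 14.47),
    },
    Topic.MOOD: {
        ("red", "orange"): (0.050, ".822", 0.767, 0.01, 10.27),
        ("red", "green"): (0.156, ".693", 1.583, 0.03, 20.50),
        ("orange", "green"): (4.680, ".031", 2.065, 1.00, 4.21),
    },
    Topic.RELATIONSHIPS: {
        ("red", "orange"): (0.016, ".901", 0.933, 0.26, 3.11),
        ("red", "green"): (3.810, ".051", 2.597, 0.81, 7.49),
        ("orange", "green"): (6.349, ".012", 2.783, 1.11, 6.73),
    },
    Topic.PHYSICAL_ACTIVITY: {
        ("red", "orange"): (0.696, ".404", 0.186, 0.00, 1.48),
        ("red", "green"): (1.474, ".225", 2.333, 0.37, 10.57),
        ("orange", "green"): (18.60, "<.001", 4.173, 2.02, 8.74),
    },
    Topic.DIET: {
        ("red", "orange"): (7.553, ".006", 0.463, 0.26, 0.83),
        ("red", "green"): (0.119, ".730", 1.27, 0.26, 6.71),
        ("orange", "green"): (2.182, ".140", 2.742, 0.54, 14.67),
    },
    Topic.SMOKING: {
        ("red", "orange"): (0.063, ".803", 1.238, 0.17, 10.06),
        ("red", "green"): (58.075, "<.001", 25.204, 7.67, 85.09),
        ("orange", "green"): (22.400, "<.001", 20.357, 2.40, 141.94),
    },
}

#: Published distribution of the number of modules used per participant
#: (the last bin is "six or more").
MODULE_COUNT_DISTRIBUTION: dict[int, int] = {0: 33, 1: 70, 2: 42, 3: 49, 4: 20, 5: 9, 6: 8}

#: 182 of 231 participants answered the 6-month appreciation questions.
N_APPRECIATION_RESPONDERS = 182
RESPONDER_PROB = N_APPRECIATION_RESPONDERS / N_PARTICIPANTS

#: ~80% of module users were last active within 16 weeks of getting access.
ENGAGEMENT_HORIZON_WEEKS = 16
ENGAGEMENT_WITHIN_HORIZON = 0.80

#: Appreciation summaries, (mean, sd) on the stated scale.
OVERALL_RATING_MEAN_SD = (7.5, 1.2)           # 1-10
MODULE_RATING_MEAN_SD: dict[str, tuple[float, float]] = {
    Topic.FATIGUE.value: (7.3, 1.3),
    Topic.RETURN_TO_WORK.value: (7.0, 1.3),
    Topic.MOOD.value: (7.5, 1.2),
    Topic.RELATIONSHIPS.value: (7.2, 0.8),
    Topic.PHYSICAL_ACTIVITY.value: (7.7, 1.1),
    Topic.DIET.value: (7.6, 1.0),
    Topic.SMOKING.value: (8.0, 1.3),
    RESIDUAL_MODULE: (6.4, 1.9),
}
SUBQUESTION_MEAN_SD: dict[str, tuple[float, float]] = {   # 1-5 scales
    "understandable": (4.3, 0.6),
    "useful": (3.7, 0.8),
    "personal_relevance": (3.2, 0.9),
    "recommendable": (3.9, 1.0),
}

#: Baseline demographic and clinical marginals of the cohort.
DEMOGRAPHIC_MARGINALS: dict[str, object] = {
    "female": 0.792,
    "age_mean_sd": (55.6, 11.5),
    "with_partner": 0.836,
    "bmi_mean_sd": (26.0, 5.0),
    "education": {"low": 0.329, "medium": 0.329, "high": 0.342},
    "working": 0.528,
    "cancer_type": {"breast": 0.701, "colon": 0.126, "other": 0.173},
    "treatment": {
        "surgery_chemo_radio": 0.372,
        "surgery_chemo": 0.264,
        "surgery_radio": 0.199,
        "other": 0.165,
    },
    "weeks_since_treatment_mean_sd": (25.1, 13.5),
    "comorbidities": 0.268,
    "aftercare": 0.628,
}
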