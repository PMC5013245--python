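"""Synthetic cohort generator calibrated to the published KNW aggregates.

No individual-level data of the KNW process evaluation are deposited, so all
downstream stages are exercised on synthetic cohorts whose *aggregate*
structure matches the published one:

* per-topic referral-color marginals match the published color distribution;
* module use is Bernoulli conditional on the received color, with the
  published conditional-use probabilities;
* screening profiles are generated **score-first**: target colors are drawn
  from the marginals and instrument scores are then sampled uniformly from
  the preimage of each color under the classification rules, so
  ``classify_all`` on the generated profile returns exactly the drawn colors;
* demographics match the published baseline marginals;
* appreciation ratings are truncated-normal (moment-matched to the published
  mean/SD, rounded to scale integers) with dropout at the published
  responder rate;
* ~80% of module users have their last module activity within 16 weeks of
  access (geometric last-activity week).

Topics are sampled independently by default; a Gaussian-copula correlation
hook (``topic_correlation``) exists but is off, because only marginals and
per-topic conditionals are published.  Everything is reproducible from the
config seed and the generator is deterministic event-by-event, so identical
configs yield byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import fsolve
from scipy.special import ndtr, ndtri

from . import reference
from .adherence import round_half_away
from .engine import (
    MODULES,
    RESIDUAL_MODULE,
    TOPICS,
    MRAColor,
    MRACutoffs,
    MRAProfile,
    Topic,
    classify_all,
)
from .instruments import (
    DietProfile,
    PAProfile,
    ScreeningProfile,
    SmokingStatus,
)
from .usage import AppreciationRecord, ModuleUsageLog, UsageEvent

__all__ = [
    "CohortConfig",
    "Demographics",
    "SyntheticParticipant",
    "sample_screening_profile",
    "simulate_cohort",
]

_COLOR_ORDER = ("green", "orange", "red")


def _normalized_color_marginals() -> dict[Topic, dict[str, float]]:
    out: dict[Topic, dict[str, float]] = {}
    for topic, pct in reference.MRA_COLOR_PCT.items():
        total = sum(pct.values())
        out[topic] = {c: pct[c] / total for c in _COLOR_ORDER}
    return out


def _default_conditional_use() -> dict[Topic, dict[str, float]]:
    return {
        t: {c: p / 100.0 for c, p in d.items()}
        for t, d in reference.MODULE_USE_GIVEN_COLOR_PCT.items()
    }


def _default_appreciation_params() -> dict[str, object]:
    return {
        "overall": reference.OVERALL_RATING_MEAN_SD,
        "modules": dict(reference.MODULE_RATING_MEAN_SD),
        "subquestions": dict(reference.SUBQUESTION_MEAN_SD),
    }


@dataclass
class CohortConfig:
    """Calibration of the synthetic cohort.

    Defaults reproduce the published study conditions: N=231, published
    color marginals (normalised to sum to 1), published conditional-use
    probabilities, published demographic marginals, appreciation means/SDs
    and responder rate, and the 80%-within-16-weeks engagement pattern.
    """

    n_participants: int = reference.N_PARTICIPANTS
    color_marginals: dict[Topic, dict[str, float]] = field(
        default_factory=_normalized_color_marginals
    )
    conditional_use: dict[Topic, dict[str, float]] = field(
        default_factory=_default_conditional_use
    )
    residual_module_use_prob: float = reference.RESIDUAL_MODULE_USE_PROB
    demographic_marginals: dict[str, object] = field(
        default_factory=lambda: dict(reference.DEMOGRAPHIC_MARGINALS)
    )
    appreciation_params: dict[str, object] = field(
        default_factory=_default_appreciation_params
    )
    responder_prob: float = reference.RESPONDER_PROB
    engagement_horizon_weeks: int = reference.ENGAGEMENT_HORIZON_WEEKS
    engagement_within_horizon: float = reference.ENGAGEMENT_WITHIN_HORIZON
    pages_per_module: int = 10
    partial_visit_prob: float = 0.3
    topic_correlation: np.ndarray | None = None   # Gaussian-copula hook, off
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.pages_per_module < 3:
            raise ValueError("pages_per_module must be >= 3 (first-three-pages rule)")
        for topic in TOPICS:
            triple = self.color_marginals[topic]
            s = sum(triple.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"color marginals for {topic.value} sum to {s}, not 1"
                )
            for c, p in triple.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"marginal P({topic.value}={c}) = {p} not in [0,1]")
            for c, p in self.conditional_use[topic].items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"conditional use P(use|{topic.value}={c}) = {p} not in [0,1]"
                    )
        for name, p in (
            ("residual_module_use_prob", self.residual_module_use_prob),
            ("responder_prob", self.responder_prob),
            ("engagement_within_horizon", self.engagement_within_horizon),
            ("partial_visit_prob", self.partial_visit_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p} not in [0,1]")
        if self.engagement_horizon_weeks < 0:
            raise ValueError("engagement_horizon_weeks must be >= 0")
        if self.topic_correlation is not None:
            m = np.asarray(self.topic_correlation, dtype=float)
            if m.shape != (len(TOPICS), len(TOPICS)):
                raise ValueError("topic_correlation must be 7x7")

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_participants": self.n_participants,
            "seed": self.seed,
            "color_marginals": {
                t.value: dict(self.color_marginals[t]) for t in TOPICS
            },
            "conditional_use": {
                t.value: dict(self.conditional_use[t]) for t in TOPICS
            },
            "residual_module_use_prob": self.residual_module_use_prob,
            "responder_prob": self.responder_prob,
            "engagement_horizon_weeks": self.engagement_horizon_weeks,
            "engagement_within_horizon": self.engagement_within_horizon,
            "pages_per_module": self.pages_per_module,
            "partial_visit_prob": self.partial_visit_prob,
            "appreciation_params": {
                "overall": list(self.appreciation_params["overall"]),
                "modules": {
                    m: list(v)
                    for m, v in self.appreciation_params["modules"].items()
                },
                "subquestions": {
                    q: list(v)
                    for q, v in self.appreciation_params["subquestions"].items()
                },
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        doc = yaml.safe_load(Path(path).read_text())
        cfg = cls()
        for key in (
            "n_participants",
            "seed",
            "residual_module_use_prob",
            "responder_prob",
            "engagement_horizon_weeks",
            "engagement_within_horizon",
            "pages_per_module",
            "partial_visit_prob",
        ):
            if key in doc:
                setattr(cfg, key, doc[key])
        if "color_marginals" in doc:
            cfg.color_marginals = {
                Topic(t): dict(v) for t, v in doc["color_marginals"].items()
            }
        if "conditional_use" in doc:
            cfg.conditional_use = {
                Topic(t): dict(v) for t, v in doc["conditional_use"].items()
            }
        if "appreciation_params" in doc:
            ap = doc["appreciation_params"]
            cfg.appreciation_params = {
                "overall": tuple(ap["overall"]),
                "modules": {m: tuple(v) for m, v in ap["modules"].items()},
                "subquestions": {q: tuple(v) for q, v in ap["subquestions"].items()},
            }
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class Demographics:
    female: bool
    age: float
    with_partner: bool
    bmi: float
    education: str
    working: bool
    cancer_type: str
    treatment: str
    weeks_since_treatment: float
    comorbidities: bool
    aftercare: bool

    def as_dict(self) -> dict[str, object]:
        return {
            "female": self.female,
            "age": self.age,
            "with_partner": self.with_partner,
            "bmi": self.bmi,
            "education": self.education,
            "working": self.working,
            "cancer_type": self.cancer_type,
            "treatment": self.treatment,
            "weeks_since_treatment": self.weeks_since_treatment,
            "comorbidities": self.comorbidities,
            "aftercare": self.aftercare,
        }


@dataclass(frozen=True)
class SyntheticParticipant:
    participant_id: str
    demographics: Demographics
    screening: ScreeningProfile
    mra: MRAProfile
    usage: ModuleUsageLog
    appreciation: AppreciationRecord


# --------------------------------------------------------------------------
# score-first profile sampling: uniform draws from color preimages
# --------------------------------------------------------------------------

def _sample_mood_scores(
    target: MRAColor, rng: np.random.Generator, cut: MRACutoffs
) -> tuple[int, int, int]:
    elev, sev, mac_elev = cut.hads_elevated_min, cut.hads_severe_min, cut.mac_elevated_min
    if target is MRAColor.GREEN:
        return (
            int(rng.integers(0, elev)),
            int(rng.integers(0, elev)),
            int(rng.integers(16, mac_elev)),
        )
    if target is MRAColor.ORANGE:
        # below severe on both subscales, but elevated somewhere (rejection)
        while True:
            a = int(rng.integers(0, sev))
            d = int(rng.integers(0, sev))
            mac = int(rng.integers(16, 65))
            if a >= elev or d >= elev or mac >= mac_elev:
                return a, d, mac
    while True:  # red: at least one severe subscale
        a = int(rng.integers(0, 22))
        d = int(rng.integers(0, 22))
        if a >= sev or d >= sev:
            return a, d, int(rng.integers(16, 65))


def sample_screening_profile(
    topic_color_targets: Mapping[Topic, MRAColor],
    rng: np.random.Generator,
    cutoffs: MRACutoffs | None = None,
) -> ScreeningProfile:
    """Draw a screening profile uniformly from the preimage of target colors.

    The returned profile classifies to exactly the requested colors
    (round-trip identity with :func:`~knwtriage.engine.classify_all`); every
    color has a non-empty preimage under the default cut-offs.
    """
    cut = cutoffs or MRACutoffs()
    t = topic_color_targets

    # fatigue: item-consistent scores 8..56 partitioned by the two cut-offs
    c = t[Topic.FATIGUE]
    if c is MRAColor.GREEN:
        cis = int(rng.integers(8, cut.fatigue_orange_min))
    elif c is MRAColor.ORANGE:
        cis = int(rng.integers(cut.fatigue_orange_min, cut.fatigue_red_min))
    else:
        cis = int(rng.integers(cut.fatigue_red_min, 57))

    c = t[Topic.RETURN_TO_WORK]
    if c is MRAColor.GREEN:
        work_total = int(rng.integers(0, cut.work_orange_min))
    elif c is MRAColor.ORANGE:
        work_total = int(rng.integers(cut.work_orange_min, cut.work_red_min))
    else:
        work_total = int(rng.integers(cut.work_red_min, 21))
    work_no_needs = work_total == 0

    hads_a, hads_d, mac = _sample_mood_scores(t[Topic.MOOD], rng, cut)

    c = t[Topic.RELATIONSHIPS]
    g_max, r_min = cut.ssl_green_max, cut.ssl_red_min
    if c is MRAColor.GREEN:
        # low discrepancy (any needs flag) or high discrepancy without needs
        combos = [(s, needs) for s in range(6, g_max + 1) for needs in (False, True)]
        combos += [(s, False) for s in range(g_max + 1, 25)]
        ssl, casun = combos[int(rng.integers(0, len(combos)))]
    elif c is MRAColor.ORANGE:
        ssl, casun = int(rng.integers(g_max + 1, r_min)), True
    else:
        ssl, casun = int(rng.integers(r_min, 25)), True

    c = t[Topic.PHYSICAL_ACTIVITY]
    wk_min, d_min = cut.pa_weekly_minutes_min, cut.pa_days_min
    hi_min = lambda: float(rng.integers(int(wk_min), int(wk_min) * 4 + 1))
    lo_min = lambda: float(rng.integers(0, int(wk_min)))
    hi_day = lambda: int(rng.integers(d_min, 8))
    lo_day = lambda: int(rng.integers(0, d_min))
    if c is MRAColor.GREEN:
        pa = PAProfile(hi_min(), hi_day())
    elif c is MRAColor.ORANGE:
        if rng.random() < 0.5:
            pa = PAProfile(hi_min(), lo_day())
        else:
            pa = PAProfile(lo_min(), hi_day())
    else:
        pa = PAProfile(lo_min(), lo_day())

    c = t[Topic.DIET]
    if c is MRAColor.GREEN:
        met = int(rng.integers(cut.diet_green_min_conditions, 6))
    elif c is MRAColor.ORANGE:
        met = int(
            rng.integers(cut.diet_red_max_conditions + 1, cut.diet_green_min_conditions)
        )
    else:
        met = int(rng.integers(0, cut.diet_red_max_conditions + 1))
    th = cut.diet_thresholds
    thresholds = (
        th.vegetables_g_per_day,
        th.fruit_pieces_per_day,
        th.fish_servings_per_week,
        th.wholegrain_g_per_day,
        th.starch_servings_per_day,
    )
    which = rng.permutation(5)[:met]
    vals = []
    for i, thr in enumerate(thresholds):
        if i in which:
            vals.append(float(thr) * (1.0 + float(rng.random())))   # >= threshold
        else:
            vals.append(float(thr) * float(rng.random()) * 0.99)    # < threshold
    diet = DietProfile(*vals)

    c = t[Topic.SMOKING]
    if c is MRAColor.GREEN:
        smoking = (
            SmokingStatus.NEVER
            if rng.random() < 0.5
            else SmokingStatus.FORMER_QUIT_BEFORE_DIAGNOSIS
        )
    elif c is MRAColor.ORANGE:
        smoking = SmokingStatus.FORMER_QUIT_AFTER_DIAGNOSIS
    else:
        smoking = SmokingStatus.CURRENT

    return ScreeningProfile(
        cis_fatigue=cis,
        hads_a=hads_a,
        hads_d=hads_d,
        mac_neg=mac,
        ssl_d=ssl,
        casun_relationship_needs=casun,
        work_needs_total=work_total,
        work_no_needs=work_no_needs,
        pa=pa,
        diet=diet,
        smoking=smoking,
    )


# --------------------------------------------------------------------------
# appreciation: moment-matched truncated normal, rounded to scale integers
# --------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _matched_truncnorm(
    target_mean: float, target_sd: float, lo: float, hi: float
) -> tuple[float, float, float, float]:
    """Parent (mu, sigma) such that the [lo,hi]-truncated normal, *rounded to
    scale integers*, has the target mean and SD; returns
    (mu, sigma, Phi(alpha), Phi(beta)).

    Matching the discretised distribution (not the continuous one) is what
    reproduces the published statistics: those are sample moments of integer
    ratings, and rounding both shifts the mean near the scale bounds and
    inflates the SD.
    """
    ks = np.arange(int(lo), int(hi) + 1, dtype=float)
    upper = np.clip(ks + 0.5, lo, hi)
    lower = np.clip(ks - 0.5, lo, hi)

    def moments(mu: float, sigma: float) -> tuple[float, float]:
        z = ndtr((hi - mu) / sigma) - ndtr((lo - mu) / sigma)
        pmf = (ndtr((upper - mu) / sigma) - ndtr((lower - mu) / sigma)) / z
        mean = float(np.dot(ks, pmf))
        var = float(np.dot(ks * ks, pmf)) - mean * mean
        return mean, math.sqrt(max(var, 1e-12))

    def resid(x: np.ndarray) -> np.ndarray:
        mu, log_sigma = x
        m, s = moments(mu, math.exp(log_sigma))
        return np.array([m - target_mean, s - target_sd])

    sol, info, ier, _ = fsolve(
        resid, np.array([target_mean, math.log(target_sd)]), full_output=True
    )
    if ier == 1:
        mu, sigma = float(sol[0]), float(math.exp(sol[1]))
    else:  # no exact match (should not occur for the published scales)
        mu, sigma = target_mean, target_sd
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return mu, sigma, float(ndtr(a)), float(ndtr(b))


def _draw_rating(
    rng: np.random.Generator, mean_sd: tuple[float, float], lo: int, hi: int
) -> int:
    mu, sigma, pa, pb = _matched_truncnorm(mean_sd[0], mean_sd[1], float(lo), float(hi))
    u = float(rng.random())
    x = mu + sigma * float(ndtri(pa + u * (pb - pa)))
    return min(hi, max(lo, round_half_away(x)))


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

def _sample_colors(
    config: CohortConfig, n: int, rng: np.random.Generator
) -> dict[Topic, np.ndarray]:
    """Vectorised per-topic color draws (independent, or Gaussian copula)."""
    if config.topic_correlation is None:
        u = rng.random((n, len(TOPICS)))
    else:
        cov = np.asarray(config.topic_correlation, dtype=float)
        z = rng.multivariate_normal(np.zeros(len(TOPICS)), cov, size=n)
        u = ndtr(z)
    out: dict[Topic, np.ndarray] = {}
    for j, topic in enumerate(TOPICS):
        probs = np.array([config.color_marginals[topic][c] for c in _COLOR_ORDER])
        edges = np.cumsum(probs)
        out[topic] = np.searchsorted(edges, u[:, j], side="right").clip(0, 2)
    return out


def _geometric_p(within: float, horizon: int) -> float:
    """Success probability of a week-0-based geometric with
    P(week <= horizon) = within."""
    return 1.0 - (1.0 - within) ** (1.0 / (horizon + 1))


def _sample_demographics(
    marg: Mapping[str, object], rng: np.random.Generator
) -> Demographics:
    def cat(d: Mapping[str, float]) -> str:
        keys = list(d)
        probs = np.array([d[k] for k in keys], dtype=float)
        probs = probs / probs.sum()
        return keys[int(rng.choice(len(keys), p=probs))]

    def norm(mean_sd: tuple[float, float], lo: float, hi: float) -> float:
        m, s = mean_sd
        return round(float(np.clip(rng.normal(m, s), lo, hi)), 1)

    return Demographics(
        female=bool(rng.random() < marg["female"]),
        age=norm(marg["age_mean_sd"], 18.0, 95.0),
        with_partner=bool(rng.random() < marg["with_partner"]),
        bmi=norm(marg["bmi_mean_sd"], 15.0, 60.0),
        education=cat(marg["education"]),
        working=bool(rng.random() < marg["working"]),
        cancer_type=cat(marg["cancer_type"]),
        treatment=cat(marg["treatment"]),
        weeks_since_treatment=norm(marg["weeks_since_treatment_mean_sd"], 0.0, 120.0),
        comorbidities=bool(rng.random() < marg["comorbidities"]),
        aftercare=bool(rng.random() < marg["aftercare"]),
    )


def simulate_cohort(config: CohortConfig) -> list[SyntheticParticipant]:
    """Generate a full synthetic cohort from a validated config.

    Profiles are generated score-first (colors drawn from the marginals,
    scores sampled from the color preimages), so ``participant.mra`` always
    equals ``classify_all(participant.screening)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    color_idx = _sample_colors(config, n, rng)
    p_geom = _geometric_p(
        config.engagement_within_horizon, config.engagement_horizon_weeks
    )
    ap = config.appreciation_params
    participants: list[SyntheticParticipant] = []
    width = max(4, len(str(n)))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        demo = _sample_demographics(config.demographic_marginals, rng)
        targets = {
            topic: MRAColor[_COLOR_ORDER[color_idx[topic][i]].upper()]
            for topic in TOPICS
        }
        screening = sample_screening_profile(targets, rng)
        mra = classify_all(screening)

        use: dict[str, bool] = {}
        for topic in TOPICS:
            p_use = config.conditional_use[topic][targets[topic].value]
            use[topic.value] = bool(rng.random() < p_use)
        use[RESIDUAL_MODULE] = bool(rng.random() < config.residual_module_use_prob)

        events: list[UsageEvent] = []
        used_modules = [m for m in MODULES if use[m]]
        if used_modules:
            u = float(rng.random())
            last_week = int(math.floor(math.log1p(-u) / math.log1p(-p_geom)))
            weeks = [int(rng.integers(0, last_week + 1)) for _ in used_modules]
            weeks[int(rng.integers(0, len(used_modules)))] = last_week
            for m, wk in zip(used_modules, weeks):
                n_pages = int(rng.integers(3, config.pages_per_module + 1))
                events.extend(
                    UsageEvent(module=m, page=p, week=wk)
                    for p in range(1, n_pages + 1)
                )
        for m in MODULES:
            if not use[m] and rng.random() < config.partial_visit_prob:
                # glanced at the module but stopped before the third page
                n_pages = int(rng.integers(1, 3))
                wk = int(rng.integers(0, config.engagement_horizon_weeks + 1))
                events.extend(
                    UsageEvent(module=m, page=p, week=wk)
                    for p in range(1, n_pages + 1)
                )
        log = ModuleUsageLog(participant_id=pid, events=tuple(events))

        if rng.random() < config.responder_prob:
            overall = _draw_rating(rng, ap["overall"], 1, 10)
            module_ratings = {
                m: (_draw_rating(rng, ap["modules"][m], 1, 10) if use[m] else None)
                for m in MODULES
            }
            sub = {
                q: _draw_rating(rng, ap["subquestions"][q], 1, 5)
                for q in ap["subquestions"]
            }
            appreciation = AppreciationRecord(
                participant_id=pid,
                overall_rating=overall,
                module_ratings=module_ratings,
                **sub,
            )
        else:
            appreciation = AppreciationRecord(
                participant_id=pid,
                overall_rating=None,
                module_ratings={m: None for m in MODULES},
                understandable=None,
                useful=None,
                personal_relevance=None,
                recommendable=None,
            )

        participants.append(
            SyntheticParticipant(
                participant_id=pid,
                demographics=demo,
                screening=screening,
                mra=mra,
                usage=log,
                appreciation=appreciation,
            )
        )
    return participants
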