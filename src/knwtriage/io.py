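"""File formats: participant CSV, usage-log JSONL, appreciation CSV.

Formats are deliberately plain text:

* **participants.csv** — one row per participant: demographics, subscale
  scores and lifestyle quantities.  The header is validated strictly and
  missing cells are rejected (the screening questionnaire enforced complete
  responses, so a gap indicates a corrupt file, not a skipped answer).
* **usage.jsonl** — one page-visit event per line:
  ``{"participant_id": ..., "module": ..., "page": ..., "week": ...}``.
* **appreciation.csv** — one row per participant; missing ratings (dropout
  at follow-up) are explicit empty cells.

``write_cohort``/``read_cohort`` round-trip a synthetic cohort exactly:
floats are serialised with ``repr`` so parsing returns identical doubles.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

from .cohort import Demographics, SyntheticParticipant
from .engine import MODULES, classify_all
from .instruments import (
    DietProfile,
    PAProfile,
    ScreeningProfile,
    SmokingStatus,
)
from .usage import SUBQUESTIONS, AppreciationRecord, ModuleUsageLog, UsageEvent

__all__ = [
    "PARTICIPANT_COLUMNS",
    "write_participants_csv",
    "read_participants_csv",
    "write_usage_jsonl",
    "read_usage_jsonl",
    "write_appreciation_csv",
    "read_appreciation_csv",
    "write_cohort",
    "read_cohort",
    "LoadedCohort",
]

_DEMOGRAPHIC_COLUMNS = [
    "female",
    "age",
    "with_partner",
    "bmi",
    "education",
    "working",
    "cancer_type",
    "treatment",
    "weeks_since_treatment",
    "comorbidities",
    "aftercare",
]

_SCREENING_COLUMNS = [
    "cis_fatigue",
    "hads_a",
    "hads_d",
    "mac_neg",
    "ssl_d",
    "casun_relationship_needs",
    "work_needs_total",
    "work_no_needs",
    "weekly_mvpa_minutes",
    "days_with_30min_moderate",
    "vegetables_g_per_day",
    "fruit_pieces_per_day",
    "fish_servings_per_week",
    "wholegrain_g_per_day",
    "starch_servings_per_day",
    "smoking_status",
]

PARTICIPANT_COLUMNS = ["participant_id"] + _DEMOGRAPHIC_COLUMNS + _SCREENING_COLUMNS

_APPRECIATION_COLUMNS = (
    ["participant_id", "overall_rating"]
    + [f"rating_{m}" for m in MODULES]
    + list(SUBQUESTIONS)
)


def _fmt(v: object) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_bool(s: str, column: str) -> bool:
    if s == "true":
        return True
    if s == "false":
        return False
    raise ValueError(f"column {column}: expected 'true'/'false', got {s!r}")


def _screening_row(p: ScreeningProfile) -> dict[str, object]:
    return {
        "cis_fatigue": p.cis_fatigue,
        "hads_a": p.hads_a,
        "hads_d": p.hads_d,
        "mac_neg": p.mac_neg,
        "ssl_d": p.ssl_d,
        "casun_relationship_needs": p.casun_relationship_needs,
        "work_needs_total": p.work_needs_total,
        "work_no_needs": p.work_no_needs,
        "weekly_mvpa_minutes": p.pa.weekly_mvpa_minutes,
        "days_with_30min_moderate": p.pa.days_with_30min_moderate,
        "vegetables_g_per_day": p.diet.vegetables_g_per_day,
        "fruit_pieces_per_day": p.diet.fruit_pieces_per_day,
        "fish_servings_per_week": p.diet.fish_servings_per_week,
        "wholegrain_g_per_day": p.diet.wholegrain_g_per_day,
        "starch_servings_per_day": p.diet.starch_servings_per_day,
        "smoking_status": p.smoking.value,
    }


def write_participants_csv(
    cohort: Sequence[SyntheticParticipant], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(PARTICIPANT_COLUMNS)
        for part in cohort:
            row = {"participant_id": part.participant_id}
            row.update(part.demographics.as_dict())
            row.update(_screening_row(part.screening))
            w.writerow([_fmt(row[c]) for c in PARTICIPANT_COLUMNS])


def read_participants_csv(
    path: str | Path,
) -> list[tuple[str, Demographics, ScreeningProfile]]:
    """Read and validate a participant CSV.

    Raises ``ValueError`` on an unexpected header or any missing cell.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != PARTICIPANT_COLUMNS:
            raise ValueError(
                f"unexpected participant CSV header: {header!r}; "
                f"expected {PARTICIPANT_COLUMNS!r}"
            )
        out = []
        for lineno, raw in enumerate(reader, start=2):
            if len(raw) != len(PARTICIPANT_COLUMNS):
                raise ValueError(
                    f"line {lineno}: expected {len(PARTICIPANT_COLUMNS)} cells, "
                    f"got {len(raw)}"
                )
            row = dict(zip(PARTICIPANT_COLUMNS, raw))
            for col, cell in row.items():
                if cell == "":
                    raise ValueError(f"line {lineno}: missing value in column {col!r}")
            demo = Demographics(
                female=_parse_bool(row["female"], "female"),
                age=float(row["age"]),
                with_partner=_parse_bool(row["with_partner"], "with_partner"),
                bmi=float(row["bmi"]),
                education=row["education"],
                working=_parse_bool(row["working"], "working"),
                cancer_type=row["cancer_type"],
                treatment=row["treatment"],
                weeks_since_treatment=float(row["weeks_since_treatment"]),
                comorbidities=_parse_bool(row["comorbidities"], "comorbidities"),
                aftercare=_parse_bool(row["aftercare"], "aftercare"),
            )
            profile = ScreeningProfile(
                cis_fatigue=int(row["cis_fatigue"]),
                hads_a=int(row["hads_a"]),
                hads_d=int(row["hads_d"]),
                mac_neg=int(row["mac_neg"]),
                ssl_d=int(row["ssl_d"]),
                casun_relationship_needs=_parse_bool(
                    row["casun_relationship_needs"], "casun_relationship_needs"
                ),
                work_needs_total=int(row["work_needs_total"]),
                work_no_needs=_parse_bool(row["work_no_needs"], "work_no_needs"),
                pa=PAProfile(
                    weekly_mvpa_minutes=float(row["weekly_mvpa_minutes"]),
                    days_with_30min_moderate=int(row["days_with_30min_moderate"]),
                ),
                diet=DietProfile(
                    vegetables_g_per_day=float(row["vegetables_g_per_day"]),
                    fruit_pieces_per_day=float(row["fruit_pieces_per_day"]),
                    fish_servings_per_week=float(row["fish_servings_per_week"]),
                    wholegrain_g_per_day=float(row["wholegrain_g_per_day"]),
                    starch_servings_per_day=float(row["starch_servings_per_day"]),
                ),
                smoking=SmokingStatus(row["smoking_status"]),
            )
            out.append((row["participant_id"], demo, profile))
    return out


def write_usage_jsonl(
    logs: Sequence[ModuleUsageLog], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for log in logs:
            for ev in log.events:
                fh.write(
                    json.dumps(
                        {
                            "participant_id": log.participant_id,
                            "module": ev.module,
                            "page": ev.page,
                            "week": ev.week,
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )


def read_usage_jsonl(
    path: str | Path, participant_ids: Sequence[str]
) -> list[ModuleUsageLog]:
    """Read a usage-log JSONL and group events per participant.

    ``participant_ids`` fixes the cohort (participants without events get an
    empty log); an event for an unknown participant raises.
    """
    events: dict[str, list[UsageEvent]] = {pid: [] for pid in participant_ids}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            missing = {"participant_id", "module", "page", "week"} - obj.keys()
            if missing:
                raise ValueError(f"line {lineno}: missing fields {sorted(missing)}")
            pid = obj["participant_id"]
            if pid not in events:
                raise ValueError(f"line {lineno}: unknown participant {pid!r}")
            events[pid].append(
                UsageEvent(module=obj["module"], page=obj["page"], week=obj["week"])
            )
    return [
        ModuleUsageLog(participant_id=pid, events=tuple(events[pid]))
        for pid in participant_ids
    ]


def write_appreciation_csv(
    records: Sequence[AppreciationRecord], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_APPRECIATION_COLUMNS)
        for r in records:
            row = [r.participant_id, r.overall_rating]
            row += [r.module_ratings.get(m) for m in MODULES]
            row += [getattr(r, q) for q in SUBQUESTIONS]
            w.writerow(["" if v is None else _fmt(v) for v in row])


def read_appreciation_csv(path: str | Path) -> list[AppreciationRecord]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _APPRECIATION_COLUMNS:
            raise ValueError(
                f"unexpected appreciation CSV header: {header!r}"
            )
        out = []
        for raw in reader:
            row = dict(zip(_APPRECIATION_COLUMNS, raw))

            def opt_int(cell: str) -> int | None:
                return None if cell == "" else int(cell)

            out.append(
                AppreciationRecord(
                    participant_id=row["participant_id"],
                    overall_rating=opt_int(row["overall_rating"]),
                    module_ratings={
                        m: opt_int(row[f"rating_{m}"]) for m in MODULES
                    },
                    **{q: opt_int(row[q]) for q in SUBQUESTIONS},
                )
            )
    return out


class LoadedCohort:
    """A cohort reassembled from its three files.

    Referral advice is recomputed from the screening profiles with
    ``classify_all`` (the advice is a deterministic function of the scores,
    so it is never serialised).
    """

    def __init__(
        self,
        participants: list[tuple[str, Demographics, ScreeningProfile]],
        logs: list[ModuleUsageLog],
        appreciation: list[AppreciationRecord],
    ) -> None:
        self.participant_ids = [pid for pid, _, _ in participants]
        self.demographics = {pid: d for pid, d, _ in participants}
        self.screening = {pid: s for pid, _, s in participants}
        self.mra = {pid: classify_all(s) for pid, _, s in participants}
        self.usage = {log.participant_id: log for log in logs}
        self.appreciation = {r.participant_id: r for r in appreciation}


def write_cohort(
    cohort: Sequence[SyntheticParticipant], outdir: str | Path
) -> dict[str, Path]:
    """Write participants.csv, usage.jsonl and appreciation.csv into outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": outdir / "participants.csv",
        "usage": outdir / "usage.jsonl",
        "appreciation": outdir / "appreciation.csv",
    }
    write_participants_csv(cohort, paths["participants"])
    write_usage_jsonl([p.usage for p in cohort], paths["usage"])
    write_appreciation_csv([p.appreciation for p in cohort], paths["appreciation"])
    return paths


def read_cohort(outdir: str | Path) -> LoadedCohort:
    outdir = Path(outdir)
    participants = read_participants_csv(outdir / "participants.csv")
    logs = read_usage_jsonl(
        outdir / "usage.jsonl", [pid for pid, _, _ in participants]
    )
    appreciation = read_appreciation_csv(outdir / "appreciation.csv")
    return LoadedCohort(participants, logs, appreciation)
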