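"""Report-corpus data model and I/O.

A corpus is a collection of patients, each with an ordered list of dated
free-text radiology reports and a right-censored survival outcome
(follow-up time in months, death indicator).  The on-disk formats are
long-format: one row per report with the patient outcome repeated on
every row.  JSONL is the canonical format because free text contains
commas and newlines; CSV (RFC-4180 quoted) is provided for convenience.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "Report",
    "SurvivalOutcome",
    "PatientRecord",
    "Cohort",
    "read_corpus",
    "write_corpus",
    "split_cohort",
    "CorpusParseError",
]

_COLUMNS = ["patient_id", "date", "text", "time_months", "event"]


class CorpusParseError(ValueError):
    """Raised when a corpus file is malformed (names the offending line)."""


@dataclass(frozen=True)
class Report:
    """One dated free-text radiology report."""

    patient_id: str
    date: _dt.date
    text: str

    def __post_init__(self) -> None:
        if not isinstance(self.date, _dt.date):
            object.__setattr__(self, "date", _dt.date.fromisoformat(str(self.date)))
        if not self.text or not self.text.strip():
            raise ValueError(f"report for patient {self.patient_id!r} has empty text")


@dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored survival outcome: follow-up in months, death indicator."""

    time: float  # months, >= 0
    event: int  # 1 = death observed, 0 = censored/alive

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"time must be finite and >= 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")
        object.__setattr__(self, "time", float(self.time))
        object.__setattr__(self, "event", int(self.event))


@dataclass(frozen=True)
class PatientRecord:
    """All serial reports of one patient plus their survival outcome.

    Reports are stored in ascending date order (stable for ties).
    """

    patient_id: str
    reports: tuple[Report, ...]
    outcome: SurvivalOutcome

    def __post_init__(self) -> None:
        reports = tuple(sorted(self.reports, key=lambda r: r.date))
        if not reports:
            raise ValueError(f"patient {self.patient_id!r} has no reports")
        for r in reports:
            if r.patient_id != self.patient_id:
                raise ValueError(
                    f"report patient_id {r.patient_id!r} != record {self.patient_id!r}"
                )
        object.__setattr__(self, "reports", reports)

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def first_report(self) -> Report:
        return self.reports[0]


@dataclass(frozen=True)
class Cohort:
    """A named collection of patient records with unique patient ids."""

    records: tuple[PatientRecord, ...]
    name: str = "cohort"

    def __post_init__(self) -> None:
        records = tuple(self.records)
        ids = [r.patient_id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_ids in cohort: {dup[:5]}")
        object.__setattr__(self, "records", records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def times(self) -> np.ndarray:
        return np.array([r.outcome.time for r in self.records], dtype=float)

    def events(self) -> np.ndarray:
        return np.array([r.outcome.event for r in self.records], dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.events().sum())

    def subset(self, patient_ids, name: str | None = None) -> "Cohort":
        wanted = set(patient_ids)
        recs = tuple(r for r in self.records if r.patient_id in wanted)
        return Cohort(recs, name=name or self.name)

    def renamed(self, name: str) -> "Cohort":
        return replace(self, name=name)


def _rows_to_cohort(rows, name: str) -> Cohort:
    """Group long-format rows (one per report) into patient records."""
    by_patient: dict[str, list[dict]] = {}
    order: list[str] = []
    for row in rows:
        pid = row["patient_id"]
        if pid not in by_patient:
            by_patient[pid] = []
            order.append(pid)
        by_patient[pid].append(row)
    records = []
    for pid in order:
        rows_p = by_patient[pid]
        outcomes = {(float(r["time_months"]), int(r["event"])) for r in rows_p}
        if len(outcomes) > 1:
            raise CorpusParseError(
                f"patient {pid!r} has conflicting outcomes: {sorted(outcomes)}"
            )
        time, event = next(iter(outcomes))
        reports = tuple(
            Report(patient_id=pid, date=r["date"], text=r["text"]) for r in rows_p
        )
        records.append(
            PatientRecord(pid, reports, SurvivalOutcome(time=time, event=event))
        )
    return Cohort(tuple(records), name=name)


def _validate_row(obj: dict, where: str) -> dict:
    for key in _COLUMNS:
        if key not in obj or obj[key] is None or obj[key] == "":
            raise CorpusParseError(f"{where}: missing field {key!r}")
    try:
        time = float(obj["time_months"])
    except (TypeError, ValueError) as exc:
        raise CorpusParseError(f"{where}: unparseable time_months") from exc
    if not np.isfinite(time) or time < 0:
        raise CorpusParseError(f"{where}: negative or non-finite time_months {time}")
    try:
        event = int(obj["event"])
    except (TypeError, ValueError) as exc:
        raise CorpusParseError(f"{where}: unparseable event") from exc
    if event not in (0, 1):
        raise CorpusParseError(f"{where}: event must be 0/1, got {obj['event']!r}")
    try:
        date = _dt.date.fromisoformat(str(obj["date"]))
    except ValueError as exc:
        raise CorpusParseError(f"{where}: date not ISO-8601: {obj['date']!r}") from exc
    return {
        "patient_id": str(obj["patient_id"]),
        "date": date,
        "text": str(obj["text"]),
        "time_months": time,
        "event": event,
    }


def read_corpus(path, format: str = "jsonl", name: str | None = None) -> Cohort:
    """Read a long-format report corpus from JSONL or CSV.

    Each row/object carries ``patient_id, date, text, time_months, event``;
    rows of one patient are grouped into a record and sorted by date.
    Conflicting outcomes for one patient raise :class:`CorpusParseError`.
    """
    path = str(path)
    rows: list[dict] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusParseError(f"{path}:{lineno}: invalid JSON") from exc
                rows.append(_validate_row(obj, f"{path}:{lineno}"))
    elif format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise CorpusParseError(f"{path}: missing columns {missing}")
        for i, row in enumerate(df.to_dict("records"), start=2):
            rows.append(_validate_row(row, f"{path}:{i}"))
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    return _rows_to_cohort(rows, name=name or path)


def write_corpus(cohort: Cohort, path, format: str = "jsonl") -> None:
    """Write a cohort in long format: one row per report, outcome repeated."""
    path = str(path)
    rows = [
        {
            "patient_id": rec.patient_id,
            "date": rep.date.isoformat(),
            "text": rep.text,
            "time_months": rec.outcome.time,
            "event": rec.outcome.event,
        }
        for rec in cohort
        for rep in rec.reports
    ]
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    elif format == "csv":
        pd.DataFrame(rows, columns=_COLUMNS).to_csv(
            path, index=False, quoting=1  # QUOTE_ALL: free text holds commas/newlines
        )
    else:
        raise ValueError(f"unknown corpus format {format!r}")


def split_cohort(
    cohort: Cohort,
    test_fraction: float,
    seed: int,
    stratify: bool = True,
) -> tuple[Cohort, Cohort]:
    """Seeded train/test split of a cohort, stratified on event status.

    Stratification keeps the death proportion balanced between the splits
    to the granularity the group sizes allow.  Deterministic for a fixed
    seed; every patient lands in exactly one split.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    idx = np.arange(n)
    events = cohort.events()
    test_idx: list[int] = []
    if stratify:
        for value in (0, 1):
            group = idx[events == value]
            if len(group) == 0:
                continue
            k = int(round(test_fraction * len(group)))
            k = min(max(k, 1 if len(group) >= 2 else 0), len(group) - 1)
            chosen = rng.choice(group, size=k, replace=False)
            test_idx.extend(int(i) for i in chosen)
    else:
        k = int(round(test_fraction * n))
        test_idx = [int(i) for i in rng.choice(idx, size=k, replace=False)]
    test_set = set(test_idx)
    train_recs = tuple(r for i, r in enumerate(cohort) if i not in test_set)
    test_recs = tuple(r for i, r in enumerate(cohort) if i in test_set)
    return (
        Cohort(train_recs, name=f"{cohort.name}-train"),
        Cohort(test_recs, name=f"{cohort.name}-test"),
    )
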