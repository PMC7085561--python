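"""Offline record store for patients, sessions and sensor buffers.

Mirrors the app's entity model — person profiles, test sessions holding one
result per item, and buffered sensor traces referenced by path — in a single
versioned JSON document so records are human-diffable and need no server.
Writes are atomic (write-to-temp then rename) and every operation works
fully offline.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from datetime import date, datetime

from .battery import ItemResult
from .errors import IntegrityError, StoreLookupError, ValidationError

SCHEMA_VERSION = 1


def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    return datetime.strptime(str(value), "%Y-%m-%d").date()


@dataclass(frozen=True)
class Person:
    person_id: str
    birth_date: date
    sex: str  # female | male
    contact: str | None = None
    photo_ref: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "birth_date", _parse_date(self.birth_date))
        if self.sex not in ("female", "male"):
            raise ValidationError("sex must be 'female' or 'male'")
        if self.birth_date >= date.today():
            raise ValidationError("birth_date must be in the past")

    def age_on(self, when: date) -> float:
        """Age in whole years on a given date (derived, never stored)."""
        when = _parse_date(when)
        years = when.year - self.birth_date.year
        if (when.month, when.day) < (self.birth_date.month, self.birth_date.day):
            years -= 1
        return float(years)


@dataclass
class SessionRecord:
    session_id: str
    person_id: str
    date: date
    item_results: list[ItemResult] = field(default_factory=list)
    completed: bool = False

    def __post_init__(self) -> None:
        self.date = _parse_date(self.date)
        codes = [r.test_code for r in self.item_results]
        if len(codes) != len(set(codes)):
            raise ValidationError("at most one result per test item per session")


@dataclass(frozen=True)
class SensorBuffer:
    session_id: str
    test_code: str
    trace_ref: str


class JsonStore:
    """Single-file JSON document store keyed by entity id; upserts are
    idempotent and persist immediately."""

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        if os.path.exists(self.path):
            with open(self.path, encoding="utf-8") as fh:
                self._doc = json.load(fh)
            if self._doc.get("schema_version") != SCHEMA_VERSION:
                raise ValidationError(
                    f"unsupported store schema_version {self._doc.get('schema_version')!r}"
                )
        else:
            self._doc = {
                "schema_version": SCHEMA_VERSION,
                "persons": {},
                "sessions": {},
                "sensor_buffers": [],
            }

    # -- persistence --------------------------------------------------------
    def _flush(self) -> None:
        directory = os.path.dirname(self.path) or "."
        fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
        try:
            with os.fdopen(fd, "w", encoding="utf-8") as fh:
                json.dump(self._doc, fh, indent=2, sort_keys=True)
            os.replace(tmp, self.path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise

    # -- upserts ------------------------------------------------------------
    def upsert(self, entity) -> str:
        if isinstance(entity, Person):
            self._doc["persons"][entity.person_id] = {
                "person_id": entity.person_id,
                "birth_date": entity.birth_date.isoformat(),
                "sex": entity.sex,
                "contact": entity.contact,
                "photo_ref": entity.photo_ref,
            }
            key = entity.person_id
        elif isinstance(entity, SessionRecord):
            if entity.person_id not in self._doc["persons"]:
                raise IntegrityError(f"unknown person_id {entity.person_id!r}")
            self._doc["sessions"][entity.session_id] = {
                "session_id": entity.session_id,
                "person_id": entity.person_id,
                "date": entity.date.isoformat(),
                "completed": entity.completed,
                "results": [
                    {
                        "test_code": r.test_code,
                        "value": r.value,
                        "source": r.source,
                        "trace_ref": r.trace_ref,
                    }
                    for r in entity.item_results
                ],
            }
            key = entity.session_id
        elif isinstance(entity, SensorBuffer):
            if entity.session_id not in self._doc["sessions"]:
                raise IntegrityError(f"unknown session_id {entity.session_id!r}")
            record = {
                "session_id": entity.session_id,
                "test_code": entity.test_code,
                "trace_ref": entity.trace_ref,
            }
            buffers = self._doc["sensor_buffers"]
            for i, existing in enumerate(buffers):
                if (existing["session_id"], existing["test_code"]) == (
                    entity.session_id,
                    entity.test_code,
                ):
                    buffers[i] = record
                    break
            else:
                buffers.append(record)
            key = f"{entity.session_id}/{entity.test_code}"
        else:
            raise ValidationError(f"cannot store entity of type {type(entity).__name__}")
        self._flush()
        return key

    # -- queries ------------------------------------------------------------
    def get_person(self, person_id: str) -> Person:
        try:
            raw = self._doc["persons"][person_id]
        except KeyError:
            raise StoreLookupError(f"unknown person_id {person_id!r}") from None
        return Person(
            person_id=raw["person_id"],
            birth_date=raw["birth_date"],
            sex=raw["sex"],
            contact=raw.get("contact"),
            photo_ref=raw.get("photo_ref"),
        )

    def _session_from_raw(self, raw) -> SessionRecord:
        return SessionRecord(
            session_id=raw["session_id"],
            person_id=raw["person_id"],
            date=raw["date"],
            completed=raw["completed"],
            item_results=[
                ItemResult(
                    test_code=r["test_code"],
                    value=r["value"],
                    source=r["source"],
                    trace_ref=r.get("trace_ref"),
                )
                for r in raw["results"]
            ],
        )

    def get_session(self, session_id: str) -> SessionRecord:
        try:
            raw = self._doc["sessions"][session_id]
        except KeyError:
            raise StoreLookupError(f"unknown session_id {session_id!r}") from None
        return self._session_from_raw(raw)

    def history(self, person_id: str) -> list[SessionRecord]:
        """All sessions of a person, oldest first; the longitudinal series of
        any item can be read straight off the ordered results."""
        if person_id not in self._doc["persons"]:
            raise StoreLookupError(f"unknown person_id {person_id!r}")
        sessions = [
            self._session_from_raw(raw)
            for raw in self._doc["sessions"].values()
            if raw["person_id"] == person_id
        ]
        return sorted(sessions, key=lambda s: (s.date, s.session_id))

    def item_series(self, person_id: str, test_code: str) -> list[float]:
        series = []
        for session in self.history(person_id):
            for result in session.item_results:
                if result.test_code == test_code:
                    series.append(result.value)
        return series

    def export_long(self) -> list[dict]:
        """Long-format rows (person_id, session_date, test_code, value) — the
        shape the agreement statistics consume."""
        rows = []
        for raw in self._doc["sessions"].values():
            for r in raw["results"]:
                rows.append(
                    {
                        "person_id": raw["person_id"],
                        "session_date": raw["date"],
                        "test_code": r["test_code"],
                        "value": r["value"],
                    }
                )
        return sorted(rows, key=lambda r: (r["person_id"], r["session_date"], r["test_code"]))
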