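"""Longitudinal patient score registry.

Patients are identified by a unique IP index; each automatic assessment is a
timestamped session entry with its intelligibility/severity pair.  Histories
can be sorted chronologically or by score and filtered by date and score
ranges.  Persistence is two plain TSV tables (``patients.tsv``,
``sessions.tsv``) in a store directory; erasing a patient cascades to their
sessions.
"""

from __future__ import annotations

import csv
import datetime as dt
import pathlib
from dataclasses import dataclass

from .errors import ConflictError, NotFoundError, ReferentialError, ValidationError
from .regressor import ScorePair


@dataclass(frozen=True)
class PatientRecord:
    full_name: str
    ip_index: str
    birthdate: dt.date

    def __post_init__(self):
        if not self.ip_index:
            raise ValidationError("ip_index must be non-empty")
        if self.birthdate > dt.date.today():
            raise ValidationError(f"birthdate {self.birthdate} is in the future")


@dataclass(frozen=True)
class SessionEntry:
    entry_id: int
    ip_index: str
    timestamp: dt.datetime
    scores: ScorePair
    audio_ref: str | None = None

    def __post_init__(self):
        if self.timestamp.tzinfo is None:
            object.__setattr__(
                self, "timestamp", self.timestamp.replace(tzinfo=dt.timezone.utc)
            )
        else:
            object.__setattr__(
                self, "timestamp", self.timestamp.astimezone(dt.timezone.utc)
            )


class MonitorStore:
    """In-memory registry with TSV persistence."""

    def __init__(self):
        self._patients: dict[str, PatientRecord] = {}
        self._sessions: dict[int, SessionEntry] = {}
        self._next_id = 1

    # -- patients ---------------------------------------------------------

    def add_patient(self, rec: PatientRecord) -> None:
        if rec.ip_index in self._patients:
            raise ConflictError(f"patient with ip_index {rec.ip_index!r} already exists")
        self._patients[rec.ip_index] = rec

    def get_patient(self, ip_index: str) -> PatientRecord:
        try:
            return self._patients[ip_index]
        except KeyError:
            raise ReferentialError(f"no patient with ip_index {ip_index!r}") from None

    def list_patients(self) -> list[PatientRecord]:
        return sorted(self._patients.values(), key=lambda p: p.ip_index)

    def erase_patient(self, ip_index: str) -> None:
        """Remove a patient and, cascading, all of their sessions."""
        self.get_patient(ip_index)
        del self._patients[ip_index]
        self._sessions = {
            eid: e for eid, e in self._sessions.items() if e.ip_index != ip_index
        }

    # -- sessions ---------------------------------------------------------

    def record_session(
        self,
        ip_index: str,
        scores: ScorePair,
        timestamp: dt.datetime | None = None,
        audio_ref: str | None = None,
    ) -> SessionEntry:
        self.get_patient(ip_index)  # referential check
        entry = SessionEntry(
            entry_id=self._next_id,
            ip_index=ip_index,
            timestamp=timestamp or dt.datetime.now(dt.timezone.utc),
            scores=scores,
            audio_ref=audio_ref,
        )
        self._sessions[entry.entry_id] = entry
        self._next_id += 1
        return entry

    def history(
        self,
        ip_index: str,
        sort: str = "chronological",
        score_key: str = "intelligibility",
        date_from: dt.datetime | None = None,
        date_to: dt.datetime | None = None,
        score_min: float | None = None,
        score_max: float | None = None,
    ) -> list[SessionEntry]:
        """One patient's entries under a stable total order and conjunctive filters.

        ``sort`` is ``chronological`` or ``by_score`` (ascending on
        ``score_key``); ties always break by entry_id.
        """
        self.get_patient(ip_index)
        if sort not in ("chronological", "by_score"):
            raise ValidationError(f"unknown sort {sort!r}")
        if score_key not in ("intelligibility", "severity"):
            raise ValidationError(f"unknown score key {score_key!r}")

        def norm(ts):
            if ts is not None and ts.tzinfo is None:
                return ts.replace(tzinfo=dt.timezone.utc)
            return ts

        date_from, date_to = norm(date_from), norm(date_to)
        entries = [e for e in self._sessions.values() if e.ip_index == ip_index]
        if date_from is not None:
            entries = [e for e in entries if e.timestamp >= date_from]
        if date_to is not None:
            entries = [e for e in entries if e.timestamp <= date_to]
        if score_min is not None:
            entries = [e for e in entries if getattr(e.scores, score_key) >= score_min]
        if score_max is not None:
            entries = [e for e in entries if getattr(e.scores, score_key) <= score_max]
        if sort == "chronological":
            entries.sort(key=lambda e: (e.timestamp, e.entry_id))
        else:
            entries.sort(key=lambda e: (getattr(e.scores, score_key), e.entry_id))
        return entries

    def delete_measurement(self, entry_id: int) -> None:
        if entry_id not in self._sessions:
            raise NotFoundError(f"no session entry with id {entry_id}")
        del self._sessions[entry_id]

    # -- persistence ------------------------------------------------------

    def save(self, directory) -> None:
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "patients.tsv", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["ip_index", "full_name", "birthdate"])
            for p in self.list_patients():
                writer.writerow([p.ip_index, p.full_name, p.birthdate.isoformat()])
        with open(directory / "sessions.tsv", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(
                ["entry_id", "ip_index", "timestamp", "intelligibility", "severity", "audio_ref"]
            )
            for eid in sorted(self._sessions):
                e = self._sessions[eid]
                writer.writerow(
                    [
                        e.entry_id,
                        e.ip_index,
                        e.timestamp.isoformat(),
                        repr(e.scores.intelligibility),
                        repr(e.scores.severity),
                        e.audio_ref or "",
                    ]
                )

    @classmethod
    def load(cls, directory) -> "MonitorStore":
        directory = pathlib.Path(directory)
        store = cls()
        patients_path = directory / "patients.tsv"
        if not patients_path.exists():
            raise NotFoundError(f"no store at {directory}")
        with open(patients_path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                store.add_patient(
                    PatientRecord(
                        full_name=row["full_name"],
                        ip_index=row["ip_index"],
                        birthdate=dt.date.fromisoformat(row["birthdate"]),
                    )
                )
        sessions_path = directory / "sessions.tsv"
        if sessions_path.exists():
            with open(sessions_path, newline="") as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    entry = SessionEntry(
                        entry_id=int(row["entry_id"]),
                        ip_index=row["ip_index"],
                        timestamp=dt.datetime.fromisoformat(row["timestamp"]),
                        scores=ScorePair(
                            float(row["intelligibility"]), float(row["severity"])
                        ),
                        audio_ref=row["audio_ref"] or None,
                    )
                    if entry.ip_index not in store._patients:
                        raise ReferentialError(
                            f"session {entry.entry_id} references unknown patient "
                            f"{entry.ip_index!r}"
                        )
                    store._sessions[entry.entry_id] = entry
            if store._sessions:
                store._next_id = max(store._sessions) + 1
        return store

    def __eq__(self, other) -> bool:
        if not isinstance(other, MonitorStore):
            return NotImplemented
        return self._patients == other._patients and self._sessions == other._sessions
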