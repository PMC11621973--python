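"""Domain model for coded camera-trap observations of a canid social group.

A field study of this kind produces a stream of short (~30 s) video
recordings. Each recording is coded against a fixed ethogram into one or
more behavioural events; individuals are identified from coat markings, so
an event carries an actor (possibly the ``UNIDENTIFIED`` sentinel when
identification failed), an optional recipient for directed behaviours, and
the set of individuals co-detected in the same recording. The recording is
the unit of co-occurrence throughout the package: two individuals are
"associated" when they appear in the same recording.

This module defines the validated containers (:class:`Individual`,
:class:`ObservationEvent`, :class:`ObservationLog`), the ethogram, and CSV
round-tripping for the roster and event-log files.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "UNIDENTIFIED",
    "ETHOGRAM",
    "DIRECTED_BEHAVIOURS",
    "SEXES",
    "LIFE_STAGES",
    "SchemaError",
    "ValidationError",
    "Individual",
    "ObservationEvent",
    "ObservationLog",
    "normalise_behaviour",
    "read_event_log",
    "write_event_log",
    "restrict_log",
]

#: Sentinel actor code for a detection whose individual could not be identified.
UNIDENTIFIED = "UNIDENTIFIED"

SEXES = frozenset({"female", "male", "unknown"})
LIFE_STAGES = frozenset({"adult", "juvenile"})

#: The 13 ethogram behaviours. Only aggression and submission are directed
#: (actor -> recipient); everything else is undirected.
ETHOGRAM: tuple[str, ...] = (
    "solitary travel",
    "social travel",
    "solitary resting",
    "social resting",
    "solitary foraging/feeding",
    "social foraging/feeding",
    "solitary vocalisation",
    "social vocalisation",
    "scent marking",
    "scanning environment",
    "affiliation",
    "aggression",
    "submission",
)

DIRECTED_BEHAVIOURS = frozenset({"aggression", "submission"})

_ETHOGRAM_SET = frozenset(ETHOGRAM)


class SchemaError(ValueError):
    """A file or value does not conform to the expected schema."""


class ValidationError(ValueError):
    """A structurally well-formed record violates a domain invariant."""


def normalise_behaviour(label: str) -> str:
    """Normalise a behaviour label to its canonical ethogram form.

    Matching is case-insensitive after collapsing internal whitespace.
    Raises :class:`SchemaError` for labels outside the ethogram.
    """
    canon = " ".join(str(label).split()).lower()
    if canon not in _ETHOGRAM_SET:
        raise SchemaError(
            f"unknown behaviour label {label!r}; expected one of the "
            f"{len(ETHOGRAM)} ethogram behaviours"
        )
    return canon


@dataclass(frozen=True)
class Individual:
    """One group member: identity code, sex, life stage and group tenure."""

    id: str
    sex: str
    life_stage: str
    entry_date: dt.date
    exit_date: dt.date | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("individual id must be non-empty")
        if self.id == UNIDENTIFIED:
            raise ValidationError(f"{UNIDENTIFIED!r} is reserved as a sentinel")
        if self.sex not in SEXES:
            raise ValidationError(f"sex {self.sex!r} not in {sorted(SEXES)}")
        if self.life_stage not in LIFE_STAGES:
            raise ValidationError(
                f"life_stage {self.life_stage!r} not in {sorted(LIFE_STAGES)}"
            )
        if self.exit_date is not None and self.exit_date < self.entry_date:
            raise ValidationError(
                f"{self.id}: exit_date {self.exit_date} precedes entry_date "
                f"{self.entry_date}"
            )

    def present_on(self, day: dt.date) -> bool:
        """Whether this individual's tenure covers ``day``."""
        if day < self.entry_date:
            return False
        return self.exit_date is None or day <= self.exit_date


@dataclass(frozen=True)
class ObservationEvent:
    """One coded behavioural event within a recording."""

    recording_id: str
    timestamp: dt.datetime
    camera_id: str
    behaviour: str
    actor: str
    recipient: str | None = None
    present: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "behaviour", normalise_behaviour(self.behaviour))
        object.__setattr__(self, "present", frozenset(self.present))
        directed = self.behaviour in DIRECTED_BEHAVIOURS
        if directed and self.recipient is None:
            raise ValidationError(
                f"recording {self.recording_id}: directed behaviour "
                f"{self.behaviour!r} requires a recipient"
            )
        if not directed and self.recipient is not None:
            raise ValidationError(
                f"recording {self.recording_id}: undirected behaviour "
                f"{self.behaviour!r} must not carry a recipient"
            )
        if self.recipient is not None and self.recipient == self.actor:
            raise ValidationError(
                f"recording {self.recording_id}: actor and recipient coincide "
                f"({self.actor})"
            )
        if self.actor != UNIDENTIFIED and self.actor not in self.present:
            raise ValidationError(
                f"recording {self.recording_id}: identified actor {self.actor} "
                f"missing from the present set"
            )

    @property
    def directed(self) -> bool:
        return self.behaviour in DIRECTED_BEHAVIOURS

    def identified_participants(self) -> set[str]:
        ids = set(self.present) - {UNIDENTIFIED}
        if self.recipient is not None and self.recipient != UNIDENTIFIED:
            ids.add(self.recipient)
        return ids


def _event_sort_key(ev: ObservationEvent) -> tuple[dt.datetime, str]:
    return (ev.timestamp, ev.recording_id)


@dataclass
class ObservationLog:
    """A roster plus a time-ordered stream of coded events.

    Events are sorted by timestamp (ties broken by recording id) on
    construction, and every identified id referenced by an event must
    appear in the roster.
    """

    roster: list[Individual]
    events: list[ObservationEvent]

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.roster]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate roster ids: {dupes}")
        known = set(ids)
        for ev in self.events:
            unknown = (ev.identified_participants() | {ev.actor}) - known - {UNIDENTIFIED}
            if unknown:
                raise ValidationError(
                    f"recording {ev.recording_id}: ids {sorted(unknown)} "
                    f"not in roster"
                )
        self.events = sorted(self.events, key=_event_sort_key)

    def roster_ids(self) -> list[str]:
        return [ind.id for ind in self.roster]

    def individual(self, code: str) -> Individual:
        for ind in self.roster:
            if ind.id == code:
                return ind
        raise KeyError(code)

    def recordings(self) -> dict[str, list[ObservationEvent]]:
        """Events grouped by recording id, preserving time order."""
        by_rec: dict[str, list[ObservationEvent]] = {}
        for ev in self.events:
            by_rec.setdefault(ev.recording_id, []).append(ev)
        return by_rec

    def __len__(self) -> int:
        return len(self.events)


ROSTER_COLUMNS = ["id", "sex", "life_stage", "entry_date", "exit_date"]
EVENT_COLUMNS = [
    "recording_id",
    "timestamp",
    "camera_id",
    "behaviour",
    "actor",
    "recipient",
    "present",
]


def read_event_log(roster_path: str | Path, events_path: str | Path) -> ObservationLog:
    """Read roster and event CSVs into a validated :class:`ObservationLog`.

    Both files are UTF-8, comma-separated with a header row. Timestamps are
    ISO 8601; the ``present`` column is a semicolon-joined id list. Rows
    with the ``UNIDENTIFIED`` actor sentinel are retained.
    """
    roster: list[Individual] = []
    with open(roster_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, ROSTER_COLUMNS, roster_path)
        for lineno, row in enumerate(reader, start=2):
            exit_raw = (row["exit_date"] or "").strip()
            try:
                roster.append(
                    Individual(
                        id=row["id"].strip(),
                        sex=row["sex"].strip().lower(),
                        life_stage=row["life_stage"].strip().lower(),
                        entry_date=dt.date.fromisoformat(row["entry_date"].strip()),
                        exit_date=dt.date.fromisoformat(exit_raw) if exit_raw else None,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{roster_path} line {lineno}: {exc}") from exc
            except ValueError as exc:
                raise SchemaError(f"{roster_path} line {lineno}: {exc}") from exc

    events: list[ObservationEvent] = []
    with open(events_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, EVENT_COLUMNS, events_path)
        for lineno, row in enumerate(reader, start=2):
            recipient = (row["recipient"] or "").strip() or None
            present_raw = (row["present"] or "").strip()
            present = frozenset(p for p in present_raw.split(";") if p)
            try:
                events.append(
                    ObservationEvent(
                        recording_id=row["recording_id"].strip(),
                        timestamp=dt.datetime.fromisoformat(row["timestamp"].strip()),
                        camera_id=row["camera_id"].strip(),
                        behaviour=row["behaviour"],
                        actor=row["actor"].strip(),
                        recipient=recipient,
                        present=present,
                    )
                )
            except SchemaError as exc:
                raise SchemaError(f"{events_path} line {lineno}: {exc}") from exc
            except ValidationError as exc:
                raise ValidationError(f"{events_path} line {lineno}: {exc}") from exc
            except ValueError as exc:
                raise SchemaError(f"{events_path} line {lineno}: {exc}") from exc
    return ObservationLog(roster=roster, events=events)


def _require_columns(
    found: Sequence[str] | None, expected: Sequence[str], path: str | Path
) -> None:
    if found is None or list(found) != list(expected):
        raise SchemaError(
            f"{path}: expected header {','.join(expected)}, found "
            f"{','.join(found) if found else '<empty file>'}"
        )


def write_event_log(
    log: ObservationLog, roster_path: str | Path, events_path: str | Path
) -> None:
    """Write the log back to roster/event CSVs; inverse of :func:`read_event_log`."""
    with open(roster_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROSTER_COLUMNS)
        for ind in log.roster:
            writer.writerow(
                [
                    ind.id,
                    ind.sex,
                    ind.life_stage,
                    ind.entry_date.isoformat(),
                    ind.exit_date.isoformat() if ind.exit_date else "",
                ]
            )
    with open(events_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for ev in log.events:
            writer.writerow(
                [
                    ev.recording_id,
                    ev.timestamp.isoformat(),
                    ev.camera_id,
                    ev.behaviour,
                    ev.actor,
                    ev.recipient or "",
                    ";".join(sorted(ev.present)),
                ]
            )


def restrict_log(
    log: ObservationLog,
    start_date: dt.date | None = None,
    end_date: dt.date | None = None,
    life_stages: Iterable[str] | None = None,
) -> ObservationLog:
    """Restrict a log to a date window and/or life stages.

    Keeps events whose timestamp date lies in ``[start_date, end_date]`` and
    whose actor and recipient (when identified) belong to the requested life
    stages; events with the ``UNIDENTIFIED`` actor pass the stage filter
    since the sentinel carries no stage. The roster is filtered to the
    requested stages and to individuals whose tenure overlaps the window,
    and ``present`` sets are intersected with the retained roster.
    """
    if start_date is not None and end_date is not None and start_date > end_date:
        raise ValueError(f"inverted date range: {start_date} > {end_date}")
    stages = frozenset(life_stages) if life_stages is not None else None
    if stages is not None and not stages <= LIFE_STAGES:
        raise ValueError(f"unknown life stages: {sorted(stages - LIFE_STAGES)}")

    def tenure_overlaps(ind: Individual) -> bool:
        if end_date is not None and ind.entry_date > end_date:
            return False
        if start_date is not None and ind.exit_date is not None and ind.exit_date < start_date:
            return False
        return True

    roster = [
        ind
        for ind in log.roster
        if (stages is None or ind.life_stage in stages) and tenure_overlaps(ind)
    ]
    kept_ids = {ind.id for ind in roster}
    stage_of = {ind.id: ind.life_stage for ind in log.roster}

    def stage_ok(code: str | None) -> bool:
        if code is None or code == UNIDENTIFIED or stages is None:
            return True
        return stage_of.get(code) in stages

    events = []
    for ev in log.events:
        day = ev.timestamp.date()
        if start_date is not None and day < start_date:
            continue
        if end_date is not None and day > end_date:
            continue
        if not (stage_ok(ev.actor) and stage_ok(ev.recipient)):
            continue
        events.append(replace(ev, present=frozenset(ev.present) & kept_ids))
    return ObservationLog(roster=roster, events=events)
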