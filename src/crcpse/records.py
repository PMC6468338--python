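"""Per-event data model for the two-round unique-object field procedure.

A capture-recapture field exercise produces one record per approached
individual per round.  In round 1 ("capture 1") peer distributors offer a
unique object (the "mark"); the record notes whether the object was offered
and whether it was accepted.  In round 2 ("capture 2"), roughly a week
later, a different team records for each approached individual whether they
presented the object, correctly identified it on a photo sheet of decoys,
picked a wrong picture, or showed no evidence of having been marked.

This module validates those records, reads and writes them as plain CSV,
and aggregates them into per-town summaries carrying the Lincoln-Petersen
inputs M (marked in capture 1), C (seen in capture 2) and the two recapture
counts:

* definition 1 — presented the object OR identified it correctly;
* definition 2 — physically presented the object.

A wrong photo pick is a misidentification and counts as a recapture under
neither definition.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

__all__ = [
    "CaptureEvent",
    "TownSummary",
    "SchemaError",
    "ValidationError",
    "parse_events",
    "write_events",
    "summarize",
    "expand_summary",
    "read_summary",
    "write_summary",
]

POPULATIONS = ("FSW", "MSM")
ROUNDS = ("capture1", "capture2")
EVIDENCE = ("presented_object", "identified_photo_correct", "identified_photo_wrong", "none")
AGE_GROUPS = ("under-18", "18-24", "25+", "unknown")

#: recapture evidence counted under each definition
DEF1_EVIDENCE = frozenset({"presented_object", "identified_photo_correct"})
DEF2_EVIDENCE = frozenset({"presented_object"})


class SchemaError(ValueError):
    """An input file is missing required columns."""


class ValidationError(ValueError):
    """A row or record violates the event/summary contract."""


@dataclass(frozen=True)
class CaptureEvent:
    """One approached individual in one capture round.

    ``offered``/``accepted`` are meaningful only in round 1 (an object was
    offered, and was or was not accepted); ``evidence`` only in round 2.
    Refusals are round-1 events with ``offered=True, accepted=False`` —
    refusers never received an object and remain unmarked.
    """

    town: str
    population: str
    round: str
    distributor_id: str
    event_date: str | None = None
    age_group: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    offered: bool | None = None
    accepted: bool | None = None
    evidence: str | None = None

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValidationError(f"unknown population {self.population!r}")
        if self.round not in ROUNDS:
            raise ValidationError(f"unknown round {self.round!r}")
        if self.age_group is not None and self.age_group not in AGE_GROUPS:
            raise ValidationError(f"unknown age_group {self.age_group!r}")
        if self.round == "capture1":
            if self.evidence not in (None, "none"):
                raise ValidationError("capture1 events carry no recapture evidence")
            if self.offered is None or self.accepted is None:
                raise ValidationError("capture1 events require offered and accepted")
            if self.accepted and not self.offered:
                raise ValidationError("accepted=true requires offered=true")
        else:
            if self.offered is not None or self.accepted is not None:
                raise ValidationError("capture2 events carry no offered/accepted")
            if self.evidence not in EVIDENCE:
                raise ValidationError(f"capture2 events require evidence; got {self.evidence!r}")
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude {self.latitude} outside [-90, 90]")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass(frozen=True)
class TownSummary:
    """Aggregated counts for one town and one population group.

    ``n_capture1`` is the Lincoln-Petersen M, ``n_capture2`` is C, and the
    two recapture columns are the candidate R values.  The distributor map
    holds per-distributor recapture counts within capture 2; its sum is
    *not* forced to equal either recapture definition, because published
    field data contain towns where the transcribed per-distributor counts
    disagree with the total (diagnostics report this, nothing corrects it).
    """

    town: str
    population: str
    adult_population: int | None
    objects_offered: int
    refusals: int
    n_capture1: int
    n_capture2: int
    recaptures_def1: int
    recaptures_def2: int
    misidentified: int
    distributor_recaptures: Mapping[str, int] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = (
            self.objects_offered, self.refusals, self.n_capture1, self.n_capture2,
            self.recaptures_def1, self.recaptures_def2, self.misidentified,
        )
        if any(c < 0 for c in counts):
            raise ValidationError(f"{self.town}/{self.population}: negative count")
        if self.recaptures_def2 > self.recaptures_def1:
            raise ValidationError(
                f"{self.town}/{self.population}: definition-2 recaptures "
                f"({self.recaptures_def2}) exceed definition-1 ({self.recaptures_def1})"
            )
        if self.recaptures_def1 > self.n_capture2:
            raise ValidationError(f"{self.town}/{self.population}: recaptures exceed capture 2")

    def recaptures(self, definition: str) -> int:
        if definition == "def1":
            return self.recaptures_def1
        if definition == "def2":
            return self.recaptures_def2
        raise ValueError(f"unknown recapture definition {definition!r}")


# ---------------------------------------------------------------------------
# event CSV I/O

_REQUIRED_COLUMNS = ("town", "population", "round", "distributor_id")
_EVENT_COLUMNS = (
    "town", "population", "round", "distributor_id", "event_date", "age_group",
    "latitude", "longitude", "offered", "accepted", "evidence",
)

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _parse_bool(raw: str, row: int, name: str) -> bool:
    try:
        return _BOOL[raw.strip().lower()]
    except KeyError:
        raise ValidationError(f"row {row}: field {name!r}: not a boolean: {raw!r}") from None


def _parse_float(raw: str, row: int, name: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ValidationError(f"row {row}: field {name!r}: not a number: {raw!r}") from None


def parse_events(source: IO[str] | str | Iterable[str]) -> list[CaptureEvent]:
    """Read capture events from comma-delimited text with a header row.

    ``source`` may be an open text file, a path, or any iterable of lines.
    Unknown columns are ignored; blank optional cells become ``None``.
    Rows violating the event invariants raise :class:`ValidationError`
    naming the 1-based data row and field.
    """
    if isinstance(source, str):
        with open(source, newline="", encoding="utf-8") as fh:
            return parse_events(fh)
    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        return []
    missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    events: list[CaptureEvent] = []
    for i, raw in enumerate(reader, start=1):
        get = lambda k: (raw.get(k) or "").strip() or None  # noqa: E731
        kwargs: dict = {
            "town": get("town"),
            "population": get("population"),
            "round": get("round"),
            "distributor_id": get("distributor_id"),
            "event_date": get("event_date"),
            "age_group": get("age_group"),
        }
        for name in _REQUIRED_COLUMNS:
            if kwargs.get(name) is None:
                raise ValidationError(f"row {i}: field {name!r}: empty")
        for name in ("latitude", "longitude"):
            val = get(name)
            kwargs[name] = _parse_float(val, i, name) if val is not None else None
        for name in ("offered", "accepted"):
            val = get(name)
            kwargs[name] = _parse_bool(val, i, name) if val is not None else None
        kwargs["evidence"] = get("evidence")
        try:
            events.append(CaptureEvent(**kwargs))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return events


def write_events(events: Iterable[CaptureEvent], sink: IO[str] | str) -> None:
    """Write events as CSV in the canonical column order."""
    if isinstance(sink, str):
        with open(sink, "w", newline="", encoding="utf-8") as fh:
            write_events(events, fh)
        return
    writer = csv.writer(sink)
    writer.writerow(_EVENT_COLUMNS)
    for e in events:
        writer.writerow([
            e.town, e.population, e.round, e.distributor_id,
            e.event_date or "", e.age_group or "",
            "" if e.latitude is None else e.latitude,
            "" if e.longitude is None else e.longitude,
            "" if e.offered is None else str(e.offered).lower(),
            "" if e.accepted is None else str(e.accepted).lower(),
            e.evidence or "",
        ])


# ---------------------------------------------------------------------------
# aggregation

def summarize(
    events: Iterable[CaptureEvent],
    denominators: Mapping[tuple[str, str], int] | None = None,
) -> list[TownSummary]:
    """Aggregate events into one :class:`TownSummary` per town x population.

    ``denominators`` maps (town, population) to the adult population of the
    relevant sex; pairs absent from the mapping get ``adult_population=None``.
    A town with capture-2 events but no accepted capture-1 events is flagged
    (``no_capture1``), never silently dropped.  The result is invariant to
    the order of the input events and sorted by (population, town).
    """
    denominators = denominators or {}
    groups: dict[tuple[str, str], list[CaptureEvent]] = {}
    for e in sorted(events, key=lambda e: (e.population, e.town)):
        groups.setdefault((e.town, e.population), []).append(e)

    out: list[TownSummary] = []
    for (town, population), evs in sorted(groups.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        offered = sum(1 for e in evs if e.round == "capture1" and e.offered)
        refusals = sum(1 for e in evs if e.round == "capture1" and e.offered and not e.accepted)
        m = sum(1 for e in evs if e.round == "capture1" and e.accepted)
        round2 = [e for e in evs if e.round == "capture2"]
        evidence = Counter(e.evidence for e in round2)
        def2 = evidence["presented_object"]
        def1 = def2 + evidence["identified_photo_correct"]
        misid = evidence["identified_photo_wrong"]
        dist = Counter(e.distributor_id for e in round2 if e.evidence in DEF1_EVIDENCE)
        flags = ("no_capture1",) if round2 and m == 0 else ()
        out.append(TownSummary(
            town=town,
            population=population,
            adult_population=denominators.get((town, population)),
            objects_offered=offered,
            refusals=refusals,
            n_capture1=m,
            n_capture2=len(round2),
            recaptures_def1=def1,
            recaptures_def2=def2,
            misidentified=misid,
            distributor_recaptures=dict(sorted(dist.items())),
            flags=flags,
        ))
    return out


def expand_summary(summary: TownSummary, event_date: str = "2017-06-07") -> list[CaptureEvent]:
    """Deterministically expand a summary into a consistent event list.

    The inverse of :func:`summarize` up to the per-distributor split:
    recapture-evidence events are allotted to distributors following the
    summary's distributor map as far as the definition-1 total allows, with
    any remainder going to the last distributor.  For summaries whose
    distributor counts sum exactly to the definition-1 recaptures,
    ``summarize(expand_summary(s))`` reproduces the map; transcribed field
    tables do not always satisfy that identity, and then only the
    Lincoln-Petersen counts round-trip exactly.
    """
    events: list[CaptureEvent] = []
    base = dict(town=summary.town, population=summary.population, event_date=event_date)
    accepted = summary.n_capture1
    for i in range(accepted):
        events.append(CaptureEvent(
            round="capture1", distributor_id=f"c1d{i % 2 + 1}",
            offered=True, accepted=True, **base))
    for i in range(summary.refusals):
        events.append(CaptureEvent(
            round="capture1", distributor_id=f"c1d{i % 2 + 1}",
            offered=True, accepted=False, **base))

    dist_ids = list(summary.distributor_recaptures) or ["d1", "d2"]
    quota = Counter(summary.distributor_recaptures)
    order: list[str] = []
    for d in dist_ids:
        order.extend([d] * quota[d])
    # pad or trim the assignment stream to the definition-1 total
    while len(order) < summary.recaptures_def1:
        order.append(dist_ids[-1])
    order = order[: summary.recaptures_def1]

    n_def2 = summary.recaptures_def2
    n_photo = summary.recaptures_def1 - summary.recaptures_def2
    for k in range(summary.n_capture2):
        if k < n_def2:
            ev, dist = "presented_object", order[k]
        elif k < n_def2 + n_photo:
            ev, dist = "identified_photo_correct", order[k]
        elif k < n_def2 + n_photo + summary.misidentified:
            ev, dist = "identified_photo_wrong", dist_ids[k % len(dist_ids)]
        else:
            ev, dist = "none", dist_ids[k % len(dist_ids)]
        events.append(CaptureEvent(round="capture2", distributor_id=dist, evidence=ev, **base))
    return events


# ---------------------------------------------------------------------------
# summary CSV I/O

_SUMMARY_COLUMNS = (
    "town", "population", "adult_population", "objects_offered", "refusals",
    "n_capture1", "n_capture2", "recaptures_def1", "recaptures_def2",
    "misidentified", "distributor_recaptures",
)


def _encode_dist(mapping: Mapping[str, int]) -> str:
    return ";".join(f"{k}:{v}" for k, v in mapping.items())


def _decode_dist(raw: str) -> dict[str, int]:
    raw = raw.strip()
    if not raw:
        return {}
    out: dict[str, int] = {}
    for part in raw.split(";"):
        key, _, val = part.partition(":")
        out[key.strip()] = int(val)
    return out


def write_summary(summaries: Iterable[TownSummary], sink: IO[str] | str) -> None:
    """Write summaries as CSV; distributor counts encode as ``id:n;id:n``."""
    if isinstance(sink, str):
        with open(sink, "w", newline="", encoding="utf-8") as fh:
            write_summary(summaries, fh)
        return
    writer = csv.writer(sink)
    writer.writerow(_SUMMARY_COLUMNS)
    for s in summaries:
        writer.writerow([
            s.town, s.population,
            "" if s.adult_population is None else s.adult_population,
            s.objects_offered, s.refusals, s.n_capture1, s.n_capture2,
            s.recaptures_def1, s.recaptures_def2, s.misidentified,
            _encode_dist(s.distributor_recaptures),
        ])


def read_summary(source: IO[str] | str | Iterable[str]) -> list[TownSummary]:
    """Read a summary CSV written by :func:`write_summary` (bit-exact counts)."""
    if isinstance(source, str):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_summary(fh)
    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        return []
    missing = [c for c in _SUMMARY_COLUMNS if c not in reader.fieldnames and c != "distributor_recaptures"]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = []
    for i, raw in enumerate(reader, start=1):
        try:
            adult = raw.get("adult_population", "").strip()
            out.append(TownSummary(
                town=raw["town"].strip(),
                population=raw["population"].strip(),
                adult_population=int(adult) if adult else None,
                objects_offered=int(raw["objects_offered"]),
                refusals=int(raw["refusals"]),
                n_capture1=int(raw["n_capture1"]),
                n_capture2=int(raw["n_capture2"]),
                recaptures_def1=int(raw["recaptures_def1"]),
                recaptures_def2=int(raw["recaptures_def2"]),
                misidentified=int(raw["misidentified"]),
                distributor_recaptures=_decode_dist(raw.get("distributor_recaptures") or ""),
            ))
        except (KeyError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise ValidationError(f"row {i}: {exc}") from None
            raise ValidationError(f"row {i}: {exc}") from None
    return out
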