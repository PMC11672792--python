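"""File-backed store for visitors, venues and check-in/check-out records.

The production system kept visitor–venue relations in a graph database; this
package replaces it with an in-memory edge list persisted to plain CSV or
JSON-lines files, which is sufficient for desk-scale analysis and keeps every
experiment reproducible from text files alone.

Timestamps are held internally as epoch seconds (floats) and serialized as
ISO-8601 with an explicit UTC offset.  A session occupies the half-open
interval ``[t_in, t_out)``: a visitor is counted as departed at exactly
``t_out``, which prevents double counting at transition instants.  Sessions
with no check-out scan are retained as open sessions; history-based
statistics ignore them.
"""

from __future__ import annotations

import csv
import io
import json
import urllib.parse
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Visitor",
    "Venue",
    "CheckinRecord",
    "RecordStoreError",
    "ParseError",
    "read_checkins",
    "write_checkins",
    "read_venues",
    "write_venues",
    "occupancy",
    "encode_qr_payload",
    "decode_qr_payload",
]

QR_SCHEME = "healthpass"
CSV_COLUMNS = ("visitor_id", "venue_id", "check_in_time",
               "check_out_time", "reason", "liability")


class RecordStoreError(ValueError):
    """Base error for record-store failures."""


class ParseError(RecordStoreError):
    """Malformed input file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Visitor:
    """An anonymous visitor; ``anon_id`` carries no personal data."""

    anon_id: str

    def __post_init__(self):
        if not self.anon_id:
            raise RecordStoreError("visitor anon_id must be non-empty")


@dataclass(frozen=True)
class Venue:
    """A venue with a manager-set maximum capacity (persons)."""

    venue_id: str
    capacity: int

    def __post_init__(self):
        if not self.venue_id:
            raise RecordStoreError("venue_id must be non-empty")
        if int(self.capacity) < 1 or self.capacity != int(self.capacity):
            raise RecordStoreError(
                f"venue {self.venue_id!r}: capacity must be a positive "
                f"integer, got {self.capacity!r}")


@dataclass(frozen=True)
class CheckinRecord:
    """One visitor–venue session, the atom of the mobility graph.

    ``t_in``/``t_out`` are epoch seconds; ``t_out`` is ``None`` for open
    sessions (the visitor never scanned out).  ``liability`` is the visitor's
    score in [0, 1] at check-in time, if recorded.
    """

    visitor: str
    venue: str
    t_in: float
    t_out: float | None = None
    reason: str | None = None
    liability: float | None = None

    def __post_init__(self):
        if not self.visitor:
            raise RecordStoreError("record visitor id must be non-empty")
        if not self.venue:
            raise RecordStoreError("record venue id must be non-empty")
        if self.t_out is not None and self.t_out < self.t_in:
            raise RecordStoreError(
                f"t_out ({self.t_out}) precedes t_in ({self.t_in})")
        if self.liability is not None and not 0.0 <= self.liability <= 1.0:
            raise RecordStoreError(
                f"liability {self.liability} outside [0, 1]")

    @property
    def closed(self) -> bool:
        return self.t_out is not None

    def duration(self) -> float | None:
        """Session length in seconds, or None for open sessions."""
        return None if self.t_out is None else self.t_out - self.t_in


# --------------------------------------------------------------------------
# timestamp handling


def format_timestamp(epoch: float) -> str:
    dt = datetime.fromtimestamp(epoch, tz=timezone.utc)
    return dt.isoformat()


def parse_timestamp(text: str) -> float:
    try:
        dt = datetime.fromisoformat(text)
    except ValueError as exc:
        raise ValueError(f"malformed timestamp {text!r}") from exc
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


# --------------------------------------------------------------------------
# serialization


def _record_to_row(rec: CheckinRecord) -> dict[str, str]:
    return {
        "visitor_id": rec.visitor,
        "venue_id": rec.venue,
        "check_in_time": format_timestamp(rec.t_in),
        "check_out_time": "" if rec.t_out is None else format_timestamp(rec.t_out),
        "reason": rec.reason or "",
        "liability": "" if rec.liability is None else repr(float(rec.liability)),
    }


def _row_to_record(row: dict[str, str], line: int) -> CheckinRecord:
    missing = [c for c in CSV_COLUMNS[:3] if not row.get(c)]
    if missing:
        raise ParseError(f"missing required field(s) {missing}", line)
    try:
        t_in = parse_timestamp(row["check_in_time"])
        t_out = (parse_timestamp(row["check_out_time"])
                 if row.get("check_out_time") else None)
    except ValueError as exc:
        raise ParseError(str(exc), line) from exc
    liability_text = row.get("liability") or ""
    try:
        liability = float(liability_text) if liability_text else None
    except ValueError as exc:
        raise ParseError(f"malformed liability {liability_text!r}", line) from exc
    try:
        return CheckinRecord(
            visitor=row["visitor_id"],
            venue=row["venue_id"],
            t_in=t_in,
            t_out=t_out,
            reason=row.get("reason") or None,
            liability=liability,
        )
    except RecordStoreError as exc:
        raise ParseError(str(exc), line) from exc


def read_checkins(path: str | Path, format: str = "csv") -> list[CheckinRecord]:
    """Read check-in records from ``path``, returned in ``t_in`` order.

    Open sessions (empty check-out field) are preserved.  Malformed rows
    raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    records: list[CheckinRecord] = []
    if format == "csv":
        with path.open(newline="") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise ParseError("empty file, expected header", 1)
            if tuple(header) != CSV_COLUMNS:
                raise ParseError(
                    f"unexpected header {header!r}, expected {list(CSV_COLUMNS)}", 1)
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != len(CSV_COLUMNS):
                    raise ParseError(
                        f"expected {len(CSV_COLUMNS)} fields, got {len(row)}", lineno)
                records.append(_row_to_record(dict(zip(CSV_COLUMNS, row)), lineno))
    elif format == "jsonl":
        with path.open() as fh:
            for lineno, raw in enumerate(fh, start=1):
                raw = raw.strip()
                if not raw:
                    continue
                try:
                    obj = json.loads(raw)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"malformed JSON: {exc}", lineno) from exc
                if not isinstance(obj, dict):
                    raise ParseError("expected a JSON object per line", lineno)
                row = {k: "" if obj.get(k) is None else str(obj.get(k))
                       for k in CSV_COLUMNS}
                records.append(_row_to_record(row, lineno))
    else:
        raise RecordStoreError(f"unknown format {format!r}")
    records.sort(key=lambda r: (r.t_in, r.visitor, r.venue))
    return records


def write_checkins(records: Iterable[CheckinRecord], path: str | Path,
                   format: str = "csv") -> Path:
    """Write records so that :func:`read_checkins` recovers them exactly."""
    path = Path(path)
    records = sorted(records, key=lambda r: (r.t_in, r.visitor, r.venue))
    if format == "csv":
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=CSV_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for rec in records:
            writer.writerow(_record_to_row(rec))
        path.write_text(buf.getvalue())
    elif format == "jsonl":
        with path.open("w") as fh:
            for rec in records:
                row = _record_to_row(rec)
                obj = {k: (v if v != "" else None) for k, v in row.items()}
                obj["liability"] = rec.liability
                fh.write(json.dumps(obj, sort_keys=False) + "\n")
    else:
        raise RecordStoreError(f"unknown format {format!r}")
    return path


def read_venues(path: str | Path) -> list[Venue]:
    path = Path(path)
    venues = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ["venue_id", "capacity"]:
            raise ParseError(
                f"unexpected header {reader.fieldnames!r}, expected "
                "['venue_id', 'capacity']", 1)
        for lineno, row in enumerate(reader, start=2):
            try:
                venues.append(Venue(row["venue_id"], int(row["capacity"])))
            except (ValueError, RecordStoreError) as exc:
                raise ParseError(str(exc), lineno) from exc
    return venues


def write_venues(venues: Iterable[Venue], path: str | Path) -> Path:
    path = Path(path)
    lines = ["venue_id,capacity"]
    lines += [f"{v.venue_id},{v.capacity}" for v in venues]
    path.write_text("\n".join(lines) + "\n")
    return path


# --------------------------------------------------------------------------
# queries


def occupancy(records: Sequence[CheckinRecord], venue_id: str, t: float) -> int:
    """Number of visitors inside ``venue_id`` at instant ``t``.

    A record counts if ``t_in <= t`` and the session is still open at ``t``
    (no check-out yet, or ``t_out > t`` under the half-open convention).
    Unknown venues simply count zero.
    """
    return sum(
        1 for r in records
        if r.venue == venue_id and r.t_in <= t and (r.t_out is None or r.t_out > t)
    )


# --------------------------------------------------------------------------
# QR payload (image rendering is out of scope; the payload string is the
# contract between the printed code and the check-in client)


def encode_qr_payload(venue_id: str) -> str:
    """URI-style payload carried by a venue's entry QR code."""
    if not venue_id:
        raise RecordStoreError("venue_id must be non-empty")
    return f"{QR_SCHEME}://venue/{urllib.parse.quote(venue_id, safe='')}"


def decode_qr_payload(payload: str) -> str:
    prefix = f"{QR_SCHEME}://venue/"
    if not payload.startswith(prefix):
        raise RecordStoreError(f"not a {QR_SCHEME} venue payload: {payload!r}")
    venue_id = urllib.parse.unquote(payload[len(prefix):])
    if not venue_id:
        raise RecordStoreError("payload carries an empty venue id")
    return venue_id
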