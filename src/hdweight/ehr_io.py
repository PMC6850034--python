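"""Session-record I/O.

Reads and writes hemodialysis session tables in a fixed CSV schema
(``patient_id,date,pre_weight_kg,post_weight_kg,uf_ml[,group]``) and
assembles per-patient, date-ordered series.  Empty weight fields denote
missing measurements; UF volume is always present and nonnegative.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field, replace

from .errors import SchemaError

__all__ = [
    "HDSession",
    "PatientSeries",
    "GROUPS",
    "read_sessions",
    "write_sessions",
]

#: Recognized clinical-group labels (plus the implicit "unknown").
GROUPS = ("stabilized", "intolerant", "near_death")

REQUIRED_COLUMNS = ("patient_id", "date", "pre_weight_kg", "post_weight_kg", "uf_ml")
OPTIONAL_COLUMNS = ("group",)

#: Validation bounds for any present weight, kg (exclusive).
WEIGHT_BOUNDS = (20.0, 200.0)


@dataclass
class HDSession:
    """One hemodialysis session record.

    ``pre_weight`` / ``post_weight`` are kilograms or ``None`` when the
    measurement is missing; ``uf_volume`` is the ultrafiltration volume in
    millilitres.  ``session_index`` is the ordinal of the session within its
    patient's date-sorted series.
    """

    patient_id: str
    date: _dt.date
    pre_weight: float | None
    post_weight: float | None
    uf_volume: float
    session_index: int = -1

    def __post_init__(self) -> None:
        if self.uf_volume < 0:
            raise SchemaError(
                f"negative UF volume {self.uf_volume} for patient "
                f"{self.patient_id!r} on {self.date}"
            )
        lo, hi = WEIGHT_BOUNDS
        for name, w in (("pre_weight", self.pre_weight), ("post_weight", self.post_weight)):
            if w is not None and not (lo < w < hi):
                raise SchemaError(
                    f"{name}={w} kg out of range ({lo}, {hi}) for patient "
                    f"{self.patient_id!r} on {self.date}"
                )

    @property
    def is_complete(self) -> bool:
        """True when both weights are present."""
        return self.pre_weight is not None and self.post_weight is not None


@dataclass
class PatientSeries:
    """Date-ordered session list for a single patient."""

    patient_id: str
    sessions: list[HDSession] = field(default_factory=list)
    group: str = "unknown"

    def __post_init__(self) -> None:
        if self.group not in GROUPS + ("unknown",):
            raise SchemaError(
                f"unknown group {self.group!r} for patient {self.patient_id!r}"
            )

    def __len__(self) -> int:
        return len(self.sessions)

    def replace_sessions(self, sessions: list[HDSession]) -> "PatientSeries":
        """Copy of this series with a new session list, indices reassigned."""
        sessions = [replace(s, session_index=i) for i, s in enumerate(sessions)]
        return PatientSeries(self.patient_id, sessions, self.group)


def _parse_weight(text: str, column: str, line_no: int) -> float | None:
    text = text.strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise SchemaError(f"line {line_no}: cannot parse {column}={text!r} as a number")


def read_sessions(path) -> list[PatientSeries]:
    """Read a session CSV into per-patient, date-sorted series.

    Rows are grouped by ``patient_id``, sorted by date, and assigned
    ``session_index`` from 0.  Empty weight fields parse as missing.

    Raises
    ------
    SchemaError
        On a missing/extra header, malformed row (with its line number),
        negative UF, out-of-range weight, duplicate (patient, date) rows,
        or conflicting group labels within one patient.
    """
    rows: dict[str, list[HDSession]] = {}
    groups: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        header = tuple(reader.fieldnames)
        if header[: len(REQUIRED_COLUMNS)] != REQUIRED_COLUMNS or not set(
            header[len(REQUIRED_COLUMNS):]
        ) <= set(OPTIONAL_COLUMNS):
            raise SchemaError(
                f"{path}: bad header {header}; expected {REQUIRED_COLUMNS} "
                f"optionally followed by {OPTIONAL_COLUMNS}"
            )
        for row in reader:
            line_no = reader.line_num
            if any(row.get(c) is None for c in REQUIRED_COLUMNS):
                raise SchemaError(f"line {line_no}: wrong number of fields")
            pid = row["patient_id"].strip()
            if not pid:
                raise SchemaError(f"line {line_no}: empty patient_id")
            try:
                date = _dt.date.fromisoformat(row["date"].strip())
            except ValueError:
                raise SchemaError(
                    f"line {line_no}: cannot parse date {row['date']!r} (ISO-8601 required)"
                )
            pre = _parse_weight(row["pre_weight_kg"], "pre_weight_kg", line_no)
            post = _parse_weight(row["post_weight_kg"], "post_weight_kg", line_no)
            uf_text = row["uf_ml"].strip()
            try:
                uf = float(uf_text)
            except ValueError:
                raise SchemaError(f"line {line_no}: cannot parse uf_ml={uf_text!r}")
            try:
                session = HDSession(pid, date, pre, post, uf)
            except SchemaError as exc:
                raise SchemaError(f"line {line_no}: {exc}") from None
            group = (row.get("group") or "").strip()
            if group:
                if group not in GROUPS:
                    raise SchemaError(f"line {line_no}: unknown group {group!r}")
                prev = groups.setdefault(pid, group)
                if prev != group:
                    raise SchemaError(
                        f"line {line_no}: conflicting group labels for patient "
                        f"{pid!r}: {prev!r} vs {group!r}"
                    )
            rows.setdefault(pid, []).append(session)

    series_list = []
    for pid, sessions in rows.items():
        sessions.sort(key=lambda s: s.date)
        for a, b in zip(sessions, sessions[1:]):
            if a.date == b.date:
                raise SchemaError(
                    f"duplicate session date {a.date} for patient {pid!r}"
                )
        sessions = [replace(s, session_index=i) for i, s in enumerate(sessions)]
        series_list.append(PatientSeries(pid, sessions, groups.get(pid, "unknown")))
    return series_list


def _fmt_weight(w: float | None) -> str:
    # gram resolution keeps CSV round-trips exact on gram-quantized data
    return "" if w is None else f"{w:.3f}"


def write_sessions(series_list: list[PatientSeries], path) -> None:
    """Write series to CSV in the fixed schema (missing weights as empty fields).

    Weights are serialized at 3 decimal places and UF at 3 decimal places,
    so ``read_sessions(write_sessions(x)) == x`` whenever the input is
    quantized at that resolution.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS + OPTIONAL_COLUMNS)
        for series in series_list:
            group = "" if series.group == "unknown" else series.group
            for s in series.sessions:
                writer.writerow(
                    [
                        s.patient_id,
                        s.date.isoformat(),
                        _fmt_weight(s.pre_weight),
                        _fmt_weight(s.post_weight),
                        f"{s.uf_volume:.3f}",
                        group,
                    ]
                )
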