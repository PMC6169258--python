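"""Flat statistical tables (variables as columns, observations as rows).

A :class:`TidyTable` is the exchange format between the join engine and
statistics software: columns are grouped by process step and carry a
variable name, a unit and a role (entity identifier, parameter value,
scalar measurement, step start/stop time, or timestamp for expanded time
series); each row is one observation.  Cells are typed values or explicit
nulls (``None``).

CSV export follows RFC 4180 (UTF-8, CRLF records, minimal quoting) with a
single machine-parseable header line ``step.variable [unit]``; nulls render
as empty fields.  JSON export is a list of row objects keyed by the header
labels.  Export -> import -> export is byte-identical.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

COLUMN_ROLES = ("entity_id", "parameter", "measurement", "start_time",
                "stop_time", "timestamp")


@dataclass(frozen=True)
class Column:
    step: str
    variable: str
    unit: str = ""
    role: str = "measurement"

    def header(self) -> str:
        base = f"{self.step}.{self.variable}" if self.step else self.variable
        return f"{base} [{self.unit}]" if self.unit else base


@dataclass
class TidyTable:
    columns: list[Column] = field(default_factory=list)
    rows: list[list] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        headers = self.header_labels()
        if len(set(headers)) != len(headers):
            raise ValidationError("column headers must be unique")
        for row in self.rows:
            if len(row) != len(self.columns):
                raise ValidationError("row width does not match columns")

    def header_labels(self) -> list[str]:
        return [c.header() for c in self.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.rows), len(self.columns))

    def column_index(self, header: str) -> int:
        for i, c in enumerate(self.columns):
            if c.header() == header:
                return i
        raise KeyError(header)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.header_labels())

    def equals(self, other: "TidyTable") -> bool:
        return (self.header_labels() == other.header_labels()
                and self.rows == other.rows)

    # -- CSV ---------------------------------------------------------------

    def to_csv_text(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
        w.writerow(self.header_labels())
        for row in self.rows:
            w.writerow([_render_cell(c) for c in row])
        return buf.getvalue()

    @classmethod
    def from_csv_text(cls, text: str) -> "TidyTable":
        rows = list(csv.reader(io.StringIO(text)))
        if not rows:
            raise ValidationError("empty CSV")
        columns = [_parse_header(h) for h in rows[0]]
        parsed = [[_parse_cell(c) for c in row] for row in rows[1:]]
        return cls(columns=columns, rows=parsed)

    # -- JSON --------------------------------------------------------------

    def to_json_text(self) -> str:
        headers = self.header_labels()
        records = [dict(zip(headers, row)) for row in self.rows]
        doc = {"columns": [c.__dict__ for c in self.columns],
               "provenance": list(self.provenance),
               "rows": records}
        return json.dumps(doc, ensure_ascii=False, indent=1) + "\n"

    @classmethod
    def from_json_text(cls, text: str) -> "TidyTable":
        doc = json.loads(text)
        columns = [Column(**c) for c in doc["columns"]]
        headers = [c.header() for c in columns]
        rows = [[rec.get(h) for h in headers] for rec in doc["rows"]]
        return cls(columns=columns, rows=rows,
                   provenance=list(doc.get("provenance", [])))


def _render_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_cell(text: str):
    if text == "":
        return None
    if text in ("true", "false"):
        return text == "true"
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def _parse_header(header: str) -> Column:
    variable, unit = header, ""
    if header.endswith("]") and " [" in header:
        variable, _, rest = header.rpartition(" [")
        unit = rest[:-1]
    return Column(step="", variable=variable, unit=unit, role="measurement")


def export_table(table: TidyTable, fmt: str, path=None) -> str:
    """Serialize a table to ``csv`` or ``json``; write to *path* if given."""
    if fmt == "csv":
        text = table.to_csv_text()
    elif fmt == "json":
        text = table.to_json_text()
    else:
        raise ValidationError(f"unknown export format {fmt!r}")
    if path is not None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
    return text


def import_table(source, fmt: str) -> TidyTable:
    """Parse a table exported by :func:`export_table`."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, encoding="utf-8", newline="") as fh:
            text = fh.read()
    if fmt == "csv":
        return TidyTable.from_csv_text(text)
    if fmt == "json":
        return TidyTable.from_json_text(text)
    raise ValidationError(f"unknown import format {fmt!r}")
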