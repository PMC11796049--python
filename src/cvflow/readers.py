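"""Vendor-dialect instrument file readers.

Potentiostat vendors export cyclic-voltammetry runs in their own text
layouts.  Each reader here parses one documented dialect into a uniform
:class:`RawFileModel` — an ordered header of key/value tags plus one or
more named numeric tables — which downstream conversion profiles consume
without knowing anything about the source dialect.

Two dialects are implemented:

``gamry-dta``
    Line-oriented tagged text.  Header lines are ``KEY<TAB>TYPE<TAB>VALUE``.
    A table starts at ``CURVE<TAB>TABLE<TAB><nrows>``, followed by one
    column-label line, one unit line, then ``nrows`` tab-separated numeric
    rows.

``palmsens-csv``
    A prologue of ``key: value`` lines, a blank line, then one delimited
    table with a single header row.  The delimiter is sniffed from
    ``{",", ";", "\\t"}``; decimal commas are accepted when the delimiter
    is ``";"``.

Files are decoded as UTF-8 (BOM tolerated) with a Latin-1 fallback.
Non-parseable numeric cells raise :class:`~cvflow.errors.ParseError` with
the line number — never a silent NaN.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParseError, UnknownDialectError

__all__ = [
    "RawTable",
    "RawFileModel",
    "read_gamry_dta",
    "read_palmsens_csv",
    "detect_reader",
    "read_file",
    "READERS",
]


@dataclass
class RawTable:
    """One named numeric table: column (label, unit) pairs and float rows."""

    name: str
    columns: list[tuple[str, str]]
    rows: list[list[float]]

    def column_index(self, label: str) -> int | None:
        for i, (lab, _unit) in enumerate(self.columns):
            if lab == label:
                return i
        return None

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class RawFileModel:
    """Uniform in-memory form of one instrument file.

    Header keys preserve file order; duplicate keys are retained and
    :meth:`header_value` returns the first occurrence (instruments repeat
    tags).
    """

    source_name: str
    header: list[tuple[str, str]] = field(default_factory=list)
    tables: list[RawTable] = field(default_factory=list)
    dialect_id: str = ""

    def header_value(self, key: str, default: str | None = None) -> str | None:
        for k, v in self.header:
            if k == key:
                return v
        return default


def _read_text(path: Path) -> str:
    data = path.read_bytes()
    if not data.strip():
        raise ParseError("empty file", source=path.name)
    try:
        return data.decode("utf-8-sig")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def _parse_number(cell: str, source: str, line_no: int, decimal_comma: bool = False) -> float:
    s = cell.strip()
    if decimal_comma:
        s = s.replace(",", ".")
    try:
        v = float(s)
    except ValueError:
        raise ParseError(f"non-numeric cell {cell.strip()!r}", source=source, line=line_no) from None
    if not math.isfinite(v):
        raise ParseError(f"non-finite cell {cell.strip()!r}", source=source, line=line_no)
    return v


def read_gamry_dta(path: str | Path) -> RawFileModel:
    """Parse a Gamry-DTA-dialect file into a :class:`RawFileModel`."""
    path = Path(path)
    lines = _read_text(path).splitlines()
    header: list[tuple[str, str]] = []
    tables: list[RawTable] = []
    i, n = 0, len(lines)
    while i < n:
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        parts = line.split("\t")
        if parts[0] == "CURVE" and len(parts) >= 2 and parts[1] == "TABLE":
            if len(parts) < 3 or not parts[2].strip().isdigit():
                raise ParseError("CURVE line missing row count", source=path.name, line=i + 1)
            nrows = int(parts[2])
            if i + 2 >= n:
                raise ParseError("truncated CURVE section", source=path.name, line=i + 1)
            labels = lines[i + 1].split("\t")
            units = lines[i + 2].split("\t")
            if len(units) < len(labels):
                units += [""] * (len(labels) - len(units))
            columns = [(lab.strip(), unit.strip()) for lab, unit in zip(labels, units)]
            if not columns:
                raise ParseError("CURVE table has no columns", source=path.name, line=i + 2)
            rows: list[list[float]] = []
            for r in range(nrows):
                ln = i + 3 + r
                if ln >= n:
                    raise ParseError(
                        f"table ends after {r} of {nrows} declared rows",
                        source=path.name, line=n,
                    )
                cells = lines[ln].split("\t")
                if len(cells) != len(columns):
                    raise ParseError(
                        f"row has {len(cells)} cells, expected {len(columns)}",
                        source=path.name, line=ln + 1,
                    )
                rows.append([_parse_number(c, path.name, ln + 1) for c in cells])
            name = "CURVE" if not tables else f"CURVE{len(tables) + 1}"
            tables.append(RawTable(name=name, columns=columns, rows=rows))
            i += 3 + nrows
        else:
            key = parts[0].strip()
            if len(parts) >= 3:
                value = parts[2].strip()
            elif len(parts) == 2:
                value = parts[1].strip()
            else:
                value = ""
            header.append((key, value))
            i += 1
    return RawFileModel(path.name, header, tables, "gamry-dta")


_KV_RE = re.compile(r"^([^,;\t:]+):\s?(.*)$")


def _split_column_label(token: str) -> tuple[str, str]:
    """Split ``"E / V"`` or ``"E (V)"`` into (label, unit)."""
    token = token.strip()
    m = re.match(r"^(.*?)\s*/\s*(\S.*)$", token)
    if m:
        return m.group(1).strip(), m.group(2).strip()
    m = re.match(r"^(.*?)\s*\((.*)\)$", token)
    if m:
        return m.group(1).strip(), m.group(2).strip()
    return token, ""


def read_palmsens_csv(path: str | Path) -> RawFileModel:
    """Parse a PalmSens-CSV-dialect file into a :class:`RawFileModel`."""
    path = Path(path)
    lines = _read_text(path).splitlines()
    n = len(lines)
    header: list[tuple[str, str]] = []
    i = 0
    while i < n and lines[i].strip():
        m = _KV_RE.match(lines[i])
        if m is None:
            break
        header.append((m.group(1).strip(), m.group(2).strip()))
        i += 1
    while i < n and not lines[i].strip():
        i += 1
    if i >= n:
        raise ParseError("no data table found", source=path.name, line=n)
    header_line = lines[i]
    delim = max([",", ";", "\t"], key=header_line.count)
    if header_line.count(delim) == 0:
        raise ParseError("could not detect a table delimiter", source=path.name, line=i + 1)
    columns = [_split_column_label(tok) for tok in header_line.split(delim)]
    decimal_comma = delim == ";"
    rows: list[list[float]] = []
    i += 1
    while i < n and lines[i].strip():
        cells = lines[i].split(delim)
        if len(cells) != len(columns):
            raise ParseError(
                f"row has {len(cells)} cells, expected {len(columns)}",
                source=path.name, line=i + 1,
            )
        rows.append([_parse_number(c, path.name, i + 1, decimal_comma) for c in cells])
        i += 1
    if not rows:
        raise ParseError("data table has no rows", source=path.name, line=i)
    return RawFileModel(path.name, header, [RawTable("data", columns, rows)], "palmsens-csv")


READERS = {
    "gamry-dta": read_gamry_dta,
    "palmsens-csv": read_palmsens_csv,
}


def detect_reader(path: str | Path) -> str:
    """Return the dialect id whose signature (extension + first-line sniff)
    matches, or raise :class:`UnknownDialectError` listing the tried dialects."""
    path = Path(path)
    try:
        text = _read_text(path)
    except ParseError:
        text = ""
    first = text.splitlines()[0] if text.strip() else ""
    tried = []

    tried.append("gamry-dta")
    if path.suffix.lower() == ".dta" or re.match(r"^[^\t]+\t[^\t]+\t", first):
        return "gamry-dta"

    tried.append("palmsens-csv")
    if path.suffix.lower() in (".csv", ".txt") and _KV_RE.match(first):
        return "palmsens-csv"

    raise UnknownDialectError(str(path), tried)


def read_file(path: str | Path) -> RawFileModel:
    """Detect the dialect and parse the file."""
    return READERS[detect_reader(path)](path)
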