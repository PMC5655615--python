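"""Reading and writing descriptor/activity tables as CSV and MDL SD files.

CSV is the RFC-4180-style dialect: comma separator, mandatory header,
``'.'`` decimal point, no locale handling.  Floats are written in shortest
``repr`` form so that ``read_csv(write_csv(t)) == t`` exactly.

The SD-file layer is deliberately a *text* layer: connection tables
(molblocks) are carried as opaque verbatim bytes, and an unmodified record
serializes back byte-identically, across both LF and CRLF files.  Only V2000
records are supported; data items are recognized by ``> <NAME>`` headers
(trailing tokens after the name are ignored) and multi-line values are
joined verbatim.  Chemistry perception is out of scope — that is what makes
byte-faithful round-tripping possible, which cheminformatics toolkits that
re-perceive molecules cannot guarantee.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, FormatError, ParseError
from .table import DescriptorTable

__all__ = [
    "SdfRecord",
    "read_csv",
    "write_csv",
    "read_sdf",
    "write_sdf",
    "parse_sdf_text",
]

_FIELD_HEADER_RE = re.compile(r"^>\s*.*?<([^<>]*)>")


def format_value(x: float) -> str:
    """Shortest-repr formatting; integers render without trailing '.0' noise
    only when the float is integral and short form is exact."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def read_csv(
    path,
    id_column: str | None = None,
    activity_columns: Sequence[str] = (),
) -> DescriptorTable:
    """Read a CSV descriptor table.

    Every column that is neither the id column nor a named activity column
    becomes a descriptor.  Raises :class:`FormatError` on duplicate headers,
    :class:`ConfigError` on missing named columns, and :class:`ParseError`
    (naming row and column) on non-numeric cells.
    """
    with open(path, "r", newline="") as fh:
        try:
            header = next(csv.reader(fh))
        except StopIteration:
            raise FormatError(f"{path}: empty file, header row required") from None
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"{path}: duplicate column header(s): {dupes}")

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for name in list(activity_columns) + ([id_column] if id_column else []):
        if name not in df.columns:
            raise ConfigError(f"{path}: named column {name!r} not present")

    if id_column is not None:
        ids = df[id_column].astype(str).tolist()
    else:
        ids = [f"rec{k}" for k in range(1, len(df) + 1)]

    activity_columns = list(activity_columns)
    descriptor_names = [
        c for c in df.columns if c != id_column and c not in activity_columns
    ]

    def numeric(colname: str) -> np.ndarray:
        # float() round-trips repr-shortest output exactly; pandas' fast
        # float parser does not
        out = np.empty(len(df))
        for row, cell in enumerate(df[colname]):
            text = cell.strip()
            try:
                out[row] = float(text) if text else float("nan")
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} in column "
                    f"{colname!r}, data row {row + 1}"
                ) from None
        return out

    values = (
        np.column_stack([numeric(c) for c in descriptor_names])
        if descriptor_names
        else np.empty((len(df), 0))
    )
    acts = (
        np.column_stack([numeric(c) for c in activity_columns])
        if activity_columns
        else np.empty((len(df), 0))
    )
    return DescriptorTable(
        record_ids=ids,
        descriptor_names=descriptor_names,
        values=values,
        activity_names=activity_columns,
        activities=acts,
    )


def write_csv(table: DescriptorTable, path) -> None:
    """Write ``id,descriptors...,activities...`` with LF line endings and
    shortest-repr float formatting (never locale-dependent)."""
    with open(path, "w", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id"] + table.descriptor_names + table.activity_names)
        for i in range(table.n_records):
            row = [table.record_ids[i]]
            row += [format_value(v) for v in table.values[i]]
            row += [format_value(v) for v in table.activities[i]]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# SDF
# ---------------------------------------------------------------------------

@dataclass
class _DataItem:
    """One ``> <NAME>`` data item, stored verbatim so that unmodified items
    re-serialize byte-identically."""

    header_line: str          # verbatim, includes line ending
    value_lines: list[str]    # verbatim, include line endings
    blank_lines: list[str]    # verbatim separator blank line(s)

    @property
    def name(self) -> str:
        m = _FIELD_HEADER_RE.match(self.header_line)
        return m.group(1) if m else ""

    @property
    def value(self) -> str:
        return "\n".join(ln.rstrip("\r\n") for ln in self.value_lines)

    def set_value(self, text: str) -> None:
        eol = "\r\n" if self.header_line.endswith("\r\n") else "\n"
        self.value_lines = [part + eol for part in text.split("\n")]

    def serialize(self) -> str:
        return self.header_line + "".join(self.value_lines) + "".join(self.blank_lines)


@dataclass
class SdfRecord:
    """One V2000 SD-file record: verbatim molblock, ordered data items, and
    the ``$$$$`` terminator line."""

    molblock: str
    items: list[_DataItem] = field(default_factory=list)
    terminator: str = "$$$$\n"

    @property
    def title(self) -> str:
        return self.molblock.split("\n", 1)[0].strip("\r").strip()

    @property
    def data_items(self) -> dict[str, str]:
        return {it.name: it.value for it in self.items}

    def get_item(self, name: str) -> _DataItem | None:
        for it in self.items:
            if it.name == name:
                return it
        return None

    def serialize(self) -> str:
        return self.molblock + "".join(it.serialize() for it in self.items) + self.terminator

    def copy(self) -> "SdfRecord":
        return SdfRecord(
            molblock=self.molblock,
            items=[
                _DataItem(it.header_line, list(it.value_lines), list(it.blank_lines))
                for it in self.items
            ],
            terminator=self.terminator,
        )


def parse_sdf_text(text: str) -> list[SdfRecord]:
    """Split SD-file text into records and parse each one's data items.

    Everything up to and including ``M  END`` (plus any non-data lines before
    the first ``>`` header) is kept verbatim as the molblock.
    """
    lines = text.splitlines(keepends=True)
    records: list[SdfRecord] = []
    start = 0
    for i, ln in enumerate(lines):
        if ln.rstrip("\r\n") == "$$$$":
            records.append(_parse_record(lines[start : i + 1], len(records) + 1))
            start = i + 1
    if any(ln.strip() for ln in lines[start:]):
        raise FormatError(
            f"trailing content after last '$$$$' terminator (record {len(records) + 1}"
            " unterminated)"
        )
    if not records:
        raise FormatError("no '$$$$'-terminated records found")
    return records


def _parse_record(lines: list[str], index: int) -> SdfRecord:
    terminator = lines[-1]
    body = lines[:-1]
    mend = None
    for i, ln in enumerate(body):
        if ln.rstrip("\r\n") == "M  END":
            mend = i
            break
    if mend is None:
        raise FormatError(f"record {index}: no 'M  END' line (V2000 required)")
    # extend the molblock over any non-item lines before the first '>' header
    j = mend + 1
    while j < len(body) and not body[j].lstrip().startswith(">"):
        if body[j].strip() and not body[j].lstrip().startswith(">"):
            pass  # property lines after M END are rare but legal; keep verbatim
        j += 1
    molblock = "".join(body[:j])
    items: list[_DataItem] = []
    while j < len(body):
        header = body[j]
        if not header.lstrip().startswith(">"):
            raise FormatError(f"record {index}: unexpected line {header!r} in data block")
        j += 1
        value_lines: list[str] = []
        while j < len(body) and body[j].strip() != "":
            value_lines.append(body[j])
            j += 1
        blank_lines: list[str] = []
        while j < len(body) and body[j].strip() == "":
            blank_lines.append(body[j])
            j += 1
        items.append(_DataItem(header, value_lines, blank_lines))
    return SdfRecord(molblock=molblock, items=items, terminator=terminator)


def _numeric_or_none(text: str) -> float | None:
    if "\n" in text:
        return None
    try:
        return float(text.strip())
    except ValueError:
        return None


def read_sdf(
    path,
    activity_fields: Sequence[str] = (),
    skip_missing: bool = False,
) -> DescriptorTable:
    """Read a V2000 SD file into a :class:`DescriptorTable`.

    Data items whose (single-line) values parse as numbers become descriptor
    columns, except those named in ``activity_fields``, which become activity
    columns.  Non-numeric items are carried as passthrough inside the record
    payloads and written back verbatim.  Record id is the molblock title
    line, or ``rec<k>`` (1-based) when blank.

    A record missing a requested activity field raises a hard error naming
    the record, unless ``skip_missing`` is true, in which case the record is
    dropped.
    """
    with open(path, "r", newline="") as fh:
        records = parse_sdf_text(fh.read())

    activity_fields = list(activity_fields)
    kept: list[SdfRecord] = []
    for k, rec in enumerate(records, start=1):
        missing = [f for f in activity_fields if rec.get_item(f) is None]
        if missing:
            if skip_missing:
                continue
            raise ConfigError(
                f"record {k} ({rec.title or 'untitled'}) missing activity "
                f"field(s) {missing}"
            )
        kept.append(rec)
    if not kept:
        raise FormatError(f"{path}: no records left after skipping missing fields")

    first = kept[0]
    descriptor_names = [
        it.name
        for it in first.items
        if it.name not in activity_fields and _numeric_or_none(it.value) is not None
    ]

    ids, rows, act_rows = [], [], []
    for k, rec in enumerate(kept, start=1):
        title = rec.title
        ids.append(title if title else f"rec{k}")
        row = []
        for name in descriptor_names:
            item = rec.get_item(name)
            if item is None:
                raise FormatError(
                    f"record {k}: missing descriptor field {name!r} present in record 1"
                )
            v = _numeric_or_none(item.value)
            if v is None:
                raise ParseError(
                    f"record {k}: non-numeric value {item.value!r} in field {name!r}"
                )
            row.append(v)
        rows.append(row)
        arow = []
        for name in activity_fields:
            v = _numeric_or_none(rec.get_item(name).value)
            if v is None:
                raise ParseError(f"record {k}: non-numeric activity field {name!r}")
            arow.append(v)
        act_rows.append(arow)

    if len(set(ids)) != len(ids):
        ids = [f"rec{k}" for k in range(1, len(kept) + 1)]

    n = len(kept)
    return DescriptorTable(
        record_ids=ids,
        descriptor_names=descriptor_names,
        values=np.array(rows, dtype=float).reshape(n, len(descriptor_names)),
        activity_names=activity_fields,
        activities=np.array(act_rows, dtype=float).reshape(n, len(activity_fields)),
        molecule_payloads=kept,
    )


def write_sdf(table: DescriptorTable, path) -> None:
    """Write the table back as an SD file.

    Requires the table to originate from :func:`read_sdf` (it must carry
    record payloads).  Fields whose table values differ from the originally
    parsed values are rewritten in shortest-repr form; everything else —
    molblocks, non-numeric fields, field order, line endings — is emitted
    byte-identically.
    """
    if table.molecule_payloads is None:
        raise ContractError("SDF output requires SDF input (no record payloads)")
    with open(path, "w", newline="") as fh:
        for i, payload in enumerate(table.molecule_payloads):
            if not isinstance(payload, SdfRecord):
                raise ContractError("molecule payloads are not SD records")
            rec = payload.copy()
            for names, matrix in (
                (table.descriptor_names, table.values),
                (table.activity_names, table.activities),
            ):
                for j, name in enumerate(names):
                    item = rec.get_item(name)
                    if item is None:
                        continue
                    orig = _numeric_or_none(item.value)
                    new = float(matrix[i, j])
                    if orig is None or orig != new:
                        item.set_value(format_value(new))
            fh.write(rec.serialize())
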