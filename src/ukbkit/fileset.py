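"""Parse a UK-Biobank-style fileset and assemble an analysis-ready dataset.

A "fileset" is the trio of files produced when a raw phenotype extract is
converted for analysis: ``<stem>.tab`` (tab-delimited data, columns
``f.eid`` and ``f.<field>.<instance>.<array>``), ``<stem>.r`` (a script
assigning categorical level/label vectors to columns) and ``<stem>.html``
(the data dictionary: UDI, Count, Type, Description).

:func:`build_dataset` composes the three parsers into a single
:class:`UKBDataset` whose columns carry descriptive snake_case names
(``body_mass_index_bmi_f21001_0_0``) and whose coded categorical values
have been replaced by their labels. The ``.r`` script is *never* executed;
its level/label vectors are extracted textually.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from lxml import html as lxml_html

from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

__all__ = [
    "ValueType",
    "FieldDescriptor",
    "CodingMap",
    "UKBDataset",
    "FieldLookup",
    "contract_name",
    "parse_udi",
    "parse_html_dictionary",
    "parse_coding_script",
    "read_tab",
    "build_dataset",
    "field_lookup",
    "merge_filesets",
    "TYPE_MAP",
    "DEFAULT_CHUNK_SIZE",
    "MISSING_TOKEN",
]

#: Default number of rows per chunk when streaming a .tab file.
DEFAULT_CHUNK_SIZE = 10_000

#: Token used for missing values in .tab files.
MISSING_TOKEN = "NA"

_UDI_RE = re.compile(r"^(\d+)-(\d+)\.(\d+)$")
_RAW_COL_RE = re.compile(r"^f\.(\d+)\.(\d+)\.(\d+)$")


class ValueType(str, enum.Enum):
    """Showcase value types, as mapped from the dictionary's Type strings."""

    INTEGER = "integer"
    CONTINUOUS = "continuous"
    CATEGORICAL_SINGLE = "categorical_single"
    CATEGORICAL_MULTIPLE = "categorical_multiple"
    TEXT = "text"
    DATE = "date"


#: Mapping from dictionary "Type" strings (lower-cased) to :class:`ValueType`.
#: Unknown strings fall back to TEXT with a warning.
TYPE_MAP: dict[str, ValueType] = {
    "integer": ValueType.INTEGER,
    "continuous": ValueType.CONTINUOUS,
    "categorical (single)": ValueType.CATEGORICAL_SINGLE,
    "categorical single": ValueType.CATEGORICAL_SINGLE,
    "categorical (multiple)": ValueType.CATEGORICAL_MULTIPLE,
    "categorical multiple": ValueType.CATEGORICAL_MULTIPLE,
    "text": ValueType.TEXT,
    "date": ValueType.DATE,
    "time": ValueType.DATE,
    "compound": ValueType.TEXT,
}


def contract_name(description: str, field_id: int, instance_index: int,
                  array_index: int) -> str:
    """Contract a variable description to a snake_case column name.

    Every maximal run of non-alphanumeric characters in the lower-cased
    description becomes one underscore, leading/trailing underscores are
    stripped, and the addressing suffix ``_f<field>_<instance>_<array>``
    is appended.

    >>> contract_name("Body mass index (BMI)", 21001, 0, 0)
    'body_mass_index_bmi_f21001_0_0'
    """
    stem = re.sub(r"[^0-9a-z]+", "_", description.lower()).strip("_")
    if not stem:
        raise FormatError(
            f"field {field_id}: description {description!r} is empty after "
            "removing non-alphanumeric characters"
        )
    return f"{stem}_f{field_id}_{instance_index}_{array_index}"


def parse_udi(udi: str) -> tuple[int, int, int]:
    """Split a UDI like ``"21001-0.0"`` into (field, instance, array)."""
    m = _UDI_RE.match(udi.strip())
    if m is None:
        raise FormatError(f"unparsable UDI: {udi!r}")
    return int(m.group(1)), int(m.group(2)), int(m.group(3))


@dataclass(frozen=True)
class FieldDescriptor:
    """One showcase variable: addressing, description, type and coding."""

    field_id: int
    instance_index: int
    array_index: int
    description: str
    value_type: ValueType
    coding_id: int | None = None

    @property
    def raw_udi(self) -> str:
        return f"{self.field_id}-{self.instance_index}.{self.array_index}"

    @property
    def raw_column(self) -> str:
        """Column name as it appears in the .tab header."""
        return f"f.{self.field_id}.{self.instance_index}.{self.array_index}"

    @property
    def column_name(self) -> str:
        return contract_name(self.description, self.field_id,
                             self.instance_index, self.array_index)

    def with_coding(self, coding_id: int | None) -> "FieldDescriptor":
        return FieldDescriptor(self.field_id, self.instance_index,
                               self.array_index, self.description,
                               self.value_type, coding_id)


@dataclass(frozen=True)
class CodingMap:
    """A data coding: ordered mapping from raw value (string form) to label."""

    coding_id: int
    entries: Mapping[str, str]
    is_ordered: bool = False

    def __post_init__(self) -> None:
        if any(not lbl for lbl in self.entries.values()):
            raise IntegrityError(
                f"coding {self.coding_id}: labels must be non-empty")


@dataclass
class UKBDataset:
    """Individuals x variables table keyed by a unique ``eid`` column.

    ``df`` holds the data (first column ``eid``); ``fields`` describe every
    non-eid column; ``provenance`` records the originating fileset stem(s).
    """

    df: pd.DataFrame
    fields: list[FieldDescriptor] = dc_field(default_factory=list)
    provenance: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if "eid" not in self.df.columns:
            raise IntegrityError("dataset has no 'eid' column")
        if self.df["eid"].isna().any():
            raise IntegrityError("missing values in 'eid'")
        if self.df["eid"].duplicated().any():
            dups = self.df["eid"][self.df["eid"].duplicated()].tolist()[:5]
            raise IntegrityError(f"duplicate eid values: {dups}")

    @property
    def n_individuals(self) -> int:
        return len(self.df)

    def save(self, path: str | Path, sep: str = "\t") -> Path:
        """Write the dataset as a delimited text file (TSV by default)."""
        path = Path(path)
        if path.suffix == ".csv":
            sep = ","
        self.df.to_csv(path, sep=sep, index=False, na_rep=MISSING_TOKEN)
        return path


class FieldLookup:
    """Field-code <-> column-name lookup table for one dataset."""

    COLUMNS = ["column_name", "description", "raw_udi", "field_id",
               "instance_index", "array_index", "value_type", "coding_id"]

    def __init__(self, descriptors: Iterable[FieldDescriptor]):
        rows = [
            (d.column_name, d.description, d.raw_udi, d.field_id,
             d.instance_index, d.array_index, d.value_type.value, d.coding_id)
            for d in descriptors
        ]
        self.frame = pd.DataFrame(rows, columns=self.COLUMNS)
        if self.frame["column_name"].duplicated().any():
            raise IntegrityError("duplicate column names in field lookup")

    def by_field(self, field_id: int) -> pd.DataFrame:
        """All rows for a showcase field code (empty frame if absent)."""
        return self.frame[self.frame["field_id"] == field_id].reset_index(drop=True)

    def by_column(self, column_name: str) -> pd.DataFrame:
        return self.frame[self.frame["column_name"] == column_name].reset_index(drop=True)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, sep="\t", index=False)
        return path

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# HTML data dictionary
# ---------------------------------------------------------------------------

def parse_html_dictionary(source: str | Path,
                          type_map: Mapping[str, ValueType] | None = None,
                          ) -> list[FieldDescriptor]:
    """Extract one :class:`FieldDescriptor` per variable row of the data
    dictionary.

    ``source`` is a path to the ``.html`` file or the document text itself.
    The dictionary table is located by its header row (cells UDI, Type,
    Description); the ``eid`` identifier row is recognised and excluded.
    """
    if type_map is None:
        type_map = TYPE_MAP
    text = source
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "<" not in source):
        text = Path(source).read_text(encoding="utf-8")
    doc = lxml_html.fromstring(text)

    table = None
    header_cells: list[str] = []
    for tbl in doc.iter("table"):
        rows = tbl.findall(".//tr")
        if not rows:
            continue
        cells = [c.text_content().strip() for c in rows[0]]
        if {"UDI", "Type", "Description"} <= set(cells):
            table, header_cells = tbl, cells
            break
    if table is None:
        raise FormatError("no data-dictionary table with a UDI/Type/"
                          "Description header found in the html document")

    idx = {name: header_cells.index(name) for name in ("UDI", "Type",
                                                       "Description")}
    descriptors: list[FieldDescriptor] = []
    seen: set[tuple[int, int, int]] = set()
    for row in table.findall(".//tr")[1:]:
        cells = [c.text_content().strip() for c in row]
        if len(cells) < len(header_cells):
            continue
        udi = cells[idx["UDI"]]
        if udi.lower() == "eid":  # identifier row, not a variable
            continue
        fid, inst, arr = parse_udi(udi)
        if (fid, inst, arr) in seen:
            raise IntegrityError(f"duplicate UDI in dictionary: {udi}")
        seen.add((fid, inst, arr))
        type_str = cells[idx["Type"]].strip().lower()
        vtype = type_map.get(type_str)
        if vtype is None:
            logger.warning("unknown dictionary Type %r for UDI %s; "
                           "treating as text", cells[idx["Type"]], udi)
            vtype = ValueType.TEXT
        descriptors.append(FieldDescriptor(fid, inst, arr,
                                           cells[idx["Description"]], vtype))
    return descriptors


# ---------------------------------------------------------------------------
# .r coding script (textual extraction only -- never executed)
# ---------------------------------------------------------------------------

_DECL_RE = re.compile(r"\b(lvl|lbl)\.(\d+)\s*<-\s*c\s*\(")
_ASSIGN_COL_RE = re.compile(r"\$\s*f\.(\d+)\.(\d+)\.(\d+)\s*<-")
_ASSIGN_LVL_RE = re.compile(r"\blvl\.(\d+)\b")


def _parse_c_vector(text: str, start: int) -> tuple[list[str], int]:
    """Parse the body of an R ``c(...)`` call starting just after the open
    paren. Handles quoted strings (single or double) containing commas and
    backslash-escaped quotes. Returns (tokens, index one past the close
    paren)."""
    tokens: list[str] = []
    buf: list[str] = []
    i = start
    depth = 1
    in_quote: str | None = None
    is_quoted_token = False

    def flush() -> None:
        tok = "".join(buf).strip()
        buf.clear()
        if tok or is_quoted_token:
            tokens.append(tok)

    while i < len(text):
        ch = text[i]
        if in_quote:
            if ch == "\\" and i + 1 < len(text):
                buf.append(text[i + 1])
                i += 2
                continue
            if ch == in_quote:
                in_quote = None
            else:
                buf.append(ch)
        elif ch in "\"'":
            in_quote = ch
            is_quoted_token = True
        elif ch == "(":
            depth += 1
            buf.append(ch)
        elif ch == ")":
            depth -= 1
            if depth == 0:
                flush()
                return tokens, i + 1
            buf.append(ch)
        elif ch == "," and depth == 1:
            flush()
            is_quoted_token = False
        elif ch in "\r\n":
            pass  # vectors may span lines
        else:
            buf.append(ch)
        i += 1
    raise FormatError("unterminated c(...) vector in coding script")


def parse_coding_script(script: str,
                        ) -> tuple[dict[int, CodingMap], dict[str, int]]:
    """Extract coding maps and column bindings from a ``.r`` script.

    Recognises paired vector declarations ``lvl.<id> <- c(...)`` /
    ``lbl.<id> <- c(...)`` and column-assignment statements that bind a raw
    column ``f.<field>.<instance>.<array>`` to a coding id by referencing
    its ``lvl.<id>`` vector. Returns ``(codings, column_to_coding)``.

    The script text is scanned, tokenised and pattern-matched; it is never
    executed.
    """
    levels: dict[int, list[str]] = {}
    labels: dict[int, list[str]] = {}
    for m in _DECL_RE.finditer(script):
        kind, cid = m.group(1), int(m.group(2))
        toks, _ = _parse_c_vector(script, m.end())
        (levels if kind == "lvl" else labels)[cid] = toks

    codings: dict[int, CodingMap] = {}
    for cid in sorted(set(levels) | set(labels)):
        lvl = levels.get(cid)
        lbl = labels.get(cid)
        if lvl is None or lbl is None or len(lvl) != len(lbl):
            raise IntegrityError(
                f"coding {cid}: level/label vectors missing or of unequal "
                f"length ({'-' if lvl is None else len(lvl)} levels, "
                f"{'-' if lbl is None else len(lbl)} labels)")
        if len(set(lvl)) != len(lvl):
            raise IntegrityError(f"coding {cid}: duplicate raw values")
        codings[cid] = CodingMap(cid, dict(zip(lvl, lbl)))

    column_to_coding: dict[str, int] = {}
    # statement granularity: a binding statement sits on one line in the
    # generated scripts; scan line-wise for "<lhs>$f.X.Y.Z <- ... lvl.N ..."
    for line in script.splitlines():
        col_m = _ASSIGN_COL_RE.search(line)
        if not col_m:
            continue
        lvl_m = _ASSIGN_LVL_RE.search(line, col_m.end())
        if not lvl_m:
            continue
        cid = int(lvl_m.group(1))
        if cid not in codings:
            raise IntegrityError(
                f"column assignment references undeclared coding {cid}")
        raw_col = f"f.{col_m.group(1)}.{col_m.group(2)}.{col_m.group(3)}"
        column_to_coding[raw_col] = cid
    return codings, column_to_coding


# ---------------------------------------------------------------------------
# .tab data table
# ---------------------------------------------------------------------------

def _convert_column(col: pd.Series, vtype: ValueType) -> pd.Series:
    if vtype is ValueType.INTEGER:
        return pd.to_numeric(col, errors="coerce").astype("Int64")
    if vtype is ValueType.CONTINUOUS:
        return pd.to_numeric(col, errors="coerce").astype("float64")
    if vtype is ValueType.DATE:
        return pd.to_datetime(col, errors="coerce", format="mixed")
    # categorical values stay in string form until labels are applied
    return col.astype("string")


def read_tab(path: str | Path,
             descriptors: Sequence[FieldDescriptor] = (),
             chunk_size: int = DEFAULT_CHUNK_SIZE,
             missing_token: str = MISSING_TOKEN) -> UKBDataset:
    """Read a ``.tab`` file into a :class:`UKBDataset` with *raw* values.

    Columns are typed according to their descriptor's value type; header
    columns without a descriptor are retained as text with a warning. The
    file is streamed in chunks of ``chunk_size`` rows; the result is
    independent of the chunk size.
    """
    path = Path(path)
    by_raw = {d.raw_column: d for d in descriptors}

    chunks = pd.read_csv(path, sep="\t", dtype=str, chunksize=chunk_size,
                         keep_default_na=False, na_values=[missing_token])
    parts = list(chunks)
    df = (pd.concat(parts, ignore_index=True) if len(parts) > 1
          else parts[0].reset_index(drop=True))

    if "f.eid" not in df.columns:
        raise FormatError(f"{path.name}: no 'f.eid' column in header")
    df = df.rename(columns={"f.eid": "eid"})
    df["eid"] = pd.to_numeric(df["eid"], errors="raise").astype("int64")

    fields: list[FieldDescriptor] = []
    for col in df.columns:
        if col == "eid":
            continue
        d = by_raw.get(col)
        if d is None:
            logger.warning("%s: column %r has no dictionary entry; "
                           "keeping as text", path.name, col)
            df[col] = df[col].astype("string")
        else:
            df[col] = _convert_column(df[col], d.value_type)
            fields.append(d)
    return UKBDataset(df, fields, provenance=[path.stem])


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _apply_coding(col: pd.Series, coding: CodingMap, name: str) -> pd.Series:
    entries = dict(coding.entries)
    notna = col.notna()
    unmapped = sorted(set(col[notna]) - set(entries))
    if unmapped:
        logger.warning("column %s: %d value(s) absent from coding %d kept "
                       "unchanged: %s", name, len(unmapped),
                       coding.coding_id, unmapped[:5])
    return col.map(lambda v: entries.get(v, v) if pd.notna(v) else v).astype("string")


def build_dataset(stem: str, path: str | Path = ".",
                  chunk_size: int = DEFAULT_CHUNK_SIZE,
                  missing_token: str = MISSING_TOKEN) -> UKBDataset:
    """Assemble the analysis-ready dataset for one fileset.

    Reads ``<stem>.tab``, ``<stem>.r`` and ``<stem>.html`` under ``path``,
    renames raw columns to their contracted descriptive names and replaces
    coded categorical values by their labels. Values absent from a coding
    map are retained unchanged (with a logged warning).
    """
    path = Path(path)
    members = {ext: path / f"{stem}{ext}" for ext in (".tab", ".r", ".html")}
    for p in members.values():
        if not p.exists():
            raise FormatError(f"fileset member not found: {p}")

    descriptors = parse_html_dictionary(members[".html"])
    codings, column_to_coding = parse_coding_script(
        members[".r"].read_text(encoding="utf-8"))
    descriptors = [d.with_coding(column_to_coding.get(d.raw_column))
                   for d in descriptors]

    ds = read_tab(members[".tab"], descriptors, chunk_size=chunk_size,
                  missing_token=missing_token)

    rename: dict[str, str] = {}
    for d in ds.fields:
        if d.raw_column in column_to_coding:
            ds.df[d.raw_column] = _apply_coding(
                ds.df[d.raw_column], codings[column_to_coding[d.raw_column]],
                d.column_name)
        rename[d.raw_column] = d.column_name
    ds.df = ds.df.rename(columns=rename)
    ds.fields = [d for d in descriptors if d.column_name in ds.df.columns]
    ds.provenance = [stem]
    return ds


def field_lookup(source: UKBDataset | str, path: str | Path = ".",
                 ) -> FieldLookup:
    """Build the field-code-to-name lookup table for a dataset or fileset
    stem. One row per non-eid variable; lookup by field code or by column
    name."""
    if isinstance(source, UKBDataset):
        return FieldLookup(source.fields)
    path = Path(path)
    html_path = path / f"{source}.html"
    if not html_path.exists():
        raise FormatError(f"fileset member not found: {html_path}")
    descriptors = parse_html_dictionary(html_path)
    r_path = path / f"{source}.r"
    if r_path.exists():
        _, column_to_coding = parse_coding_script(
            r_path.read_text(encoding="utf-8"))
        descriptors = [d.with_coding(column_to_coding.get(d.raw_column))
                       for d in descriptors]
    return FieldLookup(descriptors)


def merge_filesets(datasets: Sequence[UKBDataset]) -> UKBDataset:
    """Full outer join of several datasets on ``eid``.

    A column name present in more than one input keeps the first
    occurrence's values; later duplicates are suffixed with their
    provenance stem (the collision is logged). Row count equals the size
    of the union of eids.
    """
    if not datasets:
        raise ValueError("no datasets to merge")
    merged = datasets[0].df.copy()
    fields = list(datasets[0].fields)
    provenance = list(datasets[0].provenance)
    for ds in datasets[1:]:
        right = ds.df.copy()
        stem = ds.provenance[0] if ds.provenance else "unknown"
        collisions = (set(merged.columns) & set(right.columns)) - {"eid"}
        if collisions:
            logger.warning("column collision(s) on merge, suffixing with "
                           "%r: %s", stem, sorted(collisions))
            right = right.rename(
                columns={c: f"{c}_{stem}" for c in collisions})
        merged = merged.merge(right, on="eid", how="outer")
        fields.extend(d for d in ds.fields
                      if d.column_name not in collisions)
        provenance.extend(ds.provenance)
    merged = merged.sort_values("eid").reset_index(drop=True)
    return UKBDataset(merged, fields, provenance)
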