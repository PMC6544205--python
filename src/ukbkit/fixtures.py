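"""Synthetic fileset and genetic-metadata generators with known ground
truth.

Real biobank extracts cannot be redistributed, so every reader and query
in this package is exercised against files emitted here: a complete
``.tab``/``.r``/``.html`` fileset, KING-style kinship pair files,
headerless sample-QC tables, PLINK ``.fam`` and Oxford ``.sample`` files.
Each generator returns a :class:`GroundTruth` describing exactly what the
files contain (expected column names, label-applied values, pair
degrees), and output is byte-identical for a fixed seed.

The default fileset spec mirrors a small baseline assessment extract:
sex, ethnic background, assessment centre (three codings), BMI, age at
recruitment, Townsend deprivation, standing height, waist circumference,
two systolic blood pressure array slots, and two ICD-10 diagnosis array
slots drawing from the bundled demonstration code table — 12 variables
in all. Distributions are plain normals/uniform draws: the fixtures test
plumbing, not biology.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import icd as icd_mod
from .errors import UKBKitError
from .fileset import CodingMap, FieldDescriptor, ValueType, contract_name
from .genmeta import KINSHIP_COLUMNS, degree_of, sqc_names

__all__ = [
    "FieldSpec", "FilesetSpec", "GroundTruth", "default_fileset_spec",
    "generate_fileset", "generate_kinship", "generate_genetic_sidecars",
]

_HTML_TYPE = {
    ValueType.INTEGER: "Integer",
    ValueType.CONTINUOUS: "Continuous",
    ValueType.CATEGORICAL_SINGLE: "Categorical (single)",
    ValueType.CATEGORICAL_MULTIPLE: "Categorical (multiple)",
    ValueType.TEXT: "Text",
    ValueType.DATE: "Date",
}


@dataclass(frozen=True)
class FieldSpec:
    """One variable to generate: a descriptor plus its sampler.

    ``sampler`` is a tuple: ``("normal", mu, sd)``, ``("uniform", lo,
    hi)``, ``("int_uniform", lo, hi)``, ``("coding",)`` (uniform over the
    declared coding's raw levels) or ``("choice", values)``.
    """

    field_id: int
    instance_index: int
    array_index: int
    description: str
    value_type: ValueType
    sampler: tuple
    coding_id: int | None = None

    @property
    def descriptor(self) -> FieldDescriptor:
        return FieldDescriptor(self.field_id, self.instance_index,
                               self.array_index, self.description,
                               self.value_type, self.coding_id)


@dataclass(frozen=True)
class FilesetSpec:
    """Everything needed to emit one synthetic fileset deterministically."""

    n_individuals: int
    fields: tuple[FieldSpec, ...]
    codings: tuple[CodingMap, ...]
    missing_rate: float = 0.05
    seed: int = 0
    stem: str = "ukbsynth"
    eid_start: int = 1000001

    def __post_init__(self) -> None:
        declared = {c.coding_id for c in self.codings}
        for f in self.fields:
            if f.coding_id is not None and f.coding_id not in declared:
                raise UKBKitError(f"field {f.field_id} references "
                                  f"undeclared coding {f.coding_id}")
        if not 0 <= self.missing_rate <= 1:
            raise UKBKitError("missing_rate must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the emitted files are known to contain."""

    column_names: list[str]
    eids: list[int]
    frame: pd.DataFrame  # expected assembled dataset (labels applied)
    label_sets: dict[str, set] = dc_field(default_factory=dict)
    pairs: pd.DataFrame | None = None  # kinship fixtures
    degrees: list | None = None


def default_fileset_spec(n_individuals: int = 100, seed: int = 0,
                         missing_rate: float = 0.05,
                         stem: str = "ukbsynth") -> FilesetSpec:
    """The demo spec: 12 variables, 3 codings (see module docstring)."""
    codings = (
        CodingMap(9, {"0": "Female", "1": "Male"}, is_ordered=True),
        CodingMap(1001, {"1001": "British", "1002": "Irish",
                         "3001": "Indian", "4001": "Caribbean",
                         "5": "Chinese", "6": "Other ethnic group"}),
        CodingMap(10, {"11009": "Newcastle", "11012": "Barts",
                       "11016": "Reading", "11021": "Birmingham"}),
    )
    icd_codes = tuple(icd_mod.load_codes("icd10")["code"])
    fields = (
        FieldSpec(31, 0, 0, "Sex", ValueType.CATEGORICAL_SINGLE,
                  ("coding",), coding_id=9),
        FieldSpec(21000, 0, 0, "Ethnic background",
                  ValueType.CATEGORICAL_SINGLE, ("coding",), coding_id=1001),
        FieldSpec(54, 0, 0, "UK Biobank assessment centre",
                  ValueType.CATEGORICAL_SINGLE, ("coding",), coding_id=10),
        FieldSpec(21001, 0, 0, "Body mass index (BMI)",
                  ValueType.CONTINUOUS, ("normal", 27.4, 4.8)),
        FieldSpec(21022, 0, 0, "Age at recruitment", ValueType.INTEGER,
                  ("int_uniform", 40, 69)),
        FieldSpec(189, 0, 0, "Townsend deprivation index at recruitment",
                  ValueType.CONTINUOUS, ("normal", 0.0, 3.0)),
        FieldSpec(50, 0, 0, "Standing height", ValueType.CONTINUOUS,
                  ("normal", 168.0, 9.0)),
        FieldSpec(48, 0, 0, "Waist circumference", ValueType.CONTINUOUS,
                  ("normal", 90.0, 13.0)),
        FieldSpec(4080, 0, 0, "Systolic blood pressure, automated reading",
                  ValueType.INTEGER, ("int_uniform", 100, 180)),
        FieldSpec(4080, 0, 1, "Systolic blood pressure, automated reading",
                  ValueType.INTEGER, ("int_uniform", 100, 180)),
        FieldSpec(41270, 0, 0, "Diagnoses - ICD10",
                  ValueType.CATEGORICAL_MULTIPLE, ("choice", icd_codes)),
        FieldSpec(41270, 0, 1, "Diagnoses - ICD10",
                  ValueType.CATEGORICAL_MULTIPLE, ("choice", icd_codes)),
    )
    return FilesetSpec(n_individuals, fields, codings,
                       missing_rate=missing_rate, seed=seed, stem=stem)


# ---------------------------------------------------------------------------
# fileset emission
# ---------------------------------------------------------------------------

def _sample_raw(fs: FieldSpec, n: int, rng: np.random.Generator,
                codings: dict[int, CodingMap]) -> list[str]:
    kind = fs.sampler[0]
    if kind == "normal":
        _, mu, sd = fs.sampler
        return [f"{v:.4f}" for v in rng.normal(mu, sd, n)]
    if kind == "uniform":
        _, lo, hi = fs.sampler
        return [f"{v:.4f}" for v in rng.uniform(lo, hi, n)]
    if kind == "int_uniform":
        _, lo, hi = fs.sampler
        return [str(int(v)) for v in rng.integers(lo, hi + 1, n)]
    if kind == "coding":
        levels = list(codings[fs.coding_id].entries)
        return [levels[i] for i in rng.integers(0, len(levels), n)]
    if kind == "choice":
        values = list(fs.sampler[1])
        return [str(values[i]) for i in rng.integers(0, len(values), n)]
    raise UKBKitError(f"unknown sampler kind {kind!r}")


def _quote_r(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


_NUMERIC_RE = re.compile(r"^-?\d+(\.\d+)?$")


def _r_token(s: str) -> str:
    return s if _NUMERIC_RE.match(s) else _quote_r(s)


def _expected_column(fs: FieldSpec, raw: list[str], miss: np.ndarray,
                     codings: dict[int, CodingMap]) -> pd.Series:
    vals: list = []
    for v, m in zip(raw, miss):
        if m:
            vals.append(None)
        elif fs.coding_id is not None:
            vals.append(codings[fs.coding_id].entries[v])
        else:
            vals.append(v)
    if fs.value_type is ValueType.CONTINUOUS:
        return pd.Series([None if v is None else float(v) for v in vals],
                         dtype="float64")
    if fs.value_type is ValueType.INTEGER:
        return pd.Series([None if v is None else int(v) for v in vals],
                         dtype="Int64")
    if fs.value_type is ValueType.DATE:
        return pd.to_datetime(pd.Series(vals), errors="coerce")
    return pd.Series(vals, dtype="string")


def generate_fileset(spec: FilesetSpec, out_dir: str | Path,
                     ) -> tuple[dict[str, Path], GroundTruth]:
    """Emit ``<stem>.tab``, ``<stem>.r`` and ``<stem>.html`` under
    ``out_dir``; deterministic (byte-identical) for a fixed spec.

    Returns the file paths and the ground truth: expected column names,
    eids, the fully assembled expected dataset (descriptive names, labels
    applied, typed) and per-column label sets.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    codings = {c.coding_id: c for c in spec.codings}

    eids = list(range(spec.eid_start, spec.eid_start + n))
    raw_cols: dict[str, list[str]] = {}
    miss_masks: dict[str, np.ndarray] = {}
    expected: dict[str, pd.Series] = {"eid": pd.Series(eids, dtype="int64")}
    label_sets: dict[str, set] = {}

    for fs in spec.fields:
        raw = _sample_raw(fs, n, rng, codings)
        miss = (rng.random(n) < spec.missing_rate
                if spec.missing_rate > 0 else np.zeros(n, dtype=bool))
        d = fs.descriptor
        raw_cols[d.raw_column] = raw
        miss_masks[d.raw_column] = miss
        expected[d.column_name] = _expected_column(fs, raw, miss, codings)
        if fs.coding_id is not None:
            label_sets[d.column_name] = set(codings[fs.coding_id]
                                            .entries.values())

    # --- .tab ---
    tab_path = out_dir / f"{spec.stem}.tab"
    header = ["f.eid"] + [fs.descriptor.raw_column for fs in spec.fields]
    with tab_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for i in range(n):
            row = [str(eids[i])]
            for fs in spec.fields:
                rc = fs.descriptor.raw_column
                row.append("NA" if miss_masks[rc][i] else raw_cols[rc][i])
            fh.write("\t".join(row) + "\n")

    # --- .r ---
    r_path = out_dir / f"{spec.stem}.r"
    lines = []
    for c in sorted(codings.values(), key=lambda c: c.coding_id):
        lvl = ",".join(_r_token(v) for v in c.entries)
        lbl = ",".join(_quote_r(v) for v in c.entries.values())
        lines.append(f"lvl.{c.coding_id} <- c({lvl})")
        lines.append(f"lbl.{c.coding_id} <- c({lbl})")
    for fs in spec.fields:
        if fs.coding_id is None:
            continue
        rc = fs.descriptor.raw_column
        fn = "ordered" if codings[fs.coding_id].is_ordered else "factor"
        lines.append(f"bd${rc} <- {fn}(bd${rc}, levels=lvl.{fs.coding_id}, "
                     f"labels=lbl.{fs.coding_id})")
    r_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    # --- .html ---
    html_path = out_dir / f"{spec.stem}.html"
    rows = ['<tr><th>UDI</th><th>Count</th><th>Type</th>'
            '<th>Description</th></tr>',
            f'<tr><td>eid</td><td>{n}</td><td>Sequence</td>'
            '<td>Encoded anonymised participant ID</td></tr>']
    for fs in spec.fields:
        d = fs.descriptor
        count = int(n - miss_masks[d.raw_column].sum())
        rows.append(f'<tr><td>{d.raw_udi}</td><td>{count}</td>'
                    f'<td>{_HTML_TYPE[fs.value_type]}</td>'
                    f'<td>{d.description}</td></tr>')
    html_path.write_text(
        "<html><head><title>Data dictionary</title></head><body>\n"
        "<table border=1>\n" + "\n".join(rows) + "\n</table>\n"
        "</body></html>\n", encoding="utf-8")

    truth = GroundTruth(
        column_names=["eid"] + [fs.descriptor.column_name
                                for fs in spec.fields],
        eids=eids,
        frame=pd.DataFrame(expected),
        label_sets=label_sets,
    )
    paths = {".tab": tab_path, ".r": r_path, ".html": html_path}
    return paths, truth


def _demo_field_name(field_id: int, description: str) -> str:
    return contract_name(description, field_id, 0, 0)


# ---------------------------------------------------------------------------
# kinship fixtures
# ---------------------------------------------------------------------------

def generate_kinship(out_path: str | Path,
                     edges: Sequence[tuple] | None = None,
                     ids: Sequence | None = None,
                     n_pairs: int | None = None,
                     seed: int = 0,
                     kinship_range: tuple[float, float] = (0.0, 0.5),
                     ) -> tuple[Path, GroundTruth]:
    """Emit a KING-style pair file (header ID1 ID2 HetHet IBS0 Kinship).

    Either pass explicit ``edges`` as ``(id1, id2, kinship, ibs0)`` tuples,
    or ``ids`` plus ``n_pairs`` to draw random distinct pairs with kinship
    uniform over ``kinship_range``. Each unordered pair appears once;
    self-pairs are rejected. The ground truth records the emitted pairs
    and their degree categories.
    """
    out_path = Path(out_path)
    rng = np.random.default_rng(seed)

    if edges is None:
        if ids is None or n_pairs is None:
            raise UKBKitError("pass either edges= or ids= and n_pairs=")
        ids = list(ids)
        all_pairs = [(ids[i], ids[j]) for i in range(len(ids))
                     for j in range(i + 1, len(ids))]
        if n_pairs > len(all_pairs):
            raise UKBKitError(f"n_pairs={n_pairs} exceeds the "
                              f"{len(all_pairs)} distinct pairs available")
        chosen = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        lo, hi = kinship_range
        edges = [(*all_pairs[k], float(rng.uniform(lo, hi)),
                  float(rng.uniform(0.0, 0.02))) for k in sorted(chosen)]

    seen: set[frozenset] = set()
    rows = []
    for id1, id2, kin, ibs0 in edges:
        if id1 == id2:
            raise UKBKitError(f"self-pair requested: {id1}")
        key = frozenset((id1, id2))
        if key in seen:
            raise UKBKitError(f"pair ({id1}, {id2}) listed twice")
        seen.add(key)
        if not 0.0 <= kin <= 0.5:
            raise UKBKitError(f"kinship {kin} outside [0, 0.5]")
        rows.append((id1, id2, round(float(rng.uniform(0.1, 0.3)), 4),
                     round(float(ibs0), 6), round(float(kin), 6)))

    with out_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(" ".join(KINSHIP_COLUMNS) + "\n")
        for r in rows:
            fh.write(" ".join(str(v) for v in r) + "\n")

    pairs = pd.DataFrame(rows, columns=KINSHIP_COLUMNS)
    truth = GroundTruth(
        column_names=KINSHIP_COLUMNS,
        eids=sorted({r[0] for r in rows} | {r[1] for r in rows}, key=str),
        frame=pairs,
        pairs=pairs,
        degrees=[degree_of(k) for k in pairs["Kinship"]],
    )
    return out_path, truth


# ---------------------------------------------------------------------------
# sample-QC / fam / sample sidecars
# ---------------------------------------------------------------------------

def generate_genetic_sidecars(out_dir: str | Path, n: int, seed: int = 0,
                              stem: str = "ukbsynth",
                              ) -> tuple[dict[str, Path], GroundTruth]:
    """Emit a headerless sample-QC table, a PLINK .fam and an Oxford
    .sample file that agree on individual order.

    The sample-QC table follows the bundled default schema; values are
    synthetic but type-plausible per column (flags 0/1, principal
    components standard-normal, sexes M/F consistent with the fam file).
    """
    if n < 1:
        raise UKBKitError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    eids = list(range(1000001, 1000001 + n))
    sex = rng.integers(1, 3, n)  # PLINK: 1 male, 2 female

    schema = sqc_names()
    sqc_path = out_dir / f"{stem}_sqc.txt"
    with sqc_path.open("w", encoding="utf-8", newline="\n") as fh:
        for i in range(n):
            row: list[str] = []
            for name in schema:
                if name.startswith("pc"):
                    row.append(f"{rng.normal():.5f}")
                elif name in ("affymetrix_1", "affymetrix_2"):
                    row.append(str(int(rng.integers(1, 10**7))))
                elif name == "genotyping_array":
                    row.append("UKBB" if rng.random() < 0.9 else "UKBL")
                elif name == "batch":
                    row.append(f"Batch_b{int(rng.integers(1, 96)):03d}")
                elif "gender" in name:
                    row.append("M" if sex[i] == 1 else "F")
                elif name in ("heterozygosity",
                              "heterozygosity_pc_corrected"):
                    row.append(f"{rng.normal(0.19, 0.01):.5f}")
                elif name in ("cluster_cr", "dqc"):
                    row.append(f"{rng.uniform(0.97, 1.0):.5f}")
                elif name in ("sample_qc_missing_rate",):
                    row.append(f"{rng.uniform(0, 0.02):.5f}")
                elif name in ("x_intensity", "y_intensity",
                              "internal_pico_ng_ul"):
                    row.append(f"{rng.uniform(300, 900):.1f}")
                elif name in ("plate_name", "submitted_plate_name"):
                    row.append(f"Plate_{int(rng.integers(1, 50)):04d}")
                elif name in ("well", "submitted_well"):
                    row.append(f"{'ABCDEFGH'[int(rng.integers(0, 8))]}"
                               f"{int(rng.integers(1, 13)):02d}")
                else:  # QC flags
                    row.append(str(int(rng.random() < 0.5)))
            fh.write(" ".join(row) + "\n")

    fam_path = out_dir / f"{stem}.fam"
    with fam_path.open("w", encoding="utf-8", newline="\n") as fh:
        for i, e in enumerate(eids):
            fh.write(f"{e} {e} 0 0 {sex[i]} -9\n")

    sample_path = out_dir / f"{stem}.sample"
    with sample_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("ID_1 ID_2 missing sex\n")
        fh.write("0 0 0 D\n")
        for i, e in enumerate(eids):
            fh.write(f"{e} {e} 0 {sex[i]}\n")

    truth = GroundTruth(
        column_names=schema,
        eids=eids,
        frame=pd.DataFrame({"eid": eids, "sex": sex.astype(int)}),
    )
    return {"sqc": sqc_path, "fam": fam_path, "sample": sample_path}, truth
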