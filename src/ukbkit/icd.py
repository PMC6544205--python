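"""ICD-9/ICD-10 reference tables and diagnosis query operations.

Hospital inpatient diagnoses in UK-Biobank-style datasets are stored as
undotted ICD codes ("I74", "I251") spread across array columns. This module
bundles the full chapter tables for both revisions and a demonstration
subset of the code tables (the complete corpora are not redistributed; use
:func:`load_codes` to supply a full ``code<TAB>description`` table), and
implements code/keyword lookup, per-individual diagnosis retrieval,
dataset prevalence, and diagnosis frequency stratified by a reference
variable.

The default disease patterns are the WHO 2015 top-3 causes of death
(coronary artery disease, cerebrovascular disease, lower respiratory
tract infection) expressed as regular expressions over undotted codes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, UKBKitError
from .fileset import UKBDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ICDChapter",
    "QuantileGroups",
    "DEFAULT_DISEASE_PATTERNS",
    "DEFAULT_N_GROUPS",
    "load_chapters",
    "load_codes",
    "icd_code_meaning",
    "icd_keyword",
    "icd_chapter_of",
    "icd_diagnosis",
    "icd_prevalence",
    "icd_freq_by",
    "quantile_groups",
    "diagnosis_columns",
]

#: WHO 2015 top-3 causes of death, as regexes over undotted ICD-10 codes.
DEFAULT_DISEASE_PATTERNS: Mapping[str, str] = {
    "coronary artery disease": "^(I2[0-5])",
    "cerebrovascular disease": "^(I6[0-9])",
    "lower respiratory tract infection": "^(J09|J1[0-9]|J2[0-2]|P23|U04)",
}

#: Default number of quantile groups for a continuous reference variable.
DEFAULT_N_GROUPS = 10

_VERSIONS = ("icd9", "icd10")
_ICD10_CODE_RE = re.compile(r"^[A-Z]\d{2}\d*$")
_ICD9_CODE_RE = re.compile(r"^[EV]?\d{2,4}$")


@dataclass(frozen=True)
class ICDChapter:
    version: str
    chapter: int
    block_start: str
    block_end: str
    description: str


def _check_version(version: str) -> str:
    if version not in _VERSIONS:
        raise ValueError(f"version must be one of {_VERSIONS}, got {version!r}")
    return version


def _data_path(name: str):
    return resources.files("ukbkit.data").joinpath(name)


def load_chapters(version: str = "icd10") -> pd.DataFrame:
    """Full chapter table for a revision: chapter, block_start, block_end,
    description."""
    _check_version(version)
    with resources.as_file(_data_path(f"{version}_chapters.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"block_start": str,
                                               "block_end": str})


def load_codes(version: str = "icd10",
               path: str | Path | None = None) -> pd.DataFrame:
    """Code table (columns ``code``, ``description``), undotted codes.

    Without ``path`` the bundled demonstration subset is returned; pass a
    TSV path to use a full user-supplied table.
    """
    _check_version(version)
    if path is not None:
        codes = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"code", "description"} - set(codes.columns)
        if missing:
            raise FormatError(
                f"code table {path} lacks column(s): {sorted(missing)}")
        return codes[["code", "description"]]
    with resources.as_file(_data_path(f"{version}_codes_demo.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def _well_formed(code: str, version: str) -> bool:
    pat = _ICD10_CODE_RE if version == "icd10" else _ICD9_CODE_RE
    return bool(pat.match(code))


def icd_code_meaning(code: str, version: str = "icd10",
                     codes: pd.DataFrame | None = None) -> str:
    """Full description of an undotted ICD code (exact match).

    Raises :class:`KeyError` for a well-formed code absent from the loaded
    table and :class:`ValueError` for a malformed code, so the two failure
    modes are distinguishable.
    """
    _check_version(version)
    code = code.strip().upper()
    if not _well_formed(code, version):
        raise ValueError(f"malformed {version} code: {code!r}")
    if codes is None:
        codes = load_codes(version)
    hit = codes.loc[codes["code"] == code, "description"]
    if hit.empty:
        raise KeyError(f"{version} code {code!r} absent from the loaded "
                       "code table (bundled table is a demonstration "
                       "subset; supply a full table via load_codes)")
    return str(hit.iloc[0])


def icd_keyword(pattern: str, version: str = "icd10",
                codes: pd.DataFrame | None = None) -> pd.DataFrame:
    """All codes whose description matches ``pattern`` (case-insensitive
    regular expression), ordered by code."""
    _check_version(version)
    try:
        rx = re.compile(pattern, re.IGNORECASE)
    except re.error as exc:
        raise ValueError(f"invalid regular expression {pattern!r}: {exc}")
    if codes is None:
        codes = load_codes(version)
    mask = codes["description"].map(lambda d: rx.search(str(d)) is not None)
    return codes[mask].sort_values("code").reset_index(drop=True)


# ---------------------------------------------------------------------------
# chapter resolution
# ---------------------------------------------------------------------------

def _code_key(code: str, version: str) -> tuple[str, int]:
    """Sort key (letter prefix, leading numeric part) for block containment.

    ICD-10: single letter + first two digits ("I251" -> ("I", 25)).
    ICD-9: optional E/V prefix + leading digits ("4109" -> ("", 410),
    "E880" -> ("E", 880), "V01" -> ("V", 1)).
    """
    code = code.strip().upper()
    if version == "icd10":
        m = re.match(r"^([A-Z])(\d{2})", code)
        if not m:
            raise ValueError(f"malformed icd10 code: {code!r}")
        return m.group(1), int(m.group(2))
    m = re.match(r"^([EV]?)(\d+)", code)
    if not m:
        raise ValueError(f"malformed icd9 code: {code!r}")
    digits = m.group(2)
    width = 3 if m.group(1) != "V" else 2
    return m.group(1), int(digits[:width].ljust(width, "0"))


def icd_chapter_of(code: str, version: str = "icd10") -> ICDChapter:
    """The chapter whose block ``[block_start, block_end]`` contains the
    code (inclusive bounds, letter-then-numeric code order)."""
    _check_version(version)
    key = _code_key(code, version)
    for row in load_chapters(version).itertuples(index=False):
        lo = _code_key(str(row.block_start), version)
        hi = _code_key(str(row.block_end), version)
        if lo <= key <= hi:
            return ICDChapter(version, int(row.chapter), str(row.block_start),
                              str(row.block_end), str(row.description))
    raise KeyError(f"{version} code {code!r} falls outside every chapter block")


# ---------------------------------------------------------------------------
# dataset queries
# ---------------------------------------------------------------------------

def _frame(dataset: UKBDataset | pd.DataFrame) -> pd.DataFrame:
    return dataset.df if isinstance(dataset, UKBDataset) else dataset


def diagnosis_columns(dataset: UKBDataset | pd.DataFrame,
                      version: str = "icd10",
                      columns: Sequence[str] | None = None) -> list[str]:
    """Diagnosis array columns for a revision.

    By default, columns whose names contain the revision tag ("icd10" or
    "icd9" — matching the renamed diagnosis fields); an explicit column
    list overrides discovery. "icd10" is matched so as not to also claim
    "icd9"-only columns and vice versa.
    """
    _check_version(version)
    df = _frame(dataset)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise KeyError(f"diagnosis column(s) not in dataset: {missing}")
        return list(columns)
    other = "icd9" if version == "icd10" else "icd10"
    found = [c for c in df.columns
             if version in c.lower() and other not in c.lower()]
    if not found:
        raise UKBKitError(
            f"no {version} diagnosis columns found (looked for column names "
            f"containing {version!r}); pass columns= explicitly")
    return found


def _match_any(df: pd.DataFrame, cols: Sequence[str],
               rx: re.Pattern) -> pd.Series:
    """Boolean per row: any diagnosis value in ``cols`` matches ``rx``."""
    hit = pd.Series(False, index=df.index)
    for c in cols:
        col = df[c]
        hit |= col.map(
            lambda v: pd.notna(v) and rx.search(str(v)) is not None)
    return hit


def icd_diagnosis(dataset: UKBDataset | pd.DataFrame,
                  ids: Sequence, version: str = "icd10",
                  columns: Sequence[str] | None = None,
                  codes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Diagnoses of one or more individuals.

    Returns a tidy frame (eid, code, description, status). Codes are
    deduplicated per individual across array columns. Individuals without
    any diagnosis get one row with status ``no_diagnoses``; ids absent
    from the dataset get status ``id_not_found`` (not a fatal error).
    Unknown codes are kept with an empty description and a warning.
    """
    df = _frame(dataset)
    cols = diagnosis_columns(df, version, columns)
    if codes is None:
        codes = load_codes(version)
    desc = dict(zip(codes["code"], codes["description"]))

    rows: list[tuple] = []
    indexed = df.set_index("eid")
    for eid in ids:
        if eid not in indexed.index:
            rows.append((eid, None, None, "id_not_found"))
            continue
        values = indexed.loc[eid, cols]
        seen: list[str] = []
        for v in np.atleast_1d(values.to_numpy(dtype=object)).ravel():
            if pd.isna(v) or str(v) in seen:
                continue
            seen.append(str(v))
        if not seen:
            rows.append((eid, None, None, "no_diagnoses"))
            continue
        for code in seen:
            d = desc.get(code)
            if d is None:
                logger.warning("eid %s: %s code %r not in loaded code table",
                               eid, version, code)
                d = ""
            rows.append((eid, code, d, "ok"))
    return pd.DataFrame(rows, columns=["eid", "code", "description",
                                       "status"])


def icd_prevalence(dataset: UKBDataset | pd.DataFrame, pattern: str,
                   version: str = "icd10",
                   columns: Sequence[str] | None = None) -> float:
    """Fraction of *all* individuals in the dataset carrying at least one
    diagnosis code matching the pattern (an individual counts once,
    however many codes match)."""
    df = _frame(dataset)
    cols = diagnosis_columns(df, version, columns)
    try:
        rx = re.compile(pattern)
    except re.error as exc:
        raise ValueError(f"invalid regular expression {pattern!r}: {exc}")
    if len(df) == 0:
        return float("nan")
    return float(_match_any(df, cols, rx).sum() / len(df))


class QuantileGroups(NamedTuple):
    """Result of :func:`quantile_groups`: per-value group index (``Int64``,
    missing for missing inputs) and a per-group info table (group, label,
    n, low, high)."""

    index: pd.Series
    info: pd.DataFrame


def quantile_groups(values, n_groups: int = DEFAULT_N_GROUPS,
                    ) -> QuantileGroups:
    """Split a numeric vector into ``n_groups`` approximately equal-sized
    groups by rank.

    Non-missing values are sorted (stably, so ties keep their original
    order) and cut so group sizes differ by at most one, larger groups
    first. Missing values receive no group. Group labels carry the value
    range each group spans.
    """
    values = pd.Series(values).astype("float64")
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    notna = values.notna()
    n = int(notna.sum())
    if n < n_groups:
        raise ValueError(f"need at least n_groups={n_groups} non-missing "
                         f"values, got {n}")
    order = values[notna].sort_values(kind="stable").index
    base, extra = divmod(n, n_groups)
    sizes = [base + (1 if g < extra else 0) for g in range(n_groups)]

    index = pd.Series(pd.NA, index=values.index, dtype="Int64")
    info_rows = []
    pos = 0
    for g, size in enumerate(sizes):
        members = order[pos:pos + size]
        pos += size
        index.loc[members] = g
        lo = float(values[members].min())
        hi = float(values[members].max())
        info_rows.append((g, f"[{lo:g}, {hi:g}]", size, lo, hi))
    info = pd.DataFrame(info_rows,
                        columns=["group", "label", "n", "low", "high"])
    return QuantileGroups(index, info)


def icd_freq_by(dataset: UKBDataset | pd.DataFrame, reference_var: str,
                patterns: Mapping[str, str] | Sequence[str] | None = None,
                version: str = "icd10", n_groups: int = DEFAULT_N_GROUPS,
                columns: Sequence[str] | None = None,
                plot: bool = False):
    """Diagnosis frequency by levels of a reference variable.

    A categorical reference variable contributes its observed levels; a
    numeric one is split into ``n_groups`` approximately equal-sized
    rank groups (:func:`quantile_groups`). Within each group x pattern,
    frequency is the fraction of the group's individuals with at least one
    matching code. Individuals missing the reference variable are
    excluded. ``patterns`` defaults to the WHO 2015 top-3 causes of death.

    Returns a tidy frame (group_label, group_n, pattern_label, pattern,
    n_with_diagnosis, frequency); with ``plot=True`` returns
    ``(frame, figure)``.
    """
    df = _frame(dataset)
    if reference_var not in df.columns:
        raise KeyError(f"unknown reference variable {reference_var!r}")
    if patterns is None:
        patterns = dict(DEFAULT_DISEASE_PATTERNS)
    elif not isinstance(patterns, Mapping):
        patterns = {p: p for p in patterns}
    compiled = {}
    for label, pat in patterns.items():
        try:
            compiled[label] = (pat, re.compile(pat))
        except re.error as exc:
            raise ValueError(f"invalid regular expression {pat!r}: {exc}")
    cols = diagnosis_columns(df, version, columns)

    ref = df[reference_var]
    keep = ref.notna()
    sub = df[keep]
    ref = ref[keep]

    if pd.api.types.is_numeric_dtype(ref):
        qg = quantile_groups(ref, n_groups=n_groups)
        group_of = qg.index
        group_labels = list(qg.info["label"])
        group_ids = list(qg.info["group"])
    else:
        levels = sorted(ref.astype("string").unique())
        group_of = ref.astype("string")
        group_labels = levels
        group_ids = levels

    match = {label: _match_any(sub, cols, rx)
             for label, (_, rx) in compiled.items()}

    rows = []
    for gid, glabel in zip(group_ids, group_labels):
        in_group = (group_of == gid)
        gn = int(in_group.sum())
        for label, (pat, _) in compiled.items():
            hits = int((match[label] & in_group).sum())
            rows.append((glabel, gn, label, pat, hits,
                         hits / gn if gn else float("nan")))
    out = pd.DataFrame(rows, columns=["group_label", "group_n",
                                      "pattern_label", "pattern",
                                      "n_with_diagnosis", "frequency"])
    if not plot:
        return out

    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for label in compiled:
        part = out[out["pattern_label"] == label]
        ax.plot(range(len(part)), part["frequency"], marker="o", label=label)
    ax.set_xticks(range(len(group_labels)))
    ax.set_xticklabels([str(g) for g in group_labels], rotation=45,
                       ha="right")
    ax.set_xlabel(reference_var)
    ax.set_ylabel("diagnosis frequency")
    ax.legend(fontsize="small")
    fig.tight_layout()
    return out, fig
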