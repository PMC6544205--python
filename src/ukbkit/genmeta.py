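"""Genetic-metadata utilities: sample-QC schema, relatedness, pruning,
and PLINK/BGENIE file preparation.

Relatedness is summarised from KING-style pair files (columns ID1 ID2
HetHet IBS0 Kinship). Degrees of relatedness follow the standard KING
powers-of-two kinship bins: > 0.3536 duplicate/MZ twin, (0.1768, 0.3536]
first degree, (0.0884, 0.1768] second degree, (0.0442, 0.0884] third
degree.

:func:`samples_to_remove` selects individuals to drop so that no retained
pair with phenotype data exceeds a kinship cutoff (default 0.0884, the
third-degree boundary): the removal set is a vertex cover of the
above-cutoff relatedness graph, chosen greedily by repeatedly removing the
currently most-connected individual. The greedy policy does not guarantee
a minimum cover in general, but every removal is justified by at least one
uncovered pair, and the retained set is maximal (no removed individual
could be added back without re-creating an above-cutoff pair).
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import FormatError
from .fileset import UKBDataset

logger = logging.getLogger(__name__)

__all__ = [
    "DEGREE_THRESHOLDS",
    "DEGREE_CATEGORIES",
    "DEFAULT_KINSHIP_CUTOFF",
    "sqc_names",
    "read_sqc",
    "read_kinship",
    "degree_of",
    "rel_count",
    "related_with_data",
    "samples_to_remove",
    "read_fam",
    "read_sample",
    "write_genetic_files",
    "BGENIE_MISSING",
    "PLINK_MISSING",
]

#: KING kinship bin boundaries (upper bounds of dup/MZ, 1st, 2nd, 3rd degree).
DEGREE_THRESHOLDS: tuple[float, float, float, float] = (
    0.3536, 0.1768, 0.0884, 0.0442)

DEGREE_CATEGORIES = ("duplicate_mz", "first", "second", "third")

#: Default pruning cutoff: third-degree kinship boundary.
DEFAULT_KINSHIP_CUTOFF = 0.0884

#: Missing tokens per output convention.
PLINK_MISSING = "NA"
BGENIE_MISSING = "-999"

KINSHIP_COLUMNS = ["ID1", "ID2", "HetHet", "IBS0", "Kinship"]


# ---------------------------------------------------------------------------
# sample QC
# ---------------------------------------------------------------------------

def sqc_names(schema_source: str | Path | None = None) -> list[str]:
    """Ordered column names for the headerless sample-QC file.

    The bundled default schema reconstructs the distributed sample-QC
    layout (array/batch/plate metadata, inferred sex, heterozygosity, QC
    flags, 40 principal components, phasing-input flags). Pass a text file
    with one name per line to override.
    """
    if schema_source is None:
        src = resources.files("ukbkit.data").joinpath("sqc_schema_v2.txt")
        text = src.read_text(encoding="utf-8")
    else:
        text = Path(schema_source).read_text(encoding="utf-8")
    names = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if len(set(names)) != len(names):
        raise FormatError("duplicate names in sample-QC schema")
    return names


def read_sqc(path: str | Path,
             names: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a headerless sample-QC table and attach column names.

    Raises :class:`FormatError` if the schema length differs from the
    observed column count (both counts reported)."""
    if names is None:
        names = sqc_names()
    df = pd.read_csv(path, sep=r"\s+", header=None)
    if df.shape[1] != len(names):
        raise FormatError(
            f"sample-QC schema has {len(names)} names but {path} has "
            f"{df.shape[1]} columns; supply a matching schema")
    df.columns = list(names)
    return df


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

def read_kinship(path: str | Path) -> pd.DataFrame:
    """Read a KING-style pair file (header ID1 ID2 HetHet IBS0 Kinship)."""
    df = pd.read_csv(path, sep=r"\s+")
    missing = set(KINSHIP_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"kinship file {path} lacks column(s): "
                          f"{sorted(missing)}")
    return df[KINSHIP_COLUMNS]


def degree_of(kinship: float,
              thresholds: Sequence[float] = DEGREE_THRESHOLDS) -> str | None:
    """Degree category for a KING kinship coefficient, or None below the
    third-degree bin. Bins are half-open, inclusive on their lower bound:
    e.g. kinship == 0.0884 is third degree."""
    dup, first, second, third = thresholds
    if kinship > dup:
        return "duplicate_mz"
    if kinship > first:
        return "first"
    if kinship > second:
        return "second"
    if kinship > third:
        return "third"
    return None


def _restrict(pairs: pd.DataFrame, restrict_to: Iterable | None,
              ) -> pd.DataFrame:
    if restrict_to is None:
        return pairs
    ids = set(restrict_to)
    keep = pairs["ID1"].isin(ids) & pairs["ID2"].isin(ids)
    return pairs[keep]


def rel_count(pairs: pd.DataFrame,
              restrict_to: Iterable | None = None,
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts of pairs per degree of relatedness, plus scatter data.

    Optionally restricts to pairs with *both* members in ``restrict_to``.
    Returns ``(counts, scatter)``: counts has one row per degree category
    (zero counts retained, fixed order); scatter holds the restricted
    (IBS0, Kinship) points labelled by degree, the data behind the
    standard relatedness plot.
    """
    pairs = _restrict(pairs, restrict_to)
    degrees = pairs["Kinship"].map(degree_of) if len(pairs) else pd.Series(
        [], dtype=object)
    tally = degrees.value_counts()
    counts = pd.DataFrame({
        "degree": list(DEGREE_CATEGORIES),
        "n_pairs": [int(tally.get(cat, 0)) for cat in DEGREE_CATEGORIES],
    })
    scatter = pairs.assign(degree=degrees)[["ID1", "ID2", "IBS0", "Kinship",
                                            "degree"]].reset_index(drop=True)
    return counts, scatter


def related_with_data(pairs: pd.DataFrame,
                      phenotyped_ids: Iterable) -> pd.DataFrame:
    """The subset of related pairs in which both members have phenotype
    data."""
    ids = set(phenotyped_ids)
    keep = pairs["ID1"].isin(ids) & pairs["ID2"].isin(ids)
    return pairs[keep].reset_index(drop=True)


def samples_to_remove(pairs: pd.DataFrame, phenotyped_ids: Iterable,
                      cutoff: float = DEFAULT_KINSHIP_CUTOFF) -> list:
    """Individuals to drop to reach a maximal set of unrelateds for a
    phenotype.

    Builds a graph over ``phenotyped_ids`` with an edge for every pair
    with kinship strictly above ``cutoff`` and both members phenotyped,
    then repeatedly removes the node with the most remaining edges (ties
    broken by lexicographically smallest id, compared as strings) until no
    edge remains. Returns ids in removal order; the retained individuals
    contain no pair above the cutoff.
    """
    ids = set(phenotyped_ids)
    g = nx.Graph()
    for row in pairs.itertuples(index=False):
        if row.Kinship > cutoff and row.ID1 in ids and row.ID2 in ids:
            g.add_edge(row.ID1, row.ID2)

    removed: list = []
    while g.number_of_edges() > 0:
        top = max(deg for _, deg in g.degree)
        candidates = [node for node, deg in g.degree if deg == top]
        victim = min(candidates, key=str)
        removed.append(victim)
        g.remove_node(victim)
    return removed


# ---------------------------------------------------------------------------
# fam / sample files
# ---------------------------------------------------------------------------

FAM_COLUMNS = ["fid", "iid", "pid", "mid", "sex", "phenotype"]


def read_fam(path: str | Path) -> pd.DataFrame:
    """Read a PLINK .fam file (6 whitespace-delimited columns: FID IID PID
    MID sex phenotype). Row order is the genotype sample order and is
    preserved."""
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise FormatError(f"{path.name}:{lineno}: expected 6 columns, "
                              f"found {len(parts)}")
        rows.append(parts)
    df = pd.DataFrame(rows, columns=FAM_COLUMNS)
    df["sex"] = pd.to_numeric(df["sex"], errors="coerce")
    if not df["sex"].isin([0, 1, 2]).all():
        bad = df.loc[~df["sex"].isin([0, 1, 2]), "sex"].tolist()[:5]
        raise FormatError(f"{path.name}: sex values outside {{0,1,2}}: {bad}")
    df["sex"] = df["sex"].astype("int64")
    df["phenotype"] = pd.to_numeric(df["phenotype"], errors="coerce")
    return df


_SAMPLE_TYPE_CODES = {"0", "D", "C", "B", "P"}


def read_sample(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read an Oxford .sample file (header line, then a type line whose
    first three entries are ``0 0 0``). Returns ``(table, type_codes)``
    with data columns typed per their codes (D/B integer, C/P float).
    Row order is the genotype sample order."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path.name}: missing header or type line")
    header = lines[0].split()
    types = lines[1].split()
    if len(types) != len(header):
        raise FormatError(f"{path.name}: header has {len(header)} columns "
                          f"but type line has {len(types)}")
    if types[:3] != ["0", "0", "0"]:
        raise FormatError(f"{path.name}: type line must begin '0 0 0', "
                          f"got {' '.join(types[:3])!r}")
    bad = set(types) - _SAMPLE_TYPE_CODES
    if bad:
        raise FormatError(f"{path.name}: unknown type code(s) {sorted(bad)}")

    rows = [ln.split() for ln in lines[2:]]
    for i, r in enumerate(rows, start=3):
        if len(r) != len(header):
            raise FormatError(f"{path.name}:{i}: expected {len(header)} "
                              f"columns, found {len(r)}")
    df = pd.DataFrame(rows, columns=header)
    for col, code in zip(header, types):
        if code in ("D", "B") and col not in header[:2]:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
        elif code in ("C", "P"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        elif col == header[2]:  # 'missing' column
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df, dict(zip(header, types))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_WRITE_KINDS = ("plink_pheno", "plink_covar", "plink_exclusions",
                "bgenie_pheno", "bgenie_covar")


def _format_value(v, missing_token: str) -> str:
    if pd.isna(v):
        return missing_token
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


def write_genetic_files(kind: str, data: UKBDataset | pd.DataFrame,
                        out: str | Path,
                        columns: Sequence[str] | None = None,
                        sample_order: Sequence | None = None,
                        id_col: str = "eid",
                        missing_token: str | None = None) -> Path:
    """Write PLINK or BGENIE input files from phenotype data.

    PLINK phenotype/covariate files are whitespace-delimited with columns
    ``FID IID`` then the requested variables, one row per individual in
    ``data`` (FID = IID = eid; UKB fam files carry no family structure);
    missing values default to ``NA``. ``plink_exclusions`` writes two
    columns FID IID for the ids in ``data`` (or an id list). BGENIE files
    have a header of variable names and one row per sample in
    ``sample_order`` (from :func:`read_fam` iids or a .sample file);
    individuals absent from ``data`` are emitted as missing, default
    token ``-999``.
    """
    if kind not in _WRITE_KINDS:
        raise ValueError(f"kind must be one of {_WRITE_KINDS}, got {kind!r}")
    out = Path(out)

    if kind == "plink_exclusions":
        ids = list(data) if not isinstance(data, (UKBDataset, pd.DataFrame)) \
            else list(_frame_of(data)[id_col])
        with out.open("w") as fh:
            for i in ids:
                fh.write(f"{i} {i}\n")
        return out

    df = _frame_of(data)
    if id_col not in df.columns:
        raise KeyError(f"id column {id_col!r} not in data")
    if columns is None:
        columns = [c for c in df.columns if c != id_col]
    missing_cols = [c for c in columns if c not in df.columns]
    if missing_cols:
        raise KeyError(f"column(s) not in data: {missing_cols}")

    if kind.startswith("plink"):
        token = PLINK_MISSING if missing_token is None else missing_token
        with out.open("w") as fh:
            fh.write(" ".join(["FID", "IID", *columns]) + "\n")
            for row in df.itertuples(index=False):
                rec = dict(zip(df.columns, row))
                vals = [_format_value(rec[c], token) for c in columns]
                fh.write(f"{rec[id_col]} {rec[id_col]} " + " ".join(vals)
                         + "\n")
        return out

    # bgenie_*: rows must follow the genotype sample order exactly
    if sample_order is None:
        raise ValueError(f"{kind} requires sample_order (the genotype "
                         "sample order from a fam or sample file)")
    token = BGENIE_MISSING if missing_token is None else missing_token
    by_id = df.set_index(df[id_col].astype(str))
    with out.open("w") as fh:
        fh.write(" ".join(columns) + "\n")
        for sid in sample_order:
            key = str(sid)
            if key in by_id.index:
                rec = by_id.loc[key]
                vals = [_format_value(rec[c], token) for c in columns]
            else:
                vals = [token] * len(columns)
            fh.write(" ".join(vals) + "\n")
    return out


def _frame_of(data: UKBDataset | pd.DataFrame) -> pd.DataFrame:
    return data.df if isinstance(data, UKBDataset) else data
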