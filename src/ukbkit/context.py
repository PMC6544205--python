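"""Subset-vs-reference summaries of primary demographic variables.

Given a boolean subset indicator over an assembled dataset (TRUE = subset
of interest, FALSE = reference), :func:`demographic_summary` cross-
tabulates each categorical demographic variable by level x membership and
bins each continuous one on shared equal-width breakpoints, so the two
groups are directly comparable. :func:`render_context` draws the
multi-panel figure (stacked, side-by-side, or fill bars) and returns the
plotted numbers alongside the image, so downstream checks can assert
counts and proportions rather than pixels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fileset import UKBDataset

__all__ = ["ContextSummary", "demographic_summary", "render_context",
           "DEFAULT_DEMOGRAPHIC_FIELDS", "DEFAULT_N_BINS"]

#: Showcase field codes treated as primary demographics when present
#: (instance 0): sex, age at recruitment, ethnic background, Townsend
#: deprivation index, current employment status, assessment centre, BMI.
DEFAULT_DEMOGRAPHIC_FIELDS: tuple[int, ...] = (31, 21022, 21000, 189, 6142,
                                               54, 21001)

#: Default number of shared equal-width bins for continuous variables.
DEFAULT_N_BINS = 20

_BAR_POSITIONS = ("stack", "side_by_side", "fill")


@dataclass
class ContextSummary:
    """Per-variable subset/reference tables plus bookkeeping totals.

    ``tables[var]`` has columns ``level`` (or ``bin_low``/``bin_high`` and
    ``level`` as the bin label for continuous variables), ``n_subset`` and
    ``n_reference``. ``missing[var]`` counts rows contributing to neither
    group for that variable (variable missing, or subset indicator
    missing), so for every variable
    ``n_subset + n_reference + missing == n_total``.
    """

    tables: dict[str, pd.DataFrame]
    kinds: dict[str, str]
    missing: dict[str, int]
    n_total: int
    n_subset: int
    n_reference: int
    n_indicator_missing: int
    subset_label: str = "subset"
    metadata: dict = field(default_factory=dict)

    def variables(self) -> list[str]:
        return list(self.tables)


def _resolve_default_variables(df: pd.DataFrame) -> list[str]:
    out = []
    for fid in DEFAULT_DEMOGRAPHIC_FIELDS:
        rx = re.compile(rf"_f{fid}_0_0$")
        hits = [c for c in df.columns if rx.search(c)]
        out.extend(sorted(hits))
    return out


def demographic_summary(dataset: UKBDataset | pd.DataFrame,
                        subset,
                        variables: Sequence[str] | None = None,
                        n_bins: int = DEFAULT_N_BINS,
                        subset_label: str = "subset") -> ContextSummary:
    """Cross-tabulate demographic variables by subset membership.

    ``subset`` is a per-row boolean (may contain missing values; such
    rows are excluded from both groups and counted). Variables default to
    the instance-0 columns of the standard demographic field codes found
    in the dataset. Numeric variables are binned on ``n_bins`` shared
    equal-width bins over the pooled non-missing range; all other
    variables are treated as categorical with levels ordered by value.
    """
    df = dataset.df if isinstance(dataset, UKBDataset) else dataset
    ind = pd.Series(subset).reset_index(drop=True).astype("boolean")
    if len(ind) != len(df):
        raise ValueError(f"subset indicator length {len(ind)} != dataset "
                         f"rows {len(df)}")
    if variables is None:
        variables = _resolve_default_variables(df)
        if not variables:
            raise ValueError("no default demographic variables found; "
                             "pass variables= explicitly")
    unknown = [v for v in variables if v not in df.columns]
    if unknown:
        raise KeyError(f"unknown variable(s) {unknown}; available: "
                       f"{sorted(c for c in df.columns if c != 'eid')}")

    df = df.reset_index(drop=True)
    ind_ok = ind.notna()
    in_subset = ind_ok & (ind == True)  # noqa: E712  (boolean dtype with NA)
    in_reference = ind_ok & (ind == False)  # noqa: E712

    tables: dict[str, pd.DataFrame] = {}
    kinds: dict[str, str] = {}
    missing: dict[str, int] = {}
    for var in variables:
        col = df[var]
        counted = col.notna() & ind_ok
        missing[var] = int(len(df) - counted.sum())
        if pd.api.types.is_numeric_dtype(col):
            kinds[var] = "continuous"
            vals = col.astype("float64")
            pooled = vals[counted]
            if pooled.empty:
                tables[var] = pd.DataFrame(columns=["level", "bin_low",
                                                    "bin_high", "n_subset",
                                                    "n_reference"])
                continue
            lo, hi = float(pooled.min()), float(pooled.max())
            if lo == hi:  # degenerate range: one bin
                edges = np.array([lo, hi])
            else:
                edges = np.linspace(lo, hi, n_bins + 1)
            ns, _ = np.histogram(vals[counted & in_subset], bins=edges)
            nr, _ = np.histogram(vals[counted & in_reference], bins=edges)
            tables[var] = pd.DataFrame({
                "level": [f"[{edges[i]:g}, {edges[i + 1]:g})"
                          for i in range(len(edges) - 1)],
                "bin_low": edges[:-1],
                "bin_high": edges[1:],
                "n_subset": ns.astype(int),
                "n_reference": nr.astype(int),
            })
        else:
            kinds[var] = "categorical"
            vals = col.astype("string")
            levels = sorted(vals[counted].dropna().unique())
            ns = vals[counted & in_subset].value_counts()
            nr = vals[counted & in_reference].value_counts()
            tables[var] = pd.DataFrame({
                "level": levels,
                "n_subset": [int(ns.get(lv, 0)) for lv in levels],
                "n_reference": [int(nr.get(lv, 0)) for lv in levels],
            })

    return ContextSummary(
        tables=tables, kinds=kinds, missing=missing, n_total=len(df),
        n_subset=int(in_subset.sum()), n_reference=int(in_reference.sum()),
        n_indicator_missing=int((~ind_ok).sum()), subset_label=subset_label,
        metadata={"n_bins": n_bins, "instance": 0},
    )


def render_context(summary: ContextSummary, bar_position: str = "fill"):
    """Draw the multi-panel subset-vs-reference figure.

    ``fill`` plots the per-level proportion n_subset / (n_subset +
    n_reference); ``stack`` and ``side_by_side`` plot counts. Returns
    ``(figure, plot_table)`` where the plot table lists exactly what was
    drawn (variable, level, heights/proportion).
    """
    if bar_position not in _BAR_POSITIONS:
        raise ValueError(f"bar_position must be one of {_BAR_POSITIONS}")
    if not summary.tables:
        raise ValueError("empty summary: nothing to render")

    import matplotlib.pyplot as plt

    nvar = len(summary.tables)
    ncol = min(3, nvar)
    nrow = -(-nvar // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4.2 * ncol, 3.2 * nrow),
                             squeeze=False)
    plot_rows = []
    for ax_idx, (var, tbl) in enumerate(summary.tables.items()):
        ax = axes[ax_idx // ncol][ax_idx % ncol]
        x = np.arange(len(tbl))
        ns = tbl["n_subset"].to_numpy(dtype=float)
        nr = tbl["n_reference"].to_numpy(dtype=float)
        if bar_position == "fill":
            total = ns + nr
            with np.errstate(invalid="ignore", divide="ignore"):
                prop = np.where(total > 0, ns / np.where(total > 0, total, 1),
                                np.nan)
            ax.bar(x, np.ones_like(prop), color="0.85",
                   label=None if ax_idx else "reference")
            ax.bar(x, prop, color="C0",
                   label=None if ax_idx else summary.subset_label)
            ax.set_ylim(0, 1)
            for lv, p, a, b in zip(tbl["level"], prop, ns, nr):
                plot_rows.append((var, lv, a, b,
                                  float(p) if np.isfinite(p) else np.nan))
        elif bar_position == "stack":
            ax.bar(x, nr, color="0.7")
            ax.bar(x, ns, bottom=nr, color="C0")
            for lv, a, b in zip(tbl["level"], ns, nr):
                plot_rows.append((var, lv, a, b, np.nan))
        else:  # side_by_side
            w = 0.4
            ax.bar(x - w / 2, ns, width=w, color="C0")
            ax.bar(x + w / 2, nr, width=w, color="0.7")
            for lv, a, b in zip(tbl["level"], ns, nr):
                plot_rows.append((var, lv, a, b, np.nan))
        ax.set_title(var, fontsize=8)
        ax.set_xticks(x)
        ax.set_xticklabels(tbl["level"], rotation=90, fontsize=6)
    for k in range(nvar, nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()

    plot_table = pd.DataFrame(plot_rows, columns=["variable", "level",
                                                  "n_subset", "n_reference",
                                                  "proportion_subset"])
    return fig, plot_table
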