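"""Tabular I/O for analyte concentration matrices.

Delimited-text contract: the values table is a CSV whose first column holds
sample identifiers and whose remaining columns are analytes; the cell token
``<LOD`` marks a measurement below the assay's limit of detection.  The
metadata table carries one row per sample with columns ``sample_id``,
``subject_id``, ``group`` (``progressor`` / ``non_progressor``),
``time_week`` (0/48/80) and ``compartment`` (``blood`` / ``bal``); BAL rows
additionally carry ``total_protein``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LOD_SENTINEL = "<LOD"

META_COLUMNS = ("subject_id", "group", "time_week", "compartment")


class TableFormatError(ValueError):
    """Malformed analyte table or metadata file."""


@dataclass
class AnalyteTable:
    """Samples × analytes concentration matrix with aligned metadata.

    Parameters
    ----------
    values : DataFrame indexed by sample id, one float column per analyte.
        Cells below the limit of detection are NaN until imputed.
    sample_meta : DataFrame indexed by sample id (subject_id, group,
        time_week, compartment, optionally total_protein).
    analyte_meta : DataFrame indexed by analyte id (compartment, optionally
        min_detectable).
    lod_mask : boolean DataFrame, True where the value was below detection.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    analyte_meta: pd.DataFrame
    lod_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.values) != len(self.sample_meta):
            raise TableFormatError(
                f"values has {len(self.values)} rows but sample_meta has {len(self.sample_meta)}"
            )
        if not self.values.index.equals(self.sample_meta.index):
            missing = self.values.index.symmetric_difference(self.sample_meta.index)
            raise TableFormatError(f"sample ids differ between values and metadata: {list(missing)[:5]}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise TableFormatError(f"duplicate sample ids: {list(dups)[:5]}")
        # analyte ids must be unique within a compartment
        comp = self.analyte_meta["compartment"]
        for c in comp.unique():
            ids = self.analyte_meta.index[comp == c]
            if ids.has_duplicates:
                raise TableFormatError(f"duplicate analyte ids in compartment {c!r}")
        if list(self.values.columns) != list(self.analyte_meta.index):
            raise TableFormatError("analyte columns do not match analyte_meta index")
        if self.lod_mask is None:
            self.lod_mask = pd.DataFrame(False, index=self.values.index, columns=self.values.columns)

    # ---- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> pd.Series:
        return self.sample_meta["group"]

    def copy(self) -> "AnalyteTable":
        return AnalyteTable(
            self.values.copy(),
            self.sample_meta.copy(),
            self.analyte_meta.copy(),
            None if self.lod_mask is None else self.lod_mask.copy(),
        )

    def subset_samples(self, sample_ids) -> "AnalyteTable":
        sample_ids = list(sample_ids)
        return AnalyteTable(
            self.values.loc[sample_ids],
            self.sample_meta.loc[sample_ids],
            self.analyte_meta.copy(),
            self.lod_mask.loc[sample_ids] if self.lod_mask is not None else None,
        )

    def subset_analytes(self, analyte_ids) -> "AnalyteTable":
        analyte_ids = list(analyte_ids)
        missing = [a for a in analyte_ids if a not in self.values.columns]
        if missing:
            raise KeyError(f"analytes not in table: {missing[:5]}")
        return AnalyteTable(
            self.values[analyte_ids].copy(),
            self.sample_meta.copy(),
            self.analyte_meta.loc[analyte_ids].copy(),
            self.lod_mask[analyte_ids].copy() if self.lod_mask is not None else None,
        )

    def group_values(self, group: str) -> pd.DataFrame:
        keep = self.sample_meta["group"] == group
        if not keep.any():
            raise KeyError(f"no samples with group {group!r}")
        return self.values.loc[keep.values]


def read_analyte_table(path: str | Path, meta_path: str | Path) -> AnalyteTable:
    """Read a values CSV plus its sample-metadata CSV into an AnalyteTable.

    ``<LOD`` cells become NaN with the corresponding ``lod_mask`` entry set;
    any other non-numeric cell raises with its row and column named.
    """
    path, meta_path = Path(path), Path(meta_path)
    raw = pd.read_csv(path, dtype=str)
    if raw.shape[1] < 2:
        raise TableFormatError(f"{path}: expected a sample-id column plus analyte columns")
    raw = raw.set_index(raw.columns[0])
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique()
        raise TableFormatError(f"{path}: duplicate sample ids {list(dups)[:5]}")

    mask = raw == LOD_SENTINEL
    numeric = raw.mask(mask).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~mask & raw.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise TableFormatError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} at sample {raw.index[r]!r}, analyte {raw.columns[c]!r}"
        )

    meta = pd.read_csv(meta_path)
    if "sample_id" not in meta.columns:
        raise TableFormatError(f"{meta_path}: missing 'sample_id' column")
    meta = meta.set_index("sample_id")
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise TableFormatError(f"{meta_path}: missing metadata column {col!r}")
    # metadata may legitimately cover several tables (all compartments/time
    # points); only rows for this table's samples are attached
    missing_meta = raw.index.difference(meta.index)
    if len(missing_meta):
        raise TableFormatError(f"{meta_path}: no metadata for sample {missing_meta[0]!r}")
    meta = meta.loc[raw.index]
    if meta["compartment"].nunique() > 1:
        raise TableFormatError("a single table must hold one compartment")

    compartment = meta["compartment"].iloc[0]
    analyte_meta = pd.DataFrame(
        {"compartment": compartment}, index=pd.Index(list(numeric.columns), name="analyte_id")
    )
    return AnalyteTable(numeric.astype(float), meta, analyte_meta, mask)


def read_analyte_lods(path: str | Path) -> dict[str, float]:
    """Read an analyte metadata CSV (analyte_id, min_detectable) into a dict."""
    df = pd.read_csv(path)
    if "analyte_id" not in df.columns or "min_detectable" not in df.columns:
        raise TableFormatError(f"{path}: need columns analyte_id, min_detectable")
    sub = df.dropna(subset=["min_detectable"])
    return dict(zip(sub["analyte_id"], sub["min_detectable"].astype(float)))


def write_analyte_table(table: AnalyteTable, path: str | Path, overwrite: bool = True) -> None:
    """Write the values matrix as CSV, with below-LOD cells as ``<LOD``."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"refusing to overwrite existing file {path}")
    out = table.values.astype(object).copy()
    if table.lod_mask is not None:
        # cells still awaiting imputation are written as the sentinel;
        # imputed cells keep their (numeric) replacement value
        pending = table.lod_mask & table.values.isna()
        out = out.mask(pending, LOD_SENTINEL)
    out.index.name = "sample_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# LOD imputation, total-protein normalisation, compartment merging
# ---------------------------------------------------------------------------

def impute_lod(table: AnalyteTable, min_detectable: dict[str, float]) -> AnalyteTable:
    """Replace below-LOD cells with half the lowest minimum detectable
    concentration across all analytes' standard curves.

    The replacement value is global (one scalar for the whole panel), not
    per-analyte: 0.5 × min_j(min_detectable_j).
    """
    out = table.copy()
    mask = out.lod_mask
    if mask is None or not mask.values.any():
        return out
    if not min_detectable:
        raise ValueError("table has below-LOD cells but no min_detectable concentrations were supplied")
    masked_analytes = mask.any(axis=0)
    need = [a for a in mask.columns[masked_analytes] if a not in min_detectable]
    if need:
        raise ValueError(f"no min_detectable concentration for censored analyte(s): {need[:5]}")
    vals = np.asarray(list(min_detectable.values()), dtype=float)
    if np.any(vals <= 0):
        raise ValueError("min_detectable concentrations must be positive")
    fill = 0.5 * vals.min()
    out.values[:] = out.values.where(~mask, fill)
    return out


def normalize_total_protein(table: AnalyteTable, totals: pd.Series | dict | None = None) -> AnalyteTable:
    """Divide each BAL sample's concentrations by its total protein content.

    ``totals`` defaults to the ``total_protein`` column of ``sample_meta``.
    """
    comps = set(table.analyte_meta["compartment"].unique())
    if comps != {"bal"}:
        raise ValueError(f"compartment mismatch: total-protein normalisation applies to BAL tables, got {sorted(comps)}")
    if totals is None:
        if "total_protein" not in table.sample_meta.columns:
            raise ValueError("no totals supplied and sample_meta lacks a total_protein column")
        totals = table.sample_meta["total_protein"]
    totals = pd.Series(totals)
    missing = [s for s in table.sample_ids if s not in totals.index or not np.isfinite(totals[s])]
    if missing:
        raise ValueError(f"missing total protein for BAL sample(s): {missing[:5]}")
    t = totals.loc[table.values.index].astype(float)
    if (t <= 0).any():
        raise ValueError("total protein values must be positive")
    out = table.copy()
    out.values = out.values.div(t, axis=0)
    return out


def merge_compartments(blood: AnalyteTable, bal: AnalyteTable) -> AnalyteTable:
    """Join blood and BAL tables on shared subjects at a common time point.

    Analytes form the union of both panels; an analyte name present in both
    compartments is kept distinct by suffixing the compartment.  Values are
    carried over bit-exactly.
    """
    tw_blood = set(blood.sample_meta["time_week"].unique())
    tw_bal = set(bal.sample_meta["time_week"].unique())
    if tw_blood != tw_bal:
        raise ValueError(f"tables are at different time points: {sorted(tw_blood)} vs {sorted(tw_bal)}")

    b_subj = blood.sample_meta["subject_id"]
    l_subj = bal.sample_meta["subject_id"]
    shared = [s for s in b_subj if s in set(l_subj)]
    if not shared:
        raise ValueError("no subjects shared between the two compartments")

    b_rows = blood.sample_meta.index[b_subj.isin(shared)]
    l_by_subject = {subj: sid for sid, subj in l_subj.items()}

    clash = set(blood.analyte_ids) & set(bal.analyte_ids)

    def qualified(ids, comp):
        return [f"{a}_{comp}" if a in clash else a for a in ids]

    b_cols = qualified(blood.analyte_ids, "blood")
    l_cols = qualified(bal.analyte_ids, "bal")

    bv = blood.values.loc[b_rows].copy()
    bv.columns = b_cols
    lv = bal.values.loc[[l_by_subject[b_subj[sid]] for sid in b_rows]].copy()
    lv.index = b_rows
    lv.columns = l_cols

    values = pd.concat([bv, lv], axis=1)
    bm = blood.lod_mask.loc[b_rows].copy()
    bm.columns = b_cols
    lm = bal.lod_mask.loc[[l_by_subject[b_subj[sid]] for sid in b_rows]].copy()
    lm.index = b_rows
    lm.columns = l_cols
    mask = pd.concat([bm, lm], axis=1)

    analyte_meta = pd.concat(
        [
            blood.analyte_meta.set_axis(b_cols, axis=0),
            bal.analyte_meta.set_axis(l_cols, axis=0),
        ]
    )
    meta = blood.sample_meta.loc[b_rows].copy()
    bal_extra = [c for c in bal.sample_meta.columns if c not in meta.columns]
    for c in bal_extra:
        meta[c] = [bal.sample_meta.loc[l_by_subject[b_subj[sid]], c] for sid in b_rows]
    meta["compartment"] = "blood+bal"
    return AnalyteTable(values, meta, analyte_meta, mask)
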