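"""Synthetic two-group, multi-compartment longitudinal proteomic cohorts.

Emulates the statistical structure of an observational cohort of a
progressive lung disease: positive, right-skewed (multiplicative log-normal)
concentrations for a large blood panel measured at weeks 0/48/80 and a small
lavage (BAL) panel measured at week 0; a planted cross-compartment signature
separating progressors from non-progressors; disjoint protein blocks
elevated in each of several progressor subgroups; sparse-but-strong
correlation structure among the signature proteins in non-progressors versus
dense-but-weak structure in progressors; a linear temporal drift on a set of
blood proteins present only in progressors; and lower-limit-of-detection
censoring plus total-protein scaling of the BAL panel.

Everything planted is recorded in :class:`GroundTruth` so downstream stages
can be scored against known structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AnalyteTable, write_analyte_table

TIME_WEEKS = (0, 48, 80)
PROGRESSOR = "progressor"
NON_PROGRESSOR = "non_progressor"

# progressor correlation structure: many shared factors with low loadings
_N_WEAK_FACTORS = 8
# non-progressor correlation structure: one strong factor per small block
_STRONG_BLOCK = 3


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the simulated cohort.

    Defaults mirror the study conditions the generator emulates: 34
    progressors, 25 non-progressors, 1,129 blood analytes at three time
    points and 29 BAL analytes at baseline.  All planted effects are in
    autoscaled (per-analyte SD) units of the latent expression scale.
    """

    n_prog: int = 34
    n_nonprog: int = 25
    p_blood: int = 1129
    p_bal: int = 29
    k_signature: int = 54
    effect_size: float = 1.5
    n_subgroups: int = 3
    subgroup_block_size: int = 5
    subgroup_effect: float = 3.0
    temporal_drift: float = 1.0
    n_drift_analytes: int = 10
    corr_strong: float = 0.8
    corr_weak: float = 0.3
    lod_quantile: float = 0.10
    sigma_log: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_prog", "n_nonprog", "p_blood", "p_bal", "k_signature", "n_subgroups", "subgroup_block_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_drift_analytes < 0:
            raise ValueError(f"n_drift_analytes must be >= 0, got {self.n_drift_analytes}")
        if self.k_signature > self.p_blood + self.p_bal:
            raise ValueError(f"k_signature={self.k_signature} exceeds analyte universe {self.p_blood + self.p_bal}")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ValueError(f"lod_quantile must be in [0, 1), got {self.lod_quantile}")
        if not 0.0 <= self.corr_weak < self.corr_strong <= 1.0:
            raise ValueError(
                f"need 0 <= corr_weak < corr_strong <= 1, got corr_weak={self.corr_weak}, corr_strong={self.corr_strong}"
            )
        if self.sigma_log <= 0:
            raise ValueError(f"sigma_log must be positive, got {self.sigma_log}")
        reserved = (
            self._k_blood()
            + self.n_subgroups * self.subgroup_block_size
            + self.n_drift_analytes
        )
        if reserved > self.p_blood:
            raise ValueError(
                f"p_blood={self.p_blood} too small for signature + subgroup blocks + drift analytes ({reserved})"
            )

    def _k_bal(self) -> int:
        if self.p_bal == 0 or self.k_signature < 2:
            return 0
        share = round(self.k_signature * self.p_bal / (self.p_blood + self.p_bal))
        return int(min(self.p_bal, max(1, share)))

    def _k_blood(self) -> int:
        return self.k_signature - self._k_bal()


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    signature_analytes: list[str]
    signature_direction: dict[str, int]
    subgroup_labels: dict[str, int]          # progressor subject -> subgroup index
    subgroup_analytes: dict[int, list[str]]  # subgroup index -> elevated block
    drift_analytes: list[str]
    drift_direction: dict[str, int]
    bal_lods: dict[str, float]


@dataclass
class SyntheticCohort:
    """Generated tables plus their ground truth."""

    blood_tables: dict[int, AnalyteTable]  # week -> table
    bal_table: AnalyteTable
    truth: GroundTruth
    config: CohortConfig


def _strong_blocks(ids: list[str]) -> list[list[str]]:
    """Partition analytes into the small blocks sharing one strong factor."""
    blocks = [ids[i : i + _STRONG_BLOCK] for i in range(0, len(ids), _STRONG_BLOCK)]
    if len(blocks) > 1 and len(blocks[-1]) == 1:
        blocks[-2].extend(blocks.pop())
    return blocks


def _structured_z(rng: np.random.Generator, n_prog: int, n_nonprog: int, sig_cols: np.ndarray,
                  p: int, corr_strong: float, corr_weak: float) -> np.ndarray:
    """Latent standard-normal matrix with group-specific factor structure.

    Progressor rows (first ``n_prog``) share ``_N_WEAK_FACTORS`` factors with
    loading sqrt(corr_weak/m) on every signature analyte, giving dense pairwise
    correlation corr_weak.  Non-progressor rows get one factor per block of
    ~3 signature analytes at loading sqrt(corr_strong), giving sparse
    within-block correlation corr_strong.  Latent factors guarantee positive
    semi-definiteness at any dimension; every column has unit variance.
    """
    n = n_prog + n_nonprog
    z = rng.standard_normal((n, p))
    if len(sig_cols) == 0:
        return z
    k = len(sig_cols)

    # progressors: common weak component spread over several factors
    f = rng.standard_normal((n_prog, _N_WEAK_FACTORS))
    common = f.sum(axis=1) * math.sqrt(corr_weak / _N_WEAK_FACTORS)
    z[:n_prog, sig_cols] = (
        common[:, None] + math.sqrt(1.0 - corr_weak) * rng.standard_normal((n_prog, k))
    )

    # non-progressors: one strong factor per small block
    blocks = _strong_blocks(list(range(k)))
    zsig = math.sqrt(1.0 - corr_strong) * rng.standard_normal((n_nonprog, k))
    for block in blocks:
        g = rng.standard_normal(n_nonprog)
        for j in block:
            zsig[:, j] += math.sqrt(corr_strong) * g
    z[n_prog:, sig_cols] = zsig
    return z


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate a cohort with the planted structure described by ``config``.

    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_prog, n_nonprog = config.n_prog, config.n_nonprog
    n = n_prog + n_nonprog

    subjects = [f"P{i + 1:03d}" for i in range(n_prog)] + [f"N{i + 1:03d}" for i in range(n_nonprog)]
    groups = [PROGRESSOR] * n_prog + [NON_PROGRESSOR] * n_nonprog

    blood_ids = [f"BLD{i + 1:04d}" for i in range(config.p_blood)]
    bal_ids = [f"BAL{i + 1:03d}" for i in range(config.p_bal)]

    # --- assign planted roles over disjoint analyte sets ----------------------
    k_bal = config._k_bal()
    k_blood = config._k_blood()
    perm_blood = rng.permutation(config.p_blood)
    sig_blood_idx = np.sort(perm_blood[:k_blood])
    cursor = k_blood
    subgroup_idx: dict[int, np.ndarray] = {}
    for g in range(config.n_subgroups):
        subgroup_idx[g] = np.sort(perm_blood[cursor : cursor + config.subgroup_block_size])
        cursor += config.subgroup_block_size
    drift_idx = np.sort(perm_blood[cursor : cursor + config.n_drift_analytes])
    sig_bal_idx = np.sort(rng.permutation(config.p_bal)[:k_bal]) if k_bal else np.array([], dtype=int)

    signature = [blood_ids[j] for j in sig_blood_idx] + [bal_ids[j] for j in sig_bal_idx]
    sig_sign = {a: int(s) for a, s in zip(signature, rng.choice([-1, 1], size=len(signature)))}
    drift_analytes = [blood_ids[j] for j in drift_idx]
    drift_sign = {a: int(s) for a, s in zip(drift_analytes, rng.choice([-1, 1], size=len(drift_analytes)))}

    sub_labels = {subjects[i]: int(g) for i, g in enumerate(rng.integers(0, config.n_subgroups, size=n_prog))}
    subgroup_analytes = {g: [blood_ids[j] for j in idx] for g, idx in subgroup_idx.items()}

    # per-analyte positive baselines (wide, right-skewed panel)
    base_blood = 10.0 ** rng.uniform(1.0, 4.0, size=config.p_blood)
    base_bal = 10.0 ** rng.uniform(0.0, 2.0, size=config.p_bal)
    totals = 10.0 ** rng.normal(2.0, 0.15, size=n)  # BAL total protein per subject

    # combined analyte universe at week 0 so the cross-compartment signature
    # shares factor structure between blood and BAL
    p_all = config.p_blood + config.p_bal
    sig_cols_all = np.concatenate([sig_blood_idx, config.p_blood + sig_bal_idx]).astype(int)
    sig_cols_blood = sig_blood_idx.astype(int)

    half = 0.5 * config.effect_size
    shift_all = np.zeros(p_all)
    for a, j in zip(signature, sig_cols_all):
        shift_all[j] = sig_sign[a] * half
    shift_blood = shift_all[: config.p_blood]

    def apply_group_effects(z: np.ndarray, shift: np.ndarray, t_index: int) -> None:
        z[:n_prog] += shift
        z[n_prog:] -= shift
        # subgroup blocks: uniquely elevated within each progressor subgroup
        for i in range(n_prog):
            z[i, subgroup_idx[sub_labels[subjects[i]]]] += config.subgroup_effect
        # linear temporal drift in progressors only
        if t_index and config.temporal_drift:
            for a, j in zip(drift_analytes, drift_idx):
                z[:n_prog, j] += config.temporal_drift * t_index * drift_sign[a]

    blood_tables: dict[int, AnalyteTable] = {}
    bal_values = None
    for t_index, week in enumerate(TIME_WEEKS):
        if week == 0:
            z = _structured_z(rng, n_prog, n_nonprog, sig_cols_all, p_all, config.corr_strong, config.corr_weak)
            apply_group_effects(z, shift_all, t_index=0)
            z_blood = z[:, : config.p_blood]
            z_bal = z[:, config.p_blood :]
            bal_values = base_bal[None, :] * np.exp(config.sigma_log * z_bal)
        else:
            z_blood = _structured_z(
                rng, n_prog, n_nonprog, sig_cols_blood, config.p_blood, config.corr_strong, config.corr_weak
            )
            apply_group_effects(z_blood, shift_blood, t_index=t_index)
        x = base_blood[None, :] * np.exp(config.sigma_log * z_blood)
        sample_ids = [f"{s}_w{week}" for s in subjects]
        meta = pd.DataFrame(
            {
                "subject_id": subjects,
                "group": groups,
                "time_week": week,
                "compartment": "blood",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        analyte_meta = pd.DataFrame({"compartment": "blood"}, index=pd.Index(blood_ids, name="analyte_id"))
        blood_tables[week] = AnalyteTable(
            pd.DataFrame(x, index=meta.index, columns=blood_ids), meta, analyte_meta
        )

    # --- BAL table: measured on the raw scale (scaled by total protein), then
    # censored at the per-analyte empirical LOD quantile ------------------------
    measured = bal_values * (totals[:, None] / 100.0)
    lods = np.quantile(measured, config.lod_quantile, axis=0)
    mask = measured < lods[None, :]
    vals = measured.copy()
    vals[mask] = np.nan
    bal_sample_ids = [f"{s}_w0_bal" for s in subjects]
    bal_meta = pd.DataFrame(
        {
            "subject_id": subjects,
            "group": groups,
            "time_week": 0,
            "compartment": "bal",
            "total_protein": totals,
        },
        index=pd.Index(bal_sample_ids, name="sample_id"),
    )
    bal_analyte_meta = pd.DataFrame(
        {"compartment": "bal", "min_detectable": lods},
        index=pd.Index(bal_ids, name="analyte_id"),
    )
    bal_table = AnalyteTable(
        pd.DataFrame(vals, index=bal_meta.index, columns=bal_ids),
        bal_meta,
        bal_analyte_meta,
        pd.DataFrame(mask, index=bal_meta.index, columns=bal_ids),
    )

    truth = GroundTruth(
        signature_analytes=signature,
        signature_direction=sig_sign,
        subgroup_labels=sub_labels,
        subgroup_analytes=subgroup_analytes,
        drift_analytes=drift_analytes,
        drift_direction=drift_sign,
        bal_lods=dict(zip(bal_ids, lods)),
    )
    return SyntheticCohort(blood_tables=blood_tables, bal_table=bal_table, truth=truth, config=config)


def export_cohort(cohort: SyntheticCohort, directory: str | Path, overwrite: bool = False) -> dict[str, Path]:
    """Write the cohort as delimited text: one values table per compartment /
    time point, a pooled metadata table, an analyte table with BAL detection
    limits, and ground-truth tables.  Round-trips through
    :func:`progsig.io.read_analyte_table` without loss."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    metas = []
    for week, table in sorted(cohort.blood_tables.items()):
        path = directory / f"blood_week{week}.csv"
        write_analyte_table(table, path, overwrite=overwrite)
        files[f"blood_week{week}"] = path
        metas.append(table.sample_meta)
    path = directory / "bal_week0.csv"
    write_analyte_table(cohort.bal_table, path, overwrite=overwrite)
    files["bal_week0"] = path
    metas.append(cohort.bal_table.sample_meta)

    meta_path = directory / "metadata.csv"
    if meta_path.exists() and not overwrite:
        raise FileExistsError(f"refusing to overwrite existing file {meta_path}")
    meta = pd.concat(metas)
    meta.index.name = "sample_id"
    meta.to_csv(meta_path)
    files["metadata"] = meta_path

    analyte_path = directory / "analytes.csv"
    analytes = pd.concat(
        [cohort.blood_tables[0].analyte_meta, cohort.bal_table.analyte_meta]
    )
    analytes.index.name = "analyte_id"
    analytes.to_csv(analyte_path)
    files["analytes"] = analyte_path

    truth = cohort.truth
    rows = []
    for a in truth.signature_analytes:
        rows.append({"analyte_id": a, "role": "signature", "direction": truth.signature_direction[a]})
    for g, ids in truth.subgroup_analytes.items():
        for a in ids:
            rows.append({"analyte_id": a, "role": f"subgroup_block_{g}", "direction": 1})
    for a in truth.drift_analytes:
        rows.append({"analyte_id": a, "role": "drift", "direction": truth.drift_direction[a]})
    ta_path = directory / "truth_analytes.csv"
    pd.DataFrame(rows).to_csv(ta_path, index=False)
    files["truth_analytes"] = ta_path

    ts_path = directory / "truth_subjects.csv"
    pd.DataFrame(
        [{"subject_id": s, "subgroup": g} for s, g in truth.subgroup_labels.items()]
    ).to_csv(ts_path, index=False)
    files["truth_subjects"] = ts_path
    return files


def null_config(**overrides) -> CohortConfig:
    """A configuration with every planted effect switched off (all group and
    temporal effects zero); useful for type-I-error studies."""
    base = dict(effect_size=0.0, temporal_drift=0.0, subgroup_effect=0.0)
    base.update(overrides)
    return CohortConfig(**base)
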