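"""Panel I/O, protein normalization, detection-limit filtering, and z-scoring.

A :class:`CytokinePanel` is a sample-by-analyte concentration matrix with
per-sample metadata (group, sex) and optional per-analyte lower limits of
detection (LOD).  Concentrations start in pg/mL (assay supernatant) and are
converted to pg per mg total protein before analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Units",
    "CytokinePanel",
    "PhenotypeTable",
    "ExclusionReport",
    "read_panel",
    "write_panel",
    "normalize_total_protein",
    "filter_detectable",
    "zscore",
]

#: strings interpreted as a missing / non-detected cell when parsing tables
_NA_TOKENS = {"", "na", "n/a", "nan", "nd", "n.d.", "n.d", "none", "null", "-"}


class Units(str, Enum):
    """Concentration units carried by a panel."""

    PG_PER_ML = "pg_per_mL"
    PG_PER_MG = "pg_per_mg"


@dataclass
class CytokinePanel:
    """Sample-by-analyte concentration matrix with metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample identifier with one column per analyte.
    group
        Per-sample categorical label, aligned to ``values.index``.
    units
        Units of ``values`` (and ``lod``).
    sex
        Optional per-sample label.
    lod
        Optional per-analyte lower limit of detection, same units as values.
    below_lod
        Boolean mask, same shape as ``values``; True where the measured cell
        fell below the detection limit.
    """

    values: pd.DataFrame
    group: pd.Series
    units: Units = Units.PG_PER_MG
    sex: pd.Series | None = None
    lod: pd.Series | None = None
    below_lod: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.shape[1] == 0:
            raise ValueError("panel has zero analytes")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if not self.group.index.equals(self.values.index):
            self.group = self.group.reindex(self.values.index)
        if self.group.isna().any():
            missing = self.group.index[self.group.isna()].tolist()
            raise ValueError(f"samples missing a group label: {missing}")
        if self.lod is not None:
            self.lod = self.lod.reindex(self.values.columns).astype(float)
            if (self.lod.dropna() < 0).any():
                raise ValueError("negative detection limit")
        if self.below_lod is None:
            if self.lod is not None:
                with np.errstate(invalid="ignore"):
                    self.below_lod = self.values.lt(self.lod, axis=1)
            else:
                self.below_lod = pd.DataFrame(
                    False, index=self.values.index, columns=self.values.columns
                )
        else:
            self.below_lod = self.below_lod.reindex(
                index=self.values.index, columns=self.values.columns
            ).fillna(False).astype(bool)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    def subset(self, samples: Sequence[str]) -> "CytokinePanel":
        """Restrict to the given samples (order preserved as given)."""
        idx = pd.Index(samples)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise KeyError(f"unknown samples: {missing.tolist()}")
        return replace(
            self,
            values=self.values.loc[idx],
            group=self.group.loc[idx],
            sex=None if self.sex is None else self.sex.loc[idx],
            below_lod=self.below_lod.loc[idx],
        )


@dataclass
class PhenotypeTable:
    """Continuous per-sample covariates (glucose, insulin, plasma amyloid...)."""

    data: pd.DataFrame  # samples x variables

    def variable(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(
                f"phenotype {name!r} not present; have {list(self.data.columns)}"
            )
        s = self.data[name].dropna()
        if len(s) < 3:
            raise ValueError(f"phenotype {name!r} has < 3 non-missing values")
        return s


@dataclass
class ExclusionReport:
    """Record of analytes removed by the detectability filter."""

    threshold: float
    excluded: dict[str, float] = field(default_factory=dict)  # analyte -> fraction
    imputation: str = "half_lod"
    n_imputed_cells: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "threshold": self.threshold,
                "excluded": self.excluded,
                "imputation": self.imputation,
                "n_imputed_cells": self.n_imputed_cells,
            },
            indent=2,
        )


def _parse_cell(x: object) -> float:
    if isinstance(x, (int, float, np.integer, np.floating)):
        return float(x)
    s = str(x).strip()
    if s.lower() in _NA_TOKENS:
        return np.nan
    try:
        return float(s)
    except ValueError:
        return np.nan


def read_panel(
    path: str,
    metadata_path: str,
    *,
    sep: str = ",",
    sample_col: str = "sample_id",
    group_col: str = "group",
    sex_col: str = "sex",
    units: Units | str = Units.PG_PER_MG,
    lod_row: str = "__lod__",
    phenotype_cols: Sequence[str] | None = None,
) -> tuple[CytokinePanel, PhenotypeTable | None]:
    """Read a delimited panel table plus a sample-metadata table.

    The panel table has a header row of analyte names and one row per sample,
    first column holding the sample identifier.  A special row whose
    identifier equals ``lod_row`` supplies per-analyte detection limits.
    Metadata rows are matched by sample identifier; samples absent from
    either table are dropped with a warning.  Non-numeric cells (``n.d.``,
    blanks...) become missing values, never zeros.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=object)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers in panel: {dups}")
    if raw.shape[1] == 0:
        raise ValueError("panel table has zero analyte columns")

    lod = None
    if lod_row in raw.index:
        lod = raw.loc[lod_row].map(_parse_cell).astype(float)
        raw = raw.drop(index=lod_row)

    values = raw.map(_parse_cell).astype(float)

    meta = pd.read_csv(metadata_path, sep=sep, dtype=object)
    if sample_col not in meta.columns or group_col not in meta.columns:
        raise ValueError(
            f"metadata must contain {sample_col!r} and {group_col!r} columns"
        )
    meta[sample_col] = meta[sample_col].astype(str)
    if meta[sample_col].duplicated().any():
        dups = meta.loc[meta[sample_col].duplicated(), sample_col].tolist()
        raise ValueError(f"duplicate sample identifiers in metadata: {dups}")
    meta = meta.set_index(sample_col)

    common = values.index.intersection(meta.index)
    dropped = values.index.difference(meta.index).tolist() + meta.index.difference(
        values.index
    ).tolist()
    if dropped:
        warnings.warn(
            f"samples without a panel/metadata match were dropped: {sorted(dropped)}",
            stacklevel=2,
        )
    if len(common) == 0:
        raise ValueError("no samples shared between panel and metadata")
    # keep panel row order
    common = [s for s in values.index if s in set(common)]
    values = values.loc[common]
    meta = meta.loc[common]

    sex = meta[sex_col] if sex_col in meta.columns else None
    panel = CytokinePanel(
        values=values,
        group=meta[group_col],
        units=Units(units),
        sex=sex,
        lod=lod,
    )

    phenos = None
    if phenotype_cols is None:
        phenotype_cols = [
            c for c in meta.columns if c not in (group_col, sex_col)
        ]
    if phenotype_cols:
        pdata = meta[list(phenotype_cols)].map(_parse_cell).astype(float)
        if not pdata.empty:
            phenos = PhenotypeTable(pdata)
    return panel, phenos


def write_panel(
    panel: CytokinePanel,
    path: str,
    metadata_path: str,
    *,
    sep: str = ",",
    phenotypes: PhenotypeTable | None = None,
) -> None:
    """Write a panel (+ optional phenotypes) in the format ``read_panel`` reads."""
    out = panel.values.copy()
    if panel.lod is not None:
        out = pd.concat([pd.DataFrame([panel.lod.rename("__lod__")]), out])
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)
    meta = pd.DataFrame({"group": panel.group})
    if panel.sex is not None:
        meta["sex"] = panel.sex
    if phenotypes is not None:
        meta = meta.join(phenotypes.data, how="left")
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep=sep)


def normalize_total_protein(
    panel: CytokinePanel,
    protein_mg: Mapping[str, float] | pd.Series | float,
    assay_volume_mL: float = 0.05,
) -> CytokinePanel:
    """Convert pg/mL supernatant concentrations to pg per mg total protein.

    ``value_out = value_in * assay_volume_mL / protein_mg``.  The default
    assay volume is 0.05 mL (a 50 uL well); with lysates loaded at
    7.5 ug/uL that corresponds to 0.375 mg protein per well.
    """
    if panel.units is not Units.PG_PER_ML:
        raise ValueError(f"panel units are {panel.units.value}, expected pg_per_mL")
    if assay_volume_mL <= 0:
        raise ValueError("assay_volume_mL must be positive")
    if np.isscalar(protein_mg):
        protein = pd.Series(float(protein_mg), index=panel.values.index)
    else:
        protein = pd.Series(protein_mg, dtype=float).reindex(panel.values.index)
    bad = protein.index[(protein <= 0) | protein.isna()].tolist()
    if bad:
        raise ValueError(f"nonpositive or missing protein mass for samples: {bad}")

    factor = assay_volume_mL / protein
    values = panel.values.mul(factor, axis=0)
    lod = None
    if panel.lod is not None:
        # LOD is a per-analyte assay property; transform with the median factor
        lod = panel.lod * float(factor.median())
    return replace(
        panel,
        values=values,
        units=Units.PG_PER_MG,
        lod=lod,
        below_lod=panel.below_lod.copy(),
    )


def filter_detectable(
    panel: CytokinePanel,
    max_below_lod_fraction: float = 0.5,
    *,
    imputation: str = "half_lod",
) -> tuple[CytokinePanel, ExclusionReport]:
    """Drop analytes that are below the detection limit in too many samples.

    An analyte whose below-LOD fraction strictly exceeds
    ``max_below_lod_fraction`` is removed (the panel's G-CSF-style rule).
    Surviving censored cells are imputed per ``imputation``:
    ``half_lod`` (LOD/2, default), ``lod``, or ``missing`` (NaN).
    """
    if not 0 <= max_below_lod_fraction <= 1:
        raise ValueError("max_below_lod_fraction must be in [0, 1]")
    if imputation not in ("half_lod", "lod", "missing"):
        raise ValueError(f"unknown imputation {imputation!r}")

    frac = panel.below_lod.mean(axis=0)
    report = ExclusionReport(threshold=max_below_lod_fraction, imputation=imputation)
    keep = []
    for analyte in panel.analytes:
        if frac[analyte] > max_below_lod_fraction:
            report.excluded[analyte] = float(frac[analyte])
        else:
            keep.append(analyte)
    if not keep:
        raise ValueError("all analytes removed by detectability filter")

    values = panel.values[keep].copy()
    mask = panel.below_lod[keep]
    n_imputed = 0
    if mask.values.any():
        if panel.lod is None and imputation != "missing":
            raise ValueError("cannot impute censored cells without detection limits")
        for analyte in keep:
            col_mask = mask[analyte]
            if not col_mask.any():
                continue
            n_imputed += int(col_mask.sum())
            if imputation == "missing":
                values.loc[col_mask, analyte] = np.nan
            else:
                lod = float(panel.lod[analyte])
                values.loc[col_mask, analyte] = lod / 2 if imputation == "half_lod" else lod
    report.n_imputed_cells = n_imputed

    filtered = replace(
        panel,
        values=values,
        lod=None if panel.lod is None else panel.lod[keep],
        below_lod=mask.copy(),
    )
    return filtered, report


def zscore(
    panel: CytokinePanel | pd.DataFrame,
    subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Standardize each analyte to mean 0, sample SD 1 (ddof=1) within a subset.

    Standardization constants are computed on (and applied to) the selected
    subset only, because each group comparison is z-scored with respect to
    the groups it contains.
    """
    values = panel.values if isinstance(panel, CytokinePanel) else panel
    if subset is not None:
        values = values.loc[list(subset)]
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise ValueError(f"missing values in analytes {bad}; impute or drop first")
    sd = values.std(axis=0, ddof=1)
    zero = sd.index[(sd == 0) | sd.isna()].tolist()
    if zero:
        raise ValueError(f"zero-variance analytes in subset: {zero}")
    return (values - values.mean(axis=0)) / sd
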