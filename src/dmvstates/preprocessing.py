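"""Ct-matrix ingestion and limit-of-detection (LOD) relative expression.

Single cell-scale RT-qPCR reports a cycle threshold (Ct) per gene per
sample; lower Ct means higher expression, and reactions that never cross
threshold are "not detected".  All downstream analysis works on the
censored expression scale ``max(0, lod_ct - Ct)`` (a -dCt relative to the
LOD), where 0 marks entries at or below the limit of detection.

The containers here are thin dataclasses around pandas DataFrames indexed
by gene (rows) and sample (columns), with sample metadata carried
alongside.  Not-detected entries are stored as NaN in :class:`CtMatrix`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LOD_CT",
    "CtMatrix",
    "ExprMatrix",
    "BinnedMatrix",
    "ZMatrix",
    "load_ct_table",
    "to_expression",
    "quartile_bin",
    "zscore",
    "detection_fraction",
]

#: Default Ct ceiling treated as the limit of detection (cycles).  Common
#: microfluidic qPCR runs terminate near 28-30 cycles; configurable
#: everywhere it is used.
DEFAULT_LOD_CT = 28.0

#: Cell contents interpreted as "reaction not detected" when loading.
ND_TOKENS = frozenset({"", "nd", "n.d.", "na", "n/a", "nan", "not detected", "999"})

REQUIRED_META_COLUMNS = ("condition", "side")


@dataclass
class CtMatrix:
    """Raw Ct values (gene x sample) with per-sample metadata.

    ``values`` holds positive Ct cycles with NaN as the not-detected
    sentinel.  ``sample_meta`` is indexed by sample id and must provide
    ``condition`` and ``side`` for every sample; ``unit_type`` (single vs
    pool) and ``pool_size`` are carried as optional annotations.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        missing = [s for s in v.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        for col in REQUIRED_META_COLUMNS:
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample metadata lacks required column {col!r}")
        arr = v.to_numpy(dtype=float)
        if np.any(arr[np.isfinite(arr)] <= 0):
            raise ValueError("all numeric Ct values must be positive")
        # align metadata rows to the sample order of the matrix
        self.sample_meta = self.sample_meta.loc[v.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class ExprMatrix:
    """Expression relative to the LOD: ``lod_ct - Ct``, floored at 0.

    ``detected`` is False exactly where ``values`` is 0 (entry at or
    below the limit of detection).
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    lod_ct: float
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be >= 0")
        bad = (~self.detected.to_numpy()) & (self.values.to_numpy() != 0)
        if bad.any():
            raise ValueError("not-detected entries must have expression 0")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class BinnedMatrix:
    """Per-gene quartile bins: 0 = below LOD, 1-4 = quartiles of detected values."""

    bins: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.bins.to_numpy()
        if not np.isin(arr, [0, 1, 2, 3, 4]).all():
            raise ValueError("bins must lie in {0,1,2,3,4}")


@dataclass
class ZMatrix:
    """Per-gene Z scores of LOD-relative expression."""

    values: pd.DataFrame


def _parse_ct_cell(x: object, ct_ceiling: float | None) -> float:
    if x is None:
        return np.nan
    s = str(x).strip()
    if s.lower() in ND_TOKENS:
        return np.nan
    val = float(s)
    if ct_ceiling is not None and val >= ct_ceiling:
        return np.nan
    return val


def load_ct_table(
    path: str | Path,
    meta_path: str | Path,
    *,
    sep: str = "\t",
    ct_ceiling: float | None = None,
) -> CtMatrix:
    """Read a delimited gene x sample Ct table plus sample metadata.

    The first column of the table is taken as gene ids.  Blank cells and
    common not-detected encodings (``ND``, ``NA``, 999, and any Ct at or
    above ``ct_ceiling`` if given) are normalized to the NaN sentinel.

    Metadata must contain a ``sample_id`` column (or an index) covering
    every sample column of the table; a sample absent from the metadata is
    a hard error naming the sample.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    values = raw.apply(lambda col: [_parse_ct_cell(x, ct_ceiling) for x in col])
    values = pd.DataFrame(values, index=raw.index, columns=raw.columns).astype(float)

    meta = pd.read_csv(meta_path, sep=sep)
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    else:  # first column is the sample id
        meta = meta.set_index(meta.columns[0])
    meta.index = meta.index.astype(str)
    values.columns = values.columns.astype(str)
    return CtMatrix(values=values, sample_meta=meta)


def to_expression(ct: CtMatrix, lod_ct: float = DEFAULT_LOD_CT) -> ExprMatrix:
    """Convert Ct to censored expression relative to the LOD.

    Detected entries become ``lod_ct - Ct``; entries with Ct at or above
    ``lod_ct`` are reclassified as not detected (expression 0), as are
    NaN sentinels.
    """
    if lod_ct <= 0:
        raise ValueError("lod_ct must be positive")
    ctv = ct.values
    detected = ctv.notna() & (ctv < lod_ct)
    values = (lod_ct - ctv).where(detected, 0.0)
    return ExprMatrix(
        values=values, detected=detected, lod_ct=lod_ct, sample_meta=ct.sample_meta
    )


def quartile_bin(expr: ExprMatrix) -> BinnedMatrix:
    """Bin each gene's detected values into quartiles; below-LOD stays 0.

    Quartile boundaries are the 25/50/75 percentiles of the gene's
    detected values with right-closed intervals: a value equal to a
    boundary falls in the lower bin.  A gene with no detected samples
    yields an all-zero row; a gene whose detected values are all equal
    puts every detected entry in bin 1.
    """
    bins = pd.DataFrame(
        0, index=expr.values.index, columns=expr.values.columns, dtype=int
    )
    for gene in expr.values.index:
        mask = expr.detected.loc[gene].to_numpy()
        if not mask.any():
            continue
        vals = expr.values.loc[gene].to_numpy(dtype=float)
        det = vals[mask]
        q25, q50, q75 = np.percentile(det, [25, 50, 75])
        b = 1 + (det > q25).astype(int) + (det > q50).astype(int) + (det > q75).astype(int)
        row = np.zeros(len(vals), dtype=int)
        row[mask] = b
        bins.loc[gene] = row
    return BinnedMatrix(bins=bins)


def zscore(expr: ExprMatrix, include_censored: bool = True) -> ZMatrix:
    """Per-gene standardization of LOD-relative expression.

    By default censored zeros participate (matching heatmaps drawn over
    all samples); with ``include_censored=False`` only detected entries
    are standardized and censored entries are left NaN.  Population (n)
    standard deviation; zero-variance genes map to all-zero rows.
    """
    x = expr.values.to_numpy(dtype=float).copy()
    if x.shape[1] < 2:
        raise ValueError("zscore requires at least 2 samples")
    if not include_censored:
        x[~expr.detected.to_numpy()] = np.nan
    mean = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape) & ~np.isnan(x)] = 0.0
    return ZMatrix(values=pd.DataFrame(z, index=expr.values.index, columns=expr.values.columns))


def detection_fraction(
    expr: ExprMatrix, grouping: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Fraction of samples per group with expression above the LOD.

    ``grouping`` maps every sample id to a group label.  Returns a gene x
    group table of fractions in [0, 1].
    """
    g = pd.Series(grouping)
    missing = [s for s in expr.samples if s not in g.index]
    if missing:
        raise ValueError(f"samples without a group assignment: {missing}")
    g = g.loc[expr.samples]
    sizes = g.value_counts()
    if (sizes == 0).any():
        raise ValueError("empty group in grouping")
    det = expr.detected.astype(int)
    frac = det.T.groupby(g).mean().T
    return frac


def write_run_log(path: str | Path, *, lod_ct: float, **settings: object) -> None:
    """Write a small JSON log of the preprocessing settings used."""
    payload = {"lod_ct": lod_ct, **settings}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
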