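"""Per-state input-output signal-processing maps.

Each neuronal state is summarized as a signal-processing unit: input
edges from upstream brain regions, weighted by the state's expression of
the receptors for that region's ligand, and output signals
(neurotransmitters/neuropeptides) weighted by synthesis- or marker-gene
expression.  A connectivity prior — an editable table of
region -> ligand -> receptor genes and signal -> synthesis genes —
supplies the mapping; the expression data supply the weights.

Edges whose contributing genes are all below the limit of detection in a
state are pruned.  Differential maps between two conditions classify
every edge as increasing / unchanged / decreasing by relative weight
change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocessing import ExprMatrix
from .states import StatePartition

__all__ = [
    "ConnectivityPrior",
    "IOMap",
    "DifferentialIOMap",
    "load_prior",
    "build_map",
    "differential_map",
]


@dataclass
class ConnectivityPrior:
    """Region->ligand->receptor and signal->gene tables.

    ``inputs`` columns: region, ligand, genes (list of receptor genes),
    grouped (True for inputs that cannot be assigned to a single region,
    e.g. the NTS/AP/CVLM/LC group), missing_genes (panel check result).
    ``outputs`` columns: signal, genes, missing_genes.
    """

    inputs: pd.DataFrame
    outputs: pd.DataFrame

    def __post_init__(self) -> None:
        for df, name_col in ((self.inputs, "region"), (self.outputs, "signal")):
            if (df[name_col].astype(str).str.len() == 0).any():
                raise ValueError(f"empty {name_col} label in prior")
            if df["genes"].apply(len).eq(0).any():
                raise ValueError("prior row with empty gene list")

    @property
    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for df in (self.inputs, self.outputs):
            for genes in df["genes"]:
                for g in genes:
                    seen[g] = None
        return list(seen)

    def signature(self) -> tuple:
        """Hashable identity used to check two maps share a prior."""
        ins = tuple(
            (r.region, r.ligand, tuple(r.genes)) for r in self.inputs.itertuples()
        )
        outs = tuple((r.signal, tuple(r.genes)) for r in self.outputs.itertuples())
        return ins, outs


@dataclass
class IOMap:
    """Per-state weighted input edges and output signals.

    ``inputs`` columns: state, region, ligand, grouped, weight,
    detection_fraction; ``outputs``: state, signal, weight,
    detection_fraction.  Weight is the mean LOD-relative expression over
    the state's samples and the mapped genes; pruned edges are absent.
    """

    inputs: pd.DataFrame
    outputs: pd.DataFrame
    prior_signature: tuple
    min_detect_frac: float


@dataclass
class DifferentialIOMap:
    """Edge-level comparison of two maps: increasing/unchanged/decreasing."""

    edges: pd.DataFrame
    rel_threshold: float


def _parse_gene_list(s: str) -> list[str]:
    return [g.strip() for g in str(s).split(";") if g.strip()]


def load_prior(
    path: str | Path, panel: Sequence[str] | None = None, sep: str = "\t"
) -> ConnectivityPrior:
    """Load a connectivity prior from a delimited table.

    Columns: kind (in|out), region_or_signal, ligand, genes
    (semicolon-separated), grouped (bool).  Rows naming genes absent from
    ``panel`` (when given) are flagged in ``missing_genes`` and kept,
    with a warning — never dropped silently.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"kind", "region_or_signal", "ligand", "genes", "grouped"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"prior table missing columns: {sorted(missing_cols)}")
    df["genes"] = df["genes"].apply(_parse_gene_list)
    df["grouped"] = df["grouped"].astype(str).str.lower().isin({"true", "1", "yes"})

    def flag(genes: list[str]) -> list[str]:
        if panel is None:
            return []
        return [g for g in genes if g not in set(panel)]

    df["missing_genes"] = df["genes"].apply(flag)
    flagged = df[df["missing_genes"].apply(len) > 0]
    if len(flagged):
        names = sorted({g for row in flagged["missing_genes"] for g in row})
        warnings.warn(f"prior genes absent from panel: {names}", stacklevel=2)
    ins = (
        df[df["kind"] == "in"]
        .rename(columns={"region_or_signal": "region"})
        [["region", "ligand", "genes", "grouped", "missing_genes"]]
        .reset_index(drop=True)
    )
    outs = (
        df[df["kind"] == "out"]
        .rename(columns={"region_or_signal": "signal"})
        [["signal", "ligand", "genes", "missing_genes"]]
        .reset_index(drop=True)
    )
    return ConnectivityPrior(inputs=ins, outputs=outs)


def _edge_stats(
    expr: ExprMatrix, samples: pd.Index, genes: list[str]
) -> tuple[float, float, float]:
    """(weight, mean detection fraction, max per-gene detection fraction)."""
    present = [g for g in genes if g in expr.genes]
    if not present:
        return 0.0, 0.0, 0.0
    vals = expr.values.loc[present, samples].to_numpy(dtype=float)
    det = expr.detected.loc[present, samples].to_numpy()
    per_gene_frac = det.mean(axis=1)
    weight = float(vals.mean(axis=1).mean())
    return weight, float(per_gene_frac.mean()), float(per_gene_frac.max())


def build_map(
    expr: ExprMatrix,
    states: StatePartition,
    prior: ConnectivityPrior,
    min_detect_frac: float = 0.1,
) -> IOMap:
    """Aggregate expression into per-state input edges and output signals.

    The weight of an edge in a state is the mean over the state's samples
    of the mean LOD-relative expression of the mapped genes.  An edge is
    emitted only if at least one contributing gene is detected in at
    least ``min_detect_frac`` of the state's samples; otherwise the edge
    is absent (the below-LOD pruning rule).
    """
    labels = states.states
    missing = [s for s in labels.index if s not in expr.samples]
    if missing:
        raise ValueError(f"state-labelled samples absent from expression: {missing}")
    in_rows, out_rows = [], []
    for state in states.state_labels:
        samples = labels.index[labels == state]
        if len(samples) == 0:
            raise ValueError(f"state {state!r} has no samples")
        for row in prior.inputs.itertuples():
            w, frac, max_frac = _edge_stats(expr, samples, row.genes)
            if max_frac >= min_detect_frac and max_frac > 0:
                in_rows.append(
                    {"state": state, "region": row.region, "ligand": row.ligand,
                     "grouped": row.grouped, "weight": w, "detection_fraction": frac}
                )
        for row in prior.outputs.itertuples():
            w, frac, max_frac = _edge_stats(expr, samples, row.genes)
            if max_frac >= min_detect_frac and max_frac > 0:
                out_rows.append(
                    {"state": state, "signal": row.signal, "weight": w,
                     "detection_fraction": frac}
                )
    in_cols = ["state", "region", "ligand", "grouped", "weight", "detection_fraction"]
    out_cols = ["state", "signal", "weight", "detection_fraction"]
    return IOMap(
        inputs=pd.DataFrame(in_rows, columns=in_cols),
        outputs=pd.DataFrame(out_rows, columns=out_cols),
        prior_signature=prior.signature(),
        min_detect_frac=min_detect_frac,
    )


def _edge_weights(iomap: IOMap) -> dict[tuple, float]:
    w: dict[tuple, float] = {}
    for r in iomap.inputs.itertuples():
        w[("in", r.state, r.region, r.ligand)] = r.weight
    for r in iomap.outputs.itertuples():
        w[("out", r.state, r.signal, "")] = r.weight
    return w


def differential_map(
    map_a: IOMap, map_b: IOMap, rel_threshold: float = 0.25
) -> DifferentialIOMap:
    """Classify each edge as increasing / unchanged / decreasing from a to b.

    An edge increases when its comparison weight exceeds the baseline by
    more than ``rel_threshold`` relatively (w_b > w_a*(1+t)), decreases
    when w_b < w_a*(1-t), else is unchanged.  Edges absent from one map
    (pruned below LOD) enter with weight 0, so appearance/disappearance
    classify as increasing/decreasing.
    """
    if map_a.prior_signature != map_b.prior_signature:
        raise ValueError("maps were built from different priors")
    wa, wb = _edge_weights(map_a), _edge_weights(map_b)
    rows = []
    for key in sorted(set(wa) | set(wb)):
        a = wa.get(key, 0.0)
        b = wb.get(key, 0.0)
        if b > a * (1 + rel_threshold):
            cls = "increasing"
        elif b < a * (1 - rel_threshold):
            cls = "decreasing"
        else:
            cls = "unchanged"
        kind, state, target, ligand = key
        rows.append(
            {"kind": kind, "state": state, "target": target, "ligand": ligand,
             "baseline": a, "comparison": b, "delta": b - a, "class": cls}
        )
    cols = ["kind", "state", "target", "ligand", "baseline", "comparison", "delta", "class"]
    return DifferentialIOMap(
        edges=pd.DataFrame(rows, columns=cols), rel_threshold=rel_threshold
    )
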