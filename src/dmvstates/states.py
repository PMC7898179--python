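"""Neuronal-state and gene-module discovery by hierarchical clustering.

Samples (or genes) are clustered with average linkage on the Pearson
correlation distance ``d = 1 - r``, and the dendrogram is cut at the
height that parsimoniously segregates groups: among candidate flat cuts,
the one yielding the most clusters within an allowed range subject to a
minimum cluster size.

State labels are assigned alphabetically by decreasing cluster size so
that labels are stable across re-runs of identical inputs.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "Dendrogram",
    "StatePartition",
    "correlation_distance",
    "cluster",
    "cut_parsimonious",
    "compose_heatmap",
]


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage form, with item labels."""

    linkage: np.ndarray
    labels: list[str]
    linkage_method: str = "average"
    distance_name: str = "pearson"

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_items(self) -> int:
        return len(self.labels)

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "merges": self.linkage[:, :2].astype(int).tolist(),
            "heights": self.linkage[:, 2].tolist(),
            "linkage": self.linkage_method,
            "distance": self.distance_name,
        }


@dataclass
class StatePartition:
    """Sample-to-state (and optionally gene-to-module) assignments."""

    states: pd.Series
    modules: pd.Series | None = None
    cut_height: float | None = None
    module_cut_height: float | None = None
    sample_order: list[str] = field(default_factory=list)
    gene_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.states.isna().any():
            raise ValueError("every sample must have a state label")

    @property
    def state_labels(self) -> list[str]:
        return sorted(self.states.unique())

    @property
    def k(self) -> int:
        return self.states.nunique()


def correlation_distance(x: pd.DataFrame, axis: str = "samples") -> pd.DataFrame:
    """Pearson correlation distance ``1 - r`` between samples or genes.

    ``x`` is gene x sample; ``axis='samples'`` correlates columns,
    ``axis='genes'`` correlates rows.  Zero-variance items get maximal
    distance (2) to all other items, with a warning.
    """
    if axis == "samples":
        items = x.columns
        mat = x.to_numpy(dtype=float).T
    elif axis == "genes":
        items = x.index
        mat = x.to_numpy(dtype=float)
    else:
        raise ValueError("axis must be 'samples' or 'genes'")
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    sd = mat.std(axis=1)
    flat = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(mat)
    d = 1.0 - r
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance item(s); distance set to maximum (2)",
            stacklevel=2,
        )
        d[flat, :] = 2.0
        d[:, flat] = 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=items, columns=items)


def cluster(dist: pd.DataFrame, linkage_method: str = "average") -> Dendrogram:
    """Agglomerative clustering of a symmetric distance matrix."""
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage_method)
    return Dendrogram(linkage=Z, labels=list(dist.index), linkage_method=linkage_method)


def _relabel_by_size(raw: np.ndarray, items: list[str]) -> pd.Series:
    """Map integer cluster codes to letters, largest cluster first.

    Size ties are broken by the first occurrence of the cluster in item
    order, keeping labels deterministic.
    """
    codes, counts = np.unique(raw, return_counts=True)
    first_pos = {c: int(np.argmin(raw != c)) for c in codes}
    order = sorted(codes, key=lambda c: (-counts[list(codes).index(c)], first_pos[c]))
    alphabet = list(string.ascii_uppercase)
    names = {}
    for i, c in enumerate(order):
        names[c] = alphabet[i] if i < 26 else f"S{i + 1}"
    return pd.Series([names[c] for c in raw], index=items)


def cut_parsimonious(
    dend: Dendrogram,
    min_size: int = 5,
    k_range: tuple[int, int] = (2, 12),
) -> tuple[pd.Series, dict]:
    """Choose the flat cut that parsimoniously segregates groups.

    Candidate heights are midpoints between consecutive distinct merge
    heights (plus one above the root).  Among cuts whose every cluster
    has at least ``min_size`` members and whose cluster count k lies in
    ``k_range``, the cut maximizing k is selected; if several heights
    give that k, the highest (most robust) is used.  With no feasible
    cut, everything collapses to one state with a warning.

    Returns (labels, info) where labels maps item -> letter state and
    info records the chosen height and k.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    lo, hi = k_range
    if lo < 1 or hi > dend.n_items or lo > hi:
        raise ValueError("k_range must lie within [1, n_items]")
    Z = dend.linkage
    heights = np.unique(Z[:, 2])
    mids = (heights[:-1] + heights[1:]) / 2.0
    candidates = np.concatenate([mids, [heights[-1] + 1.0]])
    best: tuple[int, float, np.ndarray] | None = None
    for h in candidates:
        raw = hierarchy.fcluster(Z, t=h, criterion="distance")
        k = len(np.unique(raw))
        if not (lo <= k <= hi):
            continue
        sizes = np.bincount(raw)[1:]
        if sizes[sizes > 0].min() < min_size:
            continue
        if best is None or k > best[0] or (k == best[0] and h > best[1]):
            best = (k, float(h), raw)
    if best is None:
        warnings.warn("no feasible cut; returning a single state", stacklevel=2)
        raw = np.ones(dend.n_items, dtype=int)
        best = (1, float(heights[-1] + 1.0), raw)
    k, h, raw = best
    labels = _relabel_by_size(np.asarray(raw), dend.labels)
    return labels, {"k": k, "height": h, "min_size": min_size, "k_range": list(k_range)}


def compose_heatmap(
    partition: StatePartition,
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
) -> dict:
    """Deterministic heatmap export: ordered matrix plus state composition.

    Rows/columns follow the stored dendrogram leaf orders when present,
    else the matrix's own order.  For each state the exact condition and
    side proportions are computed from the metadata (the numbers behind
    per-state pie charts).
    """
    col_order = [s for s in (partition.sample_order or matrix.columns) if s in matrix.columns]
    row_order = [g for g in (partition.gene_order or matrix.index) if g in matrix.index]
    ordered = matrix.loc[row_order, col_order]
    comp: dict[str, dict] = {}
    for state in partition.state_labels:
        samples = partition.states.index[partition.states == state]
        sub = meta.loc[samples]
        comp[state] = {
            "n": int(len(samples)),
            "condition": sub["condition"].value_counts(normalize=True).to_dict(),
            "side": sub["side"].value_counts(normalize=True).to_dict(),
        }
    return {"matrix": ordered, "composition": comp, "states": partition.states}
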