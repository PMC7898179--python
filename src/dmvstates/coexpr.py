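"""Per-condition gene co-expression networks.

Pearson correlations between every gene pair within a condition, p
values from the exact t distribution, Benjamini-Hochberg q values over
all tested pairs, and a network keeping edges with q below a cutoff
(default q < 1e-3).  Cross-condition set algebra reports edges unique to
each condition and the shared core; hub analysis ranks genes by degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocessing import ExprMatrix

__all__ = [
    "CoexprNetwork",
    "correlate_all",
    "qvalues",
    "build_network",
    "edge_set_algebra",
    "hub_rank",
]


@dataclass
class CoexprNetwork:
    """Signed weighted edge list for one condition.

    ``edges`` columns: gene_i, gene_j (canonical i < j), r, p, q, sign.
    Isolated genes stay in ``nodes`` and are flagged in ``isolated``.
    """

    condition: str
    edges: pd.DataFrame
    nodes: list[str]
    q_cut: float
    min_pairs: int = 8

    def __post_init__(self) -> None:
        e = self.edges
        if len(e):
            if not (e["gene_i"] < e["gene_j"]).all():
                raise ValueError("edges must be canonically ordered gene_i < gene_j")
            if not e["r"].between(-1, 1).all():
                raise ValueError("r out of [-1, 1]")
            if not (e["q"] <= self.q_cut).all():
                raise ValueError("edge with q above the cutoff")

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["gene_i"], self.edges["gene_j"]))

    @property
    def isolated(self) -> list[str]:
        connected = set(self.edges["gene_i"]) | set(self.edges["gene_j"])
        return [g for g in self.nodes if g not in connected]


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r with n paired observations."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def correlate_all(
    expr: ExprMatrix, min_pairs: int = 8, mode: str = "censored"
) -> pd.DataFrame:
    """Pearson r and p for every gene pair in one condition's samples.

    ``mode='censored'`` (default) correlates LOD-relative values with
    censored zeros included, keeping the expression scale of the rest of
    the pipeline; ``mode='detected'`` uses only samples where both genes
    are detected.  Pairs with fewer than ``min_pairs`` jointly
    informative samples, or with a zero-variance member, are reported
    with NaN r/p (missing).
    """
    genes = list(expr.genes)
    x = expr.values.to_numpy(dtype=float)
    n = x.shape[1]
    rows = []
    if mode == "censored":
        if n >= min_pairs:
            sd = x.std(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                rmat = np.corrcoef(x)
            pmat = _pearson_p(np.nan_to_num(rmat, nan=0.0), n)
            for i, j in combinations(range(len(genes)), 2):
                ok = sd[i] > 0 and sd[j] > 0
                rows.append(
                    {"gene_i": genes[i], "gene_j": genes[j], "n": n,
                     "r": rmat[i, j] if ok else np.nan,
                     "p": pmat[i, j] if ok else np.nan}
                )
        else:
            for i, j in combinations(range(len(genes)), 2):
                rows.append({"gene_i": genes[i], "gene_j": genes[j], "n": n,
                             "r": np.nan, "p": np.nan})
    elif mode == "detected":
        det = expr.detected.to_numpy()
        for i, j in combinations(range(len(genes)), 2):
            both = det[i] & det[j]
            m = int(both.sum())
            r = p = np.nan
            if m >= min_pairs:
                xi, xj = x[i, both], x[j, both]
                if xi.std() > 0 and xj.std() > 0:
                    r = float(np.corrcoef(xi, xj)[0, 1])
                    p = float(_pearson_p(np.array([r]), m)[0])
            rows.append({"gene_i": genes[i], "gene_j": genes[j], "n": m, "r": r, "p": p})
    else:
        raise ValueError("mode must be 'censored' or 'detected'")
    out = pd.DataFrame(rows, columns=["gene_i", "gene_j", "n", "r", "p"])
    # canonical ordering within each pair
    flip = out["gene_i"] > out["gene_j"]
    out.loc[flip, ["gene_i", "gene_j"]] = out.loc[flip, ["gene_j", "gene_i"]].to_numpy()
    return out


def qvalues(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted values over all tested pairs."""
    p = pd.Series(p)
    if ((p.dropna() < 0) | (p.dropna() > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    q = pd.Series(np.nan, index=p.index)
    tested = p.notna()
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    return q


def build_network(
    corr_table: pd.DataFrame,
    q_cut: float = 1e-3,
    condition: str = "",
    nodes: list[str] | None = None,
    min_pairs: int = 8,
) -> CoexprNetwork:
    """Threshold a correlation table into a signed network (q < q_cut)."""
    tab = corr_table.copy()
    if "q" not in tab.columns:
        tab["q"] = qvalues(tab["p"])
    keep = tab["q"].notna() & (tab["q"] < q_cut)
    edges = tab.loc[keep, ["gene_i", "gene_j", "r", "p", "q"]].copy()
    edges["sign"] = np.sign(edges["r"]).astype(int)
    edges = edges.sort_values(["gene_i", "gene_j"]).reset_index(drop=True)
    if nodes is None:
        nodes = sorted(set(tab["gene_i"]) | set(tab["gene_j"]))
    return CoexprNetwork(
        condition=condition, edges=edges, nodes=list(nodes),
        q_cut=q_cut, min_pairs=min_pairs,
    )


def edge_set_algebra(networks: list[CoexprNetwork]) -> dict:
    """Unique / shared edge accounting across condition networks.

    unique(c) = edges present in c and in no other network; the shared
    core is the intersection of all networks.  Fractions are relative to
    each network's own edge count.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 networks")
    panels = {tuple(net.nodes) for net in networks}
    if len(panels) > 1:
        raise ValueError("networks built on mismatched gene panels")
    sets = {net.condition: net.edge_set for net in networks}
    if len(sets) != len(networks):
        raise ValueError("duplicate condition labels")
    core = set.intersection(*sets.values())
    out: dict[str, dict] = {"shared_core": sorted(core), "per_condition": {}}
    for cond, edges in sets.items():
        others = set.union(*(s for c, s in sets.items() if c != cond)) if len(sets) > 1 else set()
        unique = edges - others
        out["per_condition"][cond] = {
            "n_edges": len(edges),
            "n_unique": len(unique),
            "unique_fraction": len(unique) / len(edges) if edges else 0.0,
            "unique": sorted(unique),
        }
    return out


def hub_rank(net: CoexprNetwork, top_k: int = 5) -> pd.DataFrame:
    """Rank genes by degree; ties by summed |r| then gene name.

    Returns a table with degree, strength (sum of |r| over incident
    edges), rank (1 = most connected), and membership in the top_k.  In
    an empty network every gene ties at degree 0 and rank 1.
    """
    degree = pd.Series(0, index=pd.Index(net.nodes, name="gene"), dtype=int)
    strength = pd.Series(0.0, index=degree.index)
    for row in net.edges.itertuples():
        degree[row.gene_i] += 1
        degree[row.gene_j] += 1
        strength[row.gene_i] += abs(row.r)
        strength[row.gene_j] += abs(row.r)
    out = pd.DataFrame({"degree": degree, "strength": strength})
    out = out.sort_values(
        ["degree", "strength", "gene"], ascending=[False, False, True],
        kind="mergesort",
    )
    # competition rank on the (degree, strength) key
    keys = list(zip(out["degree"], out["strength"]))
    ranks, last_key, last_rank = [], None, 0
    for pos, key in enumerate(keys, start=1):
        if key != last_key:
            last_rank, last_key = pos, key
        ranks.append(last_rank)
    out["rank"] = ranks
    out["in_top_k"] = out["rank"] <= top_k
    return out
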