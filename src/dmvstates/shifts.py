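"""Condition-induced redistribution of neuronal states and per-gene effects.

A perturbation (sham surgery, remote ischemic preconditioning, coronary
ligation) shifts the proportions of neuronal states; this module
quantifies that redistribution with a chi-square test of homogeneity
(Monte Carlo p-value when expected cells are small), and tests per-gene
condition effects with one-way ANOVA on LOD-relative expression,
optionally restricted to a marker-positive subset (e.g. Fos+ neurons)
with Benjamini-Hochberg correction across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocessing import ExprMatrix

__all__ = [
    "ShiftResult",
    "state_distribution",
    "shift_test",
    "gene_condition_anova",
    "marker_subset",
]


@dataclass
class ShiftResult:
    """Contingency table with test statistic, p value and residuals."""

    table: pd.DataFrame
    statistic: float
    p_value: float
    residuals: pd.DataFrame
    method: str
    n_sim: int = 0


def state_distribution(
    states: pd.Series,
    meta: pd.DataFrame,
    stratify_by_side: bool = False,
) -> pd.DataFrame:
    """State proportions per condition (optionally per condition x side).

    Each column sums to 1; zero-count cells are kept as exact zeros.
    """
    meta = meta.loc[states.index]
    if stratify_by_side:
        cols = [meta["condition"], meta["side"]]
    else:
        cols = meta["condition"]
    counts = pd.crosstab(states, cols)
    return counts / counts.sum(axis=0)


def _standardized_residuals(obs: np.ndarray) -> np.ndarray:
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / n
    denom = np.sqrt(expected * (1 - row / n) * (1 - col / n))
    with np.errstate(invalid="ignore", divide="ignore"):
        res = (obs - expected) / denom
    return np.where(np.isfinite(res), res, 0.0)


def shift_test(
    table: pd.DataFrame,
    n_sim: int = 2000,
    seed: int = 0,
    force_monte_carlo: bool = False,
) -> ShiftResult:
    """Chi-square test of homogeneity of a state x condition table.

    When any expected cell count falls below 5 (or ``force_monte_carlo``),
    the p value is estimated by Monte Carlo over random tables with the
    observed margins, with the add-one correction
    ``p = (1 + #{sim >= obs}) / (n_sim + 1)``.  Standardized (adjusted)
    residuals identify which states drive a shift.
    """
    obs = table.to_numpy(dtype=float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    chi2, p, _, expected = stats.chi2_contingency(obs, correction=False)
    residuals = pd.DataFrame(
        _standardized_residuals(obs), index=table.index, columns=table.columns
    )
    method = "chi-square"
    used_sim = 0
    if force_monte_carlo or (expected < 5).any():
        rng = np.random.default_rng(seed)
        sampler = stats.random_table(
            obs.sum(axis=1).astype(int), obs.sum(axis=0).astype(int)
        )
        sims = sampler.rvs(n_sim, random_state=rng)
        exp = np.asarray(expected)
        sim_stats = ((sims - exp) ** 2 / exp).sum(axis=(1, 2))
        p = (1 + np.sum(sim_stats >= chi2 - 1e-12)) / (n_sim + 1)
        method = "chi-square (Monte Carlo)"
        used_sim = n_sim
    return ShiftResult(
        table=table, statistic=float(chi2), p_value=float(p),
        residuals=residuals, method=method, n_sim=used_sim,
    )


def gene_condition_anova(
    expr: ExprMatrix,
    gene: str,
    condition_labels: pd.Series | None = None,
    detected_only: bool = False,
) -> tuple[float, float]:
    """One-way ANOVA of a gene's LOD-relative expression across conditions.

    Censored zeros are kept by default, mirroring expression-relative-to-
    LOD summaries; ``detected_only`` restricts to detected samples.
    Returns (F, p).  An all-identical response gives F=0, p=1.
    """
    if gene not in expr.genes:
        raise KeyError(f"gene {gene!r} not in panel")
    if condition_labels is None:
        if expr.sample_meta is None:
            raise ValueError("no condition labels available")
        condition_labels = expr.sample_meta["condition"]
    condition_labels = pd.Series(condition_labels).loc[expr.samples]
    y = expr.values.loc[gene]
    if detected_only:
        keep = expr.detected.loc[gene]
        y, condition_labels = y[keep], condition_labels[keep]
    groups = [y[condition_labels == c].to_numpy() for c in condition_labels.unique()]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 samples each")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def marker_subset(
    expr: ExprMatrix,
    marker_gene: str,
    condition_labels: pd.Series | None = None,
    detected_only: bool = False,
) -> tuple[pd.Index, pd.DataFrame]:
    """Per-gene ANOVA within the marker-positive sample subset.

    The subset is every sample where ``marker_gene`` is detected (e.g.
    Fos+ activated neurons).  Each panel gene is tested with
    :func:`gene_condition_anova` inside the subset, and p values are
    Benjamini-Hochberg adjusted across genes.
    """
    if marker_gene not in expr.genes:
        raise KeyError(f"marker gene {marker_gene!r} not in panel")
    keep = expr.detected.loc[marker_gene]
    subset = expr.samples[keep]
    if len(subset) == 0:
        raise ValueError(f"marker {marker_gene!r} detected in no samples")
    meta = expr.sample_meta.loc[subset] if expr.sample_meta is not None else None
    sub = ExprMatrix(
        values=expr.values[subset],
        detected=expr.detected[subset],
        lod_ct=expr.lod_ct,
        sample_meta=meta,
    )
    if condition_labels is not None:
        condition_labels = pd.Series(condition_labels).loc[subset]
    rows = []
    for gene in sub.genes:
        try:
            f, p = gene_condition_anova(
                sub, gene, condition_labels, detected_only=detected_only
            )
        except ValueError:
            f, p = np.nan, np.nan
        rows.append({"gene": gene, "F": f, "p": p})
    out = pd.DataFrame(rows).set_index("gene")
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return subset, out
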