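"""NanoString-style miRNA analysis: detection, template matching, targets.

Digital count data for a few hundred miRNA probes across treatment
groups (control, LAD ligation, RIPC+LAD).  Probes are called detected
against the negative-control background; each detected miRNA's
group-level profile is scored against a hypothesis template —
dysregulated by injury, normalized by preconditioning — with a
label-permutation p value; candidates are prioritized by p value, fold
change, and abundance; and a consensus target-prediction table filtered
to genes expressed in the tissue yields a bipartite miRNA-target
network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MiRNACounts",
    "detect",
    "normalize_counts",
    "template_match",
    "fold_change",
    "prioritize",
    "target_network",
    "DEFAULT_TEMPLATE",
]

#: Group-level pattern: baseline at control, dysregulated under LAD
#: ligation, renormalized when RIPC precedes the ligation.
DEFAULT_TEMPLATE = {"control": 0.0, "LAD": 1.0, "RIPC+LAD": 0.0}


@dataclass
class MiRNACounts:
    """Count matrix (probe x sample) with control flags and group labels."""

    counts: pd.DataFrame
    is_negative_control: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")
        self.is_negative_control = self.is_negative_control.reindex(
            self.counts.index, fill_value=False
        ).astype(bool)
        if not self.is_negative_control.any():
            raise ValueError("at least one negative-control probe is required")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        self.groups = self.groups.loc[self.counts.columns]

    @property
    def probes(self) -> pd.Index:
        return self.counts.index

    @property
    def endogenous(self) -> pd.Index:
        return self.counts.index[~self.is_negative_control]


def detect(counts: MiRNACounts, k_sd: float = 2.0) -> list[str]:
    """Probes whose mean count exceeds background mean + k_sd * SD.

    Background is the distribution of per-probe mean counts over the
    negative-control probes.  The comparison is strict, so a probe
    sitting exactly at the threshold is not detected.  Raising ``k_sd``
    can only shrink the detected set.
    """
    neg = counts.counts.loc[counts.is_negative_control].mean(axis=1)
    threshold = neg.mean() + k_sd * neg.std(ddof=1)
    means = counts.counts.loc[counts.endogenous].mean(axis=1)
    return list(means.index[means > threshold])


def normalize_counts(counts: MiRNACounts) -> pd.DataFrame:
    """Per-sample total-count scaling of endogenous probes, then log2(x+1).

    Each sample is scaled so its endogenous total matches the mean total
    across samples (negative controls excluded from both the totals and
    the output).
    """
    endo = counts.counts.loc[counts.endogenous].astype(float)
    totals = endo.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero endogenous counts")
    scaled = endo * (totals.mean() / totals)
    return np.log2(scaled + 1.0)


def _expand_template(groups: pd.Series, template: dict[str, float]) -> np.ndarray:
    missing = set(groups.unique()) - set(template)
    if missing:
        raise ValueError(f"template lacks values for groups: {sorted(missing)}")
    return groups.map(template).to_numpy(dtype=float)


def template_match(
    profiles: pd.DataFrame,
    groups: pd.Series,
    template: dict[str, float] | None = None,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score each probe's profile against a group-level template.

    The score is the Pearson correlation between the probe's
    (normalized, log-scale) per-sample values and the template expanded
    over samples.  Significance comes from permuting the sample labels
    (``n_perm`` draws, fixed seed) with the add-one estimator; matching
    is sign-agnostic (two-sided on |score|) since a miRNA may be up- or
    down-dysregulated.  Zero-variance profiles score 0 with p = 1.

    Returns a table with score, p, and abundance per probe.  Abundance
    is the maximum group-mean level, so that a probe strongly
    down-regulated in one condition still counts as abundant if it is
    well expressed elsewhere; the grand mean would conflate abundance
    with the very dysregulation being screened for.
    """
    if template is None:
        template = DEFAULT_TEMPLATE
    groups = pd.Series(groups).loc[profiles.columns]
    counts_per_group = groups.value_counts()
    if (counts_per_group < 2).any():
        raise ValueError("need >= 2 samples per group")
    t = _expand_template(groups, template)
    if np.std(t) == 0:
        raise ValueError("template is constant across groups")
    x = profiles.to_numpy(dtype=float)
    n = x.shape[1]
    sd = x.std(axis=1)
    xc = x - x.mean(axis=1, keepdims=True)
    xs = np.divide(xc, sd[:, None] * np.sqrt(n), out=np.zeros_like(xc),
                   where=sd[:, None] > 0)
    tc = (t - t.mean()) / (t.std() * np.sqrt(n))
    scores = xs @ tc

    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_templates = tc[perm_idx]                     # n_perm x n
    perm_scores = np.abs(xs @ perm_templates.T)       # probes x n_perm
    exceed = (perm_scores >= np.abs(scores)[:, None] - 1e-12).sum(axis=1)
    p = (1 + exceed) / (n_perm + 1)
    p[sd == 0] = 1.0
    scores[sd == 0] = 0.0
    group_means = np.column_stack(
        [x[:, (groups == g).to_numpy()].mean(axis=1) for g in groups.unique()]
    )
    return pd.DataFrame(
        {"score": scores, "p": p, "abundance": group_means.max(axis=1)},
        index=profiles.index,
    )


def fold_change(
    profiles: pd.DataFrame,
    groups: pd.Series,
    numerator: str = "LAD",
    denominator: str = "control",
) -> pd.Series:
    """Linear fold change between group means of log2 profiles."""
    groups = pd.Series(groups).loc[profiles.columns]
    for g in (numerator, denominator):
        if g not in set(groups):
            raise ValueError(f"group {g!r} absent")
    num = profiles.loc[:, (groups == numerator).to_numpy()].mean(axis=1)
    den = profiles.loc[:, (groups == denominator).to_numpy()].mean(axis=1)
    return np.power(2.0, num - den)


def prioritize(
    matches: pd.DataFrame,
    folds: pd.Series,
    detected: list[str],
    p_cut: float = 0.05,
    fold_cut: float = 2.0,
    abundance_quantile: float = 0.5,
) -> pd.DataFrame:
    """Candidate miRNAs: detected, template-significant, strong fold, abundant.

    Fold-change magnitude is direction-agnostic (``max(f, 1/f)``), so a
    2-fold drop passes ``fold_cut=2`` just as a 2-fold rise does.  The
    abundance floor is the given quantile of detected-probe abundances.
    Output is sorted by p value; always a subset of the detected set.
    """
    detected_idx = matches.index.intersection(detected)
    tab = matches.loc[detected_idx].copy()
    tab["fold"] = folds.loc[detected_idx]
    tab["fold_magnitude"] = np.maximum(tab["fold"], 1.0 / tab["fold"])
    floor = tab["abundance"].quantile(abundance_quantile) if len(tab) else np.inf
    keep = (
        (tab["p"] <= p_cut)
        & (tab["fold_magnitude"] >= fold_cut)
        & (tab["abundance"] >= floor)
    )
    return tab.loc[keep].sort_values("p")


def target_network(
    candidates: list[str],
    hits: pd.DataFrame,
    expressed_genes: list[str],
    category_map: dict[str, str] | None = None,
    min_algorithms: int = 2,
) -> nx.Graph:
    """Bipartite miRNA-target network from consensus predictions.

    ``hits`` has columns miRNA, gene, plus one boolean column per
    prediction algorithm (e.g. mirwalk, rna22, miranda, targetscan).  An
    edge requires a consensus hit — more than one algorithm predicting a
    binding site — and a target present in the expressed-gene list
    (genes without robust tissue expression are filtered out).
    Candidates missing from the hit table are kept as isolated nodes
    with a warning.
    """
    if not expressed_genes:
        raise ValueError("expressed gene list is empty")
    algo_cols = [c for c in hits.columns if c not in ("miRNA", "gene")]
    if not algo_cols:
        raise ValueError("hit table has no algorithm columns")
    expressed = set(expressed_genes)
    g = nx.Graph()
    for mir in candidates:
        g.add_node(mir, kind="miRNA")
    known = set(hits["miRNA"])
    for mir in candidates:
        if mir not in known:
            warnings.warn(f"candidate {mir!r} absent from hit table", stacklevel=2)
    sub = hits[hits["miRNA"].isin(candidates)]
    for row in sub.itertuples(index=False):
        votes = sum(bool(getattr(row, c)) for c in algo_cols)
        if votes >= min_algorithms and row.gene in expressed:
            category = (category_map or {}).get(row.gene, "unannotated")
            g.add_node(row.gene, kind="gene", category=category)
            g.add_edge(row.miRNA, row.gene, votes=votes)
    return g
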