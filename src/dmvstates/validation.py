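"""Synthetic-recovery and calibration experiments.

Self-contained experiments that run the pipeline on generated data with
known truth and measure how well each stage recovers it: planted-state
recovery by the clustering stage, type-I error calibration of the
permutation and contingency tests, recovery of planted miRNA candidates,
and the closed-form check of the PCA ellipsoid volume.  Used by the test
suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import landscape, mirna, preprocessing, shifts, simulate, states

__all__ = [
    "state_recovery",
    "shift_type1_error",
    "template_type1_error",
    "mirna_recovery",
    "isotropic_ellipsoid_volume",
]


def state_recovery(seed: int) -> dict:
    """Cluster a default synthetic study and compare to planted states.

    Runs the homeostatic route (quartile-binned matrix -> Pearson
    correlation distance -> average linkage -> parsimonious cut) and
    scores the recovered partition with the adjusted Rand index.
    """
    spec = simulate.SynthSpec(seed=seed)
    ct, truth = simulate.generate_qpcr(spec)
    expr = preprocessing.to_expression(ct, lod_ct=spec.lod_ct)
    bins = preprocessing.quartile_bin(expr)
    dist = states.correlation_distance(bins.bins, axis="samples")
    labels, info = states.cut_parsimonious(states.cluster(dist))
    ari = adjusted_rand_score(truth["states"], labels.loc[truth["states"].index])
    return {"k": info["k"], "ari": float(ari), "n_samples": spec.n_samples,
            "n_genes": spec.n_genes, "k_true": spec.k_states}


def shift_type1_error(
    n_sims: int = 500, seed: int = 0, n_per_arm: int = 60,
    proportions: tuple[float, ...] = (0.3, 0.3, 0.2, 0.2), alpha: float = 0.05,
) -> dict:
    """Rejection rate of the state-shift test under a planted null.

    Both arms draw from the same state distribution; the fraction of
    simulations rejected at ``alpha`` estimates the achieved type-I
    error.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        a = rng.multinomial(n_per_arm, proportions)
        b = rng.multinomial(n_per_arm, proportions)
        table = pd.DataFrame({"a": a, "b": b})
        res = shifts.shift_test(table, n_sim=500, seed=int(rng.integers(2**31)))
        rejections += res.p_value < alpha
    return {"rate": rejections / n_sims, "n_sims": n_sims, "alpha": alpha}


def template_type1_error(
    n_null: int = 500, seed: int = 0, n_perm: int = 999, alpha: float = 0.05,
) -> dict:
    """Template-match discovery rate on null (patternless) profiles."""
    rng = np.random.default_rng(seed)
    group_sizes = {"control": 5, "LAD": 5, "RIPC+LAD": 5}
    labels, samples = [], []
    for g, n in group_sizes.items():
        labels += [g] * n
        samples += [f"{g}_{i}" for i in range(n)]
    groups = pd.Series(labels, index=samples)
    profiles = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(n_null, len(samples))),
        index=[f"null{i}" for i in range(n_null)], columns=samples,
    )
    out = mirna.template_match(profiles, groups, n_perm=n_perm,
                               seed=int(rng.integers(2**31)))
    return {"rate": float((out["p"] <= alpha).mean()), "n_sims": n_null,
            "alpha": alpha}


def mirna_recovery(n_runs: int = 200, seed: int = 0, n_perm: int = 999) -> dict:
    """Fraction of seeded runs recovering every planted miRNA candidate.

    Each run generates a fresh count table (planted fold-4 candidates
    among ~150 expressed probes), applies detection, template matching,
    and prioritization, and checks the planted set is fully recovered.
    Also reports the detected / prioritized counts of the first run.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    first: dict = {}
    for run in range(n_runs):
        run_seed = int(rng.integers(2**31 - 2))
        spec = simulate.SynthSpec(seed=run_seed)
        counts, truth = simulate.generate_mirna(spec)
        detected = mirna.detect(counts)
        norm = mirna.normalize_counts(counts)
        matches = mirna.template_match(norm, counts.groups, n_perm=n_perm,
                                       seed=run_seed)
        folds = mirna.fold_change(norm, counts.groups)
        cand = mirna.prioritize(matches, folds, detected)
        if run == 0:
            first = {"n_detected": len(detected), "n_prioritized": len(cand),
                     "n_planted": len(truth["planted"])}
        hits += set(truth["planted"]) <= set(cand.index)
    return {"rate": hits / n_runs, "n_runs": n_runs, **first}


def isotropic_ellipsoid_volume(
    seed: int = 0, n: int = 500, radius_sd: float = 2.0
) -> dict:
    """Ellipsoid volume of an isotropic unit-Gaussian group vs closed form."""
    rng = np.random.default_rng(seed)
    z = pd.DataFrame(rng.normal(size=(3, n)),
                     index=["g0", "g1", "g2"],
                     columns=[f"s{i}" for i in range(n)])
    groups = pd.Series("all", index=z.columns)
    out = landscape.pca_ellipsoids(z, groups, n_pc=3, radius_sd=radius_sd)
    expected = (4.0 / 3.0) * np.pi * radius_sd**3
    return {"volume": out.volumes["all"], "expected": float(expected), "n": n}
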