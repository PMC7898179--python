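"""Truth-labelled synthetic data for every pipeline stage.

Emulates the structure of a mesoscale single-neuron qPCR study of the
dorsal motor nucleus of the vagus: a gene x sample Ct matrix with
condition- and side-dependent planted neuronal states, gene- and
state-dependent detection dropout (reactions below the limit of
detection), planted gene modules aligned with the connectivity prior's
receptor lists, and a NanoString-style miRNA count table with an
injury-dysregulated / preconditioning-normalized pattern planted in a
few probes.

Default dimensions mirror the scale of the emulated study (about 180
samples by 170 genes; about 400 miRNA probes of which ~150 sit above
background) so runtimes and sparsity are representative.  Detection is
coupled to the expression mean through a logistic model,
``P(detect) = 1 / (1 + exp(-(mu - tau)/s))``, reflecting the empirical
pattern that weakly expressed genes drop out most.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .iomap import ConnectivityPrior, load_prior
from .mirna import MiRNACounts
from .preprocessing import CtMatrix

__all__ = [
    "SynthSpec",
    "default_prior",
    "default_panel",
    "generate_qpcr",
    "generate_mirna",
]

HOUSEKEEPING = ["Actb", "Gapdh", "Hprt1", "Ppia"]

EXTRA_PANEL_GENES = [
    "Fos", "Slc17a6", "Npy", "Gal", "Calca", "Grp", "Vip", "Penk",
    "Hcn2", "Kcnn4", "Cacna1b", "Cacna1c", "Cacna1d", "Grin2a",
    "Cebpd", "Pax4a", "Foxo4", "Camk2a", "Rgs2", "Rgs3", "Girk2",
]

#: Planted state proportions per (condition, side).  Naive is the
#: homeostatic baseline; sham surgery over-represents one state (stress
#: response, strongest on the left); RIPC diminishes one state on the
#: right while enhancing two others, mirroring the emulated study's
#: qualitative redistribution.
DEFAULT_MIXTURES: dict[tuple[str, str], tuple[float, ...]] = {
    ("naive", "left"): (0.25, 0.20, 0.15, 0.15, 0.15, 0.10),
    ("naive", "right"): (0.25, 0.20, 0.15, 0.15, 0.15, 0.10),
    ("sham", "left"): (0.10, 0.15, 0.25, 0.10, 0.15, 0.25),
    ("sham", "right"): (0.15, 0.18, 0.20, 0.12, 0.15, 0.20),
    ("RIPC", "left"): (0.22, 0.22, 0.14, 0.14, 0.14, 0.14),
    ("RIPC", "right"): (0.18, 0.30, 0.10, 0.10, 0.05, 0.27),
}


@dataclass
class SynthSpec:
    """Parameters of the synthetic study; the seed is mandatory.

    qPCR block: panel size, number of states, per-(condition, side)
    state mixtures, program means in LOD-relative (-dCt) units, noise
    SD, logistic detection parameters, LOD cycle.  miRNA block: probe
    and group counts, planted-pattern size and fold, negative-binomial
    dispersion, background level.
    """

    seed: int
    # qPCR block
    n_genes: int = 170
    k_states: int = 6
    condition_sizes: dict[str, int] = field(
        default_factory=lambda: {"naive": 60, "sham": 60, "RIPC": 60}
    )
    state_mixtures: dict[tuple[str, str], tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURES)
    )
    mu_high: float = 8.0
    mu_low: float = 2.0
    mu_housekeeping: float = 10.0
    noise_sd: float = 1.5
    detect_tau: float = 3.0
    detect_scale: float = 1.0
    lod_ct: float = 28.0
    # miRNA block
    n_probes: int = 400
    n_negative_controls: int = 8
    n_expressed: int = 150
    n_planted: int = 3
    mirna_fold: float = 4.0
    mirna_group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 5, "LAD": 5, "RIPC+LAD": 5}
    )
    nb_dispersion: float = 0.1
    background_mean: float = 15.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for key, mix in self.state_mixtures.items():
            if len(mix) != self.k_states:
                raise ValueError(f"mixture {key} has wrong length")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"mixture {key} does not sum to 1")
        if self.noise_sd <= 0 or self.detect_scale <= 0:
            raise ValueError("noise_sd and detect_scale must be positive")
        if self.n_expressed + self.n_negative_controls > self.n_probes:
            raise ValueError("more expressed+control probes than probes")
        if self.n_planted > self.n_expressed:
            raise ValueError("more planted candidates than expressed probes")

    @property
    def n_samples(self) -> int:
        return sum(self.condition_sizes.values())


def default_prior() -> ConnectivityPrior:
    """The shipped region->ligand->receptor / output-signal prior."""
    with resources.as_file(
        resources.files("dmvstates").joinpath("data/default_prior.tsv")
    ) as path:
        return load_prior(path)


def default_panel(n_genes: int = 170) -> list[str]:
    """Gene panel: every prior gene, named markers, housekeeping, filler."""
    prior = default_prior()
    panel: dict[str, None] = {}
    for g in prior.all_genes + EXTRA_PANEL_GENES + HOUSEKEEPING:
        panel.setdefault(g, None)
    i = 1
    while len(panel) < n_genes:
        panel.setdefault(f"Gene{i:03d}", None)
        i += 1
    return list(panel)[:n_genes]


def _program_means(spec: SynthSpec, panel: list[str]) -> tuple[pd.DataFrame, pd.Series]:
    """Per-state mean expression per gene, plus gene->module truth labels.

    Each input row of the connectivity prior is assigned to one state so
    that the state's samples over-express that row's receptor genes
    (letting the IO-map stage see a planted top edge per state).  The
    remaining non-housekeeping genes are spread round-robin over the
    state signature modules.
    """
    prior = default_prior()
    k = spec.k_states
    module = pd.Series("", index=pd.Index(panel, name="gene"), dtype=object)
    for g in HOUSEKEEPING:
        if g in module.index:
            module[g] = "HK"
    for i, row in enumerate(prior.inputs.itertuples()):
        state_idx = i % k
        for g in row.genes:
            if g in module.index and module[g] == "":
                module[g] = f"M{state_idx + 1}"
    counter = 0
    for g in panel:
        if module[g] == "":
            module[g] = f"M{(counter % k) + 1}"
            counter += 1
    means = pd.DataFrame(
        spec.mu_low, index=pd.Index(panel, name="gene"),
        columns=[f"state{s}" for s in range(k)],
    )
    for g in panel:
        if module[g] == "HK":
            means.loc[g] = spec.mu_housekeeping
        else:
            s = int(module[g][1:]) - 1
            means.loc[g, f"state{s}"] = spec.mu_high
    return means, module


def generate_qpcr(spec: SynthSpec) -> tuple[CtMatrix, dict]:
    """Simulate a Ct matrix with planted states, modules, and dropout.

    Detected entries get ``Ct = lod_ct - (program mean + Gaussian
    noise)`` clipped to stay below the LOD; detection itself is Bernoulli
    with the logistic probability of the entry's program mean.  Returns
    the Ct matrix plus truth: sample states, gene modules, and the
    detection-probability matrix.
    """
    if spec.k_states > spec.n_samples:
        raise ValueError("more states than samples")
    rng = np.random.default_rng(spec.seed)
    panel = default_panel(spec.n_genes)
    means, modules = _program_means(spec, panel)

    sample_ids, conditions, sides, states = [], [], [], []
    idx = 0
    for cond, size in spec.condition_sizes.items():
        for j in range(size):
            side = "left" if j < size // 2 else "right"
            mix = spec.state_mixtures[(cond, side)]
            state = int(rng.choice(spec.k_states, p=mix))
            idx += 1
            sample_ids.append(f"S{idx:03d}")
            conditions.append(cond)
            sides.append(side)
            states.append(state)
    meta = pd.DataFrame(
        {"condition": conditions, "side": sides,
         "unit_type": "single", "pool_size": 1},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    mu = means.to_numpy()[:, np.asarray(states)]          # gene x sample
    p_detect = expit((mu - spec.detect_tau) / spec.detect_scale)
    detected = rng.random(mu.shape) < p_detect
    expr = mu + rng.normal(0.0, spec.noise_sd, size=mu.shape)
    expr = np.maximum(expr, 0.01)                         # keep Ct below the LOD
    ct = np.where(detected, spec.lod_ct - expr, np.nan)
    ct_df = pd.DataFrame(ct, index=means.index, columns=sample_ids)
    truth = {
        "states": pd.Series(states, index=sample_ids, name="state"),
        "modules": modules,
        "detect_prob": pd.DataFrame(p_detect, index=means.index, columns=sample_ids),
        "program_means": means,
    }
    return CtMatrix(values=ct_df, sample_meta=meta), truth


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = m + dispersion*m^2 (Poisson limit)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def generate_mirna(spec: SynthSpec) -> tuple[MiRNACounts, dict]:
    """Simulate NanoString-style miRNA counts with a planted pattern.

    ``n_expressed`` probes get base means log-uniform above background;
    the rest sit at the negative-control background.  Planted probes
    follow (control = base, LAD = base*fold, RIPC+LAD = base), with
    alternating up/down direction, so template matching and
    prioritization have ground truth to recover.
    """
    rng = np.random.default_rng(spec.seed + 1)
    groups_list: list[str] = []
    sample_ids: list[str] = []
    for grp, size in spec.mirna_group_sizes.items():
        for j in range(size):
            sample_ids.append(f"{grp.replace('+', '_')}_{j + 1}")
            groups_list.append(grp)
    groups = pd.Series(groups_list, index=sample_ids, name="group")

    n_endog = spec.n_probes - spec.n_negative_controls
    probe_ids = [f"miR-{i + 1}" for i in range(n_endog)]
    neg_ids = [f"NEG_{chr(ord('A') + i)}" for i in range(spec.n_negative_controls)]

    expressed = probe_ids[: spec.n_expressed]
    base = np.full(n_endog, spec.background_mean)
    base[: spec.n_expressed] = np.exp(
        rng.uniform(np.log(50.0), np.log(5000.0), size=spec.n_expressed)
    )
    # planted candidates: mid/high abundance so the abundance filter keeps them
    planted = [expressed[i] for i in
               rng.choice(spec.n_expressed, size=spec.n_planted, replace=False)]
    planted_idx = [probe_ids.index(m) for m in planted]
    base[planted_idx] = np.exp(
        rng.uniform(np.log(600.0), np.log(2000.0), size=spec.n_planted)
    )

    mean_matrix = np.tile(base[:, None], (1, len(sample_ids)))
    lad_mask = (groups == "LAD").to_numpy()
    directions = {}
    for j, (mir, row) in enumerate(zip(planted, planted_idx)):
        up = j % 2 == 0
        directions[mir] = "up" if up else "down"
        factor = spec.mirna_fold if up else 1.0 / spec.mirna_fold
        mean_matrix[row, lad_mask] = base[row] * factor

    endo_counts = _nb_counts(rng, mean_matrix, spec.nb_dispersion)
    neg_counts = _nb_counts(
        rng,
        np.full((spec.n_negative_controls, len(sample_ids)), spec.background_mean),
        spec.nb_dispersion,
    )
    counts = pd.DataFrame(
        np.vstack([endo_counts, neg_counts]),
        index=probe_ids + neg_ids, columns=sample_ids,
    )
    is_neg = pd.Series(
        [False] * n_endog + [True] * spec.n_negative_controls,
        index=counts.index,
    )
    truth = {
        "expressed": expressed,
        "planted": planted,
        "directions": directions,
        "base_means": pd.Series(base, index=probe_ids),
    }
    return MiRNACounts(counts=counts, is_negative_control=is_neg, groups=groups), truth


def write_qpcr_tables(ct: CtMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write the Ct matrix and metadata in the formats the loaders read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ct_path = out / "ct_matrix.tsv"
    meta_path = out / "sample_meta.tsv"
    ct.values.to_csv(ct_path, sep="\t", na_rep="ND", index_label="gene")
    ct.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")
    return {"ct": ct_path, "meta": meta_path}
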