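"""miRNA detection, template matching, and target-network filtering.

Simulates a NanoString-style count table (control / LAD / RIPC+LAD,
three planted candidates dysregulated 4-fold by LAD and renormalized by
RIPC), detects probes above the negative-control background, scores the
injury-dysregulated/preconditioning-normalized template, prioritizes
candidates, and builds a consensus target network.
"""

import pandas as pd

from dmvstates import mirna, simulate

spec = simulate.SynthSpec(seed=1)
counts, truth = simulate.generate_mirna(spec)
print(f"{counts.counts.shape[0]} probes x {counts.counts.shape[1]} samples "
      f"({int(counts.is_negative_control.sum())} negative controls)")

detected = mirna.detect(counts, k_sd=2.0)
print(f"{len(detected)} probes detected above background "
      f"({spec.n_expressed} planted expressed)")

norm = mirna.normalize_counts(counts)
matches = mirna.template_match(norm, counts.groups, n_perm=9999, seed=1)
folds = mirna.fold_change(norm, counts.groups, numerator="LAD",
                          denominator="control")
candidates = mirna.prioritize(matches, folds, detected,
                              p_cut=0.05, fold_cut=2.0)
print("prioritized candidates (planted:", ", ".join(truth["planted"]) + "):")
print(candidates[["score", "p", "fold", "abundance"]].round(3).to_string())
# The planted candidates surface with near-extreme template scores,
# permutation p at the resolution floor, and |fold| >= 4.

# consensus target network for the top candidate, from a toy
# prediction table (real use: a precomputed miRWalk/RNA22/miRanda/
# TargetScan hit table)
top = candidates.index[0]
hits = pd.DataFrame({
    "miRNA": [top] * 3,
    "gene": ["Gria1", "Gabra1", "Scn1a"],
    "mirwalk": [True, True, True],
    "rna22": [True, False, True],
    "miranda": [False, False, True],
    "targetscan": [True, False, False],
})
net = mirna.target_network([top], hits,
                           expressed_genes=["Gria1", "Scn1a"])
print(f"target network: {net.number_of_edges()} consensus edges "
      "(>=2 algorithms, expressed genes only)")
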