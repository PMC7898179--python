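"""Build per-state input-output signal-processing maps.

Each neuronal state becomes a signal-processing unit: input edges from
brain regions weighted by receptor expression (via the shipped
region->ligand->receptor prior), output signals weighted by
transmitter/peptide synthesis genes, with below-LOD edges pruned.  A
differential map between two conditions classifies edges as
increasing / unchanged / decreasing.
"""

from dmvstates import iomap, preprocessing, simulate, states

spec = simulate.SynthSpec(seed=1)
ct, truth = simulate.generate_qpcr(spec)
expr = preprocessing.to_expression(ct)
labels = truth["states"].map(lambda s: chr(65 + s))
part = states.StatePartition(states=labels)

prior = simulate.default_prior()
m = iomap.build_map(expr, part, prior, min_detect_frac=0.1)
print(f"{len(m.inputs)} input edges, {len(m.outputs)} output signals")
top = m.inputs.sort_values("weight", ascending=False).head(5)
print(top[["state", "region", "ligand", "weight"]].to_string(index=False))
# The heaviest edges are the planted receptor programs: each state
# over-expresses the receptors of the regions assigned to it, so its
# input edge weight (mean expression over samples and receptor genes,
# in -dCt units above the LOD) dominates.

# differential map: naive vs RIPC samples of one state
meta = expr.sample_meta
for cond in ("naive", "RIPC"):
    keep = meta.index[meta["condition"] == cond]
    sub = preprocessing.ExprMatrix(
        values=expr.values[keep], detected=expr.detected[keep],
        lod_ct=expr.lod_ct, sample_meta=meta.loc[keep],
    )
    sub_part = states.StatePartition(states=labels.loc[keep])
    if cond == "naive":
        map_a = iomap.build_map(sub, sub_part, prior)
    else:
        map_b = iomap.build_map(sub, sub_part, prior)

diff = iomap.differential_map(map_a, map_b, rel_threshold=0.25)
print(diff.edges["class"].value_counts().to_string())
strong = diff.edges[diff.edges["baseline"] > 4]
print(strong["class"].value_counts().to_string())
# The planted (high-weight) edges stay unchanged: state programs are
# condition-independent in this simulation, and the shifting happens
# between states.  Weak near-LOD edges fluctuate with the small
# per-state-per-condition sample counts and cross the 25% threshold.
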