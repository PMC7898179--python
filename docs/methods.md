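# Methods

## The measurement model

Single cell-scale microfluidic RT-qPCR reports a cycle threshold (Ct) per
gene per reaction; lower Ct means higher expression, and reactions that
never cross threshold are "not detected". We work throughout on the
censored expression scale

    x = max(0, Ct_LOD − Ct),

a −ΔCt relative to the limit of detection: x = 0 means at or below the
LOD, and each unit is one qPCR cycle (~2-fold in template). The LOD cycle
is not a property of the data file but of the instrument run; it defaults
to 28 cycles (a common microfluidic ceiling) and every downstream result
is parameterized by it. Entries loaded with Ct at or above the LOD are
reclassified as not detected. No housekeeping normalization or efficiency
correction is applied by default: the analyses are rank- and
correlation-based or explicitly on the LOD-relative scale, and a
housekeeping pre-step can be layered on by transforming the Ct matrix
before loading.

Censored zeros are *kept* by default in quartile bins, Z scores, ANOVA,
and correlations. This matches summaries of "expression relative to the
LOD" over all samples, where non-detection is informative (it is how
low-expressing states differ from high-expressing ones), at the cost of a
point mass at zero that makes Pearson correlations partly
detection-driven. Detected-only variants are exposed
(`zscore(include_censored=False)`, `correlate_all(mode="detected")`); the
detected-only Z score leaves censored entries NaN rather than imputing
them, so exclusion is visible downstream.

## State discovery

Samples (or genes) are clustered by average-linkage agglomeration on the
Pearson correlation distance d = 1 − r (d ∈ [0, 2]; zero-variance items
are pushed to the maximum distance 2 with a warning rather than dropped,
so sample sets stay intact). For sample states the homeostatic analysis
clusters the quartile-binned matrix; for perturbation studies the Z score
of −ΔCt is used; both are exposed and share the convention.

The flat cut is chosen parsimoniously: candidate heights are midpoints
between consecutive distinct merge heights (plus one above the root);
among cuts where every cluster has at least `min_size` members (default
5) and the cluster count lies in `k_range` (default 2–12), the cut
maximizing k is taken, using the highest such height for robustness. With
no feasible cut everything collapses to one state with a warning. State
labels are assigned alphabetically by decreasing cluster size, which
makes labels stable across re-runs; published figure labels (A–F, U–Z)
are presentation choices, not invariants.

## State shifts

State-by-condition contingency tables are tested with a chi-square test
of homogeneity; when any expected cell is below 5 the p value is replaced
by Monte Carlo over random tables with the observed margins (2000 draws,
fixed seed, add-one estimator). The source does not name a test for these
shifts, so the choice is ours; adjusted standardized residuals identify
the driving states. Per-gene condition effects use one-way ANOVA on the
censored-inclusive −ΔCt, optionally inside a marker-positive subset
(samples where the marker, e.g. Fos, is detected) with BH correction
across genes. Left/right sides are pooled by default with a flag to
stratify. Animal-level nesting is out of scope (no sample→animal map).

## Input–output maps

The connectivity prior is data, not code: a TSV of input rows
(region, ligand, receptor genes — e.g. TMN → histamine → Hrh1/2/3) and
output rows (signal, synthesis/marker genes — e.g. NE → Th/Ddc/Dbh),
shipped with the package and user-replaceable. Inputs that cannot be
assigned to a single region (dopamine/GABA/norepinephrine from the
NTS/AP/CVLM/LC complex) are flagged `grouped` and rendered as one pooled
source. Receptor genes absent from the assay panel are flagged, never
silently dropped.

Edge weight in a state = mean over the state's samples of the mean
LOD-relative expression of the mapped genes (mean-of-means; reported with
the mean per-gene detection fraction). The underlying figure convention
gives only proportionality of line thickness to receptor expression, so
this aggregation is our explicit reconstruction, isolated in one function
(`iomap._edge_stats`) for easy revision. An edge is emitted only if at
least one contributing gene is detected in ≥ `min_detect_frac` (default
0.1) of the state's samples — the below-LOD pruning rule. Differential
maps classify each edge by relative change: increasing if
w_b > w_a(1 + t), decreasing if w_b < w_a(1 − t), else unchanged, with
t = 0.25 by default (the figure threshold is unstated); the
classification is scale-free, and edges pruned in one condition enter at
weight 0 so appearance/disappearance classify as increasing/decreasing.

## Co-expression networks

Within each condition, Pearson r and exact t-distribution p values are
computed for every gene pair (censored-inclusive by default; pairs with
fewer than `min_pairs` = 8 informative samples are missing, which guards
against spurious perfect correlations in tiny groups). Benjamini–Hochberg
q values are computed over all tested pairs within the condition, and
edges kept at q < 10⁻³. Note Pearson r is invariant to per-gene affine
transforms, so correlating Z scores or raw −ΔCt is identical. Unique
edges per condition, the all-condition shared core, and degree-ranked
hubs (ties by summed |r|, then name; competition ranking, so an empty
network ties everyone at rank 1) complete the module. Storey q values,
partial correlations, and scale-free fit testing are out of scope.

## Landscape

The minimum spanning tree is built over pairwise Euclidean distances
between sample Z-profiles. Exact-zero distances (duplicate samples) are
lifted to a negligible weight (1e-300) before the sparse-graph MST so
their edges are not read as "no edge", then reported at true length 0.
Tree distances come in two metrics — hops and summed Euclidean length —
because published "distance in the MST" phrasing is ambiguous between
them.

Terminal vs transitional states: a member node is *leaf-side* when
removing it leaves at most one component containing nodes of another
state (i.e., it does not lie *between* other states on the tree). A state
is terminal when ≥ 70% of its members are leaf-side (threshold
configurable), else transitional — its members bridge other states, as a
population caught mid-shift would. An earlier same-state-neighbor rule
was rejected because any large contiguous middle segment of a path
satisfies it. Singleton states are terminal by convention and flagged.

PCA ellipsoids: PCA is fit on all samples jointly (sign convention: the
largest-|loading| entry of each component is positive, for determinism);
each group is summarized by its centroid and covariance in the first 3 PC
scores. The ellipsoid at radius 2 SD (figure convention unstated;
configurable) has volume (4/3)π·∏(2·√λᵢ); containment of group g in
group h is the fraction of g's points with Mahalanobis distance ≤ 2 from
h's centroid under h's covariance. Note that at 2 SD a trivariate
Gaussian contains only ~74% of its own mass, so containment fractions
should be read against that baseline, not against 1.

## miRNA analysis

Detection: a probe is detected when its mean count exceeds the mean plus
`k_sd` = 2 SDs of the per-probe means of the negative-control probes
(strict inequality; the exact platform background rule is isolated and
configurable). Normalization: per-sample total-count scaling over
endogenous probes, then log2(x+1); both steps are replaceable.

Template matching scores each probe's per-sample profile against a
group-level template (default: control = 0, LAD = 1, RIPC+LAD = 0 — the
injury-dysregulated, preconditioning-normalized pattern) by Pearson
correlation, with p from sample-label permutations (default 10,000,
fixed seed, add-one estimator). Matching is two-sided on |score| because
candidates may be up- or down-dysregulated. Prioritization requires
detection, p ≤ p_cut, direction-agnostic fold magnitude
max(f, 1/f) ≥ 2 between LAD and control, and abundance at or above a
quantile (default median) of detected-probe abundances. Abundance is the
*maximum group-mean* log2 level rather than the grand mean: a probe
4-fold down in LAD is still abundant if well expressed in controls, and a
grand mean would conflate abundance with the very dysregulation being
screened for. Target networks keep consensus predictions (> 1 algorithm)
restricted to a user-supplied expressed-gene list; live database queries
and seed-sequence scanning are out of scope.

## Synthetic data

The generator emulates the study structure at its native scale so
runtimes and sparsity are representative: 170 genes × 180 samples, six
states, three conditions (naive/sham/RIPC, 60 each, balanced left/right)
with per-(condition, side) state mixtures in which sham over-represents
one state (strongest left) and RIPC depletes one state on the right while
enhancing two others. Each state over-expresses a signature module
(mean 8 cycles above LOD vs background 2, noise SD 1.5, housekeeping 10);
the receptor genes of each prior input row are assigned to one state's
module, so IO-map recovery has planted top edges. Detection is logistic
in the program mean, P(detect) = 1/(1+exp(−(μ−τ)/s)) with τ = 3, s = 1,
coupling dropout to expression as seen empirically (low expressors drop
out most; overall ~40% of reactions detected). Detected Ct is
lod − (μ + noise), clipped to stay below the LOD.

miRNA block: 400 probes (8 negative controls at background mean 15),
150 expressed with base means log-uniform in [50, 5000], negative
binomial counts with dispersion 0.1 (var = m + 0.1 m²; Poisson in the
dispersion → 0 limit), groups control/LAD/RIPC+LAD at n = 5. Three
planted candidates at mid/high base abundance follow
(control = base, LAD = base×4 or base/4 alternating, RIPC+LAD = base).

What the generator does **not** emulate: amplification chemistry and
primer efficiency, spatial capture artifacts, animal-level nesting,
sub-state structure within states, and continuous trajectories between
states (planted states are discrete, so landscape branch calls on default
data are all terminal; trajectory behavior is exercised with purpose-built
inputs). Passing recovery tests therefore show the pipeline is correct
and well-calibrated under the planted model, not that real DMV data will
cluster this cleanly.

## Numerical conventions and degenerate inputs

Population (n) SD in Z scores; right-closed quartile intervals with ties
collapsing to the lower bin and all-equal genes in bin 1; zero-variance
genes → all-zero Z rows; zero-variance profiles → template score 0,
p = 1; degenerate group covariance → ellipsoid volume 0, flagged;
all-censored genes → all-zero bin rows; empty marker subsets, empty
groups, degenerate contingency margins, and mismatched priors or panels
are hard errors. All stochastic steps (Monte Carlo p values, permutation
tests, the generator) take explicit seeds and are reproducible
bit-for-bit under them.

## Problem sizes

Default test and validation runs use the generator's native scale
(180 × 170; 400 miRNA probes × 15 samples), 500-simulation calibration
runs, 200-seed miRNA recovery, and 999–20,000 permutations depending on
the resolution the check needs.
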