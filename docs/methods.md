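# Methods

This note documents the model conventions, the tunable parameters, the
phantom generator's scope, and the numerical choices made where the design
was genuinely open.

## Patch grid

Patches are axis-aligned parallelepipeds of exactly V voxels in the shared
registered space. Because the method never states patch edge lengths, only
the volume V, the package uses the most isotropic factorization of V (the
ordered factor triple minimizing max-edge/min-edge, ties broken by the
lexicographically smallest triple): cubes where V is a perfect cube
(1000 → 10×10×10), near-cubes otherwise (3000 → 10×15×20, 5000 → 10×20×25).
Isotropy maximizes the chance that a patch samples one local texture rather
than a pencil through several structures. A prime V degrades to (1,1,V)
with a logged warning.

The x axis is taken as left–right. Tiling grows outward from the medial
sagittal plane at `floor(X/2)` in both directions so the hemispheres get
mirror-homologous boxes (exactly so for even X); on y and z the grid starts
at voxel 0 — a convention fixed for reproducibility, since only the
midplane anchoring is intrinsic to the method. Incomplete boundary boxes
are dropped: every node must be a full V-voxel patch so that patch vectors
are comparable across nodes and subjects.

A patch becomes a network node iff its non-brain fraction does not
*exceed* 10% (brain fraction ≥ 0.9; a patch at exactly 90% brain is kept).
The comparison is done on integer voxel counts, so the boundary is exact.

## Layer networks

Patch vectors are flattened x-fastest, identically for every subject, so
element t always refers to the same voxel of the shared space. The link
weight is |Pearson r| between patch vectors; weights strictly below 0.3 are
set to zero (|r| = 0.3 is kept — "lower than" is strict). The absolute
value is taken first and the threshold applied to it. A zero-variance
patch (e.g. flat background inside the mask) has no defined correlation
and contributes weight 0 rather than NaN. Weight matrices are dense; N is
at most a few thousand at the finest scale, so N² doubles fit comfortably
in memory.

## Nodal metrics and the 8N features

Per layer α and node i: degree `k_i` (count of nonzero weights), strength
`s_i = Σ_j w_ij`, inverse participation ratio `y_i = Σ_j (w_ij/s_i)²`
(defined as 0 for isolated nodes, avoiding NaN while reading naturally as
"no participation"), and the conditional means of s and y over the nodes
sharing the node's degree. Conditional metrics are materialized per node
(each node carries its degree class's mean), which is what makes every
metric contribute N columns and the total 8N.

The multiplex degree is `k_multi_i = Σ_j a_ij` with `a_ij = 1` iff at
least one layer links i and j; it dominates every single-layer degree by
construction. "Weighing the single-layer quantities on the multiplex
degree" is under-determined, so the package fixes one convention and
isolates it in a single function (`multiplex_features`) so it can be
swapped: the nodal multiplex metrics scale the layer metric by the
normalized multiplex degree, `multiS_i = s_i · k_multi_i/(N−1)` (likewise
multiY), and the conditional multiplex metrics condition s and y on
k_multi classes instead of degree classes. This uses k_multi exactly once
per quantity and reduces to the single-layer metrics on a complete
multiplex.

Feature filtering drops constant columns (which covers null mean and
variance) and then scans columns in their fixed block order, dropping any
later column whose signed Pearson correlation with an already-kept column
exceeds 0.95; the retained partner is recorded. The greedy first-kept scan
makes the operation deterministic and idempotent. Signed (not absolute)
correlation is used, mirroring the ">0.95" phrasing; the choice is
swappable at one call site.

## Cross-validation and feature selection

Each round: the majority class is undersampled without replacement to the
minority size (the "balanced datasets" reading of stratification; the
alternative — proportional stratification — is a one-line change in
`stratify_round`), each class is split 80/20 with counts rounded to
nearest and at least one validation subject per class, a 500-tree random
forest (feature subsample √p per split) is fit on the training set, and
features whose importance strictly exceeds the third quartile (linear
interpolation between order statistics) are selected. Importance is
Breiman-style out-of-bag permutation importance: per tree, its out-of-bag
rows are scored before and after permuting one feature, and decreases are
averaged over all trees. Only features a tree actually splits on are
permuted — the others contribute an exact zero — which makes the exact
computation fast. If no feature exceeds the quartile (degenerate
importance distribution), the round falls back to the full feature set
with a logged warning.

A second forest is trained on the selected features only and scored on the
held-out validation subjects (probability cutoff 0.5; the case class is
"positive" for sensitivity). Selection and training never see validation
rows; the test suite poisons validation rows and verifies the selection is
unchanged. Per-round seeds derive from `SeedSequence((seed, round))`, so
any round is reproducible in isolation and the full run is deterministic.

The Wilson score interval on the mean accuracy uses n = the pooled number
of validation classifications (rounds × validation-set size); the method
does not pin this n down, and the choice is recorded here rather than
inferred.

## Feature-stability assessment

A feature selected in c of R rounds is tested one-sided against the null
proportion p0 = 0.25 — the fraction the top-quartile rule selects per
round by construction — with the continuity-corrected chi-square test of
given proportions (the `prop.test` form); an exact binomial alternative is
provided and serves as the test oracle. Significance requires
p < α/N with α = 0.05 and N the *node* count (not 8N), exactly as the
selection rule that motivated the divisor states. Significant features map
to their patches; with a label volume, a region is reported for a patch
when it occupies strictly more than 10% of the patch's voxels.

**Known limitation — the null proportion test is anticonservative on a
fixed cohort.** The test treats a feature's selection as independent
Bernoulli(p0) draws across rounds, but all rounds resample one finite
cohort: training sets overlap heavily, so whichever features happen to
separate the groups in that cohort — under a true null, the best of ~100
features at n = 30 reaches |t| ≈ 3 by chance — are ranked top-quartile in
nearly every round. Their selection frequencies concentrate near 100%
rather than fluctuating around 25%, and Bonferroni over features cannot
repair dependence across rounds. On null phantom cohorts this flags on the
order of a quarter of the surviving features. Selection frequencies and
the recovery of strongly planted effects are unaffected; but the
"significant" label should be read as *stably selected in this cohort*,
not as a calibrated familywise error statement. A calibrated alternative
(label-permutation null for the selection frequencies) is out of scope
here.

A second, milder caveat: patch attribution happens after the >0.95
correlation filter, so when two strongly affected patches produce
near-duplicate feature columns, the later patch's columns are dropped in
favor of the earlier patch's and only the retained patch is flagged. The
`dropped` provenance (feature, reason, retained partner) records exactly
which patches were folded into which, so no affected area is silently
lost — it is reported under its partner.

## Phantom generator

The generator emulates exactly what the pipeline assumes of its input:
co-registered, skull-stripped, intensity-normalized volumes, two groups,
group differences confined to known patches. The shared template is a sum
of two unit-variance smooth Gaussian random fields — a fine texture
(kernel width 2 voxels) and a coarse component (width ≈ one fifth of the
smallest edge, weight 3) standing in for global tissue-intensity
structure — standardized inside the brain mask and zero outside. The
coarse component matters: short-range texture alone leaves disjoint
patches nearly orthogonal, and the control networks would be empty below
the 0.3 threshold. The weight was calibrated once so that a control
layer has a nontrivial mean degree, before any classifier was run.
The mask is either the full volume or an ellipsoid with semi-axes 0.45 of
each edge, mirror-symmetric about the midplanes.

Subjects add i.i.d. Gaussian noise (default SD 0.2 template-SD units)
inside the mask. Case subjects additionally carry the planted effect in
the stated patches: `mean_shift` adds a constant (in template-SD units) —
note Pearson weights are affine-invariant, so this deliberately produces
*no* network signal and serves as a generator-level control; `decorrelate`
replaces a fraction `min(magnitude, 1)` of the patch's variance with an
independent smooth field matched in mean and SD (variance-preserving
square-root blend), the patch-level analogue of focal edema or hemorrhage
destroying normal texture. The replacement texture uses kernel width 1,
finer than the template's: a width-2 field inside an 8-voxel box spans so
few independent dimensions that its chance correlation with intact patches
would routinely exceed the link threshold, i.e. the "decorrelated" patch
would gain spurious edges.

Per-subject random streams derive from `SeedSequence((seed, subject))`, so
cohorts are bit-reproducible and independent of evaluation order.

What the phantom does **not** model: bias fields, motion, partial-volume
effects, anatomically shaped lesions, registration error, scanner
differences. Passing tests therefore demonstrate the correctness and
statistical behavior of the pipeline, not clinical performance; no
clinical classification numbers are claimed or reproduced here.

## Problem sizes in the test suite

The acceptance-level phantom study uses 40³ volumes, 512-voxel patches
(~28 nodes inside the ellipsoid mask), 15+15 subjects and 100 CV rounds —
chosen as the smallest sizes at which every stage (masking, filtering,
selection, assessment) is exercised with non-trivial statistics. Unit
tests run on 16³–24³ volumes with fewer rounds and smaller forests. The
full-size defaults (scales 1000–8000, 1,000 rounds, 500 trees) remain
the configuration defaults for real-size volumes.
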