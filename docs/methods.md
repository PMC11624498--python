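# Methods

This note documents the models, estimators and design choices behind
`rsomvasc`, in the order the pipeline runs.

## Problem setting

Raster-scan optoacoustic mesoscopy (RSOM) images the skin microvasculature at
micrometre-to-millimetre scale. Reconstructed volumes are split into two
co-registered acoustic frequency bands — low (10–40 MHz), dominated by larger
microvessels, and high (40–120 MHz), dominated by smaller ones. During a
post-occlusive reactive hyperemia (PORH) test, one volume is acquired per
minute: a baseline scan, three scans under supra-systolic brachial cuff
occlusion, and two after cuff release. Impaired endothelial function blunts
the hyperemic overshoot, so the dynamics of morphometric features extracted
from these volumes act as a functional readout of microvascular health. The
package quantifies those dynamics, builds a per-minute disease index and
tests it for confounding.

The timeline is encoded as `baseline, occl1, occl2, occl3, hyp1, hyp2`
(minutes); all geometry is in micrometres, with axis 0 pointing into the
skin.

## Dermal layer segmentation

The skin surface is located per lateral column as the first sustained rise
(two consecutive voxels above 25 % of the global maximum) of the
depth-smoothed summed-band profile, refined to the first voxel whose raw
value clears the threshold (the depth smoothing otherwise biases the surface
one voxel shallow); empty columns are filled from their nearest detected
neighbour and the map is median-smoothed laterally (default window 50 µm).
The epidermis is modelled as a fixed-thickness band below the surface
(default 100 µm) and the dermis (DE) as the next `de_um` (default 500 µm) of
depth, clipped to the volume with a logged warning. The fixed band is a
deliberately simple, reproducible stand-in for signal-based dermo-epidermal
junction detection and is isolated behind the `segment_dermis` interface so a
different strategy can be swapped in. Depth is measured along z only;
surface tilt at mesoscopy scale is small.

Vessels are segmented per frequency band inside the DE by Otsu's threshold
on the in-band intensities (default) or a fixed upper percentile. A band
whose Otsu threshold does not clear the noise floor of its own sub-threshold
population (mean + 5 SD) is treated as vessel-free — without this check,
Otsu on a band that contains no vessels simply splits the noise. Components
below `min_component_size` (default 27 voxels, i.e. a 3×3×3 cube) are
removed. Both thresholds are relative, so segmentation is invariant to
global positive intensity rescaling.

## Skeleton graph and the 18 features

The vessel mask is reduced to a 3-D skeleton (`skimage.morphology.skeletonize`)
and converted to a graph: skeleton voxels with 26-neighbour degree ≥ 3 form
branch points, degree-1 voxels are endpoints, and adjacent branch-point
voxels are merged into junction nodes at their centroid. Branches are traced
deterministically (lexicographic voxel order) between nodes; pure cycles
become branches with coincident ends. Three artefact controls matter in
practice:

- **Spur pruning.** Branches with an endpoint end shorter than
  `prune_len_um` (default 50 µm) are removed and the graph re-derived once.
- **Junction-blob contraction.** Inside a junction of thick vessels the
  medial axis fragments into several nearby branch points; junction pairs
  linked by a branch shorter than 1.5× the local diameter are contracted
  into one node, and self-loops below the same bound are dropped.
- **Degree-2 dissolution.** Nodes left with exactly two incident branches
  are not junctions; their branches are concatenated.

Per-point radii are the Euclidean distance transform of the vessel mask
evaluated along the skeleton. The raw EDT overestimates the true radius by a
fraction of a voxel; at radii of three voxels and above the relative error
stays under ~6 %, which bounds diameter recovery well inside the 15 %
discretisation tolerance the tests assert. Radii below about two voxels are
not resolvable and phantoms for quantitative recovery keep radii above
~2.5 voxels in every PORH phase.

Branch length and tortuosity are measured on a cubic smoothing spline fitted
to the traced centreline (residual budget ≈ (spacing/3.2)² per point, raw
polyline fallback for very short branches): the raw voxel chain overestimates
the length of a smooth curve by several percent (staircase effect), while the
spline recovers a semicircle's tortuosity to within ~0.01 of π/2 and a
helix length to within ~1 %. Tortuosity is spline length over the chord
between the smoothed curve ends (cycles: undefined, excluded from averages
but still counted). Branch volume integrates πr² along the spline. Junction
angles use, per incident branch, the unit vector from the junction node to
the k-th skeleton point leaving it (default k = 3), averaged over unordered
branch pairs.

The 18 dermal features are: mean junction angle; mean branch length,
tortuosity, length-to-width ratio, diameter and volume; branch count;
junction density (mm⁻³ of DE); vascular density (vessel voxel fraction of
DE); junctions-to-vessels ratio; junction-to-junction and
junction-to-endpoint branch counts; junction count; mean DE thickness; total
vessel area (en-face projection, mm²); mean summed-band signal in vessels
and in the DE; and DE area on the (z, x) side projection. The scale-of-detail
classes — micro (f1–f6, single-vessel), meso (f7–f13, network organisation),
macro (f14–f18, whole-layer) — follow the single-vessel/network/whole-layer
reading of the three scales; the mapping is data (`DEFAULT_SCALE_MAP`),
overridable in configuration, because the printed feature-to-scale table is
not machine-recoverable from the source text. Empty graphs yield zero counts
and missing (NaN) mean-type features, which are excluded pairwise downstream:
a percentage change of an undefined mean is undefined, not zero.

## Synthetic phantoms

No clinical volumes are distributable, so every stage is validated on
ground-truthed phantoms.

**Vessel trees** grow by a stochastic branching random walk (15 µm steps,
lateral bias) confined to a dermis band, with depth-dependent radius taper
(25 % over the band) and symmetric bifurcations (children diverge ±25–50°
from the parent by default). Walks are self-avoiding and mutually avoiding
(configurable clearance margin), with collision exemptions scoped to the
parent and sibling walks near a shared junction — without this scoping,
junction neighbourhoods either block all children or admit silent overlaps
that break the ground-truth topology. Branches that terminate before a
minimum length (default 60 µm, below the spur-pruning scale) are discarded.
Ground truth (branch/junction counts, branch types, per-branch length,
tortuosity, radius, volume) is recomputed from the stored structure with
chains through degree-2 nodes merged, because a skeleton cannot see a
degree-2 node.

**Rasterisation** paints spheres of the local radius along each centreline
onto a regular grid at intensity 1; branches with mean radius ≥ 30 µm
(configurable) go to the low band, the rest to the high band. This geometric
band split deliberately emulates — not simulates — the acoustic frequency
separation. An epidermis slab sits above the dermis band in both bands, and
optional Gaussian noise is clipped at zero.

Two vetted fixture networks are exposed: `plexus_phantom` (junction-rich,
radii ≥ 3 voxels on an 8 µm grid, junctions ≥ 150 µm apart, wide
bifurcations) whose rasterised skeleton reproduces the ground-truth counts
exactly, and `tube_field_phantom` (disjoint unbranched tubes on a 5 µm grid)
for reactivity recovery, where junction blobs — the one skeleton region that
fragments under strong dilation — are absent by design.

**PORH reactivity** applies per-phase multiplicative factors per group:
radius scale, endpoint-recruitment probability and signal intensity.
Defaults encode the study conditions: occlusion minute 1 at baseline level
(the published table cannot classify that minute because feature values
barely move), minutes 2–3 at radius factor 0.9, healthy hyperemia at 1.30
(minute 1) and 1.15 (minute 2) with recruitment 0.5/0.25, and a blunted
patient response (1.08/1.05, recruitment 0.1/0.05). Baseline factors are
fixed at 1 and occlusion factors may not exceed 1; a model with equal
healthy and patient factors is valid and encodes null dynamics. The noise
field is frozen across the timeline (static speckle), so a null model
reproduces six bit-identical volumes.

**Feature-level cohorts** bypass imaging for the statistics and
classification stages. Baselines are log-normal (typical forearm-scan
magnitudes, log-SD 0.25) and identically distributed in both groups — the
baseline is null by construction, mirroring the published finding of no
significant baseline differences. Post-baseline values are
`baseline × (1 + Δ/100)` with Δ ~ Normal(µ, 10) percentage points, where µ
follows a healthy response profile (+20 at hyp1, +10 at hyp2, −8 under late
occlusion) plus a patient offset. Presets: `null` (no offset), `strong`
(−2 SD on nine features spanning all three scales at hyp1, half at hyp2),
`paper_like` (−1 SD on the same nine). These effect sizes are synthetic
test conditions, not estimates of the clinical effect, which the source
reports only as directions and significance. Covariates: age ~ N(67, 10),
BMI ~ N(25.7, 3.4), binary covariates Bernoulli with the published group
frequencies (hypertension 10/13 vs 4/13, smoking 4/13 vs 0, hyperlipidemia
2/13 vs 2/13, diabetes 2/13 vs 0), all configurable for confounding studies.

What the phantoms do not emulate: acoustic wave propagation and frequency-
dependent point spread, speckle statistics, melanin absorption, motion
artefacts, and capillary-scale (< 10 µm) vessels. Passing tests therefore
demonstrate correctness of the measurement chain on resolvable, well-
separated vasculature, not device-level fidelity.

## Dynamics and multiscale statistics

Percentage changes are `100·(f_t − f_baseline)/f_baseline` per subject and
feature at the five post-baseline minutes; zero or missing baselines yield
missing values with a logged count. Group comparison uses the classic
equal-variance two-sided Student's t-test (Welch via `equal_var=False`),
with boxplot summaries (median, quartiles, whiskers at 1.5 IQR clipped to
the data). No multiple-testing correction is applied by default, matching
the per-feature presentation; Benjamini–Hochberg is available. Degenerate
inputs: two zero-variance groups with equal means give t = 0, p = 1; with
distinct means the comparison is flagged.

The multiscale analysis min–max normalises each feature across the cohort at
baseline (normalisation per feature; min–max chosen over z-scoring as the
simplest reading of "normalised values", configurable), averages unweighted
within each scale per subject, and compares groups per scale; at the
hyperemic minute the percentage changes are averaged instead. Features
constant across the cohort cannot be normalised and are dropped with a
warning.

## Disease index

At each post-baseline minute the classifier input is the matrix of
percentage changes (raw features at baseline). Leave-one-subject-out (LOSO)
cross-validation wraps the entire fitting path: within each fold the top-k
features by the one-way between-group F statistic are selected (constant
features rank last, ties break by column order) and a random forest is
fitted; the held-out subject's class-1 probability is its feature-based
index. Selection strictly inside the fold is the leakage-free reading of the
published order of operations, which is ambiguous. With `k="auto"` the full
LOSO is repeated for every k = 1…18 and the AUC-maximising k kept (smallest
on ties) — documented caveat: this optimises k in-sample, and it multiplies
cost by 18, so fixed k is the practical default for simulation studies
(k = 9, the published hyperemia-minute-1 count, is used in the acceptance
runs). The selected-feature report lists features chosen in ≥ 50 % of folds;
importances come from a refit on all subjects restricted to those features,
normalised to sum to one.

Random-forest defaults: 500 trees, √p features per split, balanced class
weights and `min_samples_leaf=5`, seeded. The last two are deliberate: plain
leave-one-out probabilities at n ≈ 26 are pessimistically biased on null
data (each training fold under-represents the held-out subject's class, and
leaf-level memorisation anti-correlates with the held-out label), which
pushed null-cohort mean AUC to ~0.39–0.43; with both regularisers the null
mean is ≈ 0.48 over 100 simulated cohorts while strong-effect cohorts remain
perfectly separable.

AUC is the Mann–Whitney probability that a random diseased index exceeds a
random healthy one, ties counting one half (rank form; exhaustive pair
enumeration serves as the oracle in tests). Confusion metrics use a 0.5
index threshold by default (the published threshold is unstated;
Youden-optimal thresholds can be computed from the index directly). A minute
whose percentage changes are entirely missing is reported "not classifiable"
rather than raising, mirroring the published table's N/A column.

## Confounding analysis

For each candidate confounder three nested logistic models of disease status
are fitted: M1 confounder only, M2 plus the feature-based index, M3 plus
their interaction. "Residuals" are residual deviances (−2 log-likelihood at
the MLE; the Bernoulli saturated log-likelihood is zero). The binomial/logit
reading of "generalized linear models" is fixed by the published residual
scale: values near 30 for n = 26 sit just below the intercept-only bound
52·ln 2 ≈ 36.04, which is a logistic residual deviance. Added terms are
tested by 1-df likelihood-ratio chi-square (Wald optional). The fitter is
IRLS with step halving, so deviance never increases within a fit, and each
larger model is warm-started at the smaller model's MLE — together these
make the nested-deviance monotonicity d(M1) ≥ d(M2) ≥ d(M3) structural
rather than hoped-for. Quasi-separation (|coef| > 30 or deviance ≈ 0) is
flagged; estimates are still reported at the last iterate.

The multivariate block is ordinary least squares of the 0/1 outcome on all
retained covariates plus the index — a linear probability model, which is
what places coefficients on the probability scale as printed. Binary
confounders with any confounder-by-outcome cell under 3 subjects stay in the
triplet panel (flagged) but are excluded from the multivariate model, a
rule-based version of the published small-cell exclusions.

## Problem sizes in the validation suite

The acceptance runs use: analytic tube/arc fixtures on 10 µm grids
(≤ 40×60×80 voxels); 200 random trees at 10 µm for branch-type conservation;
one six-volume tube-field series at 5 µm (180³ voxels) for reactivity
recovery; 10 strong-effect and 100 null cohorts of 13+13 subjects for
classification calibration (50–200 trees); 500 random datasets for the
nested-GLM monotonicity check; and ~2 000 null baseline tests for type-I
calibration. These sizes give stable statistics (e.g. ±0.017 SE on the null
mean AUC) while keeping a full run in a few minutes.

## Known limitations

- The skeleton tracer recovers exact ground-truth topology only for
  well-separated vessels with radii ≥ 3 voxels; dense plexuses with touching
  tubes merge junctions, as real skeletonisation does.
- EDT radii are biased high by a sub-voxel amount; percentage changes of the
  diameter are compressed by 1–3 points at 3–6 voxel radii.
- The fixed-thickness epidermis band and fixed DE depth are surrogates for
  anatomical layer detection.
- `k="auto"` selects k in-sample over the LOSO AUC; its selected-k values
  should be read as descriptive, not as an unbiased model choice.
- The linear probability model can predict outside [0, 1]; it is used for
  coefficient-scale comparability, not prediction.
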