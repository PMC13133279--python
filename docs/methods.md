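# Methods

This note documents the models, numerical choices and limitations
behind the package. It reads bottom-up: image simulation, image
processing, morphometry and classification, then the cohort
statistics.

## What the simulators emulate — and what they do not

**Core images.** A simulated core is an 8-channel 16-bit stack
(1600×1600 px, 0.5 µm/px; 0.64 mm² frame). The intensity model is
deliberately minimal: a uniform autofluorescence-like background
(default 500 counts) plus a constant signal (default 5000, ~10×
background) on painted structures, optional additive Gaussian noise.
This leaves Otsu's histogram a clean valley by design, so the
binarization stage is exercised for correctness, not robustness to
realistic texture. DAPI is painted as ~5000 nuclei/mm² of small disks
(a density in the range of cellular tumor tissue); KRT⁺ epithelium as
a smoothed-Gaussian-field excursion set covering 40% of the frame;
vessels as CD34⁺ archetype masks (below) placed by rejection sampling
in the stromal compartment with a 3 px guard band so that no two
vessels touch or merge under refinement. The vessel count is
Poisson(197/mm² × frame area) — the planted overall density, matching
the cohort-median magnitude of the real assay.

Auxiliary markers are painted per vessel from independent Bernoulli
draws at the planted rates (ACKR1 0.042, CD36 0.067, KDR 0.14, LAMB1
0.068, MADCAM1 0.014). A positive vessel receives a compact painted
patch covering 50–100% of its area, grown as a Euclidean ball around
an interior seed and never smaller than 80 px, so the patch always
contains a disk thick enough to survive the refinement opening; small
vessels are painted entirely. A negative vessel receives no paint.
This guarantees the strict >5%-area rule recovers the planted flags
exactly on noiseless images — a generator contract the tests rely on.
Real marker expression is partial, graded and sometimes extravascular
(ACKR1 in stromal cells); none of that is modeled, so passing recovery
tests demonstrates pipeline correctness, not robustness to biological
staining variation.

**Vessel archetypes.** Sizes are in px at 0.5 µm/px; published work
gives no vessel-size distributions, so ranges were chosen once for
geometric separability and for survival under the radius-2 opening
(all widths ≥ 5 px):

| class | construction | key ranges |
|---|---|---|
| micro | filled ellipse | radius 3–8, axis ratio ≤ 1.25 |
| collapsed | straight stadium (ribbon) | width 5–8, length 40–90 |
| patent | near-circular disk, 1 px-radius central lumen | outer radius 9.5–16 |
| irregular | 2–4 overlapping stadium lobes at angles ≥ 0.6 rad apart | lobe width 5–8, length 22–50 |

The micro branch accept-rejects rasterizations until Solidity > 0.9
and Eccentricity < 0.7, making the archetype contract hold for every
draw despite discretization artifacts at radius ~3. The patent lumen
radius (1 px) sits below the default closing radius (2 px), so refined
patent masks are filled disks: patent is separated from micro by
equivalent diameter (≥19 px vs ≤16 px) and near-zero eccentricity, as
a filled annulus cannot also present a high-circularity outline.

**Cohort tables.** The generator emits 4476 incident cases. Ages are
uniform within three bands (45–55, 55–70, 70–85) with full-cohort
group proportions 0.10/0.47/0.43; covariates are drawn from
Table-1-like marginals (sex 56% female, MSI-high 18%, CIMP-high 19%,
KRAS 40%, …) independently of each other and of the outcomes.
Tissue availability follows a logistic model in age group, sex, stage
IV and diagnosis year; the age-group intercepts are calibrated by
Newton iteration against the realized group sizes so the expected
available count is exactly 52 + 400 + 391 = 843. Availability is
independent of the density outcomes given age, which is what makes
inverse-probability weighting consistent here.

For available cases, binary high/low density states are drawn from
per-age-group probabilities chosen so the group odds versus the ≥70
referent equal the planted odds ratios: overall 0.386/0.459/0.500
(ORs 0.63 and 0.85), micro 0.537/0.457/0.500 (1.16, 0.84), LAMB1
0.219/0.359/0.500 (0.28, 0.56). Continuous densities consistent with
the states are attached (log-normal half-distributions around the
population medians; LAMB1 low/negative cases are zero with
probability 0.55). Note the planted high-state probabilities average
slightly below 0.5 over the available cases, so re-dichotomizing the
continuous values at the realized sample median reproduces the
planted states only approximately; analyses of planted associations
therefore regress on the planted binary columns, while the
dichotomization machinery is exercised on the continuous columns.

## Image processing

* **Smoothing**: 9×9 uniform (averaging) filter; borders by
  edge-inclusive reflection, chosen so tissue touching the frame edge
  is not darkened. Implemented with `scipy.ndimage.uniform_filter`
  and tested against a brute-force double-loop windowed mean.
* **Otsu**: between-class variance is maximized over the exact set of
  observed intensity levels (histogram binning to 4096 levels only
  for dense float images), with foreground strictly above the
  threshold; ties take the lowest threshold. A constant image yields
  an empty mask plus a warning. The in-package implementation exists
  because the tests require exact agreement with an exhaustive
  within-class-variance search, which binned library implementations
  do not guarantee; `skimage.filters.threshold_otsu` serves as an
  independent cross-check.
* **Refinement**: closing then opening with a discrete Euclidean disk
  (pixels within `radius` of the center; default radius 2 px = 1 µm,
  configurable — the published pipeline states the element shape but
  not its size). Small radii use direct binary morphology, large
  radii an exact distance-transform formulation; the two are tested
  equal, and the close-open composite is idempotent (an alternating
  filter). Out-of-frame pixels count as background for dilation and
  foreground for erosion. One consequence worth noting: a disk
  opening rounds convex corners (~3 px per corner at radius 2); this
  is inherent to disk openings, continuous or discrete.
* **Tissue mask**: union of all refined channel masks (including
  DAPI), closed with a 40 px (20 µm) disk — large enough to bridge
  internuclear gaps at the simulated nuclear density. Core area from
  this mask; epithelial area from the KRT mask intersected with it;
  stromal = core − epithelial exactly.
* **QC**: a core fails on tissue fraction < 5%, saturated-pixel
  fraction > 20% in any channel, or membership in a manual exclusion
  list. A per-batch intensity report flags batches whose per-channel
  median deviates more than 2-fold from the grand median over cores.

## Morphometry

Features follow the MATLAB/skimage regionprops conventions: Area is
the foreground pixel count (holes excluded); ConvexArea the pixel
count of the rasterized convex hull (the polygon-hull area of pixel
centers would make a 10×10 square's Solidity exceed 1); axis lengths
and Eccentricity come from the ellipse with the same normalized second
central moments (no 1/12 pixel-width correction); Extent uses the
axis-aligned bounding box. Perimeter is the 4-direction Crofton
estimator: an 8-connected chain code with √2 diagonal weights
overestimates a digital circle's perimeter by ~4.5% and would bias
round-vessel Circularity to ~0.92, whereas Crofton is unbiased to
within ~1% for radii ≥ 10, keeping Circularity = 4πA/P² ≈ 1 on disks.
A single-pixel mask is degenerate: Perimeter and axis lengths 0,
Circularity reported as 0; the default 12 px minimum vessel area keeps
degenerate and heavily discretization-biased objects out of the
analysis.

## Classification

`VesselMorphologyClassifier` wraps a 1000-tree random forest with 4
candidate features per split, trees grown to purity on bootstrap
samples the size of the training set — the stated hyperparameters;
everything else is left at standard forest defaults. Features enter
raw: forests are invariant to monotone per-feature scaling, so the
z-scoring used for the medians display is not applied for training.
Prediction ties break toward the earlier class in the fixed order
(micro, collapsed, patent, irregular) for determinism. Labels for
synthetic training come from the ground truth (the "simulated
pathologist"), transferred to recovered vessels by majority pixel
overlap; an optional label-noise rate emulates rater disagreement.
Training uses 100 randomly selected vessels per class and validation
a disjoint 100 per class. On the synthetic archetypes the validation
accuracy is essentially 100% — the archetypes are cleanly separable
by construction, so the published 92% figure acts as a floor, not a
calibration target. Impurity importances are normalized to sum to 1;
because five of the ten features are size proxies that share their
importance, shape features (Eccentricity, Solidity, Circularity) lead
the ranking, while the class-wise standardized medians still show the
expected structure (micro lowest in Area, collapsed highest in
Eccentricity, …). Interobserver agreement reports the concordance
rate and unweighted Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from
the raters' marginal products; the degenerate p_e = 1 case returns 1
for perfect agreement and 0 otherwise.

## Cohort statistics

* **Pooling**: per-case density = summed category counts over summed
  core areas across QC-passing cores — robust to unequal core tissue
  areas (the published pipeline does not state its rule). Cases with
  no passing core are dropped and logged.
* **Dichotomization**: "high" is strictly above the median (the
  median-valued case goes low); for CD34⁺LAMB1⁺ the median is taken
  over non-zero values only and zeros are always low/negative.
* **Spearman trends**: `scipy.stats.spearmanr` (mid-ranks, two-sided
  t-approximation), cross-checked against a rank-then-Pearson oracle;
  constant inputs are flagged as undefined.
* **IPW**: availability is modeled by logistic regression on age
  group, sex, stage and diagnosis year over all incident cases (the
  published availability model's exact covariates are described
  elsewhere and treated as configuration here); available cases get
  weight 1/p̂, truncated at the 99th percentile to guard against
  extreme inverse probabilities in small strata. A balance table of
  standardized mean differences (full cohort vs weighted available
  cases) is emitted; at the defaults the post-weighting SMDs are
  below 0.01.
* **Weighted logistic fits**: maximum likelihood via `statsmodels`
  GLM with case weights; variance by the HC0 sandwich, since the
  weights are estimated and a model-based variance would understate
  uncertainty. Complete separation (every fitted probability pinned
  to its label) raises with a diagnostic; quasi-separation on a
  sparse dummy is tolerated because its Wald p ≈ 1 sends it out in
  elimination.
* **Backward elimination**: categorical covariates move as whole
  blocks (dummies plus their missing indicator) judged by joint Wald
  tests; the weakest block with p ≥ 0.1 is removed per step; the age
  block never leaves. Under the null a removable covariate survives
  with probability ~0.1, so "noise is eliminated" holds at a ~90%
  rate, not higher.
* **Missing data**: categorical covariates are imputed to the
  majority level with a per-variable missing-indicator column;
  LINE-1 methylation instead keeps its missing cases as a separate
  level of the categorical itself.
* **P_trend**: from a companion model in which the age-group dummies
  are replaced by raw age in years, keeping the retained covariates.
* **Multiplicity**: two-sided α = 0.005 (≈ 0.05 Bonferroni-corrected
  for the nine vessel variables).
* **Replicate averaging**: when odds-ratio estimates are averaged
  over replicate cohorts, the geometric mean (mean on the log-odds
  scale) is used: with only ~52 available cases under 55, a single
  replicate's log-OR has SE ≈ 0.3, and the arithmetic mean of ORs
  would carry a Jensen bias of ≈ exp(SE²/2) ≈ 3–5% away from the
  planted value.

## Problem sizes

The recovery analyses run at sizes chosen as the smallest that make
the planted parameters statistically identifiable at their stated
tolerances: 40 simulated cores (~5000 vessels, giving binomial 99% CI
half-widths of ~0.7 percentage points on a 4% marker fraction), 250
labeled vessels per class for the 100-per-class protocol, and 100
replicate cohorts at the full 4476-case design (log-OR SE of the
replicate mean ≈ 0.03–0.04).

## Known limitations

* The intensity model (flat background, two-level signal) makes Otsu
  near-trivial; no illumination gradients, spectral bleed-through or
  autofluorescence texture are modeled (the real assay's unmixing and
  artifact review are upstream of this package's scope).
* Vessel-size distributions are separability-driven, not measured;
  consequently the classifier's near-perfect synthetic accuracy says
  nothing about accuracy on real vessels.
* Covariates are generated independently, so confounding is absent by
  construction; the multivariable machinery is exercised, but its
  adjustment behavior under real confounding is untested.
* Cores within a case are independent draws; no within-case
  correlation of vessel phenotypes is modeled.
* Survival outcomes, tertiary lymphoid structures and cell-level
  endothelial segmentation are out of scope.
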