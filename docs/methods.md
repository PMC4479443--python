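# Methods

`leukosmear` implements a contextual analysis pipeline for bone-marrow smear
micrographs: segmentation of leukocyte nucleus and cytoplasm from color and
texture evidence, separation of overlapped cells, a 67-feature morphometric
description, supervised classification of acute-leukemia families (ALL/AML)
and FAB subtypes (L1, L2, M2, M3, M5), and a patient-level majority-vote
diagnosis. Because no public image collection with per-pixel truth exists for
this setting, the package ships a synthetic smear generator that defines the
benchmark conditions for every stage.

## Color model

Images are converted from sRGB to CIE L\*a\*b\* (D65 white, textbook gamma
expansion and XYZ matrix; the reference white maps to exactly (100, 0, 0)).
Wright staining makes the nucleus the darkest object in L\* and gives
nucleus and cytoplasm strongly negative b\* (blue/purple) while erythrocytes
sit at positive b\* (orange/rose) and plasma near zero. Pixels of the working
channel (L\* for the nucleus, b\* for the whole cell) are grouped by k-means
on scalar intensity; the foreground group is the darkest (nucleus mode) or
most blue (cell mode) group, ties broken to the lowest index.

`k` is a configuration knob (`color.k_L`, `color.k_b`). Both default to 3:
with k = 2 the within-sum-of-squares optimum on L\* merges the nucleus with
erythrocytes and cytoplasm (the pale background dominates the split), which
destroys the nucleus observation. With k = 3 the three natural intensity
strata (nucleus / mid-tones / background on L\*, leukocyte / plasma /
erythrocyte on b\*) are recovered, and the extra groups are put to use in the
MRF (below). k-means uses 10 restarts under a fixed seed (`color.restarts`,
`color.seed`); on planes above 20k pixels the centroids are fit on a random
subsample and all pixels assigned to the nearest centroid, which is exact for
scalar data.

## Texture model

Texture is modeled by the 2-D Wold decomposition: the channel splits into a
harmonic field (isolated spectral peaks), a generalized evanescent field
(energy on lines through the frequency plane) and a stochastic residual, with
mutually disjoint frequency support. The channel mean (DC) is recorded
separately so the stochastic residual is zero-mean even for a constant plane;
`harmonic + evanescent + stochastic + mean` reconstructs the input to
machine precision.

Conventions the literature leaves open, fixed here:

* **Amplitude scale.** A bin's amplitude is `2|F|/Npix`, so a pure cosine of
  amplitude A scores A. The peak threshold (`texture.amplitude_threshold`,
  default 10) is therefore in the intensity units of the channel; with a raw
  unnormalized DFT magnitude a threshold of 10 would be vacuous for 8-bit
  256×256 images.
* **Isolation.** A harmonic peak must exceed its 8 neighbors strictly (with a
  1e-9 relative tolerance); dense evanescent line support, where adjacent
  bins tie, is thereby excluded from the harmonic stage. Accepted peaks are
  taken greedily by descending amplitude with a minimum mutual separation of
  2 bins; conjugate pairs are returned together.
* **Evanescent lines.** The residual amplitude spectrum is thresholded at the
  same amplitude threshold and voted with a Hough accumulator at 1° angular
  and 1-bin radial resolution; up to 4 lines (`texture.max_evanescent_lines`)
  are kept, each requiring at least 8 supporting bins; support masks are
  conjugate-symmetrized so the field stays real.

## Per-site texture observations

The Wold split is global: its harmonic field is a full-frame sinusoid, so
windowed energy of the global fields cannot localize texture. Per-site
observations therefore come from each site's own 16×16 window spectrum
(`texture.window`): structural energy is the mean squared contribution of
window bins above the amplitude threshold (concentrated, structured content);
stochastic energy is the remainder. Windows are evaluated on a stride-2 grid
with reflective padding and nearest-filled to pixel resolution — the maps are
smooth at window scale, so the halved resolution costs nothing and saves a
factor 4 of compute. Both maps enter the MRF on a `log(1 + E)` scale: local
energy is heavy-tailed (edges dominate), and the log makes a Gaussian class
model adequate.

## MRF segmentation

Each pixel carries three observations: channel intensity, structural energy
and stochastic energy, assumed conditionally independent given the label.
The foreground class has one Gaussian per plane, estimated over the selected
foreground group's pixels. The background of a smear is heterogeneous —
plasma and erythrocytes differ in color and texture — so each non-foreground
k-means group contributes its own Gaussian component and a pixel's background
energy is that of its best-fitting component. A single background Gaussian
was tried first and produced systematic erythrocyte false positives in cell
mode (the broad Gaussian covered the erythrocyte stratum poorly).

The label prior is a Potts model on the 8-neighborhood with weight
`mrf.beta` (default 1.5). MAP estimation uses Iterated Conditional Modes
from the per-pixel maximum-likelihood start: sites update in four 2×2-block
phases (no two simultaneously updated sites are neighbors, so each phase is
exact block coordinate descent and the recorded global energy never
increases), stopping at a label fixpoint or `mrf.max_sweeps` (20).

Post-processing: (i) labels within half a window of the ICM boundary are
re-decided on intensity evidence alone, because windowed texture
observations straddle the boundary there and smear the mask outward by a
1–3 px halo — this is the dominant false-positive source without it; (ii)
connected components under 50 px are removed and holes under 200 px filled
(`mrf.min_object`, `mrf.max_hole`); (iii) when the foreground and closest
background intensity means sit within `mrf.min_contrast` (10 channel units)
the image is declared free of stained objects and the mask is empty — real
nucleus/cell stain contrast is several times larger.

Masks are scored with shared-denominator metrics: precision = TP/P and
FP rate = FP/P over the predicted-foreground count P, FN rate = FN/N over
the predicted-background count N, all in percent. With P = 0 precision and
FP rate are reported as NaN with a note.

## Region identification

Connected regions (8-connectivity) are described by area, chain-code
perimeter (unit steps, √2 diagonals), circularity (perimeter²/4πA),
second-moment eccentricity, mean L\* and bounding box. Nucleus-mask regions
pass threshold rules: plausible area, circularity ≤ `rules.circ_max` (1.5)
and eccentricity ≤ `rules.ecc_max` (0.95) → nucleus; oversized or irregular
but within twice the area ceiling → overlapped aggregate (routed to
separation); otherwise rejected. `induce_shape_thresholds` re-derives the
thresholds from labeled regular/irregular example regions, mirroring how
such rules are induced from a small annotated set.

A cell is accepted when it contains a nucleus at containment proportion
≥ 95% (`rules.containment_min`) and that nucleus is darker (lower mean L\*)
than the cell's cytoplasm ring; a cell matching two or more nuclei is
flagged overlapped. Matching is injective for accepted records.

## Overlapped-cell separation

An overlapped aggregate is cut at concave points: convexity-defect apexes at
least `separation.depth_min` (3 px) deep, found as local maxima (prominence
half the depth floor) of the depth profile along each convex-hull arc — so
two waists whose crest dips just below the hull still yield separate apexes.
The cut pair is the mutually closest pair of apexes whose connecting chord
stays inside the region (the waist chord). Each open fragment is re-closed
by linear interpolation of r(θ) about the fragment centroid across the
angular gap, sampled at 1° (`separation.step_deg`), giving a conic-like
closing arc in cartesian space that restores the occluded border while
keeping the visible boundary pixels exactly. Contested pixels between
children go to the nearer fragment centroid; a 3×3 morphological closing
joins discontinuities; children under `separation.min_area` (50 px) are
dropped; the procedure recurses for clumps of three or more cells.

## Feature extraction

Each accepted cell yields the 67-feature description: 14 morphologic
features for nucleus and cell (area only for the cytoplasm), mode / mean /
SD / variance / sum and five GLCM statistics per region over R, G, B and
gray (ITU-R 601 luma), the first 10 eigenvalues of the nucleus and cell
crops per channel, and three nucleus/cell size ratios. Images are *not*
normalized before extraction — absolute size and color are discriminative.
Conventions: population (1/n) variance; mode ties to the smallest value;
GLCM at offset (0,1), 32 gray levels, symmetric, only pixel pairs fully
inside the region, energy = Σp² and entropy in bits; eigen crops are
bounding boxes with out-of-region pixels filled by the region mean (no
background leakage), rows treated as observations, eigenvalues sorted
descending, zero-padded below rank 10. The flat table expands the
per-region/per-channel blocks to 232 named columns; `flat_feature_names()`
is the single schema source.

## Classification

Six tasks: ALL vs AML, L1 vs L2, three one-vs-rest myeloblastic splits, and
the three-way myeloblastic task. Learners: 1-nearest-neighbor (features
standardized — raw column scales differ by orders of magnitude purely from
units), random forest (100 trees), logistic regression, linear-kernel SVM
(decision-function scores for AUC), and an extremely-randomized-tree
committee. Evaluation is stratified 10-fold cross-validation with pooled
predictions: overall accuracy (%), TPR/TNR as positive/negative recall
(macro-averaged for multiclass), AUC from continuous scores (one-vs-rest
averaged for multiclass; inverse-distance class scores for kNN). The
nucleus+cytoplasm vs whole-cell-only comparison runs both column subsets on
identical folds.

## Diagnosis

Per patient, two schemes fuse per-sample predictions:

* **Cascade** — majority over samples decides the family; only the winning
  family's subtype classifier is consulted. A wrong family call forces a
  wrong subtype (the scheme's documented weakness).
* **Fusion** — the ensemble (three-way myeloblastic model, three one-vs-rest
  myeloblastic models, L1-vs-L2, ALL-vs-AML) votes on every sample; a vote
  endorsing m candidate subtypes adds 1/m to each tally. Pooling is
  hierarchical: the family is the strict plurality of the family-competent
  voters' implications, the subtype the strict plurality within the winning
  family among voters able to discriminate inside it. A flat plurality
  across all subtypes was rejected: four of the six voters can only ever
  name myeloblastic subtypes, so flat pooling is structurally biased toward
  AML and fails every ALL patient.

A tie at either level (winner margin below `diagnosis.min_margin`, default:
exact ties only) yields "not determined". Cohort evaluation reports
correct / not-determined / failed percentages per family and subtype; each
row sums to 100%.

## Synthetic data

The smear generator renders 8-bit RGB images (default 256×256) with:
leukocytes as randomly rotated ellipses (radius 16–24 px) with low-order
radial boundary jitter; nuclei as smaller offset ellipses wholly inside
their cell, darker and bluer than the cytoplasm; erythrocytes (radius
8–12 px) in orange/rose, never intruding on leukocytes; a pale mottled
background; a per-image affine stain transform (channel gains in
[0.97, 1.03], hue/brightness shift ±8) and additive Gaussian sensor noise
(`noise_sd`, default 4). A requested fraction of leukocytes is translated
against a partner until the masks intersect by 10–30% of the smaller area,
producing the concave waists the separator needs; nuclei of overlapped cells
are pushed away from the waist so each nucleus stays visible. All draws
derive from the spec's seed; identical specs reproduce bit-identical images
and masks. Subtypes differ only in parameterized statistics (nucleus/cell
radius ratio from 0.80 for L1 down to 0.46 for M5, a chroma shift, and
nucleus texture grain of SD 2–7) — no cytological realism is attempted.

The feature-table generator draws class-conditional Gaussians over the
feature schema with hierarchical mean placement: each subtype mean is an
orthonormal subtype direction plus its family's shared direction, scaled so
same-family subtypes sit `class_separation` pooled SDs apart and different
families √2 times farther — families are morphologically more distinct than
subtypes within a family. Zero separation makes classes exchangeable.
Optionally the signal is confined to one region's columns (e.g. nucleus),
the condition under which the nucleus+cytoplasm vs whole-cell comparison is
meaningful. The patient generator assigns one subtype per patient and draws
that patient's samples from the subtype's distribution.

**What passing tests do and do not show.** The synthetic conditions exercise
the full mechanics — color/texture evidence assembly, MAP estimation,
overlap geometry, schema integrity, voting — but the rendered cells are far
cleaner than real marrow smears: no focus gradients, no touching
leukocyte/erythrocyte ambiguity, no chromatin structure, subtype differences
that are statistical rather than cytological. Segmentation precision near
100% on this benchmark says the estimator is correct, not that real-image
accuracy would match; nucleus crops in particular are noise-dominated, so
their eigen spectra are flatter than real chromatin would give.

## Benchmark sizes

The bundled benchmarks use 100 smears (256×256, default noise) for
segmentation, 40 samples per class at separation 3 (nucleus-region signal)
for classification, and ten 20-patient cohorts of 10 samples each at
separation 2 for diagnosis — sizes chosen to make the statistics stable on a
single CPU in minutes.

## Known limitations

* ICM is a greedy MAP solver; it converges to a local optimum of the
  posterior energy (exact inference is out of scope by design).
* The separator assumes clump fragments are near-star-shaped about their
  centroids; pathological shapes fall back to returning the region intact.
* The rule thresholds for region identification are tuned to the synthetic
  geometry; real smears would need the rule-induction path on annotated
  regions.
* Pixel scale is unknown (no physical calibration), so all size features are
  in pixels.
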