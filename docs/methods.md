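# Methods

This note documents the models and procedures implemented in `hyaloquant`,
the parameters that matter and why their defaults are what they are, what
the synthetic generators do and do not emulate, and the numerical choices
made where the underlying manual workflow left the design open.

## Flatmount quantification

### Vessel mask

The "solid" endothelial mask is built from the CD31 channel by automatic
global thresholding (Otsu by default; IsoData, Yen, mean and triangle are
selectable, and an explicit threshold can be passed), morphological closing
with a disc of radius 3 px, binary hole filling, and removal of objects
below `min_mask_object_area_um2` (default 50 µm²). Closing bridges small
staining gaps so that one vessel yields one object; hole filling assigns
vessel lumina to the footprint, which is what "solid" means here. An
all-zero channel yields an empty mask with a warning rather than an error,
since blank control stains are legitimate inputs.

### Nuclei and cell classes

Nuclei are segmented on DAPI by IsoData thresholding followed by a
Euclidean-distance-transform watershed. Two numerical choices stabilize
this on noisy data: the raster is pre-smoothed with a Gaussian of
`smoothing_sigma_px` (default 1 px) before thresholding, which suppresses
single-pixel threshold exceedances without moving object boundaries
appreciably; and watershed seeds are local maxima of the lightly smoothed
distance transform with a minimum separation of
`watershed_min_separation_um` (default 7 µm, about one radius of the larger
nuclei) so that digitization plateaus of elongated nuclei do not oversplit.
Components below `min_nucleus_area_um2` (default 10 µm², replacing manual
artifact exclusion) are discarded.

Each nucleus carries area, perimeter (from the boundary contour, as in the
Fiji "circularity" measurement) and circularity `4πA/P²` clipped to 1.
Classification is a fixed rule: centroid inside the solid mask →
endothelial; outside with circularity ≤ `circularity_cutoff` (default
0.6, inclusive) → pericyte; otherwise other non-endothelial. Centroid
membership was chosen over whole-pixel containment because nuclei commonly
overhang vessel edges; it is a single unambiguous rule, and the cutoff
boundary (exactly 0.6 → pericyte) is pinned by tests.

### Marker intensities

Nuclear markers: the background level is the mean marker intensity inside
the vessel mask excluding all nuclear pixels; each nucleus reports the
integrated intensity `Σpixels − background·n_pixels`. Negative corrected
values are retained — clipping would bias group means upward. The
per-flatmount summary is the median over nuclei of the requested class.
Membrane markers: per-field value `mean(inside mask) − mean(outside
mask)`. Positive areas are threshold-count × pixel-area, with ratios (e.g.
GPR124⁺/CD31⁺ area) and percent-of-control defined only for positive
denominators. Technical replicates (fields of view; both eyes of one
animal) are averaged into one biological replicate per animal.

### TUNEL puncta

Yen thresholding (appropriate for sparse bright spots on a dark
background) followed by the same smoothing/watershed machinery, with
`min_punctum_area_um2` default 2 µm²: apoptotic bodies are ≥ ~1.5 µm
across, while at the ~1 µm/px resolution of stitched overview scans a
smaller cutoff cannot reject single-pixel noise speckles. A punctum whose
centroid falls outside the vessel mask is extravascular; the rest await
segment assignment.

## Vessel topology and regressing segments

The mask skeleton (topology-preserving thinning) is converted to an
undirected multigraph: skeleton pixels with ≠ 2 neighbors are clustered
into nodes, ordered pixel paths between clusters become edges with
µm lengths. Cleanup removes terminal spurs shorter than `prune_length_um`
(default 15 µm, a skeletonization artifact scale below the shortest real
segments), contracts equally short branch–branch stubs produced at
junctions, and merges the pass-through nodes this leaves behind. Pure
cycles without nodes are retained as self-edges. Node/edge identifiers are
assigned by sorted position, so runs are reproducible and rotation changes
nothing but labels.

Each intravascular punctum is assigned to the edge whose centerline is
nearest to its centroid, if within `corridor_halfwidth_um` (default 10 µm,
roughly a vessel radius plus registration slack); exact ties go to the
lower edge id; puncta beyond every corridor are treated as extravascular.

A segment call is then a conjunction of two explicit criteria
operationalizing what was originally a visual judgment:

- **linear cluster**: at least `min_cluster_puncta` (default 3) assigned
  puncta whose projections onto the centerline span at least twice the
  corridor half-width — a cluster must extend *along* the vessel, not just
  sit at a point;
- **CD31 discontinuity**: the fraction of centerline samples whose
  locally max-pooled CD31 (disc radius 3 px, tolerating centerline
  wobble within the vessel width) reaches the continuity threshold is at
  most `max_continuity_for_regressing` (default 0.8). The threshold
  defaults to an Otsu split of the pooled along-path samples — a
  vessel-level statistic; a whole-image Otsu would be dominated by the
  dark background and sit far below any staining attenuation worth
  calling a gap.

These defaults were fixed against the synthetic fixtures and make no claim
to replicate any particular annotator; all are configurable. The
per-flatmount summary reports the number of regressing segments, total and
mean puncta on them (mean undefined at zero segments), and total puncta on
intact segments.

## Retina metrics

Radial vascular expansion replaces a manually drawn oval with the
minimum-area enclosing ellipse of the collagen IV-positive pixels,
computed by Khachiyan's algorithm on the convex hull (tolerance 1e-5);
the result is half the mean axis length, `(major + minor)/4` in pixels
scaled to µm. Vascular density is `area/(expansion²·π)`; values above 1
(positive area outside the fitted disc) are flagged. The four radial
incisions of flatmounting are ignored — the mask is used as-is.

## SORT-seq pipeline

Stages run in the stated order: plate normalization → QC → typing →
log-normalization → differential expression → enrichment.

- **Plate normalization**: per plate, the median of per-cell UMI totals
  over wells with at least one count; every cell is scaled by
  `max_median/plate_median`. A plate with no counted wells is an error.
- **QC**: totals in `[1000, 8000]` (both ends inclusive — en-dash ranges
  read as closed intervals; the boundary behavior is pinned by tests) and
  mitochondrial percentage strictly below 10, with mitochondrial genes
  matched by case-insensitive symbol prefix (`mt-`, the mouse convention).
- **Typing**: detection-only rule on raw counts (`UMI > 0`), no
  thresholds to tune; both-or-neither cells are excluded.
- **Log-normalization**: `ln(1 + x·10⁴/total)` per cell; a separate
  per-gene z-scaling is available for heatmaps.
- **Differential expression**: per gene, group membership is regressed on
  log-normalized expression by Newton/IRLS (max 25 iterations, step
  tolerance 1e-8, linear predictor clipped at ±30); the p-value is the
  χ²(1) likelihood-ratio test against the closed-form intercept-only
  null. Under perfect separation the capped-iteration fit is used and
  flagged unconverged — its LRT is still finite and extreme, which is the
  desired behavior for an all-or-nothing marker. Fold changes are
  `log2((mean expm1 + ε)/(mean expm1 + ε))` with pseudo-count ε = 1
  (configurable); this estimator is deliberately shrunk for weakly
  expressed genes, which callers should remember when interpreting
  |log2FC| cutoffs. No multiple-testing correction is applied — the
  significance rule is raw p < 0.05 with |log2FC| > 1, as in the analysis
  this pipeline mirrors. Gene and cell order are canonicalized before
  fitting, so results are independent of file ordering. Optional
  min-detection-fraction and minimum-|log2FC| prefilters exist but are
  off by default.
- **Enrichment**: hypergeometric upper tail `P(X ≥ k)` on the supplied
  universe, sets intersected with the universe first; a set is reported
  at overlap ≥ 5 and p < 0.01. Panels (GMT) are intersected with the
  significant gene list and annotated with direction.

## Synthetic data

### Flatmount generator

The vessel network is the minimum spanning tree of the Delaunay
triangulation of random seed points (default 14 points, ≥ 55 µm apart):
connected, with realistic branch-point geometry, a known contracted
segment list, and — being a tree — no enclosed faces for hole filling to
swallow. Tubes have 6 µm radius. Networks unable to host the requested
regressing segments and isolated puncta are redrawn (deterministically
from the same seed stream).

Nuclei are rendered as filled ellipses (semi-axes: endothelial
4.5 × 3 µm on the centerlines, oriented along the vessel; pericytes
12 × 2 µm outside the footprint — measured circularity ≈ 0.44–0.55,
safely under the 0.6 cutoff across orientations; other cells are 3.5 µm
discs). TUNEL puncta are Gaussian spots (σ 1.5 px): per regressing
segment a linear cluster (default 4 puncta spanning 36 µm around the
segment midpoint), at most two isolated puncta per intact segment (so
isolated events can never satisfy the 3-punctum cluster rule), and
extravascular puncta well clear of the mask. CD31 on the middle
`cd31_gap_fraction` (default 0.5) of each regressing segment is
attenuated to 50% of the signal: strong attenuation rather than full
dropout, because a fully dark gap longer than the closing diameter would
disconnect the automated mask — a situation the original visual scoring
bridged by eye and the automated mask cannot. Channels get flat
backgrounds, additive signals and optional Gaussian noise specified as a
fraction of the signal (`with_noise(0.1)` reproduces the 10%-noise test
condition).

What the generator does **not** emulate: optical blur/PSF, shading and
stitching artifacts, autofluorescence texture, nucleus intensity
variation, curved vessels between branch points, crossing (non-planar)
vessels, and ghost-vessel remnants. Passing recovery tests therefore
demonstrates that the measurement chain is correct and noise-tolerant
under its stated geometric assumptions — not that segmentation will be
artifact-free on real micrographs, where the visual-validation step the
size filters replace remains advisable.

### Counts generator

Four plates (two per genotype, default 40 cells each — preserving the
plate/genotype confounding structure of two 384-well capture plates per
condition at tractable size) with multiplicative depth factors
(1.0–1.2×). Gene abundances are log-normal (σ = 1); counts are negative
binomial with dispersion θ = 8 — mild overdispersion appropriate for a
FACS-sorted, single-cell-type population (θ → ∞ gives the Poisson limit
used for null-calibration tests; an optional Bernoulli dropout exists and
defaults off). Cells planted to fail QC target totals far outside the
window (≤ 600 or ≥ 11000 before scaling) or mitochondrial fractions of
15–25% versus 2–6% normally; the margins exceed sampling noise by an
order of magnitude, which is what makes planted QC status an exact
oracle. Marker genes follow the detection rule exactly (endothelial cells
always have Cldn5 ≥ 1 and Pdgfrb = 0, and so on), so planted type is
likewise exact.

Differential expression is planted as 30 genes per cell type (~1.5% of
the 2000 genes, the order of magnitude of DEG fractions in comparable
analyses) at log2 fold changes {±2, ±3}, multiplying knockout-cell means
of the affected type. DE genes are drawn from mid-abundance genes (a few
UMI per cell, excluding the ~40 most abundant): abundant enough that
fold-change recovery is limited by the ε = 1 estimator rather than by
dropout, yet collectively light enough that the knockout library-mass
shift stays below ~7% — planting large fold changes on top-abundance
genes would compositionally depress every null gene under per-cell
normalization and contaminate false-discovery measurements with a real
but unintended artifact.

## Orchestration

`run_pipeline` executes mask → nuclei → markers → puncta → topology (→
retina) in order, aborts naming the failing stage while retaining earlier
outputs, and stamps every table with the seed, package version and a hash
of all parameters, making reports a pure function of (inputs, config,
seed). Percent-of-control tables divide per-animal values by the
control-group mean (×100). Group significance testing (t-tests, ANOVA) is
deliberately left to general statistics packages.

## Problem sizes

Default test and acceptance runs use 512² px flatmounts (~50 nuclei, ~21
puncta, 7–9 segments) and 160-cell × 2000-gene count matrices, with three
flatmount replicates per noise level and ≥ 2000 gene draws for null
calibration — sizes chosen so the full verification cycle runs in minutes
on a laptop while keeping every estimate's sampling error well inside the
tested tolerances.

## Known limitations

- The regressing-segment criteria are one reasonable operationalization;
  agreement with any particular expert annotator is untested.
- The LRT p-value is asymptotic; at very small group sizes (the QC floor
  allows 3 cells) it is only approximate, and the unconverged-fit path
  under perfect separation yields extreme rather than exact p-values.
- The enclosing-ellipse expansion is sensitive to isolated outlier
  pixels in the collagen mask, as the manual oval was to annotator
  judgment; the mask's small-object filter is the only guard.
- Skeleton topology at near-tangent junctions can differ from the
  generating network by short-edge rearrangements; cleanup contracts
  these below 15 µm but cannot recover a junction the thinning never
  produced.
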