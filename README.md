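# hyaloquant

Quantification of hyaloid (vitreous-body) blood vessel regression from
flatmount immunofluorescence, plus the accompanying SORT-seq single-cell
expression pipeline.

During early postnatal development the hyaloid vasculature regresses
segment by segment: apoptotic endothelial cells (TUNEL-positive puncta)
accumulate in linear clusters along vessel stretches whose CD31 staining
becomes discontinuous, between two branch points or a branch point and an
endpoint. `hyaloquant` turns multi-channel flatmount images and
plate-structured UMI count matrices into the quantities used to compare
genotypes in this setting. It is written for researchers analyzing vascular
remodeling who want the whole measurement chain — segmentation rules,
classification cutoffs, background corrections, statistical tests — to be
explicit, scriptable and testable against ground truth.

## What it computes

**Imaging** (`image_quant`, `vessel_topology`, `retina_metrics`)

- a *solid CD31 mask* — automatic threshold, morphological closing, hole
  filling — and marker-positive areas in µm² with ratio/percent-of-control
  reporting;
- nuclei by IsoData thresholding of DAPI followed by distance-transform
  watershed, with circularity `4πA/P²`; cells classified as endothelial
  (nucleus centroid inside the mask), pericyte (outside, circularity
  ≤ 0.6) or other non-endothelial;
- background-corrected marker intensities: nuclear markers (e.g. LEF1)
  against the mean signal inside the mask excluding nuclei, membrane
  markers (e.g. VE-cadherin) against the area outside the mask;
- TUNEL puncta by Yen thresholding plus watershed;
- a skeleton graph of vessel segments (branch points, endpoints, per-edge
  centerline paths) and a regressing/intact call per segment: *regressing*
  iff it carries a linear cluster of puncta **and** its CD31 continuity
  along the centerline falls below a cutoff;
- retinal radial vascular expansion — half the mean axis of the minimum
  enclosing ellipse of the collagen IV mask — and vascular density
  `area / (expansion² · π)`.

**Single cell** (`sortseq`)

- plate normalization by scaling every 384-well plate to the plate with
  the highest median per-cell UMI total;
- QC: total UMI in [1000, 8000] and mitochondrial fraction < 10%;
- marker-rule typing: *Cldn5* (UMI > 0) endothelial, *Pdgfrb* pericyte,
  both/neither excluded;
- log-normalization (scale 10⁴), per-gene logistic-regression
  likelihood-ratio differential expression (significant at p < 0.05 and
  |log2FC| > 1), hypergeometric gene-set enrichment (reported at overlap
  ≥ 5 and p < 0.01), and marker-panel screens from GMT files.

**Synthetic data** (`synthetic`) — seeded generators for both modalities
with complete ground truth (true nuclei classes, puncta, regressing
segments, QC status, cell types, DE genes with known log2 fold changes),
so every stage is benchmarked without any downloads.

## Worked example

```bash
python examples/regressing_segments.py
```

```
skeleton graph: 7 segments, 3 branch points, 5 endpoints (planted: 7/3/5)
  segment 0: regressing puncta=4 CD31 continuity=0.46 linear=True
  segment 1: intact     puncta=1 CD31 continuity=1.00 linear=False
  ...
per-flatmount summary: {'n_regressing_segments': 3, 'total_puncta_in_regressing': 12,
                        'mean_puncta_per_regressing_segment': 4.0, 'total_puncta_in_intact': 5}
planted regressing segments: 3
```

The skeleton of the vessel mask recovered all seven planted segments; the
three segments carrying linear four-puncta clusters over attenuated CD31
are called regressing, isolated puncta on continuous vessels are not. The
summary line holds the per-flatmount statistics compared between
genotypes. The other scripts in `examples/` walk through nucleus
classification and marker intensities, retina metrics, the SORT-seq
pipeline, data simulation, and reproduction of the deposited accession
(`data/GSE284257/`, fetched separately).

A thin CLI wraps the same library calls:

```bash
hyaloquant simulate-flatmount --out sim/ --seed 0
hyaloquant quantify --image sim/flatmount.tif --config sim/channels.yaml --out results/
hyaloquant sortseq --mtx matrix.mtx --genes genes.tsv --cells cells.tsv --out results/
```

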