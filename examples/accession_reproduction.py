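"""Reproduce the deposited SORT-seq analysis from raw UMI counts.

Expects a local copy of accession GSE284257 converted to an MTX triplet:

    data/GSE284257/matrix.mtx   genes x cells UMI counts
    data/GSE284257/genes.tsv    one gene symbol per line
    data/GSE284257/cells.tsv    TSV with barcode, plate, genotype columns
                                (genotype in {control, knockout})

Applying the stated pipeline — plate scaling to the highest median, QC at
1000-8000 total UMI and < 10% mitochondrial reads, Cldn5/Pdgfrb typing —
should retain 31 cells (5 control + 6 knockout endothelial, 10 + 10
pericytes), and the per-type logistic-LRT differential expression at
p < 0.05, |log2FC| > 1 targets 249 endothelial DEG and 327 up / 213 down
pericyte DEG.
"""

import sys
from pathlib import Path

from hyaloquant import sortseq as ss

root = Path("data/GSE284257")
if not (root / "matrix.mtx").exists():
    sys.exit(
        f"accession not found under {root}/ — download GSE284257 and convert "
        "it to the MTX triplet described in this script's docstring"
    )

adata = ss.read_counts_mtx(root / "matrix.mtx", root / "genes.tsv", root / "cells.tsv")
result = ss.run_accession_pipeline(adata)

print(f"cells retained after QC: {result['n_cells_retained']} (target 31)")
print("cell type x genotype:", result["cell_type_counts"])
for cell_type, targets in (("endothelial", "249 DEG"), ("pericyte", "327 up / 213 down")):
    deg = result.get(f"deg_{cell_type}")
    if deg is None:
        continue
    sig = deg[deg["significant"]]
    print(f"{cell_type}: {len(sig)} significant "
          f"({(sig['log2fc'] > 0).sum()} up, {(sig['log2fc'] < 0).sum()} down) "
          f"— published: {targets}")
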