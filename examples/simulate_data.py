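"""Generate ground-truthed synthetic data to disk.

Writes a flatmount TIFF with its channel map and truth tables, and a
plate-structured counts matrix as an MTX triplet — the same files the
command-line interface produces (`hyaloquant simulate-flatmount`,
`hyaloquant simulate-counts`).
"""

from pathlib import Path

import pandas as pd
from scipy import io as spio
from scipy.sparse import csr_matrix

from hyaloquant import io as hqio
from hyaloquant.synthetic import (
    CountsSimSpec,
    ImageSimSpec,
    generate_counts,
    generate_flatmount,
)

out = Path("scratch/simulated")
out.mkdir(parents=True, exist_ok=True)

image, img_truth = generate_flatmount(ImageSimSpec(seed=0).with_noise(0.1))
order = hqio.write_flatmount(image, out / "flatmount.tif")
(out / "channels.yaml").write_text(
    "channels:\n"
    + "".join(f"  {i}: {name}\n" for i, name in enumerate(order))
    + f"pixel_size_um: {image.pixel_size}\n"
)
img_truth.nuclei.to_csv(out / "truth_nuclei.csv", index=False)
img_truth.puncta.to_csv(out / "truth_puncta.csv", index=False)
print(f"flatmount: {image.shape} px, channels {order} -> {out}/flatmount.tif")
print(f"  planted: {len(img_truth.nuclei)} nuclei, {len(img_truth.puncta)} puncta, "
      f"{len(img_truth.regressing_edges)} regressing segments")

adata, cnt_truth = generate_counts(CountsSimSpec(seed=0))
spio.mmwrite(str(out / "matrix.mtx"), csr_matrix(adata.X.T))
pd.Series(adata.var_names).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
adata.obs[["barcode", "plate", "genotype"]].to_csv(out / "cells.tsv", sep="\t", index=False)
cnt_truth.cells.to_csv(out / "truth_cells.csv")
cnt_truth.de_genes.to_csv(out / "truth_de_genes.csv", index=False)
print(f"counts: {adata.n_obs} cells x {adata.n_vars} genes -> {out}/matrix.mtx")
print(f"  planted: {int(cnt_truth.cells['qc_pass'].sum())} QC-passing cells, "
      f"{len(cnt_truth.de_genes)} DE genes")
# Every downstream stage can be benchmarked against these truth tables;
# the seed makes the whole dataset bit-reproducible.
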