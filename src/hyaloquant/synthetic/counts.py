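"""Synthetic plate-structured UMI counts with planted ground truth.

Emulates plate-based single-cell capture of a sorted endothelial/pericyte
mixture from two genotypes, two plates per genotype: negative-binomial
counts over log-normal baseline gene abundances, multiplicative per-plate
depth factors, a mitochondrial gene block, detection-rule marker genes
(*Cldn5* for endothelial cells, *Pdgfrb* for pericytes), cells planted to
fail quality control on either the total-UMI window or the mitochondrial
fraction, and genotype-dependent differentially expressed genes per cell
type with known log2 fold changes.

Planted QC outcomes are made deterministic by wide margins: passing cells
target totals well inside the window, failing cells well outside, so the
sampling noise (a few percent of the total) cannot flip a planted status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from ..sortseq import counts_matrix

__all__ = ["CountsSimSpec", "CountsGroundTruth", "generate_counts"]

_MITO_SYMBOLS = [
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
]


@dataclass
class CountsSimSpec:
    """Study conditions of the synthetic SORT-seq matrix.

    ``cells_per_plate`` of 40 keeps four plates tractable while preserving
    the plate structure of 384-well capture plates; DE cell numbers at the
    defaults roughly quadruple the sorted-cell yield of a single litter
    pool, which stabilizes the logistic-regression fits.
    """

    n_genes: int = 2000
    n_plates: int = 4
    cells_per_plate: int = 40
    plate_depth_factors: tuple[float, ...] = (1.0, 0.8, 1.2, 0.9)
    control_plates: tuple[int, ...] = (0, 1)  # plate indices per genotype
    baseline_meanlog: float = 0.0
    baseline_sdlog: float = 1.0
    pass_total_range: tuple[float, float] = (2200.0, 5200.0)
    fail_low_total_range: tuple[float, float] = (300.0, 600.0)
    fail_high_total_range: tuple[float, float] = (11000.0, 14000.0)
    n_fail_low: int = 8
    n_fail_high: int = 6
    n_fail_mito: int = 10
    normal_mito_frac: tuple[float, float] = (0.02, 0.06)
    high_mito_frac: tuple[float, float] = (0.15, 0.25)
    frac_endothelial: float = 0.4
    n_excluded_both: int = 4
    n_excluded_neither: int = 4
    ec_marker: str = "Cldn5"
    pc_marker: str = "Pdgfrb"
    marker_mean: float = 5.0
    n_de_genes_per_type: int = 30
    de_log2fc_values: tuple[float, ...] = (2.0, -2.0, 3.0, -3.0)
    dispersion: float | None = 8.0  # NB size; None → Poisson limit
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_special = self.n_fail_low + self.n_fail_high + self.n_fail_mito
        if n_special + self.n_excluded_both + self.n_excluded_neither > (
            self.n_plates * self.cells_per_plate
        ):
            raise ValueError("more planted special cells than cells available")
        if len(self.plate_depth_factors) != self.n_plates:
            raise ValueError("need one depth factor per plate")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.fail_low_total_range[1] >= 900 or self.fail_high_total_range[0] <= 9000:
            raise ValueError(
                "planted failing totals must clear the QC window with margin; "
                "infeasible total-UMI targets"
            )


@dataclass
class CountsGroundTruth:
    """Planted per-cell and per-gene truth."""

    cells: pd.DataFrame  # index = plate:barcode; planted annotations
    de_genes: pd.DataFrame  # gene, cell_type, log2fc
    marker_genes: tuple[str, str]
    mito_genes: list[str]


def generate_counts(spec: CountsSimSpec) -> tuple[ad.AnnData, CountsGroundTruth]:
    """Sample the counts matrix and its ground truth, deterministically."""
    rng = np.random.default_rng(spec.seed)
    n_mito = len(_MITO_SYMBOLS)
    n_base = spec.n_genes - n_mito - 2
    if n_base < 4 * spec.n_de_genes_per_type:
        raise ValueError("n_genes too small for the requested DE structure")
    base_genes = [f"Gene{i:05d}" for i in range(n_base)]
    genes = base_genes + _MITO_SYMBOLS + [spec.ec_marker, spec.pc_marker]

    n_cells = spec.n_plates * spec.cells_per_plate
    plates = np.repeat([f"P{i+1}" for i in range(spec.n_plates)], spec.cells_per_plate)
    genotype_by_plate = {
        f"P{i+1}": ("control" if i in spec.control_plates else "knockout")
        for i in range(spec.n_plates)
    }
    genotypes = np.array([genotype_by_plate[p] for p in plates])
    barcodes = np.array(
        [f"BC{i % spec.cells_per_plate:04d}" for i in range(n_cells)]
    )

    # --- planted QC status and cell types --------------------------------
    order = rng.permutation(n_cells)
    fail_low = order[: spec.n_fail_low]
    fail_high = order[spec.n_fail_low : spec.n_fail_low + spec.n_fail_high]
    fail_mito = order[
        spec.n_fail_low + spec.n_fail_high : spec.n_fail_low
        + spec.n_fail_high
        + spec.n_fail_mito
    ]
    reason = np.array(["pass"] * n_cells, dtype=object)
    reason[fail_low] = "low_umi"
    reason[fail_high] = "high_umi"
    reason[fail_mito] = "high_mito"
    qc_pass = reason == "pass"

    targets = rng.uniform(*spec.pass_total_range, size=n_cells)
    targets[fail_low] = rng.uniform(*spec.fail_low_total_range, size=len(fail_low))
    targets[fail_high] = rng.uniform(*spec.fail_high_total_range, size=len(fail_high))
    mito_frac = rng.uniform(*spec.normal_mito_frac, size=n_cells)
    mito_frac[fail_mito] = rng.uniform(*spec.high_mito_frac, size=len(fail_mito))

    # cell types among QC-passing cells (failing cells typed too, harmless)
    cell_type = np.array(["pericyte"] * n_cells, dtype=object)
    n_ec = int(round(spec.frac_endothelial * n_cells))
    ec_idx = rng.choice(n_cells, size=n_ec, replace=False)
    cell_type[ec_idx] = "endothelial"
    passing_idx = np.flatnonzero(qc_pass)
    excl = rng.choice(
        passing_idx,
        size=spec.n_excluded_both + spec.n_excluded_neither,
        replace=False,
    )
    cell_type[excl[: spec.n_excluded_both]] = "excluded_both"
    cell_type[excl[spec.n_excluded_both :]] = "excluded_neither"

    # --- gene abundance model --------------------------------------------
    w = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, size=n_base)
    w = w / w.sum()
    w_mito = rng.lognormal(0.0, 0.5, size=n_mito)
    w_mito = w_mito / w_mito.sum()

    # DE genes drawn from well-expressed but not top-abundance genes (a few
    # UMI per cell): detectable at the planted fold changes, yet the total
    # library-mass shift in knockout cells stays small, so per-cell
    # normalization does not depress null genes compositionally
    hi = max(40, spec.n_de_genes_per_type)
    lo = hi + max(240, 4 * spec.n_de_genes_per_type)
    detectable = np.argsort(w)[-lo:-hi]
    de_pick = rng.choice(detectable, size=2 * spec.n_de_genes_per_type, replace=False)
    de_rows = []
    lfc_cycle = np.resize(spec.de_log2fc_values, spec.n_de_genes_per_type)
    de_factor = np.ones((n_cells, n_base))
    for t, (ct, picks) in enumerate(
        [
            ("endothelial", de_pick[: spec.n_de_genes_per_type]),
            ("pericyte", de_pick[spec.n_de_genes_per_type :]),
        ]
    ):
        for g, lfc in zip(picks, lfc_cycle):
            de_rows.append(
                {"gene": base_genes[g], "cell_type": ct, "log2fc": float(lfc)}
            )
            affected = (cell_type == ct) & (genotypes == "knockout")
            de_factor[affected, g] = 2.0**lfc

    depth = np.array(
        [spec.plate_depth_factors[int(p[1:]) - 1] for p in plates]
    )

    base_mean = w[None, :] * de_factor
    base_mean = base_mean / base_mean.sum(axis=1, keepdims=True)
    mean = np.empty((n_cells, spec.n_genes))
    mean[:, :n_base] = (
        base_mean * ((1.0 - mito_frac) * targets * depth)[:, None]
    )
    mean[:, n_base : n_base + n_mito] = (
        w_mito[None, :] * (mito_frac * targets * depth)[:, None]
    )
    mean[:, n_base + n_mito :] = 0.0

    if spec.dispersion is None:
        counts = rng.poisson(mean).astype(float)
    else:
        shape = spec.dispersion
        lam = rng.gamma(shape, mean / shape)
        counts = rng.poisson(lam).astype(float)
    if spec.dropout_rate > 0:
        keep = rng.random(size=counts.shape) >= spec.dropout_rate
        counts *= keep

    # --- marker genes by detection rule ----------------------------------
    ec_col = genes.index(spec.ec_marker)
    pc_col = genes.index(spec.pc_marker)
    marker_draw = rng.poisson(spec.marker_mean, size=(n_cells, 2))
    express_ec = (cell_type == "endothelial") | (cell_type == "excluded_both")
    express_pc = (cell_type == "pericyte") | (cell_type == "excluded_both")
    counts[:, ec_col] = np.where(express_ec, np.maximum(marker_draw[:, 0], 1), 0)
    counts[:, pc_col] = np.where(express_pc, np.maximum(marker_draw[:, 1], 1), 0)

    adata = counts_matrix(counts, genes, barcodes, plates, genotypes)
    obs_names = pd.Index([f"{p}:{b}" for p, b in zip(plates, barcodes)])
    cells = pd.DataFrame(
        {
            "plate": plates,
            "barcode": barcodes,
            "genotype": genotypes,
            "qc_pass": qc_pass,
            "fail_reason": reason,
            "cell_type": np.where(
                np.char.startswith(cell_type.astype(str), "excluded"),
                "excluded",
                cell_type.astype(str),
            ),
            "target_total": targets,
            "target_mito_frac": mito_frac,
        },
        index=obs_names,
    ).loc[adata.obs_names]
    gt = CountsGroundTruth(
        cells=cells,
        de_genes=pd.DataFrame(de_rows, columns=["gene", "cell_type", "log2fc"]),
        marker_genes=(spec.ec_marker, spec.pc_marker),
        mito_genes=list(_MITO_SYMBOLS),
    )
    return adata, gt
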