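"""SORT-seq single-cell pipeline: plate normalization, QC, marker-rule cell
typing, log-normalization, logistic-regression LRT differential expression
and hypergeometric gene-set enrichment.

The pipeline starts from a UMI count matrix of 384-well capture plates.
Counts are scaled so every plate matches the plate with the highest median
per-cell UMI total, cells are kept when their total falls in a fixed window
(default 1000–8000, inclusive) with a mitochondrial fraction below 10%, and
cell types are assigned purely by marker detection: *Cldn5* (UMI > 0) marks
endothelial cells, *Pdgfrb* pericytes, and cells expressing both or neither
are excluded.  Differential expression per gene is a likelihood-ratio test
between logistic regressions of group membership on log-normalized
expression (intercept-only null), mirroring the Seurat ``FindMarkers``
logistic-regression test.

The in-memory container is an :class:`anndata.AnnData` with cells in
``obs`` (columns ``plate`` and ``genotype``) and genes in ``var``; gene and
cell order are canonicalized (sorted) at construction so downstream results
do not depend on input file ordering.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import stats

__all__ = [
    "counts_matrix",
    "read_counts_mtx",
    "read_counts_csv",
    "read_gmt",
    "normalize_plates",
    "qc_filter",
    "assign_cell_types",
    "log_normalize",
    "scale_expression",
    "logistic_lrt",
    "differential_expression",
    "hypergeometric_enrichment",
    "panel_screen",
    "run_accession_pipeline",
]


# ---------------------------------------------------------------------------
# container construction and I/O


def counts_matrix(
    counts: np.ndarray,
    genes: Sequence[str],
    barcodes: Sequence[str],
    plates: Sequence[str],
    genotypes: Sequence[str],
) -> ad.AnnData:
    """Build the canonical AnnData counts container (cells × genes).

    ``counts`` is cells × genes and non-negative; ``(barcode, plate)`` pairs
    must be unique.  Genes and cells are sorted so results are independent
    of input ordering.
    """
    counts = np.asarray(counts, dtype=float)
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("gene symbols must be unique")
    if counts.min() < 0 or not np.isfinite(counts).all():
        raise ValueError("counts must be finite and non-negative")
    obs = pd.DataFrame(
        {
            "barcode": list(barcodes),
            "plate": [str(p) for p in plates],
            "genotype": list(genotypes),
        }
    )
    obs.index = obs["plate"] + ":" + obs["barcode"]
    if obs.index.duplicated().any():
        dup = obs.index[obs.index.duplicated()].tolist()
        raise ValueError(f"duplicate (plate, barcode) pairs: {dup[:5]}")
    adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata = adata[np.argsort(adata.obs_names), np.argsort(adata.var_names)].copy()
    adata.uns["normalized"] = False
    return adata


def read_counts_mtx(mtx_path, genes_path, cells_path) -> ad.AnnData:
    """Read a genes × cells MTX triplet with gene and cell annotation TSVs.

    The cells TSV needs columns ``barcode``, ``plate`` and ``genotype``;
    the genes TSV has the symbol in its first column.
    """
    m = spio.mmread(str(mtx_path)).toarray().T  # to cells × genes
    genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].tolist()
    cells = pd.read_csv(cells_path, sep="\t")
    return counts_matrix(m, genes, cells["barcode"], cells["plate"], cells["genotype"])


def read_counts_csv(path) -> ad.AnnData:
    """Read a dense CSV: genes in rows, cells in columns named ``plate:barcode``;
    genotype per cell in a mandatory first row ``__genotype__``."""
    df = pd.read_csv(path, index_col=0)
    genotypes = df.loc["__genotype__"].astype(str).tolist()
    df = df.drop(index="__genotype__").astype(float)
    plates, barcodes = zip(*(c.split(":", 1) for c in df.columns))
    return counts_matrix(df.to_numpy().T, df.index, barcodes, plates, genotypes)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# normalization and QC


def _totals(adata: ad.AnnData) -> np.ndarray:
    return np.asarray(adata.X).sum(axis=1)


def normalize_plates(adata: ad.AnnData) -> ad.AnnData:
    """Scale counts so every plate matches the highest plate median UMI total.

    The per-plate median is taken over cells with at least one count (empty
    wells do not contribute); every cell on a plate is multiplied by
    ``max_median / plate_median``.
    """
    totals = _totals(adata)
    medians = {}
    for plate in sorted(adata.obs["plate"].unique()):
        sel = (adata.obs["plate"] == plate).to_numpy()
        nonzero = totals[sel][totals[sel] > 0]
        if len(nonzero) == 0:
            raise ValueError(f"plate {plate!r} has no cells with nonzero counts")
        medians[plate] = float(np.median(nonzero))
    top = max(medians.values())
    factors = adata.obs["plate"].map({p: top / m for p, m in medians.items()}).to_numpy()
    out = adata.copy()
    out.X = np.asarray(out.X) * factors[:, None]
    out.obs["plate_scale_factor"] = factors
    out.uns["normalized"] = True
    return out


def qc_filter(
    adata: ad.AnnData,
    umi_min: float = 1000.0,
    umi_max: float = 8000.0,
    mito_max_pct: float = 10.0,
    mito_prefix: str = "mt-",
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Keep cells with total UMI in [umi_min, umi_max] and mito % strictly
    below ``mito_max_pct``.

    Applied after plate normalization (the stated order); bounds are
    inclusive, the mitochondrial cutoff strict.  Mitochondrial genes are
    identified by a case-insensitive symbol prefix.
    """
    if not adata.uns.get("normalized", False):
        raise ValueError("qc_filter expects plate-normalized counts; run normalize_plates first")
    totals = _totals(adata)
    mito_genes = np.array(
        [g.lower().startswith(mito_prefix.lower()) for g in adata.var_names]
    )
    if not mito_genes.any():
        warnings.warn(
            f"no genes match mitochondrial prefix {mito_prefix!r}; mito_pct set to 0",
            stacklevel=2,
        )
        mito_pct = np.zeros(adata.n_obs)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_pct = 100.0 * np.asarray(adata.X)[:, mito_genes].sum(axis=1) / totals
        mito_pct = np.where(totals > 0, mito_pct, 0.0)
    passing = (totals >= umi_min) & (totals <= umi_max) & (mito_pct < mito_max_pct)
    records = pd.DataFrame(
        {
            "barcode": adata.obs["barcode"].to_numpy(),
            "plate": adata.obs["plate"].to_numpy(),
            "total_umi": totals,
            "mito_pct": mito_pct,
            "pass": passing,
        },
        index=adata.obs_names,
    )
    return adata[passing].copy(), records


def assign_cell_types(
    adata: ad.AnnData,
    ec_marker: str = "Cldn5",
    pc_marker: str = "Pdgfrb",
) -> pd.DataFrame:
    """Marker-rule cell typing: endothelial iff only the endothelial marker
    is detected (UMI > 0), pericyte iff only the pericyte marker is
    detected; both or neither → excluded.

    Stores the call in ``adata.obs['cell_type']`` and returns the table.
    """
    for marker in (ec_marker, pc_marker):
        if marker not in adata.var_names:
            raise ValueError(f"marker gene {marker!r} not present in the gene list")
    ec = np.asarray(adata[:, ec_marker].X).ravel() > 0
    pc = np.asarray(adata[:, pc_marker].X).ravel() > 0
    call = np.where(ec & ~pc, "endothelial", np.where(pc & ~ec, "pericyte", "excluded"))
    adata.obs["cell_type"] = call
    return pd.DataFrame({"barcode": adata.obs["barcode"], "call": call}, index=adata.obs_names)


def log_normalize(adata: ad.AnnData, scale_factor: float = 1e4, layer: str = "lognorm") -> ad.AnnData:
    """Per-cell log-normalization: x → ln(1 + x · scale_factor / total).

    Stored as a layer; raises for cells with zero total (cannot occur after
    QC with a positive lower bound).
    """
    X = np.asarray(adata.X, float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = adata.obs_names[totals == 0].tolist()
        raise ValueError(f"cells with zero total counts cannot be log-normalized: {bad[:5]}")
    adata.layers[layer] = np.log1p(X * scale_factor / totals[:, None])
    return adata


def scale_expression(adata: ad.AnnData, layer: str = "lognorm") -> np.ndarray:
    """Per-gene z-scaling (mean 0, sd 1) of a layer, for heatmap rendering."""
    X = np.asarray(adata.layers[layer], float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


# ---------------------------------------------------------------------------
# differential expression


def logistic_lrt(
    x: np.ndarray,
    y: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> tuple[float, float, bool]:
    """Likelihood-ratio test of a single-covariate logistic regression.

    Fits ``P(y=1) = expit(b0 + b1 x)`` by Newton/IRLS (capped at
    ``max_iter`` iterations) against the intercept-only null and returns
    ``(lrt_statistic, p_value, converged)`` with the p-value from χ²(1).
    Under perfect separation the capped fit is used and ``converged`` is
    False.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p)
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        H[np.diag_indices_from(H)] += 1e-12
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30.0, 30.0)
    p = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-300
    ll_full = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    pbar = y.mean()
    n1 = y.sum()
    ll_null = 0.0
    if 0 < pbar < 1:
        ll_null = float(n1 * np.log(pbar) + (n - n1) * np.log(1 - pbar))
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    p_value = float(stats.chi2.sf(lrt, df=1))
    return lrt, max(p_value, np.nextafter(0, 1)), converged


def _group_log2fc(
    expr1: np.ndarray, expr2: np.ndarray, pseudocount: float
) -> float:
    m1 = float(np.expm1(expr1).mean()) if len(expr1) else 0.0
    m2 = float(np.expm1(expr2).mean()) if len(expr2) else 0.0
    return float(np.log2((m1 + pseudocount) / (m2 + pseudocount)))


def differential_expression(
    adata: ad.AnnData,
    groupby: str,
    group1: str,
    group2: str,
    layer: str = "lognorm",
    p_cutoff: float = 0.05,
    lfc_cutoff: float = 1.0,
    pseudocount: float = 1.0,
    min_pct: float | None = None,
    min_abs_log2fc: float | None = None,
) -> pd.DataFrame:
    """Per-gene logistic-regression LRT differential expression.

    For every gene expressed in at least one cell of either group, group
    membership is regressed on log-normalized expression; the p-value comes
    from the χ²(1) likelihood-ratio test against the intercept-only model.
    ``log2fc`` compares expm1-scale group means with a pseudo-count
    (``group1`` over ``group2``); a gene is significant when
    ``p < p_cutoff`` and ``|log2fc| > lfc_cutoff``.  Optional Seurat-style
    prefilters (``min_pct``, ``min_abs_log2fc``) are off by default.
    """
    labels = adata.obs[groupby].astype(str)
    sel1 = (labels == str(group1)).to_numpy()
    sel2 = (labels == str(group2)).to_numpy()
    if sel1.sum() < 3 or sel2.sum() < 3:
        raise ValueError(
            f"both groups need >= 3 cells (got {int(sel1.sum())} and {int(sel2.sum())})"
        )
    E = np.asarray(adata.layers[layer], float)
    e1, e2 = E[sel1], E[sel2]
    y = np.concatenate([np.ones(sel1.sum()), np.zeros(sel2.sum())])
    rows = []
    for j, gene in enumerate(adata.var_names):
        x1, x2 = e1[:, j], e2[:, j]
        if (x1 > 0).sum() + (x2 > 0).sum() == 0:
            continue
        if min_pct is not None:
            if max((x1 > 0).mean(), (x2 > 0).mean()) < min_pct:
                continue
        log2fc = _group_log2fc(x1, x2, pseudocount)
        if min_abs_log2fc is not None and abs(log2fc) < min_abs_log2fc:
            continue
        lrt, p, converged = logistic_lrt(np.concatenate([x1, x2]), y)
        rows.append(
            {
                "gene": gene,
                "log2fc": log2fc,
                "p_value": p,
                "lrt_statistic": lrt,
                "converged": converged,
                "significant": (p < p_cutoff) and (abs(log2fc) > lfc_cutoff),
            }
        )
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["log2fc", "p_value", "lrt_statistic", "converged", "significant"]
    )


# ---------------------------------------------------------------------------
# enrichment and panels


def hypergeometric_enrichment(
    input_genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    min_overlap: int = 5,
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in an input list.

    For each set, ``p = P(X >= k)`` with X hypergeometric(N, K, n) where
    N = |universe|, K = |set ∩ universe|, n = |input| and k the observed
    overlap.  A set is ``reported`` when k >= min_overlap and p < p_cutoff.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe must be non-empty")
    input_set = set(input_genes)
    if not input_set:
        raise ValueError("input gene list must be non-empty")
    if not input_set <= universe_set:
        missing = sorted(input_set - universe_set)
        raise ValueError(f"input genes outside the universe: {missing[:5]}")
    N, n = len(universe_set), len(input_set)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe_set
        K = len(members)
        k = len(members & input_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap_k": k,
                "set_size_K": K,
                "input_size_n": n,
                "universe_N": N,
                "p_value": min(max(p, np.nextafter(0, 1)), 1.0),
                "reported": (k >= min_overlap) and (p < p_cutoff),
            }
        )
    return pd.DataFrame(rows).set_index("set_name")


def panel_screen(
    deg: pd.DataFrame, panels: Mapping[str, Sequence[str]]
) -> dict[str, pd.DataFrame]:
    """Intersect significant differentially expressed genes with marker panels.

    Returns, per panel, the significant genes it contains with their log2
    fold change and direction (up/down in group1).  Empty panels yield an
    empty table with a warning.
    """
    sig = deg[deg["significant"]] if "significant" in deg else deg
    out = {}
    for name in sorted(panels):
        members = list(dict.fromkeys(panels[name]))
        if not members:
            warnings.warn(f"panel {name!r} is empty", stacklevel=2)
        hits = sig.loc[sig.index.intersection(members)].copy()
        hits["direction"] = np.where(hits["log2fc"] > 0, "up", "down")
        out[name] = hits.sort_values("p_value") if len(hits) else hits
    return out


# ---------------------------------------------------------------------------
# end-to-end convenience


def run_accession_pipeline(
    adata: ad.AnnData,
    control: str = "control",
    knockout: str = "knockout",
    **de_kwargs,
) -> dict:
    """Run the full stated pipeline on a raw counts container.

    Plate normalization → QC (UMI 1000–8000, mito < 10%) → marker typing →
    log-normalization → per-cell-type differential expression between
    genotypes.  Returns retained-cell bookkeeping and the DE tables.
    """
    norm = normalize_plates(adata)
    kept, qc = qc_filter(norm)
    types = assign_cell_types(kept)
    result: dict = {
        "n_cells_retained": int(kept.n_obs),
        "qc_table": qc,
        "cell_type_counts": kept.obs.groupby(["cell_type", "genotype"]).size().to_dict(),
    }
    for ct in ("endothelial", "pericyte"):
        sub = kept[kept.obs["cell_type"] == ct].copy()
        counts = sub.obs["genotype"].value_counts()
        if counts.get(control, 0) >= 3 and counts.get(knockout, 0) >= 3:
            log_normalize(sub)
            result[f"deg_{ct}"] = differential_expression(
                sub, "genotype", knockout, control, **de_kwargs
            )
    return result
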