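"""Standard scRNA-seq preprocessing: QC, normalization, HVG, scaling, PCA.

The four-step workflow mirrors the common Scanpy recipe: (i) drop cells
expressing fewer than 10 genes, then genes expressed in fewer than 3 of the
remaining cells; (ii) per-cell library-size normalization to 10 000 counts
followed by log1p; (iii) selection of 2000 highly variable genes by binned
normalized dispersion; (iv) per-gene z-score scaling and PCA down to 100
components.  Conventions that the recipe leaves open are fixed here for
exact testability: "expressed" means count > 0, the z-score uses the
population (1/N) standard deviation, HVG ties break by gene ID, and PCA
signs are fixed so each component's largest-magnitude loading is positive.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .io_core import (
    NORMALIZED,
    RAW_COUNTS,
    SCALED,
    ConfigError,
    Dataset,
    Embedding,
    derive_seed,
)

MIN_GENES_PER_CELL = 10
MIN_CELLS_PER_GENE = 3
TARGET_SUM = 10_000.0


class EmptyDatasetError(ValueError):
    pass


def _require_state(ds: Dataset, state: str, op: str) -> None:
    if ds.layer_state != state:
        raise ConfigError(f"{op} requires layer_state={state!r}, got {ds.layer_state!r}")


def qc_filter(ds: Dataset) -> Dataset:
    """Remove low-quality cells, then lowly expressed genes.

    Cells expressing (count > 0) fewer than 10 genes are dropped first;
    genes expressed in fewer than 3 of the *remaining* cells are dropped
    second.  Idempotent: a second pass removes nothing, because dropping
    genes cannot raise a cell's expressed-gene count and the surviving
    genes were counted against the surviving cells. (A cell can in
    principle fall below 10 expressed genes after gene filtering; the
    documented order is cells-then-genes, applied once.)
    """
    _require_state(ds, RAW_COUNTS, "qc_filter")
    X = ds.matrix
    if sp.issparse(X):
        genes_per_cell = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        genes_per_cell = np.count_nonzero(X > 0, axis=1)
    keep_cells = genes_per_cell >= MIN_GENES_PER_CELL
    if not keep_cells.any():
        raise EmptyDatasetError(
            f"all cells removed: every cell expresses < {MIN_GENES_PER_CELL} genes"
        )
    X2 = X[keep_cells]
    if sp.issparse(X2):
        cells_per_gene = np.asarray((X2 > 0).sum(axis=0)).ravel()
    else:
        cells_per_gene = np.count_nonzero(X2 > 0, axis=0)
    keep_genes = cells_per_gene >= MIN_CELLS_PER_GENE
    if not keep_genes.any():
        raise EmptyDatasetError(
            f"all genes removed: every gene is expressed in < {MIN_CELLS_PER_GENE} cells"
        )
    return ds.subset(cells=np.flatnonzero(keep_cells), genes=np.flatnonzero(keep_genes))


def normalize_log1p(ds: Dataset) -> Dataset:
    """Library-size normalize each cell to 10 000 counts, then log1p."""
    _require_state(ds, RAW_COUNTS, "normalize_log1p")
    X = ds.dense().astype(float)
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError(
            "cell(s) with zero total count; run qc_filter before normalization"
        )
    X = np.log1p(X / totals[:, None] * TARGET_SUM)
    return ds.with_matrix(X, NORMALIZED)


def select_hvg(ds: Dataset, n_hvg: int = 2000, n_bins: int = 20) -> Dataset:
    """Keep the ``n_hvg`` most variable genes by binned normalized dispersion.

    Per gene, mean and dispersion (variance / mean) are computed on the
    log-normalized layer; genes are grouped into ``n_bins`` equal-frequency
    mean-expression bins and each gene's dispersion is z-scored within its
    bin.  Genes are ranked by that normalized dispersion, descending, with
    ties broken by gene ID (ascending), and the top ``n_hvg`` are retained
    in their original column order.  If ``n_hvg`` >= n_genes all genes are
    kept unchanged.
    """
    _require_state(ds, NORMALIZED, "select_hvg")
    if n_hvg <= 0:
        raise ConfigError("n_hvg must be positive")
    if n_hvg >= ds.n_genes:
        return ds
    X = ds.dense()
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # equal-frequency bins over gene means; degenerate bins get z-score 0
    order = np.argsort(mean, kind="stable")
    bins = np.empty(ds.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(ds.n_genes) * n_bins) // ds.n_genes, n_bins - 1
    )
    norm_disp = np.zeros(ds.n_genes)
    for b in range(n_bins):
        mask = bins == b
        if not mask.any():
            continue
        d = disp[mask]
        sd = d.std()
        norm_disp[mask] = (d - d.mean()) / sd if sd > 0 else 0.0
    rank_key = sorted(
        range(ds.n_genes), key=lambda g: (-norm_disp[g], str(ds.gene_ids[g]))
    )
    selected = np.sort(np.asarray(rank_key[:n_hvg]))
    return ds.subset(genes=selected)


def zscore_scale(ds: Dataset) -> Dataset:
    """Center each gene and divide by its population (1/N) standard deviation.

    Zero-variance genes map to all-zero columns rather than NaN.
    """
    _require_state(ds, NORMALIZED, "zscore_scale")
    X = ds.dense().astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd, ddof=0
    Xc = X - mu
    out = np.divide(Xc, sd, out=np.zeros_like(Xc), where=sd > 0)
    return ds.with_matrix(out, SCALED)


def pca_embed(ds: Dataset, n_pcs: int = 100, seed: int = 0) -> Embedding:
    """Project scaled data onto its top principal components.

    Components are ordered by decreasing explained variance.  The solver is
    exact (full SVD) up to 5000 cells and seeded randomized SVD above.  For
    determinism each component's sign is fliped so that its
    largest-magnitude gene loading is positive.
    """
    _require_state(ds, SCALED, "pca_embed")
    if n_pcs < 1:
        raise ConfigError("n_pcs must be >= 1")
    X = ds.dense()
    max_rank = min(ds.n_cells, ds.n_genes)
    d = min(n_pcs, max_rank)
    if ds.n_cells <= 5000:
        pca = PCA(n_components=d, svd_solver="full")
    else:
        pca = PCA(
            n_components=d,
            svd_solver="randomized",
            random_state=derive_seed(seed, "pca"),
        )
    coords = pca.fit_transform(X)
    # sign convention: largest-|loading| positive per component
    comp = pca.components_
    flip = np.sign(comp[np.arange(comp.shape[0]), np.argmax(np.abs(comp), axis=1)])
    flip[flip == 0] = 1.0
    coords = coords * flip
    return Embedding(coords=coords, cell_ids=ds.cell_ids, space="pca")


def preprocess(
    ds: Dataset, n_hvg: int = 2000, n_pcs: int = 100, seed: int = 0
) -> tuple[Dataset, Embedding]:
    """Run the full four-step workflow; returns (scaled dataset, PCA embedding)."""
    ds = qc_filter(ds)
    ds = normalize_log1p(ds)
    ds = select_hvg(ds, n_hvg=n_hvg)
    ds = zscore_scale(ds)
    return ds, pca_embed(ds, n_pcs=n_pcs, seed=seed)
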