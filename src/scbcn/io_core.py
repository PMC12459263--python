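"""Data model, file I/O, configuration and seed management.

The central containers are :class:`Dataset` (a cells x genes expression
matrix with per-cell batch labels and optional ground-truth type labels)
and :class:`Embedding` (a cells x d coordinate matrix, either the PCA
space or the corrected space produced by the network).

Batch labels are opaque categoricals ordered by first appearance; every
per-batch loop in the package iterates in that order, which makes results
deterministic for a fixed input ordering.  A single global seed fans out
to per-stage seeds through :func:`derive_seed`.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("scbcn")

RAW_COUNTS = "raw_counts"
NORMALIZED = "normalized"
SCALED = "scaled"

#: obsm key used when writing a corrected embedding back into an h5ad file.
H5AD_EMBEDDING_KEY = "X_scbcn"
#: obs column used when writing global cluster labels back into an h5ad file.
H5AD_CLUSTER_KEY = "scbcn_cluster"


def derive_seed(base_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed from the global seed.

    Uses the first four bytes of ``blake2b(f"{base_seed}:{stage}")`` reduced
    modulo 2**31 - 1, so each stage (Leiden, tuplet sampling, network init,
    metric subsampling, ...) can be re-run in isolation with a reproducible
    seed that fits any 32-bit RNG API.
    """
    digest = hashlib.blake2b(f"{base_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


class ConfigError(ValueError):
    """Raised for invalid configuration or contract violations."""


class FormatError(ValueError):
    """Raised for malformed input files."""


def _dedupe_ids(ids: Sequence[str]) -> np.ndarray:
    """Make IDs unique: first occurrence wins, later duplicates get '-<n>'."""
    seen: dict[str, int] = {}
    out = []
    for x in map(str, ids):
        if x in seen:
            seen[x] += 1
            out.append(f"{x}-{seen[x]}")
        else:
            seen[x] = 0
            out.append(x)
    return np.asarray(out, dtype=object)


@dataclass
class Dataset:
    """Cells x genes expression matrix with per-cell annotations.

    ``layer_state`` records which preprocessing steps have been applied:
    ``raw_counts`` -> ``normalized`` (library-size + log1p) -> ``scaled``
    (per-gene z-score on the HVG subset).
    """

    matrix: np.ndarray | sp.spmatrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    batch: np.ndarray
    type_label: Optional[np.ndarray] = None
    layer_state: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.batch = np.asarray(self.batch, dtype=object)
        if self.type_label is not None:
            self.type_label = np.asarray(self.type_label, dtype=object)
            if len(self.type_label) != self.n_cells:
                raise ConfigError("type_label length must equal number of cells")
        n, g = self.matrix.shape
        if len(self.cell_ids) != n or len(self.batch) != n:
            raise ConfigError("cell_ids/batch length must equal matrix rows")
        if len(self.gene_ids) != g:
            raise ConfigError("gene_ids length must equal matrix columns")
        if len(set(self.cell_ids)) != n:
            raise ConfigError("cell_ids must be unique")
        if len(set(self.gene_ids)) != g:
            raise ConfigError("gene_ids must be unique")
        if self.layer_state not in (RAW_COUNTS, NORMALIZED, SCALED):
            raise ConfigError(f"unknown layer_state {self.layer_state!r}")
        if self.layer_state == RAW_COUNTS:
            m = self.matrix.data if sp.issparse(self.matrix) else self.matrix
            if m.size and np.min(m) < 0:
                raise FormatError("raw counts must be nonnegative")
        if self.n_batches == 1:
            warnings.warn(
                "dataset has a single batch; MNN search will be intra-batch only",
                stacklevel=2,
            )

    # -- convenience views -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def batch_categories(self) -> list:
        """Distinct batch labels in order of first appearance."""
        return list(pd.unique(self.batch))

    @property
    def n_batches(self) -> int:
        return len(self.batch_categories)

    def dense(self) -> np.ndarray:
        return self.matrix.toarray() if sp.issparse(self.matrix) else np.asarray(self.matrix)

    def subset(
        self,
        cells: Optional[np.ndarray] = None,
        genes: Optional[np.ndarray] = None,
        layer_state: Optional[str] = None,
    ) -> "Dataset":
        m = self.matrix
        if cells is not None:
            m = m[cells]
        if genes is not None:
            m = m[:, genes]
        return Dataset(
            matrix=m,
            cell_ids=self.cell_ids[cells] if cells is not None else self.cell_ids,
            gene_ids=self.gene_ids[genes] if genes is not None else self.gene_ids,
            batch=self.batch[cells] if cells is not None else self.batch,
            type_label=(
                self.type_label[cells]
                if (self.type_label is not None and cells is not None)
                else self.type_label
            ),
            layer_state=layer_state or self.layer_state,
        )

    def with_matrix(self, matrix, layer_state: str) -> "Dataset":
        return replace(self, matrix=matrix, layer_state=layer_state)


@dataclass
class Embedding:
    """Cells x d coordinates, in ``pca`` or ``corrected`` space."""

    coords: np.ndarray
    cell_ids: np.ndarray
    space: str = "pca"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise ConfigError("embedding must be 2-D with d >= 1")
        if self.coords.shape[0] != len(self.cell_ids):
            raise ConfigError("coords rows must match cell_ids")
        if not np.all(np.isfinite(self.coords)):
            raise ConfigError("embedding contains non-finite values")
        if self.space not in ("pca", "corrected"):
            raise ConfigError(f"unknown embedding space {self.space!r}")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline with their defaults.

    Defaults follow the method's stated operating point: Leiden resolution
    3.0, 100 global PCs, the first 10 PCs for the cosine MNN search,
    k = 10 neighbors, T = 10 walk steps.
    """

    leiden_resolution: float = 3.0
    snn_k: int = 15
    n_pcs_global: int = 100
    n_pcs_mnn: int = 10
    knn_k: int = 10
    walk_steps: int = 10
    n_spectral_groups: int | str = "auto"
    n_hvg: int = 2000
    embed_dim: int = 32
    k_tuple: int = 4
    epochs: int = 50
    batch_size: int = 256
    learning_rate: float = 0.01
    momentum: float = 0.9
    cluster_norm: str = "product"  # or "sqrt": cluster-size normalization rule
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snn_k", "n_pcs_global", "n_pcs_mnn", "knn_k", "n_hvg",
                     "embed_dim", "k_tuple", "epochs", "batch_size"):
            if int(getattr(self, name)) < (0 if name == "epochs" else 1):
                raise ConfigError(f"{name} must be positive")
        if self.leiden_resolution <= 0:
            raise ConfigError("leiden_resolution must be > 0")
        if self.walk_steps < 0:
            raise ConfigError("walk_steps must be >= 0")
        if self.n_pcs_mnn > self.n_pcs_global:
            raise ConfigError("n_pcs_mnn must be <= n_pcs_global")
        if self.cluster_norm not in ("product", "sqrt"):
            raise ConfigError("cluster_norm must be 'product' or 'sqrt'")

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.rng_seed, stage)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def load_dataset(
    path,
    format: str,
    batch_key: str,
    label_key: Optional[str] = None,
) -> Dataset:
    """Load a Dataset from ``h5ad``, ``mtx`` (triplet) or ``csv``.

    * ``h5ad``: an AnnData container; ``batch_key``/``label_key`` name obs
      columns.
    * ``mtx``: ``path`` is a directory holding ``matrix.mtx`` (cells x genes
      MatrixMarket), ``genes.txt`` (one gene ID per line) and ``cells.csv``
      (index = cell IDs, columns include ``batch_key``).
    * ``csv``: one table, cells as rows, a header row; ``batch_key`` (and
      optionally ``label_key``) are metadata columns, every other column is
      a gene.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "h5ad":
        return _load_h5ad(path, batch_key, label_key)
    if format == "mtx":
        return _load_mtx(path, batch_key, label_key)
    if format in ("csv", "tsv"):
        return _load_csv(path, batch_key, label_key, sep="\t" if format == "tsv" else ",")
    raise ConfigError(f"unknown format {format!r}")


def _load_h5ad(path: Path, batch_key: str, label_key: Optional[str]) -> Dataset:
    import anndata

    adata = anndata.read_h5ad(path)
    if batch_key not in adata.obs:
        raise ConfigError(f"batch key {batch_key!r} not found in obs")
    if label_key is not None and label_key not in adata.obs:
        raise ConfigError(f"label key {label_key!r} not found in obs")
    X = adata.X
    if sp.issparse(X):
        X = X.tocsr().astype(float)
    else:
        X = np.asarray(X, dtype=float)
    return Dataset(
        matrix=X,
        cell_ids=_dedupe_ids(adata.obs_names),
        gene_ids=_dedupe_ids(adata.var_names),
        batch=np.asarray(adata.obs[batch_key].astype(str)),
        type_label=(
            np.asarray(adata.obs[label_key].astype(str)) if label_key is not None else None
        ),
    )


def _load_mtx(path: Path, batch_key: str, label_key: Optional[str]) -> Dataset:
    mtx = path / "matrix.mtx"
    genes = path / "genes.txt"
    cells = path / "cells.csv"
    for f in (mtx, genes, cells):
        if not f.exists():
            raise FileNotFoundError(f)
    X = scipy.io.mmread(mtx).tocsr().astype(float)
    gene_ids = _dedupe_ids([ln.strip() for ln in genes.read_text().splitlines() if ln.strip()])
    meta = pd.read_csv(cells, index_col=0)
    if batch_key not in meta.columns:
        raise ConfigError(f"batch key {batch_key!r} not found in cells.csv")
    if label_key is not None and label_key not in meta.columns:
        raise ConfigError(f"label key {label_key!r} not found in cells.csv")
    return Dataset(
        matrix=X,
        cell_ids=_dedupe_ids(meta.index),
        gene_ids=gene_ids,
        batch=np.asarray(meta[batch_key].astype(str)),
        type_label=np.asarray(meta[label_key].astype(str)) if label_key else None,
    )


def _load_csv(path: Path, batch_key: str, label_key: Optional[str], sep: str) -> Dataset:
    df = pd.read_csv(path, index_col=0, sep=sep)
    if batch_key not in df.columns:
        raise ConfigError(f"batch key {batch_key!r} not found in CSV header")
    meta_cols = [batch_key] + ([label_key] if label_key else [])
    if label_key is not None and label_key not in df.columns:
        raise ConfigError(f"label key {label_key!r} not found in CSV header")
    expr = df.drop(columns=meta_cols)
    try:
        X = expr.to_numpy(dtype=float)
    except ValueError as e:
        raise FormatError(f"non-numeric expression values: {e}") from e
    return Dataset(
        matrix=X,
        cell_ids=_dedupe_ids(df.index),
        gene_ids=_dedupe_ids(expr.columns),
        batch=np.asarray(df[batch_key].astype(str)),
        type_label=np.asarray(df[label_key].astype(str)) if label_key else None,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def save_dataset_mtx(ds: Dataset, path) -> None:
    """Write the MTX triplet consumed by ``load_dataset(..., format='mtx')``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(ds.matrix))
    (path / "genes.txt").write_text("\n".join(map(str, ds.gene_ids)) + "\n")
    meta = pd.DataFrame({"batch": ds.batch}, index=pd.Index(ds.cell_ids, name="cell_id"))
    if ds.type_label is not None:
        meta["type"] = ds.type_label
    meta.to_csv(path / "cells.csv")


def save_dataset_h5ad(ds: Dataset, path) -> None:
    """Write a Dataset as an h5ad container (obs: 'batch', optional 'type')."""
    import anndata

    obs = pd.DataFrame(index=pd.Index(ds.cell_ids.astype(str), name="cell_id"))
    obs["batch"] = pd.Categorical(ds.batch.astype(str))
    if ds.type_label is not None:
        obs["type"] = pd.Categorical(ds.type_label.astype(str))
    adata = anndata.AnnData(
        X=ds.matrix if sp.issparse(ds.matrix) else np.asarray(ds.matrix),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(ds.gene_ids.astype(str), name="gene_id")),
    )
    adata.write_h5ad(Path(path))


def save_result(
    embedding: Embedding,
    global_labels: np.ndarray,
    path,
    h5ad_path=None,
) -> Path:
    """Write the corrected embedding plus per-cell cluster labels.

    Always writes a CSV (cell_id index, one column per coordinate, final
    ``cluster`` column).  When ``h5ad_path`` points at an existing h5ad
    container, the embedding is additionally stored under
    ``obsm['X_scbcn']`` and the labels under ``obs['scbcn_cluster']``.
    """
    if not np.all(np.isfinite(embedding.coords)):
        raise ConfigError("embedding must be finite")
    if len(global_labels) != embedding.n_cells:
        raise ConfigError("labels length must match embedding")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        embedding.coords,
        index=pd.Index(embedding.cell_ids.astype(str), name="cell_id"),
        columns=[f"dim{i}" for i in range(embedding.dim)],
    )
    df["cluster"] = np.asarray(global_labels)
    df.to_csv(path)
    if h5ad_path is not None:
        import anndata

        adata = anndata.read_h5ad(h5ad_path)
        if adata.n_obs != embedding.n_cells:
            raise ConfigError("h5ad cell count does not match embedding")
        adata.obsm[H5AD_EMBEDDING_KEY] = embedding.coords
        adata.obs[H5AD_CLUSTER_KEY] = pd.Categorical(np.asarray(global_labels).astype(str))
        adata.write_h5ad(h5ad_path)
    return path


def load_result(path) -> tuple[Embedding, np.ndarray]:
    """Inverse of :func:`save_result` (CSV side)."""
    df = pd.read_csv(path, index_col=0)
    labels = df["cluster"].to_numpy()
    coords = df.drop(columns=["cluster"]).to_numpy(dtype=float)
    return Embedding(coords, np.asarray(df.index, dtype=object), space="corrected"), labels
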