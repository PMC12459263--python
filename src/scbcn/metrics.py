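"""Integration-quality metrics.

Biological-conservation side: ARI and NMI between predicted clusters and
ground-truth cell types, and the average silhouette width over types
(ASW_celltype, rescaled from [-1, 1] to [0, 1]).  Batch-mixing side: a
label-aware iLISI deviation score and the KL divergence between local and
global batch proportions (BatchKL).

The iLISI used here is a *deviation from ideal mixing*: for each cell the
inverse Simpson index of batch proportions among its 90 nearest neighbors
is compared with N_i, the number of batches in which the cell's type
occurs at all, as |iLISI(i) - N_i| / N_i; these deviations are averaged
within each batch and then across batches, so LOWER is better (0 = ideal
mixing).  BatchKL subsamples up to 1000 cells (seeded, chosen on a
cell-ID-sorted ordering so the value is invariant to cell order) and
averages per-cell KL divergences computed over 100-nearest-neighbor batch
proportions; lower is better.

Composites: Biological_conservation = mean(ARI, NMI, ASW_celltype), and
Batch_mixing = ((3 - BatchKL)/3 + iLISI/3) / 2 with BatchKL clipped to
[0, 3].  The raw BatchKL is what MetricReport stores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from math import log
from typing import Optional

import numpy as np
from scipy.special import comb
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

from .io_core import ConfigError, Embedding, derive_seed

K_LISI = 90
K_KL = 100
KL_SUBSAMPLE = 1000


@dataclass
class MetricReport:
    """One integration run's scores. ilisi and batch_kl: lower is better."""

    ari: float
    nmi: float
    asw_celltype: float
    ilisi: float
    batch_kl: float
    biological_conservation: float
    batch_mixing: float
    k_lisi: int = K_LISI
    k_kl: int = K_KL

    def __post_init__(self) -> None:
        if self.ari > 1 + 1e-9:
            raise ConfigError("ARI cannot exceed 1")
        if not (-1e-9 <= self.nmi <= 1 + 1e-9):
            raise ConfigError("NMI out of [0, 1]")
        if not (-1e-9 <= self.asw_celltype <= 1 + 1e-9):
            raise ConfigError("ASW_celltype out of [0, 1]")
        if self.ilisi < -1e-9 or self.batch_kl < -1e-9:
            raise ConfigError("iLISI and BatchKL are nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


def _contingency(pred, truth) -> np.ndarray:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ConfigError("label vectors must have equal length")
    if len(pred) < 2:
        raise ConfigError("need at least 2 cells")
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(truth, return_inverse=True)
    table = np.zeros((pi.max() + 1, ti.max() + 1))
    np.add.at(table, (pi, ti), 1)
    return table


def ari(pred, truth) -> float:
    """Adjusted Rand index from the contingency table (permutation model)."""
    t = _contingency(pred, truth)
    n = t.sum()
    sum_ij = comb(t, 2).sum()
    a = comb(t.sum(axis=1), 2).sum()
    b = comb(t.sum(axis=0), 2).sum()
    expected = a * b / comb(n, 2)
    max_index = (a + b) / 2
    if max_index == expected:  # both labelings trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def nmi(pred, truth) -> float:
    """Normalized mutual information, 2*MI / (H(pred) + H(truth)), natural logs."""
    t = _contingency(pred, truth)
    n = t.sum()
    a = t.sum(axis=1) / n
    b = t.sum(axis=0) / n
    h_a = -sum(p * log(p) for p in a if p > 0)
    h_b = -sum(p * log(p) for p in b if p > 0)
    if h_a == 0 and h_b == 0:
        return 1.0  # both labelings single-class
    if h_a == 0 or h_b == 0:
        return 0.0
    mi = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            if t[i, j] > 0:
                p = t[i, j] / n
                mi += p * log(p / (a[i] * b[j]))
    return float(2 * mi / (h_a + h_b))


def asw_celltype(emb: Embedding, types) -> float:
    """Mean Euclidean silhouette over type labels, rescaled to [0, 1].

    Singleton-type cells contribute s_i = 0.
    """
    types = np.asarray(types)
    uniq, counts = np.unique(types, return_counts=True)
    if len(uniq) < 2:
        raise ConfigError("ASW_celltype needs >= 2 cell types")
    if len(uniq) == len(types):
        s = np.zeros(len(types))  # all singletons
    else:
        s = silhouette_samples(emb.coords, types, metric="euclidean")
        s[np.isin(types, uniq[counts == 1])] = 0.0
    return float((s.mean() + 1) / 2)


def _knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbors per cell, self excluded, clamped to n - 1."""
    k_eff = min(k, coords.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k_eff).fit(coords)
    return nn.kneighbors(return_distance=False)


def ilisi(emb: Embedding, batch, types, k_lisi: int = K_LISI) -> float:
    """Label-aware local inverse Simpson deviation; 0 = ideal batch mixing.

    Per cell: iLISI(i) = 1 / sum_b f_b^2 where f_b are batch proportions
    among the cell's k nearest neighbors; deviation |iLISI(i) - N_i| / N_i
    with N_i the number of batches that contain the cell's type; averaged
    within each batch, then across batches.
    """
    if types is None:
        raise ConfigError("iLISI needs type labels (the ideal mixing N_i is label-aware)")
    batch = np.asarray(batch)
    types = np.asarray(types)
    batches = np.unique(batch)
    _, binv = np.unique(batch, return_inverse=True)
    # N_i: number of batches in which cell i's type occurs
    n_batches_per_type = {
        t: len(np.unique(batch[types == t])) for t in np.unique(types)
    }
    N = np.asarray([n_batches_per_type[t] for t in types], dtype=float)
    if emb.n_cells < 2:
        raise ConfigError("iLISI needs >= 2 cells")
    idx = _knn_indices(emb.coords, k_lisi)
    k_eff = idx.shape[1]
    lisi = np.empty(emb.n_cells)
    for i in range(emb.n_cells):
        counts = np.bincount(binv[idx[i]], minlength=len(batches))
        f = counts / k_eff
        lisi[i] = 1.0 / (f**2).sum()
    dev = np.abs(lisi - N) / N
    per_batch = [dev[batch == b].mean() for b in batches]
    return float(np.mean(per_batch))


def batch_kl(
    emb: Embedding,
    batch,
    seed: int = 0,
    k_kl: int = K_KL,
    n_subsample: int = KL_SUBSAMPLE,
) -> float:
    """Mean per-cell KL divergence between local and global batch proportions.

    Evaluated on a seeded subsample of min(n_subsample, n) cells drawn from
    the cell-ID-sorted ordering; zero local proportions contribute nothing
    (0 * log 0 = 0).  Single-batch input returns 0 with a warning.
    """
    batch = np.asarray(batch)
    cats, binv = np.unique(batch, return_inverse=True)
    if len(cats) < 2:
        warnings.warn("BatchKL of a single batch is 0 by convention")
        return 0.0
    q = np.bincount(binv) / len(batch)
    order = np.argsort(np.asarray(emb.cell_ids).astype(str), kind="stable")
    rng = np.random.default_rng(derive_seed(seed, "batchkl-subsample"))
    n_eval = min(n_subsample, emb.n_cells)
    chosen = order[rng.choice(emb.n_cells, size=n_eval, replace=False)]
    idx = _knn_indices(emb.coords, k_kl)
    k_eff = idx.shape[1]
    kls = np.empty(n_eval)
    for pos, i in enumerate(chosen):
        counts = np.bincount(binv[idx[i]], minlength=len(cats))
        p = counts / k_eff
        mask = p > 0
        kls[pos] = (p[mask] * np.log(p[mask] / q[mask])).sum()
    return float(kls.mean())


def biological_conservation(ari_val: float, nmi_val: float, asw_val: float) -> float:
    """Average of ARI, NMI and ASW_celltype."""
    return (ari_val + nmi_val + asw_val) / 3


def batch_mixing(batch_kl_val: float, ilisi_val: float) -> float:
    """((3 - BatchKL)/3 + iLISI/3) / 2, with BatchKL clipped to [0, 3]."""
    clipped = min(max(batch_kl_val, 0.0), 3.0)
    return ((3 - clipped) / 3 + ilisi_val / 3) / 2


def evaluate(
    emb: Embedding,
    batch,
    types,
    pred_labels,
    seed: int = 0,
    k_lisi: int = K_LISI,
    k_kl: int = K_KL,
) -> MetricReport:
    """Compute the full metric report for one embedding + clustering."""
    a = ari(pred_labels, types)
    m = nmi(pred_labels, types)
    s = asw_celltype(emb, types)
    li = ilisi(emb, batch, types, k_lisi=k_lisi)
    kl = batch_kl(emb, batch, seed=seed, k_kl=k_kl)
    return MetricReport(
        ari=a,
        nmi=m,
        asw_celltype=s,
        ilisi=li,
        batch_kl=kl,
        biological_conservation=biological_conservation(a, m, s),
        batch_mixing=batch_mixing(kl, li),
        k_lisi=k_lisi,
        k_kl=k_kl,
    )
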