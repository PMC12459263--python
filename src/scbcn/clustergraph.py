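"""Cross-batch cell clustering.

Stage 1: each batch is clustered independently at high resolution (Leiden
on a shared-nearest-neighbor graph in PCA space, resolution 3.0) to give
fine-grained, batch-pure clusters.  Stage 2: mutual nearest neighbor (MNN)
pairs are found between every batch pair (a <= b, so intra-batch pairs are
included) under cosine distance on the first 10 PCs, expanded for T steps
by deterministic within-batch 1-NN propagation, and aggregated into a
cluster-level similarity graph whose edge weights are MNN-pair counts
normalized by cluster sizes.  Spectral clustering of that graph merges
fine clusters across batches into global groups; each cell inherits the
group of its fine cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .io_core import ConfigError, Embedding, derive_seed

logger = logging.getLogger("scbcn")

Pair = tuple[int, int]


@dataclass
class InitialClusters:
    """Per-cell fine-cluster assignment; IDs carry their batch prefix."""

    assignment: np.ndarray  # per-cell cluster ID strings, "batch|local"
    resolution: float

    @property
    def cluster_ids(self) -> list:
        seen: dict = {}
        for c in self.assignment:
            seen.setdefault(c, None)
        return list(seen)


@dataclass
class MNNPairSet:
    """Unordered cell-index pairs with (batch_a, batch_b, walk step) provenance."""

    pairs: set = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def add(self, i: int, j: int, batches: tuple, step: int) -> bool:
        if i == j:
            return False
        key = (i, j) if i < j else (j, i)
        if key in self.pairs:
            return False
        self.pairs.add(key)
        self.provenance[key] = (*batches, step)
        return True

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: Pair) -> bool:
        i, j = pair
        return ((i, j) if i < j else (j, i)) in self.pairs

    def union(self, other: "MNNPairSet") -> "MNNPairSet":
        out = MNNPairSet(set(self.pairs), dict(self.provenance))
        for p in other.pairs:
            if p not in out.pairs:
                out.pairs.add(p)
                out.provenance[p] = other.provenance[p]
        return out


@dataclass
class ClusterGraph:
    node_ids: list
    weight: np.ndarray  # symmetric nonnegative
    sizes: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.weight, dtype=float)
        if W.shape[0] != W.shape[1] or not np.allclose(W, W.T):
            raise ConfigError("cluster graph weight matrix must be square symmetric")
        if (W < 0).any():
            raise ConfigError("cluster graph weights must be nonnegative")
        self.weight = W


@dataclass
class GlobalClusters:
    assignment: np.ndarray  # per-cell int labels in 0..n_groups-1
    n_groups: int
    cluster_to_group: dict


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def cosine_distances(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """1 - cosine similarity; zero vectors are at distance 1 to everything."""
    An = np.linalg.norm(A, axis=1)
    Bn = np.linalg.norm(B, axis=1)
    Au = np.divide(A, An[:, None], out=np.zeros_like(A, dtype=float), where=An[:, None] > 0)
    Bu = np.divide(B, Bn[:, None], out=np.zeros_like(B, dtype=float), where=Bn[:, None] > 0)
    return 1.0 - Au @ Bu.T


# ---------------------------------------------------------------------------
# Stage 1: per-batch Leiden
# ---------------------------------------------------------------------------

def _snn_graph(X: np.ndarray, k: int, prune: float) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph: Jaccard overlap of k-neighborhoods.

    The neighborhood of a cell is itself plus its k nearest neighbors
    (Euclidean); edges below the prune threshold are dropped.
    """
    n = X.shape[0]
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff).fit(X)
    idx = nn.kneighbors(return_distance=False)  # excludes self
    rows = np.repeat(np.arange(n), k_eff)
    A = sp.csr_matrix((np.ones(n * k_eff), (rows, idx.ravel())), shape=(n, n))
    A = A + sp.eye(n, format="csr")  # neighborhood includes the cell itself
    shared = (A @ A.T).tocoo()
    deg = k_eff + 1
    jac = shared.data / (2 * deg - shared.data)
    keep = (jac >= prune) & (shared.row < shared.col)
    return sp.csr_matrix((jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))


def leiden_per_batch(
    emb: Embedding,
    batch: np.ndarray,
    resolution: float = 3.0,
    seed: int = 0,
    snn_k: int = 15,
    prune: float = 1 / 15,
) -> InitialClusters:
    """High-resolution Leiden clustering, run independently inside each batch."""
    if emb.space != "pca":
        raise ConfigError("leiden_per_batch expects a PCA-space embedding")
    batch = np.asarray(batch, dtype=object)
    assignment = np.empty(emb.n_cells, dtype=object)
    import pandas as pd

    for b in pd.unique(batch):
        cells = np.flatnonzero(batch == b)
        if len(cells) < 2:
            warnings.warn(f"batch {b!r} has < 2 cells; forming one singleton cluster")
            assignment[cells] = f"{b}|0"
            continue
        snn = _snn_graph(emb.coords[cells], k=snn_k, prune=prune)
        coo = snn.tocoo()
        g = igraph.Graph(
            n=len(cells),
            edges=list(zip(coo.row.tolist(), coo.col.tolist())),
            edge_attrs={"weight": coo.data.tolist()},
        )
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=derive_seed(seed, f"leiden:{b}"),
        )
        labels = np.asarray(part.membership)
        for c, lab in zip(cells, labels):
            assignment[c] = f"{b}|{lab}"
    return InitialClusters(assignment=assignment, resolution=resolution)


# ---------------------------------------------------------------------------
# Stage 2a: MNN pairs and random-walk expansion
# ---------------------------------------------------------------------------

def find_mnn_pairs(
    emb: Embedding,
    batch: np.ndarray,
    a,
    b,
    k: int = 10,
    n_pcs_mnn: int = 10,
) -> MNNPairSet:
    """Mutual k-nearest-neighbor pairs between batches a and b (a may equal b).

    Neighborhoods use cosine distance restricted to the first ``n_pcs_mnn``
    embedding coordinates.  For a == b the cell itself is excluded from its
    own neighbor list and each unordered pair is kept once.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    if n_pcs_mnn > emb.dim:
        raise ConfigError("n_pcs_mnn exceeds embedding dimension")
    batch = np.asarray(batch, dtype=object)
    ia = np.flatnonzero(batch == a)
    ib = np.flatnonzero(batch == b)
    out = MNNPairSet()
    same = a == b
    if same and len(ia) < 2:
        return out
    if len(ia) == 0 or len(ib) == 0:
        return out
    X = emb.coords[:, :n_pcs_mnn]
    D = cosine_distances(X[ia], X[ib])
    if same:
        np.fill_diagonal(D, np.inf)
    ka = min(k, D.shape[1] - (1 if same else 0))
    kb = min(k, D.shape[0] - (1 if same else 0))
    # nn_ab[p] = set of positions q in ib that are among ka nearest of ia[p]
    nn_ab = np.argsort(D, axis=1, kind="stable")[:, :ka]
    nn_ba = np.argsort(D.T, axis=1, kind="stable")[:, :kb]
    in_ba = [set(row) for row in nn_ba]
    for p in range(len(ia)):
        for q in nn_ab[p]:
            if p in in_ba[q]:
                out.add(int(ia[p]), int(ib[q]), (a, b), step=0)
    return out


def _within_batch_1nn(
    emb: Embedding, batch: np.ndarray, n_pcs_mnn: int
) -> np.ndarray:
    """Per cell, the index of its nearest within-batch neighbor (cosine), or -1."""
    import pandas as pd

    batch = np.asarray(batch, dtype=object)
    X = emb.coords[:, :n_pcs_mnn]
    nn1 = np.full(emb.n_cells, -1, dtype=int)
    for b in pd.unique(batch):
        cells = np.flatnonzero(batch == b)
        if len(cells) < 2:
            continue
        D = cosine_distances(X[cells], X[cells])
        np.fill_diagonal(D, np.inf)
        nn1[cells] = cells[np.argmin(D, axis=1)]
    return nn1


def random_walk_expand(
    s0: MNNPairSet,
    emb: Embedding,
    batch: np.ndarray,
    T: int = 10,
    n_pcs_mnn: int = 10,
) -> MNNPairSet:
    """Expand an MNN pair set by T steps of within-batch 1-NN propagation.

    At step t every pair (i, j) produced at step t-1 spawns the candidates
    (nn1(i), j) and (i, nn1(j)), where nn1 is the cell's within-batch
    nearest neighbor under cosine distance on the first ``n_pcs_mnn``
    coordinates; candidates that are self-pairs or already present are
    skipped.  The result is the union over steps 0..T.  Propagation stops
    early at a fixed point (no new pairs).  The rule is deterministic
    (argmin ties break by index), so T bounds the propagation radius.
    """
    if T < 0:
        raise ConfigError("T must be >= 0")
    out = MNNPairSet(set(s0.pairs), dict(s0.provenance))
    if T == 0 or len(s0) == 0:
        return out
    batch = np.asarray(batch, dtype=object)
    nn1 = _within_batch_1nn(emb, batch, n_pcs_mnn)
    frontier = list(s0.pairs)
    for t in range(1, T + 1):
        new: list[Pair] = []
        for i, j in frontier:
            for cand in ((int(nn1[i]), j), (i, int(nn1[j]))):
                ci, cj = cand
                if ci < 0 or cj < 0:
                    continue
                if out.add(ci, cj, (batch[ci], batch[cj]), step=t):
                    new.append((ci, cj) if ci < cj else (cj, ci))
        if not new:
            break
        frontier = new
    return out


def find_all_mnn_pairs(
    emb: Embedding,
    batch: np.ndarray,
    k: int = 10,
    T: int = 10,
    n_pcs_mnn: int = 10,
) -> MNNPairSet:
    """MNN pairs over every batch pair a <= b, random-walk expanded."""
    import pandas as pd

    cats = list(pd.unique(np.asarray(batch, dtype=object)))
    s0 = MNNPairSet()
    for ai in range(len(cats)):
        for bi in range(ai, len(cats)):
            s0 = s0.union(
                find_mnn_pairs(emb, batch, cats[ai], cats[bi], k=k, n_pcs_mnn=n_pcs_mnn)
            )
    return random_walk_expand(s0, emb, batch, T=T, n_pcs_mnn=n_pcs_mnn)


# ---------------------------------------------------------------------------
# Stage 2b: cluster graph and spectral partition
# ---------------------------------------------------------------------------

def build_cluster_graph(
    pairs: MNNPairSet, init: InitialClusters, norm: str = "product"
) -> ClusterGraph:
    """Aggregate MNN pairs into a cluster-level similarity graph.

    W[c, d] = (#pairs with one endpoint in c and the other in d) divided by
    |c|*|d| (``norm='product'``, the default pair-capacity normalization) or
    sqrt(|c|*|d|) (``norm='sqrt'``).  Intra-cluster pairs populate the
    diagonal under the same rule.
    """
    node_ids = init.cluster_ids
    index = {c: i for i, c in enumerate(node_ids)}
    m = len(node_ids)
    sizes = np.zeros(m)
    for c in init.assignment:
        sizes[index[c]] += 1
    counts = np.zeros((m, m))
    for i, j in pairs.pairs:
        ci, cj = index[init.assignment[i]], index[init.assignment[j]]
        counts[ci, cj] += 1
        if ci != cj:
            counts[cj, ci] += 1
    denom = np.outer(sizes, sizes)
    if norm == "sqrt":
        denom = np.sqrt(denom)
    elif norm != "product":
        raise ConfigError("norm must be 'product' or 'sqrt'")
    W = counts / denom
    return ClusterGraph(node_ids=node_ids, weight=W, sizes=sizes)


def _eigengap_n_groups(eigvals: np.ndarray, max_groups: int = 20) -> int:
    """Largest gap between consecutive ascending Laplacian eigenvalues."""
    m = len(eigvals)
    upper = min(max_groups, m)
    if upper < 2:
        return 1
    gaps = np.diff(eigvals[:upper])
    return int(np.argmax(gaps)) + 1


def spectral_partition(
    g: ClusterGraph,
    init: InitialClusters,
    n_groups: int | str = "auto",
    seed: int = 0,
) -> GlobalClusters:
    """Partition the cluster graph with normalized spectral clustering.

    Uses the symmetric normalized Laplacian L = I - D^{-1/2} W D^{-1/2};
    with n_groups = "auto" the group count is the position of the largest
    eigengap among the first min(20, n_nodes) ascending eigenvalues, floored
    at the number of connected components.  Node embeddings (row-normalized
    leading eigenvectors) are clustered with seeded k-means, and each cell
    inherits the group of its fine cluster.
    """
    m = len(g.node_ids)
    if m < 1:
        raise ConfigError("cluster graph has no nodes")
    W = g.weight.copy()
    np.fill_diagonal(W, W.diagonal())  # keep intra-cluster weight as self-loop
    n_comp, _ = connected_components(sp.csr_matrix(W > 0), directed=False)
    deg = W.sum(axis=1)
    inv_sqrt = np.divide(1.0, np.sqrt(deg), out=np.zeros_like(deg), where=deg > 0)
    L = np.eye(m) - inv_sqrt[:, None] * W * inv_sqrt[None, :]
    # zero-degree (isolated) nodes: their Laplacian row is e_i with eigenvalue 1;
    # zero it so each isolated node reads as its own zero-eigenvalue component.
    iso = np.flatnonzero(deg == 0)
    for i in iso:
        L[i, i] = 0.0
    eigvals, eigvecs = scipy.linalg.eigh(L)
    if n_groups == "auto":
        k = max(_eigengap_n_groups(eigvals), n_comp)
    else:
        k = int(n_groups)
        if k > m:
            raise ConfigError(f"n_groups={k} exceeds number of clusters ({m})")
        if k < 1:
            raise ConfigError("n_groups must be >= 1")
    if k >= m:
        node_labels = np.arange(m)
        k = m
    elif k == 1:
        node_labels = np.zeros(m, dtype=int)
    else:
        U = eigvecs[:, :k]
        norms = np.linalg.norm(U, axis=1)
        U = np.divide(U, norms[:, None], out=np.zeros_like(U), where=norms[:, None] > 0)
        km = KMeans(n_clusters=k, n_init=10, random_state=derive_seed(seed, "spectral-kmeans"))
        node_labels = km.fit_predict(U)
    cluster_to_group = {c: int(node_labels[i]) for i, c in enumerate(g.node_ids)}
    assignment = np.asarray([cluster_to_group[c] for c in init.assignment], dtype=int)
    return GlobalClusters(
        assignment=assignment,
        n_groups=int(node_labels.max()) + 1,
        cluster_to_group=cluster_to_group,
    )


def cross_batch_cluster(
    emb: Embedding,
    batch: np.ndarray,
    resolution: float = 3.0,
    snn_k: int = 15,
    k: int = 10,
    T: int = 10,
    n_pcs_mnn: int = 10,
    n_groups: int | str = "auto",
    cluster_norm: str = "product",
    seed: int = 0,
) -> tuple[InitialClusters, MNNPairSet, ClusterGraph, GlobalClusters]:
    """Run the full two-stage cross-batch clustering."""
    init = leiden_per_batch(emb, batch, resolution=resolution, seed=seed, snn_k=snn_k)
    pairs = find_all_mnn_pairs(emb, batch, k=k, T=T, n_pcs_mnn=n_pcs_mnn)
    graph = build_cluster_graph(pairs, init, norm=cluster_norm)
    glob = spectral_partition(graph, init, n_groups=n_groups, seed=seed)
    logger.info(
        "cross-batch clustering: %d fine clusters, %d MNN pairs, %d global groups",
        len(graph.node_ids), len(pairs), glob.n_groups,
    )
    return init, pairs, graph, glob
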