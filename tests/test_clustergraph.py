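"""Cross-batch clustering tests with brute-force oracles."""

import itertools

import numpy as np
import pytest

from scbcn.io_core import ConfigError, Embedding
from scbcn.clustergraph import (
    ClusterGraph,
    InitialClusters,
    MNNPairSet,
    build_cluster_graph,
    cosine_distances,
    find_mnn_pairs,
    leiden_per_batch,
    random_walk_expand,
    spectral_partition,
)


def _emb(coords):
    coords = np.asarray(coords, dtype=float)
    return Embedding(coords, [f"c{i}" for i in range(len(coords))], space="pca")


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------

def brute_force_mnn(coords, batch, a, b, k):
    """O(n^2) mutual-kNN under cosine distance via the full distance matrix."""
    from scipy.spatial.distance import cdist

    ia = np.flatnonzero(batch == a)
    ib = np.flatnonzero(batch == b)
    D = cdist(coords[ia], coords[ib], metric="cosine")
    if a == b:
        np.fill_diagonal(D, np.inf)
    pairs = set()
    for p, i in enumerate(ia):
        knn_i = set(ib[np.argsort(D[p])[: min(k, len(ib) - (a == b))]])
        for q, j in enumerate(ib):
            if j not in knn_i:
                continue
            knn_j = set(ia[np.argsort(D[:, q])[: min(k, len(ia) - (a == b))]])
            if i in knn_j:
                pairs.add((min(i, j), max(i, j)))
    return pairs


def brute_force_walk(pairs0, coords, batch, T):
    """Independent re-implementation of the documented 1-NN propagation rule."""
    from scipy.spatial.distance import cdist

    nn1 = {}
    for bb in np.unique(batch):
        cells = np.flatnonzero(batch == bb)
        if len(cells) < 2:
            continue
        D = cdist(coords[cells], coords[cells], metric="cosine")
        np.fill_diagonal(D, np.inf)
        for p, i in enumerate(cells):
            nn1[i] = cells[np.argmin(D[p])]
    current = set(pairs0)
    frontier = set(pairs0)
    for _ in range(T):
        new = set()
        for i, j in frontier:
            for ci, cj in ((nn1.get(i, -1), j), (i, nn1.get(j, -1))):
                if ci < 0 or cj < 0 or ci == cj:
                    continue
                key = (min(ci, cj), max(ci, cj))
                if key not in current:
                    new.add(key)
        if not new:
            break
        current |= new
        frontier = new
    return current


# ---------------------------------------------------------------------------
# MNN pairs
# ---------------------------------------------------------------------------

class TestMNNPairs:
    def test_two_singleton_batches_forced_pair(self, rng):
        emb = _emb(rng.normal(size=(2, 4)))
        s = find_mnn_pairs(emb, np.array(["A", "B"], dtype=object), "A", "B", k=1, n_pcs_mnn=4)
        assert s.pairs == {(0, 1)}

    def test_saturated_neighborhoods_all_cross_pairs(self, rng):
        batch = np.array(["A"] * 3 + ["B"] * 4, dtype=object)
        emb = _emb(rng.normal(size=(7, 5)))
        s = find_mnn_pairs(emb, batch, "A", "B", k=10, n_pcs_mnn=5)
        assert len(s) == 12

    def test_intra_batch_singleton_empty(self, rng):
        batch = np.array(["A", "B", "B"], dtype=object)
        emb = _emb(rng.normal(size=(3, 3)))
        assert len(find_mnn_pairs(emb, batch, "A", "A", k=2, n_pcs_mnn=3)) == 0

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        na, nb = rng.integers(5, 100, size=2)
        d = int(rng.integers(2, 10))
        k = int(rng.integers(1, 11))
        same = trial % 5 == 0
        if same:
            nb = 0
        coords = rng.normal(size=(na + nb, d))
        batch = np.asarray(["A"] * na + ["B"] * nb, dtype=object)
        a, b = ("A", "A") if same else ("A", "B")
        s = find_mnn_pairs(_emb(coords), batch, a, b, k=k, n_pcs_mnn=d)
        assert s.pairs == brute_force_mnn(coords, batch, a, b, k)

    def test_mnn_symmetry_predicate(self, rng):
        # every reported pair satisfies the mutual-kNN predicate, and vice versa
        coords = rng.normal(size=(60, 6))
        batch = np.asarray(["A"] * 30 + ["B"] * 30, dtype=object)
        s = find_mnn_pairs(_emb(coords), batch, "A", "B", k=5, n_pcs_mnn=6)
        assert s.pairs == brute_force_mnn(coords, batch, "A", "B", 5)


class TestRandomWalk:
    def test_T0_identity(self, rng):
        coords = rng.normal(size=(20, 4))
        batch = np.asarray(["A"] * 10 + ["B"] * 10, dtype=object)
        s0 = find_mnn_pairs(_emb(coords), batch, "A", "B", k=3, n_pcs_mnn=4)
        out = random_walk_expand(s0, _emb(coords), batch, T=0, n_pcs_mnn=4)
        assert out.pairs == s0.pairs

    def test_chain_cell_gains_pair_after_one_step(self):
        # batch A: a0 (angle 0.1), a1 (angle 0.25); batch B: b0 (angle 0)
        # k=1 gives S0={(a0,b0)}; a1 is a0's within-batch 1-NN -> paired at t=1
        ang = np.array([0.1, 0.25, 0.0])
        coords = np.column_stack([np.cos(ang), np.sin(ang)])
        batch = np.asarray(["A", "A", "B"], dtype=object)
        s0 = find_mnn_pairs(_emb(coords), batch, "A", "B", k=1, n_pcs_mnn=2)
        assert s0.pairs == {(0, 2)}
        out = random_walk_expand(s0, _emb(coords), batch, T=1, n_pcs_mnn=2)
        assert (1, 2) in out
        assert out.provenance[(1, 2)][2] == 1  # produced at step 1

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_transition_rule(self, trial):
        rng = np.random.default_rng(2000 + trial)
        n = int(rng.integers(10, 60))
        coords = rng.normal(size=(n, 5))
        batch = rng.choice(np.asarray(["A", "B", "C"], dtype=object), size=n)
        T = int(rng.integers(0, 6))
        s0 = MNNPairSet()
        for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
            s0 = s0.union(find_mnn_pairs(_emb(coords), batch, a, b, k=3, n_pcs_mnn=5))
        out = random_walk_expand(s0, _emb(coords), batch, T=T, n_pcs_mnn=5)
        assert out.pairs == brute_force_walk(s0.pairs, coords, batch, T)

    def test_monotone_in_T(self, rng):
        coords = rng.normal(size=(40, 4))
        batch = np.asarray(["A"] * 20 + ["B"] * 20, dtype=object)
        s0 = find_mnn_pairs(_emb(coords), batch, "A", "B", k=2, n_pcs_mnn=4)
        prev = set()
        for T in range(6):
            cur = random_walk_expand(s0, _emb(coords), batch, T=T, n_pcs_mnn=4).pairs
            assert prev <= cur
            prev = cur
        assert s0.pairs <= prev


# ---------------------------------------------------------------------------
# Cluster graph
# ---------------------------------------------------------------------------

def _init(assignment):
    return InitialClusters(np.asarray(assignment, dtype=object), resolution=3.0)


class TestClusterGraph:
    def test_empty_pair_set_zero_weights(self):
        g = build_cluster_graph(MNNPairSet(), _init(["A|0", "A|0", "B|0"]))
        assert np.all(g.weight == 0)

    def test_hand_counted_normalization(self):
        # cluster c = {0,1,2} (3 cells), d = {3,4} (2 cells), 4 linking pairs
        init = _init(["c", "c", "c", "d", "d"])
        pairs = MNNPairSet()
        for i, j in [(0, 3), (0, 4), (1, 3), (2, 4)]:
            pairs.add(i, j, ("A", "B"), 0)
        g = build_cluster_graph(pairs, init)
        ci, di = g.node_ids.index("c"), g.node_ids.index("d")
        assert g.weight[ci, di] == pytest.approx(4 / 6)
        np.testing.assert_array_equal(g.weight, g.weight.T)

    def test_sqrt_normalization_option(self):
        init = _init(["c", "c", "c", "d", "d"])
        pairs = MNNPairSet()
        pairs.add(0, 3, ("A", "B"), 0)
        g = build_cluster_graph(pairs, init, norm="sqrt")
        ci, di = g.node_ids.index("c"), g.node_ids.index("d")
        assert g.weight[ci, di] == pytest.approx(1 / np.sqrt(6))

    def test_relabeling_equivariance(self, rng):
        cells = 30
        assignment = rng.choice(np.asarray(["x", "y", "z"], dtype=object), size=cells)
        pairs = MNNPairSet()
        for _ in range(40):
            i, j = rng.choice(cells, 2, replace=False)
            pairs.add(int(i), int(j), ("A", "A"), 0)
        g1 = build_cluster_graph(pairs, _init(assignment))
        renamed = np.asarray([{"x": "q1", "y": "q2", "z": "q3"}[c] for c in assignment], dtype=object)
        g2 = build_cluster_graph(pairs, _init(renamed))
        perm = [g2.node_ids.index({"x": "q1", "y": "q2", "z": "q3"}[c]) for c in g1.node_ids]
        np.testing.assert_allclose(g1.weight, g2.weight[np.ix_(perm, perm)])


# ---------------------------------------------------------------------------
# Spectral partition
# ---------------------------------------------------------------------------

def exhaustive_best_partition(W, n_groups):
    """Maximize total within-group weight over all partitions (<= 8 nodes)."""
    n = W.shape[0]
    best, best_score = None, -np.inf
    for labels in itertools.product(range(n_groups), repeat=n):
        if len(set(labels)) != n_groups:
            continue
        score = sum(
            W[i, j] for i in range(n) for j in range(i + 1, n) if labels[i] == labels[j]
        )
        if score > best_score:
            best_score, best = score, labels
    return np.asarray(best)


class TestSpectralPartition:
    def _graph(self, W, names=None):
        W = np.asarray(W, dtype=float)
        names = names or [f"n{i}" for i in range(len(W))]
        sizes = np.ones(len(W))
        return ClusterGraph(node_ids=names, weight=W, sizes=sizes), names

    def test_two_disconnected_cliques_recovered(self):
        W = np.zeros((6, 6))
        W[:3, :3] = 1.0
        W[3:, 3:] = 1.0
        np.fill_diagonal(W, 0)
        g, names = self._graph(W)
        init = _init(names)  # one cell per node
        out = spectral_partition(g, init, n_groups=2, seed=0)
        assert len(set(out.assignment[:3])) == 1
        assert len(set(out.assignment[3:])) == 1
        assert out.assignment[0] != out.assignment[3]

    def test_identity_partition(self):
        W = np.ones((4, 4)) - np.eye(4)
        g, names = self._graph(W)
        out = spectral_partition(g, _init(names), n_groups=4, seed=0)
        assert len(set(out.assignment)) == 4

    def test_planted_blocks_match_exhaustive_oracle(self, rng):
        sizes = [3, 3, 2]
        n = sum(sizes)
        labels_true = np.repeat(np.arange(3), sizes)
        W = np.where(labels_true[:, None] == labels_true[None, :], 1.0, 0.01)
        W += rng.normal(0, 1e-3, W.shape)
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        W = np.abs(W)
        g, names = self._graph(W)
        out = spectral_partition(g, _init(names), n_groups=3, seed=0)
        oracle = exhaustive_best_partition(W, 3)
        from scbcn.metrics import ari

        assert ari(out.assignment, oracle) == pytest.approx(1.0)

    def test_auto_eigengap_finds_block_count(self):
        labels_true = np.repeat(np.arange(3), [4, 4, 4])
        W = np.where(labels_true[:, None] == labels_true[None, :], 1.0, 0.02)
        np.fill_diagonal(W, 0)
        g, names = self._graph(W)
        out = spectral_partition(g, _init(names), n_groups="auto", seed=0)
        assert out.n_groups == 3

    def test_too_many_groups_errors(self):
        g, names = self._graph(np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ConfigError):
            spectral_partition(g, _init(names), n_groups=5, seed=0)


# ---------------------------------------------------------------------------
# Leiden
# ---------------------------------------------------------------------------

class TestLeiden:
    def test_separated_blobs_pure_clusters(self, rng):
        centers = np.array([[0, 0], [30, 0], [0, 30]])
        blobs, batches, truth = [], [], []
        for b in ("A", "B"):
            for t, c in enumerate(centers):
                blobs.append(c + rng.normal(0, 0.5, size=(40, 2)))
                batches += [b] * 40
                truth += [t] * 40
        emb = _emb(np.vstack(blobs))
        batch = np.asarray(batches, dtype=object)
        init = leiden_per_batch(emb, batch, resolution=3.0, seed=0)
        truth = np.asarray(truth)
        for b in ("A", "B"):
            mask = batch == b
            assert len(set(init.assignment[mask])) >= 3
        # merge-coarsened clustering (majority true label per fine cluster)
        from scbcn.metrics import ari

        coarse = np.empty(len(truth), dtype=int)
        for c in set(init.assignment):
            m = init.assignment == c
            coarse[m] = np.bincount(truth[m]).argmax()
        assert ari(coarse, truth) == pytest.approx(1.0)

    def test_clusters_are_batch_pure(self, rng):
        emb = _emb(rng.normal(size=(60, 5)))
        batch = np.asarray(["A"] * 30 + ["B"] * 30, dtype=object)
        init = leiden_per_batch(emb, batch, seed=0)
        for c in set(init.assignment):
            members = batch[init.assignment == c]
            assert len(set(members)) == 1

    def test_identical_points_single_cluster_at_unit_resolution(self):
        # at resolution > 1 the RB quality degenerates to singletons on a
        # uniform complete graph, so "no structure" is probed at gamma = 1
        emb = _emb(np.ones((20, 4)))
        init = leiden_per_batch(emb, np.repeat("A", 20), resolution=1.0, seed=0)
        assert len(set(init.assignment)) == 1

    def test_tiny_batch_becomes_singleton_with_warning(self, rng):
        emb = _emb(rng.normal(size=(11, 3)))
        batch = np.asarray(["A"] * 10 + ["B"], dtype=object)
        with pytest.warns(UserWarning, match="singleton"):
            init = leiden_per_batch(emb, batch, seed=0)
        assert init.assignment[10] == "B|0"


class TestCosineDistance:
    def test_zero_vector_distance_one(self):
        A = np.array([[0.0, 0.0], [1.0, 0.0]])
        D = cosine_distances(A, A)
        assert D[0, 1] == pytest.approx(1.0)
        assert D[1, 1] == pytest.approx(0.0, abs=1e-12)
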