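"""Batch-correction network: residual MLP trained with a Tuplet Margin Loss.

The network maps the 100-dimensional PCA coordinates of each cell to a
low-dimensional batch-corrected embedding.  Architecture: two stacked
residual blocks, each made of five layers — FC(d->d), batch-norm, PReLU,
FC(d->d), batch-norm — with an identity skip connection added after the
second batch-norm, followed by one linear projection to ``embed_dim``.

Training minimizes the tuplet margin loss

    L = log(1 + sum_i exp(d(x_a, x_p) - d(x_a, x_{n_i})))

over sampled tuples (anchor, positive with the same global cluster label,
k-1 negatives with different labels), where d is Euclidean distance in the
output space.  Cells sharing a global cluster are pulled together —
including across batches, which is what removes the batch effect — while
different clusters are pushed apart.  Optimization is plain mini-batch SGD
with momentum.

Everything here is numpy with hand-written forward/backward passes so the
package has no deep-learning framework dependency; a finite-difference
gradient check in the test suite validates the backprop.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_core import ConfigError, Embedding, RunConfig, derive_seed

logger = logging.getLogger("scbcn")

_DIST_EPS = 1e-12  # guards d/dx of sqrt at coincident points


# ---------------------------------------------------------------------------
# Layers (numpy, manual backprop)
# ---------------------------------------------------------------------------

class _Linear:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.W = rng.normal(0.0, math.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [("W", self.W, lambda: self.gW), ("b", self.b, lambda: self.gb)]


class _BatchNorm:
    """Standard batch normalization: batch statistics while training,
    exponential running averages at inference."""

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(d)
        self.beta = np.zeros(d)
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        return self.gamma * self._xhat + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        n = g.shape[0]
        self.ggamma = (g * xhat).sum(axis=0)
        self.gbeta = g.sum(axis=0)
        dxhat = g * self.gamma
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )

    def params(self):
        return [
            ("gamma", self.gamma, lambda: self.ggamma),
            ("beta", self.beta, lambda: self.gbeta),
        ]


class _PReLU:
    def __init__(self, init: float = 0.25):
        self.alpha = np.array([init])

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return np.where(x > 0, x, self.alpha[0] * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        self.galpha = np.array([(g * np.where(x > 0, 0.0, x)).sum()])
        return g * np.where(x > 0, 1.0, self.alpha[0])

    def params(self):
        return [("alpha", self.alpha, lambda: self.galpha)]


class _ResidualBlock:
    """FC -> BN -> PReLU -> FC -> BN, identity skip added after the last BN."""

    def __init__(self, rng: np.random.Generator, d: int):
        self.layers = [_Linear(rng, d, d), _BatchNorm(d), _PReLU(), _Linear(rng, d, d), _BatchNorm(d)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h, train)
        return x + h

    def backward(self, g: np.ndarray) -> np.ndarray:
        h = g
        for layer in reversed(self.layers):
            h = layer.backward(h)
        return g + h

    def params(self):
        return [
            (f"l{i}.{n}", p, g)
            for i, layer in enumerate(self.layers)
            for n, p, g in layer.params()
        ]


@dataclass
class NetworkSpec:
    """Architecture hyperparameters; parameter count is deterministic given dims."""

    input_dim: int = 100
    embed_dim: int = 32
    n_blocks: int = 2

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.embed_dim < 1 or self.n_blocks < 1:
            raise ConfigError("network dimensions must be positive")


class BatchCorrectionNet:
    def __init__(self, spec: NetworkSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.blocks = [_ResidualBlock(rng, spec.input_dim) for _ in range(spec.n_blocks)]
        self.proj = _Linear(rng, spec.input_dim, spec.embed_dim)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.spec.input_dim:
            raise ConfigError(
                f"input dim {x.shape[1]} != network input_dim {self.spec.input_dim}"
            )
        h = x
        for blk in self.blocks:
            h = blk.forward(h, train)
        return self.proj.forward(h, train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        h = self.proj.backward(g)
        for blk in reversed(self.blocks):
            h = blk.backward(h)
        return h

    def params(self):
        out = []
        for i, blk in enumerate(self.blocks):
            out += [(f"block{i}.{n}", p, g) for n, p, g in blk.params()]
        out += [(f"proj.{n}", p, g) for n, p, g in self.proj.params()]
        return out

    def n_params(self) -> int:
        return sum(p.size for _, p, _ in self.params())


# ---------------------------------------------------------------------------
# Tuplet margin loss
# ---------------------------------------------------------------------------

def tuplet_margin_loss(d_ap: float, d_an) -> float:
    """log(1 + sum_i exp(d_ap - d_an_i)), overflow-safe.

    ``d_ap`` is the anchor-positive Euclidean distance, ``d_an`` the
    anchor-negative distances.  Equals log(k_tuple) when every distance is
    equal and tends to 0+ as the negatives move infinitely far away.
    """
    d_an = np.asarray(d_an, dtype=float)
    if d_an.size == 0:
        raise ConfigError("tuplet margin loss needs at least one negative")
    s = float(d_ap) - d_an
    m = float(np.max(s))
    if m <= 0:
        # log1p keeps the result strictly positive even when exp(s) underflows
        return math.log1p(np.exp(s).sum())
    return m + math.log(math.exp(-m) + np.exp(s - m).sum())


def _batched_loss_and_grads(
    za: np.ndarray, zp: np.ndarray, zn: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Mean tuplet loss over B anchors plus gradients w.r.t. the embeddings.

    za, zp: (B, d); zn: (B, k-1, d).  Distances carry a tiny epsilon inside
    the square root so the gradient stays defined at coincident points.
    """
    diff_ap = za - zp                                      # (B, d)
    d_ap = np.sqrt((diff_ap**2).sum(axis=1) + _DIST_EPS)   # (B,)
    diff_an = za[:, None, :] - zn                          # (B, k-1, d)
    d_an = np.sqrt((diff_an**2).sum(axis=2) + _DIST_EPS)   # (B, k-1)

    s = d_ap[:, None] - d_an
    m = np.maximum(0.0, s.max(axis=1))
    lse = m + np.log(np.exp(-m) + np.exp(s - m[:, None]).sum(axis=1))
    loss = float(lse.mean())

    B = za.shape[0]
    w = np.exp(s - lse[:, None]) / B        # dL/ds_i, mean over anchors
    g_dap = w.sum(axis=1)                   # (B,)
    g_dan = -w                              # (B, k-1)

    u_ap = diff_ap / d_ap[:, None]
    u_an = diff_an / d_an[:, :, None]
    g_za = g_dap[:, None] * u_ap + (g_dan[:, :, None] * u_an).sum(axis=1)
    g_zp = -g_dap[:, None] * u_ap
    g_zn = -g_dan[:, :, None] * u_an
    return loss, g_za, g_zp, g_zn


# ---------------------------------------------------------------------------
# Tuplet sampling
# ---------------------------------------------------------------------------

@dataclass
class TupletBatch:
    """Index arrays into the cell axis: anchors (B,), positives (B,),
    negatives (B, k_tuple-1)."""

    anchors: np.ndarray
    positives: np.ndarray
    negatives: np.ndarray


def sample_tuplets(labels: np.ndarray, batch_size: int, k_tuple: int, seed: int):
    """Endless, seeded stream of class-balanced tuplet mini-batches.

    Each tuple draws its anchor label uniformly over the labels with >= 2
    members, the anchor and positive uniformly (without coincidence) inside
    that label, and its k_tuple - 1 negatives one per distinct other label
    (labels reused with replacement only when fewer than k_tuple - 1 other
    labels exist).  Raises when fewer than two labels exist, since the loss
    is undefined without negatives.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ConfigError(
            "training needs >= 2 global clusters (tuplet loss has no negatives otherwise)"
        )
    if k_tuple < 2:
        raise ConfigError("k_tuple must be >= 2 (one positive plus >= 1 negative)")
    members = {l: np.flatnonzero(labels == l) for l in uniq}
    anchor_labels = [l for l in uniq if len(members[l]) >= 2]
    if not anchor_labels:
        raise ConfigError("no cluster has >= 2 members; cannot form anchor-positive pairs")
    rng = np.random.default_rng(seed)
    n_neg = k_tuple - 1
    label_pos = {l: i for i, l in enumerate(uniq)}
    while True:
        anchors = np.empty(batch_size, dtype=int)
        positives = np.empty(batch_size, dtype=int)
        negatives = np.empty((batch_size, n_neg), dtype=int)
        for t in range(batch_size):
            la = anchor_labels[rng.integers(len(anchor_labels))]
            pool = members[la]
            a, p = rng.choice(len(pool), size=2, replace=False)
            anchors[t], positives[t] = pool[a], pool[p]
            others = [l for l in uniq if l != la]
            if n_neg <= len(others):
                neg_labels = rng.choice(len(others), size=n_neg, replace=False)
            else:
                neg_labels = rng.integers(len(others), size=n_neg)
            for q, li in enumerate(neg_labels):
                neg_pool = members[others[li]]
                negatives[t, q] = neg_pool[rng.integers(len(neg_pool))]
        yield TupletBatch(anchors, positives, negatives)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    net: BatchCorrectionNet
    loss_history: list = field(default_factory=list)


def train(
    emb: Embedding,
    labels: np.ndarray,
    spec: NetworkSpec | None = None,
    cfg: RunConfig | None = None,
) -> TrainedModel:
    """Fit the batch-correction network on PCA coordinates + global labels.

    Mini-batch SGD with momentum on the tuplet margin loss; the loss
    trajectory (mean loss per epoch) is recorded.  Deterministic for a
    fixed ``cfg.rng_seed``.  With ``cfg.epochs == 0`` the returned model is
    its seeded initialization.
    """
    cfg = cfg or RunConfig()
    if spec is None:
        spec = NetworkSpec(input_dim=emb.dim, embed_dim=cfg.embed_dim)
    labels = np.asarray(labels)
    if len(labels) != emb.n_cells:
        raise ConfigError("labels must cover all cells")
    if not np.all(np.isfinite(emb.coords)):
        raise ConfigError("embedding must be finite")
    net = BatchCorrectionNet(spec, seed=derive_seed(cfg.rng_seed, "net-init"))
    model = TrainedModel(net=net)
    if cfg.epochs == 0:
        return model
    sampler = sample_tuplets(
        labels, cfg.batch_size, cfg.k_tuple, seed=derive_seed(cfg.rng_seed, "tuplets")
    )
    velocity = {name: np.zeros_like(p) for name, p, _ in net.params()}
    X = emb.coords
    steps_per_epoch = max(1, math.ceil(emb.n_cells / cfg.batch_size))
    for epoch in range(cfg.epochs):
        epoch_loss = 0.0
        for step in range(steps_per_epoch):
            tb = next(sampler)
            B, n_neg = tb.negatives.shape
            rows = np.concatenate([tb.anchors, tb.positives, tb.negatives.ravel()])
            Z = net.forward(X[rows], train=True)
            za, zp = Z[:B], Z[B : 2 * B]
            zn = Z[2 * B :].reshape(B, n_neg, -1)
            loss, g_za, g_zp, g_zn = _batched_loss_and_grads(za, zp, zn)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {step}"
                )
            g = np.concatenate([g_za, g_zp, g_zn.reshape(B * n_neg, -1)])
            net.backward(g)
            for name, p, grad in net.params():
                v = velocity[name]
                v *= cfg.momentum
                v += grad()
                p -= cfg.learning_rate * v
            epoch_loss += loss
        model.loss_history.append(epoch_loss / steps_per_epoch)
    logger.info(
        "trained %d params, %d epochs; loss %.4f -> %.4f",
        net.n_params(), cfg.epochs, model.loss_history[0], model.loss_history[-1],
    )
    return model


def embed(model: TrainedModel, emb: Embedding) -> Embedding:
    """Inference-mode forward pass; returns the corrected embedding."""
    coords = model.net.forward(emb.coords, train=False)
    return Embedding(coords=coords, cell_ids=emb.cell_ids, space="corrected")
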