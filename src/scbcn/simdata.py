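"""Splatter-style simulation of multi-batch, multi-type scRNA-seq counts.

Generative recipe (all draws from a single seeded generator, in this order):

1. Base gene means  mu_g ~ Gamma(shape=mean_shape, rate=mean_rate).
2. Type DE factors: independently per (type t, gene g), with probability
   ``de_prob`` the gene is differentially expressed in t and receives a
   multiplicative factor exp(s * x), x ~ Normal(de_facLoc, de_facScale),
   s = +1 or -1 with equal probability (down-regulation = reciprocal
   factor); otherwise the factor is 1.
3. Batch factors: per (batch b, gene g) a factor exp(s * x),
   x ~ Normal(batch_facLoc, batch_facScale), s = +-1 equiprobable, applied
   to every gene (batch effects are genome-wide, unlike DE).
4. Cells: each batch b draws its type labels i.i.d. from that batch's
   ``type_proportions`` row and a library size L_c ~ LogNormal(lib_loc,
   lib_scale).
5. Counts: the cell's gene weights w_g = mu_g * de[t_c, g] * batch[b_c, g]
   are normalized to sum 1, giving expected counts m_cg = L_c * w_g /
   sum(w); biological noise enters as a Gamma-Poisson mixture with
   coefficient of variation ``bcv``: lambda ~ Gamma(1/bcv^2, scale =
   m * bcv^2), count ~ Poisson(lambda), i.e. a negative binomial with mean
   m and dispersion bcv^2.

This emulates the structure of Splatter output (gamma gene means,
multiplicative DE and batch factors, lognormal library sizes, NB counts)
without outlier genes, dropout or trajectory paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import ConfigError, Dataset


@dataclass
class SimParams:
    """Parameters of the count generator; defaults give a mid-sized
    clearly-structured dataset."""

    n_cells: int = 1000
    n_genes: int = 1000
    n_types: int = 4
    n_batches: int = 2
    type_proportions: np.ndarray | None = None  # (n_batches, n_types); default uniform
    de_prob: float = 0.1
    de_facLoc: float = 1.0
    de_facScale: float = 0.4
    batch_facLoc: float = 0.1
    batch_facScale: float = 0.1
    lib_loc: float = 9.0
    lib_scale: float = 0.25
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    bcv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ConfigError("need at least 2 cell types")
        if self.n_batches < 1:
            raise ConfigError("need at least 1 batch")
        for name in ("de_facScale", "batch_facScale", "lib_scale", "mean_shape",
                     "mean_rate", "bcv", "lib_loc"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0 <= self.de_prob <= 1):
            raise ConfigError("de_prob must be in [0, 1]")
        if self.type_proportions is None:
            self.type_proportions = np.full(
                (self.n_batches, self.n_types), 1.0 / self.n_types
            )
        else:
            self.type_proportions = np.asarray(self.type_proportions, dtype=float)
            if self.type_proportions.shape != (self.n_batches, self.n_types):
                raise ConfigError("type_proportions must be (n_batches, n_types)")
            if not np.allclose(self.type_proportions.sum(axis=1), 1.0):
                raise ConfigError("type_proportions rows must sum to 1")


def _signed_lognormal(rng, loc, scale, size) -> np.ndarray:
    """exp(s * N(loc, scale)) with s = +-1 equiprobable."""
    x = rng.normal(loc, scale, size=size)
    s = rng.choice([-1.0, 1.0], size=size)
    return np.exp(s * x)


def _exact_type_counts(nb: int, props: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment: per-type counts matching props exactly."""
    raw = props * nb
    counts = np.floor(raw).astype(int)
    short = nb - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def simulate_counts(p: SimParams, return_truth: bool = False):
    """Draw a multi-batch, multi-type count Dataset under the documented recipe.

    With ``return_truth=True`` also returns the generative ground truth
    (base gene means, DE factor matrix, batch factor matrix, library sizes)
    for construction checks.
    """
    rng = np.random.default_rng(p.seed)
    mu = rng.gamma(shape=p.mean_shape, scale=1.0 / p.mean_rate, size=p.n_genes)
    mu = np.maximum(mu, 1e-8)

    de_mask = rng.random((p.n_types, p.n_genes)) < p.de_prob
    de_factors = np.ones((p.n_types, p.n_genes))
    de_factors[de_mask] = _signed_lognormal(
        rng, p.de_facLoc, p.de_facScale, int(de_mask.sum())
    )

    if p.batch_facLoc > 0:
        batch_factors = _signed_lognormal(
            rng, p.batch_facLoc, p.batch_facScale, (p.n_batches, p.n_genes)
        )
    else:
        batch_factors = np.ones((p.n_batches, p.n_genes))

    # cells split as evenly as possible across batches
    per_batch = np.full(p.n_batches, p.n_cells // p.n_batches)
    per_batch[: p.n_cells % p.n_batches] += 1

    batch_labels, type_labels, rows, libs = [], [], [], []
    for b in range(p.n_batches):
        nb = int(per_batch[b])
        # exact per-batch composition, shuffled so types interleave in order
        t = np.repeat(np.arange(p.n_types), _exact_type_counts(nb, p.type_proportions[b]))
        t = rng.permutation(t)
        lib = rng.lognormal(mean=p.lib_loc, sigma=p.lib_scale, size=nb)
        w = mu[None, :] * de_factors[t] * batch_factors[b][None, :]
        m = lib[:, None] * w / w.sum(axis=1, keepdims=True)
        shape = 1.0 / p.bcv**2
        lam = rng.gamma(shape=shape, scale=m / shape)
        rows.append(rng.poisson(lam).astype(float))
        batch_labels.append(np.repeat(f"batch{b}", nb))
        type_labels.append(np.char.add("type", t.astype(str)))
        libs.append(lib)
    X = np.vstack(rows)
    ds = Dataset(
        matrix=X,
        cell_ids=np.asarray([f"cell{i}" for i in range(p.n_cells)], dtype=object),
        gene_ids=np.asarray([f"gene{g}" for g in range(p.n_genes)], dtype=object),
        batch=np.concatenate(batch_labels),
        type_label=np.concatenate(type_labels),
    )
    if return_truth:
        truth = {
            "gene_means": mu,
            "de_factors": de_factors,
            "batch_factors": batch_factors,
            "library_sizes": np.concatenate(libs),
        }
        return ds, truth
    return ds


#: Frozen parameters of the four-type, three-batch acceptance fixture:
#: 168 cells per type per batch (2016 cells), 2000 genes, strong type
#: separation (10% DE genes at ~e^1-fold) and a moderate genome-wide batch
#: effect that separates batches in raw PCA.
DATASET1_PARAMS = dict(
    n_cells=2016,
    n_genes=2000,
    n_types=4,
    n_batches=3,
    de_prob=0.1,
    de_facLoc=1.0,
    de_facScale=0.4,
    batch_facLoc=0.15,
    batch_facScale=0.15,
    lib_loc=9.0,
    lib_scale=0.25,
    mean_shape=0.6,
    mean_rate=0.3,
    bcv=0.1,
)


def make_dataset1_analog(seed: int = 0, **overrides) -> Dataset:
    """The frozen 4-type x 3-batch simulation used by the acceptance suite."""
    params = {**DATASET1_PARAMS, **overrides}
    return simulate_counts(SimParams(seed=seed, **params))
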