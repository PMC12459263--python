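"""Shared fixtures.

``dataset1_runs`` is the expensive one: it runs the full pipeline on the
frozen four-type / three-batch simulation for five seeds and is shared by
the acceptance tests and the end-to-end property tests.
"""

import warnings

import numpy as np
import pytest

import scbcn
from scbcn import metrics
from scbcn.clustergraph import leiden_per_batch
from scbcn.pipeline import run_pipeline


@pytest.fixture(scope="session")
def dataset1_runs():
    """Full-pipeline results on the dataset1 analog for seeds 0..4.

    Each entry carries the corrected-embedding metric report plus the
    raw-PCA reference values (ASW_celltype, BatchKL, and the metric report
    of a plain Leiden clustering of the raw PCA space).
    """
    runs = []
    for seed in range(5):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = scbcn.make_dataset1_analog(seed=seed)
            res = run_pipeline(ds, scbcn.RunConfig(rng_seed=seed))
            raw_labels = leiden_per_batch(
                res.pca, np.repeat("all", res.pca.n_cells), resolution=3.0, seed=seed
            ).assignment
            raw_report = metrics.evaluate(
                res.pca, ds.batch, ds.type_label, raw_labels, seed=seed
            )
        runs.append(
            {
                "seed": seed,
                "dataset": ds,
                "result": res,
                "report": res.report,
                "raw_asw": raw_report.asw_celltype,
                "raw_kl": raw_report.batch_kl,
                "raw_report": raw_report,
            }
        )
    return runs


@pytest.fixture(scope="session")
def small_sim():
    """A small 2-batch / 3-type simulation for fast pipeline tests."""
    return scbcn.simulate_counts(
        scbcn.SimParams(n_cells=360, n_genes=300, n_types=3, n_batches=2, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
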