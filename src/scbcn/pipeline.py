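"""One-call orchestration: preprocess -> cluster -> integrate -> evaluate.

Each stage writes its artifact into a run directory (when one is given)
and is skipped on re-run if the artifact already exists, so deleting a
downstream file and re-running regenerates it from the cached upstream
artifacts.  The effective configuration is serialized next to them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import clustergraph, metrics, model
from .io_core import ConfigError, Dataset, Embedding, RunConfig
from .preprocess import preprocess as _preprocess_workflow

logger = logging.getLogger("scbcn")

STAGES = ("preprocess", "cluster", "integrate", "evaluate")


@dataclass
class PipelineResult:
    pca: Embedding
    global_clusters: np.ndarray
    corrected: Embedding
    report: Optional[metrics.MetricReport]
    n_groups: int


def _save_embedding(emb: Embedding, path: Path) -> None:
    df = pd.DataFrame(
        emb.coords,
        index=pd.Index(emb.cell_ids.astype(str), name="cell_id"),
        columns=[f"dim{i}" for i in range(emb.dim)],
    )
    df.to_csv(path)


def _load_embedding(path: Path, space: str) -> Embedding:
    df = pd.read_csv(path, index_col=0)
    return Embedding(df.to_numpy(dtype=float), np.asarray(df.index, dtype=object), space=space)


def run_pipeline(
    ds: Dataset,
    cfg: RunConfig | None = None,
    outdir=None,
    until: str = "evaluate",
) -> PipelineResult:
    """Run the pipeline on a loaded Dataset.

    ``until`` stops after the named stage ("preprocess", "cluster",
    "integrate" or "evaluate").  The metric report is produced only when
    the dataset carries true type labels.
    """
    cfg = cfg or RunConfig()
    if until not in STAGES:
        raise ConfigError(f"unknown stage {until!r}")
    last = STAGES.index(until)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(
            json.dumps(dataclasses.asdict(cfg), indent=2, default=str) + "\n"
        )

    def stage_path(name: str) -> Optional[Path]:
        return None if out is None else out / name

    # -- preprocess --------------------------------------------------------
    t0 = time.perf_counter()
    pca_file = stage_path("pca.csv")
    if pca_file is not None and pca_file.exists():
        pca = _load_embedding(pca_file, "pca")
        logger.info("preprocess: loaded cached %s", pca_file)
    else:
        _, pca = _preprocess_workflow(
            ds, n_hvg=cfg.n_hvg, n_pcs=cfg.n_pcs_global, seed=cfg.rng_seed
        )
        if pca_file is not None:
            _save_embedding(pca, pca_file)
    batch = ds.batch[np.isin(ds.cell_ids, pca.cell_ids)]
    types = (
        ds.type_label[np.isin(ds.cell_ids, pca.cell_ids)]
        if ds.type_label is not None
        else None
    )
    logger.info("stage preprocess done in %.1fs", time.perf_counter() - t0)
    if last == 0:
        return PipelineResult(pca, None, None, None, 0)

    # -- cluster -----------------------------------------------------------
    t0 = time.perf_counter()
    clusters_file = stage_path("clusters.csv")
    if clusters_file is not None and clusters_file.exists():
        cdf = pd.read_csv(clusters_file, index_col=0)
        global_labels = cdf["global_cluster"].to_numpy()
        n_groups = int(global_labels.max()) + 1
        logger.info("cluster: loaded cached %s", clusters_file)
    else:
        init, pairs, graph, glob = clustergraph.cross_batch_cluster(
            pca,
            batch,
            resolution=cfg.leiden_resolution,
            snn_k=cfg.snn_k,
            k=cfg.knn_k,
            T=cfg.walk_steps,
            n_pcs_mnn=cfg.n_pcs_mnn,
            n_groups=cfg.n_spectral_groups,
            cluster_norm=cfg.cluster_norm,
            seed=cfg.rng_seed,
        )
        global_labels, n_groups = glob.assignment, glob.n_groups
        if clusters_file is not None:
            pd.DataFrame(
                {"initial_cluster": init.assignment, "global_cluster": global_labels},
                index=pd.Index(pca.cell_ids.astype(str), name="cell_id"),
            ).to_csv(clusters_file)
            edges = [
                (graph.node_ids[i], graph.node_ids[j], graph.weight[i, j])
                for i in range(len(graph.node_ids))
                for j in range(i, len(graph.node_ids))
                if graph.weight[i, j] > 0
            ]
            pd.DataFrame(edges, columns=["cluster_a", "cluster_b", "weight"]).to_csv(
                stage_path("cluster_graph.csv"), index=False
            )
    logger.info("stage cluster done in %.1fs", time.perf_counter() - t0)
    if last == 1:
        return PipelineResult(pca, global_labels, None, None, n_groups)

    # -- integrate ---------------------------------------------------------
    t0 = time.perf_counter()
    corrected_file = stage_path("corrected.csv")
    if corrected_file is not None and corrected_file.exists():
        corrected = _load_embedding(corrected_file, "corrected")
        logger.info("integrate: loaded cached %s", corrected_file)
    else:
        spec = model.NetworkSpec(input_dim=pca.dim, embed_dim=cfg.embed_dim)
        trained = model.train(pca, global_labels, spec=spec, cfg=cfg)
        corrected = model.embed(trained, pca)
        if corrected_file is not None:
            _save_embedding(corrected, corrected_file)
    logger.info("stage integrate done in %.1fs", time.perf_counter() - t0)
    if last == 2 or types is None:
        if last == 3 and types is None:
            logger.warning("no true type labels: skipping metric report")
        return PipelineResult(pca, global_labels, corrected, None, n_groups)

    # -- evaluate ----------------------------------------------------------
    t0 = time.perf_counter()
    report = metrics.evaluate(
        corrected, batch, types, global_labels, seed=cfg.rng_seed
    )
    if out is not None:
        (out / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    logger.info("stage evaluate done in %.1fs", time.perf_counter() - t0)
    return PipelineResult(pca, global_labels, corrected, report, n_groups)
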