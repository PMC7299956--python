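"""End-to-end atlas construction: QC → classes → types.

``run_atlas`` reproduces the two-round workflow: cells passing the
detected-genes filter are normalized, clustered into major cell classes on
a Jaccard-weighted kNN graph, artifact clusters (doublets, low-quality
debris) are flagged and removed, and each retained class is subclustered
into types with the dendrogram merge rule. The result carries per-cell
class/type labels and a run manifest recording every threshold used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (
    ClusterModel,
    assign_classes,
    build_graph,
    flag_artifact_clusters,
    louvain_cluster,
    merge_clusters,
    subcluster_class,
)
from .io import CountMatrix, MarkerPanel, ValidationError
from .preprocess import compute_qc, filter_cells, normalize_log, pca_rmt, regress_batch, select_hvgs


@dataclass
class PipelineConfig:
    """Every tunable threshold of the atlas pipeline, with its default."""

    min_genes: int = 600                  # detected-genes cell filter (inclusive)
    mito_prefix: str = "MT-"
    norm_scale: float | str = "median"
    hvg_n_top: int = 1000
    pca_n_max: int = 50
    tw_alpha: float | None = 0.01
    knn_k: int = 30
    resolution: float = 1.0
    seed: int = 0
    regress_batches: bool = True
    # cluster-merge rule
    merge_max_de_genes: int = 5
    merge_min_lfc: float = 1.1
    merge_alpha: float = 0.001
    # artifact flagging
    doublet_marker_z: float = 1.0
    doublet_genes_factor: float = 1.2
    lowq_depth_factor: float = 0.5
    lowq_mito_threshold: float = 0.10
    # subclustering
    sub_hvg_n_top: int = 500
    sub_pca_n_max: int = 30
    sub_resolution: float = 1.0
    subcluster_classes: tuple[str, ...] | None = None  # None = all classes
    exclusion_classes: tuple[str, ...] = ()            # contaminant classes to drop

    def to_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        for key in ("subcluster_classes", "exclusion_classes"):
            if raw[key] is not None:
                raw[key] = list(raw[key])
        return raw

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("subcluster_classes", "exclusion_classes"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class AtlasResult:
    """Per-cell labels, per-cluster annotations, and the run manifest."""

    cells: pd.DataFrame            # cell_id, class_cluster, class, type, doublet, low_quality
    class_assignments: pd.DataFrame
    class_flags: pd.DataFrame
    class_models: dict[str, ClusterModel]
    manifest: dict

    @property
    def type_labels(self) -> pd.Series:
        kept = self.cells[~self.cells["doublet"] & ~self.cells["low_quality"]]
        return pd.Series(kept["type"].to_numpy(), index=kept["cell_id"].to_numpy())

    def n_types(self) -> int:
        return self.type_labels.nunique()

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "cell_labels.tsv", sep="\t", index=False)
        self.class_assignments.to_csv(outdir / "class_assignments.tsv", sep="\t", index=False)
        self.class_flags.to_csv(outdir / "cluster_flags.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _hash_counts(counts: CountMatrix) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(counts.counts.sum(axis=1)).tobytes())
    h.update(str(counts.counts.nnz).encode())
    return h.hexdigest()[:16]


def run_atlas(
    counts: CountMatrix,
    metadata: pd.DataFrame,
    panel: MarkerPanel,
    config: PipelineConfig | None = None,
) -> AtlasResult:
    """Run the full two-round clustering workflow on one species' matrix."""
    cfg = config or PipelineConfig()
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "input_hash": _hash_counts(counts),
        "n_cells_input": counts.n_cells,
        "stages": [],
    }

    filtered = filter_cells(counts, cfg.min_genes)
    qc = compute_qc(filtered, cfg.mito_prefix)
    manifest["stages"].append({"stage": "qc", "n_cells": filtered.n_cells,
                               "min_genes": cfg.min_genes})

    norm = normalize_log(filtered, cfg.norm_scale)
    meta = metadata.set_index("cell_id").loc[filtered.cell_ids]
    hvgs = select_hvgs(norm, min(cfg.hvg_n_top, norm.n_genes))
    norm_hvg = norm.subset_genes(hvgs)
    batches = meta["batch"].to_numpy()
    if cfg.regress_batches and len(set(batches)) > 1:
        norm_hvg = regress_batch(norm_hvg, batches)
    emb = pca_rmt(norm_hvg, cfg.pca_n_max, cfg.tw_alpha)
    manifest["stages"].append({"stage": "embed", "n_hvgs": len(hvgs), "n_sig": emb.n_sig,
                               "scale_factor": norm.scale_factor})

    graph = build_graph(emb, k=cfg.knn_k)
    class_clusters = louvain_cluster(graph, seed=cfg.seed, resolution=cfg.resolution)
    assignments = assign_classes(class_clusters, norm, panel)
    flags = flag_artifact_clusters(
        class_clusters, assignments, qc, norm, panel,
        marker_z_high=cfg.doublet_marker_z,
        genes_factor=cfg.doublet_genes_factor,
        lowq_depth_factor=cfg.lowq_depth_factor,
        lowq_mito_threshold=cfg.lowq_mito_threshold,
    )
    manifest["stages"].append({
        "stage": "class_clustering",
        "n_clusters": int(len(np.unique(class_clusters))),
        "n_doublet_clusters": int(flags["doublet"].sum()),
        "n_lowq_clusters": int(flags["low_quality"].sum()),
    })

    cluster_class = dict(zip(assignments["cluster"], assignments["class"]))
    cluster_doublet = dict(zip(flags["cluster"], flags["doublet"]))
    cluster_lowq = dict(zip(flags["cluster"], flags["low_quality"]))

    cells = pd.DataFrame({
        "cell_id": filtered.cell_ids,
        "class_cluster": class_clusters,
        "class": [cluster_class[c] for c in class_clusters],
        "doublet": [bool(cluster_doublet[c]) for c in class_clusters],
        "low_quality": [bool(cluster_lowq[c]) for c in class_clusters],
    })
    cells["excluded_class"] = cells["class"].isin(cfg.exclusion_classes)

    keep = ~cells["doublet"] & ~cells["low_quality"] & ~cells["excluded_class"]
    cells["type"] = pd.NA
    models: dict[str, ClusterModel] = {}
    target_classes = cfg.subcluster_classes or sorted(set(cells.loc[keep, "class"]))
    for cls in target_classes:
        mask = (keep & (cells["class"] == cls)).to_numpy()
        if not mask.any():
            continue
        model = subcluster_class(
            filtered, norm, cls, mask,
            k=cfg.knn_k, seed=cfg.seed, resolution=cfg.sub_resolution,
            hvg_n_top=cfg.sub_hvg_n_top, pca_n_max=cfg.sub_pca_n_max,
            merge_kwargs={
                "max_de_genes": cfg.merge_max_de_genes,
                "min_lfc": cfg.merge_min_lfc,
                "alpha": cfg.merge_alpha,
            },
        )
        models[cls] = model
        cells.loc[mask, "type"] = model.as_series().loc[cells.loc[mask, "cell_id"]].to_numpy()
        manifest["stages"].append({"stage": f"subcluster:{cls}",
                                   "n_cells": int(mask.sum()),
                                   "n_types": model.n_clusters})

    n_types = cells.loc[keep, "type"].nunique()
    manifest["n_types"] = int(n_types)
    manifest["n_cells_typed"] = int(keep.sum())
    return AtlasResult(
        cells=cells, class_assignments=assignments, class_flags=flags,
        class_models=models, manifest=manifest,
    )
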