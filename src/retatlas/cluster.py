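"""Graph clustering of cells and cluster-level curation.

Cells are linked in a k-nearest-neighbour graph whose edges are reweighted
by the Jaccard overlap of the two endpoints' neighbour sets, then
partitioned with the Louvain modularity algorithm. Clusters are annotated
with cell classes from a canonical marker panel, screened for doublet and
low-quality artifacts, and — during within-class subclustering — iteratively
merged along a complete-linkage dendrogram whenever fewer than a handful of
genes separate two sibling clusters.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster import hierarchy
from sklearn.neighbors import NearestNeighbors

from .de import count_de_genes, de_test, find_markers
from .io import CountMatrix, MarkerPanel, ValidationError
from .preprocess import Embedding, NormalizedMatrix, normalize_log, pca_rmt, select_hvgs


@dataclass
class NeighborGraph:
    """Jaccard-weighted kNN graph over cells."""

    edges: np.ndarray      # (m, 2) int
    weights: np.ndarray    # (m,) in (0, 1]
    n_cells: int
    k: int

    def to_igraph(self) -> igraph.Graph:
        g = igraph.Graph(n=self.n_cells, edges=[tuple(e) for e in self.edges])
        g.es["weight"] = list(self.weights)
        return g


def build_graph(embedding: Embedding | np.ndarray, k: int = 30) -> NeighborGraph:
    """kNN graph in PC space with Jaccard edge weights.

    Neighbour sets are the k nearest neighbours of each cell (the cell
    itself included), by Euclidean distance in the significant-PC score
    space. Any ordered pair appearing in either set yields a candidate
    edge, weighted ``|N(i) ∩ N(j)| / |N(i) ∪ N(j)|``; zero-weight edges
    cannot arise and identical neighbour sets give weight 1.
    """
    scores = embedding.scores if isinstance(embedding, Embedding) else np.asarray(embedding)
    n = scores.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k, algorithm="auto").fit(scores)
    _, idx = nn.kneighbors(scores)
    # membership matrix: M[i, j] = 1 iff j in N(i); force self-membership
    rows = np.repeat(np.arange(n), k)
    M = sp.csr_matrix((np.ones(n * k, dtype=np.int32), (rows, idx.ravel())), shape=(n, n))
    M.data[:] = 1
    M = M.maximum(sp.identity(n, dtype=np.int32, format="csr"))
    sizes = np.asarray(M.sum(axis=1)).ravel()

    inter = (M @ M.T).tocoo()
    cand = ((M + M.T) > 0).tocoo()
    cmask = cand.row < cand.col
    cand_keys = np.sort(cand.row[cmask].astype(np.int64) * n + cand.col[cmask])
    mask = inter.row < inter.col
    r, c, v = inter.row[mask], inter.col[mask], inter.data[mask]
    keep = np.isin(r.astype(np.int64) * n + c, cand_keys, assume_unique=True)
    r, c, v = r[keep], c[keep], v[keep]
    union = sizes[r] + sizes[c] - v
    w = v / union
    nz = w > 0
    return NeighborGraph(edges=np.column_stack([r[nz], c[nz]]), weights=w[nz], n_cells=n, k=k)


def louvain_cluster(graph: NeighborGraph, seed: int = 0, resolution: float = 1.0) -> np.ndarray:
    """Louvain community detection on the weighted graph.

    Deterministic for a given seed; labels are renumbered by descending
    cluster size (ties by smallest member index).
    """
    if graph.n_cells == 0:
        raise ValidationError("empty graph")
    igraph.set_random_number_generator(random.Random(seed))
    g = graph.to_igraph()
    part = g.community_multilevel(weights="weight", resolution=resolution)
    labels = np.asarray(part.membership)
    igraph.set_random_number_generator(None)
    return _renumber_by_size(labels)


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    uniq, first, counts = np.unique(labels, return_index=True, return_counts=True)
    order = np.lexsort((first, -counts))
    remap = {int(uniq[o]): i for i, o in enumerate(order)}
    return np.array([remap[int(u)] for u in labels], dtype=int)


def assign_classes(labels, norm: NormalizedMatrix, panel: MarkerPanel) -> pd.DataFrame:
    """Assign each cluster the marker-panel class with the highest score.

    A class's score in a cluster is the mean, over its markers, of the
    cluster-mean expression standardized across clusters. Ties break
    alphabetically and are flagged ambiguous.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    present = set(map(str, norm.gene_ids))
    cluster_means = {}
    for cls, markers in panel.classes.items():
        kept = [g for g in markers if g in present]
        dropped = [g for g in markers if g not in present]
        if dropped:
            warnings.warn(f"markers absent from matrix for class {cls!r}: {dropped}")
        if not kept:
            raise ValidationError(f"class {cls!r} has no markers present in the matrix")
        cluster_means[cls] = kept

    rows = []
    for cls in sorted(panel.classes):
        kept = cluster_means[cls]
        sub = norm.subset_genes(kept)
        vals = sub.dense()
        per_cluster = np.column_stack(
            [vals[:, labels == c].mean(axis=1) for c in clusters]
        )  # markers x clusters
        mu = per_cluster.mean(axis=1, keepdims=True)
        sd = per_cluster.std(axis=1, ddof=0, keepdims=True)
        z = np.where(sd > 0, (per_cluster - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        rows.append(z.mean(axis=0))
    score = np.vstack(rows)  # classes x clusters
    class_names = sorted(panel.classes)

    out = []
    for j, c in enumerate(clusters):
        col = score[:, j]
        order = np.lexsort((class_names, -col))
        best, runner = order[0], order[1] if len(col) > 1 else order[0]
        margin = float(col[best] - col[runner]) if len(col) > 1 else float("inf")
        out.append({
            "cluster": int(c),
            "class": class_names[best],
            "margin": margin,
            "ambiguous": bool(margin == 0.0 and len(col) > 1),
            "n_cells": int((labels == c).sum()),
        })
    return pd.DataFrame(out)


def flag_artifact_clusters(
    labels,
    class_assignments: pd.DataFrame,
    qc: pd.DataFrame,
    norm: NormalizedMatrix,
    panel: MarkerPanel,
    *,
    marker_z_high: float = 1.0,
    genes_factor: float = 1.2,
    lowq_depth_factor: float = 0.5,
    lowq_mito_threshold: float = 0.10,
    unique_marker_min_lfc: float = 0.5,
    unique_marker_alpha: float = 0.001,
    unique_marker_min_pct: float = 0.2,
) -> pd.DataFrame:
    """Flag clusters that look like doublets or low-quality debris.

    A cluster is flagged *doublet* when (i) markers of at least two classes
    are high (class marker z-score across clusters > ``marker_z_high``),
    (ii) no gene is uniquely enriched in it against *every* related cluster
    (clusters of the co-expressed classes — a genuine type has private
    markers, a doublet's genes are each shared with one parent), and
    (iii) its mean detected-gene count exceeds ``genes_factor`` times the
    mean of the related clusters'. It is flagged *low-quality* when its
    median transcript count falls below ``lowq_depth_factor`` times the
    median of its assigned class and its median mitochondrial fraction
    exceeds ``lowq_mito_threshold``.
    """
    labels = np.asarray(labels)
    clusters = class_assignments["cluster"].to_numpy()
    qc = qc.set_index("cell_id").loc[norm.cell_ids]

    # class-marker z-scores per cluster (same construction as assign_classes)
    present = set(map(str, norm.gene_ids))
    high_classes: dict[int, list[str]] = {int(c): [] for c in clusters}
    for cls in sorted(panel.classes):
        kept = [g for g in panel.classes[cls] if g in present]
        if not kept:
            continue
        vals = norm.subset_genes(kept).dense()
        per_cluster = np.column_stack([vals[:, labels == c].mean(axis=1) for c in clusters])
        mu = per_cluster.mean(axis=1, keepdims=True)
        sd = per_cluster.std(axis=1, ddof=0, keepdims=True)
        z = np.where(sd > 0, (per_cluster - mu) / np.where(sd > 0, sd, 1.0), 0.0).mean(axis=0)
        for j, c in enumerate(clusters):
            if z[j] > marker_z_high:
                high_classes[int(c)].append(cls)

    mean_genes = {
        int(c): float(qc["n_genes_detected"].to_numpy()[labels == c].mean()) for c in clusters
    }
    class_of = dict(zip(class_assignments["cluster"], class_assignments["class"]))

    def _unique_marker_exists(c: int, related: list[int]) -> bool:
        """Any gene enriched in cluster c against every related cluster?"""
        shared: set | None = None
        for o in related:
            res = de_test(norm, labels == c, labels == o,
                          min_pct=unique_marker_min_pct, min_lfc=unique_marker_min_lfc)
            hits = set(res.loc[
                res["tested"] & (res["logFC"] >= unique_marker_min_lfc)
                & (res["p_adj"] < unique_marker_alpha), "gene",
            ])
            shared = hits if shared is None else (shared & hits)
            if not shared:
                return False
        return bool(shared)

    out = []
    for c in clusters:
        c = int(c)
        in_c = labels == c
        doublet = False
        if len(high_classes[c]) >= 2 and len(clusters) > 1:
            related = [
                int(o) for o in clusters
                if int(o) != c and class_of[o] in high_classes[c]
            ]
            if related:
                ref = float(np.mean([mean_genes[o] for o in related]))
                big = mean_genes[c] > genes_factor * ref
                if big:
                    doublet = not _unique_marker_exists(c, related)
        # low-quality: depth well below the class median, high mito load
        same_class = np.isin(labels, [o for o in clusters if class_of[o] == class_of[c]])
        class_median = float(np.median(qc["n_transcripts"].to_numpy()[same_class]))
        med_depth = float(np.median(qc["n_transcripts"].to_numpy()[in_c]))
        med_mito = float(np.median(qc["mito_fraction"].to_numpy()[in_c]))
        low_quality = (med_depth < lowq_depth_factor * class_median) and (
            med_mito > lowq_mito_threshold
        )
        out.append({
            "cluster": c,
            "doublet": bool(doublet),
            "low_quality": bool(low_quality),
            "n_classes_high": len(high_classes[c]),
            "mean_genes": mean_genes[c],
            "median_mito": med_mito,
        })
    return pd.DataFrame(out)


@dataclass
class ClusterModel:
    """Final partition of a set of cells plus cluster-level annotations."""

    cell_ids: np.ndarray
    labels: np.ndarray                       # per-cell integer cluster
    class_label: str | None = None
    dendrogram: np.ndarray | None = None     # scipy linkage over final clusters
    cluster_names: list[str] | None = None
    flags: pd.DataFrame | None = None

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def as_series(self) -> pd.Series:
        names = self.cluster_names or [str(i) for i in range(self.n_clusters)]
        return pd.Series([names[l] for l in self.labels], index=self.cell_ids)


def _cluster_mean_matrix(norm: NormalizedMatrix, labels: np.ndarray,
                         genes: list[str] | None) -> tuple[np.ndarray, np.ndarray]:
    sub = norm.subset_genes(genes) if genes is not None else norm
    vals = sub.values
    uniq = np.unique(labels)
    means = np.column_stack([
        np.asarray(vals[:, labels == c].mean(axis=1)).ravel() for c in uniq
    ])
    return uniq, means.T  # clusters x genes


def merge_clusters(
    labels,
    norm: NormalizedMatrix,
    hvg_ids: list[str] | None = None,
    *,
    max_de_genes: int = 5,
    min_lfc: float = 1.1,
    alpha: float = 0.001,
    min_pct: float = 0.0,
    de_fn=None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Iteratively merge dendrogram siblings separated by few DE genes.

    A complete-linkage Euclidean dendrogram is built over per-cluster mean
    HVG expression. Sibling pairs (joins of two current clusters) are
    tested in order of merge height; if no more than ``max_de_genes`` genes
    show ``|logFC| >= min_lfc`` at adjusted p < ``alpha``, the pair is
    merged and the dendrogram recomputed. Repeats until no pair merges.

    Returns (merged labels renumbered by size, final linkage or None if a
    single cluster remains).
    """
    labels = np.asarray(labels).copy()
    if de_fn is None:
        def de_fn(a_mask, b_mask):
            res = de_test(norm, a_mask, b_mask, min_pct=min_pct, min_lfc=min_lfc)
            return count_de_genes(res, min_lfc, alpha)

    tested_pairs: set[frozenset] = set()
    while True:
        uniq = np.unique(labels)
        if len(uniq) < 2:
            return _renumber_by_size(labels), None
        uniq, means = _cluster_mean_matrix(norm, labels, hvg_ids)
        Z = hierarchy.linkage(means, method="complete", metric="euclidean")
        merged = False
        n_leaves = len(uniq)
        for row in Z:  # ascending height
            a, b = int(row[0]), int(row[1])
            if a >= n_leaves or b >= n_leaves:
                continue  # join involves an internal node, not a sibling pair
            pair = frozenset((int(uniq[a]), int(uniq[b])))
            if pair in tested_pairs:
                continue
            mask_a = labels == uniq[a]
            mask_b = labels == uniq[b]
            if mask_a.sum() < 3 or mask_b.sum() < 3:
                n_de = 0  # too small to defend separate status
            else:
                n_de = de_fn(mask_a, mask_b)
            if n_de <= max_de_genes:
                labels[mask_b] = uniq[a]
                # the surviving cluster changed content: stale verdicts must be retested
                tested_pairs = {p for p in tested_pairs if uniq[a] not in p}
                merged = True
                break
            tested_pairs.add(pair)
        if not merged:
            return _renumber_by_size(labels), Z


def dendrogram_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def subcluster_class(
    counts: CountMatrix,
    global_norm: NormalizedMatrix,
    class_name: str,
    cell_mask,
    *,
    k: int = 30,
    seed: int = 0,
    resolution: float = 1.0,
    hvg_n_top: int = 500,
    pca_n_max: int = 30,
    renormalize: bool | None = None,
    merge_kwargs: dict | None = None,
    batch_labels=None,
) -> ClusterModel:
    """Second-round clustering of one cell class into types.

    Reruns HVG selection, RMT-PCA, graph building, Louvain and the
    dendrogram merge rule on the class's cells. By default expression is
    re-normalized on the class submatrix only for RGCs — whose much higher
    transcript capture otherwise distorts the shared scale — matching the
    pipeline's treatment of that class; other classes reuse the global
    normalization. ``renormalize`` overrides this.
    """
    cell_mask = np.asarray(cell_mask)
    if cell_mask.dtype != bool:
        mask = np.zeros(global_norm.n_cells, dtype=bool)
        mask[cell_mask] = True
        cell_mask = mask
    n_class = int(cell_mask.sum())
    if renormalize is None:
        renormalize = class_name.upper() == "RGC"

    if n_class < 2 * k:
        warnings.warn(
            f"class {class_name!r} has only {n_class} cells (< 2k); returned as one type"
        )
        return ClusterModel(
            cell_ids=global_norm.cell_ids[cell_mask],
            labels=np.zeros(n_class, dtype=int),
            class_label=class_name,
            cluster_names=[f"{class_name}_1"],
        )

    if renormalize:
        sub_counts = counts.subset_cells(cell_mask)
        norm = normalize_log(sub_counts)
    else:
        norm = global_norm.subset_cells(cell_mask)

    hvgs = select_hvgs(norm, min(hvg_n_top, norm.n_genes))
    emb = pca_rmt(norm.subset_genes(hvgs), pca_n_max)
    if emb.n_sig == 0:
        # no structure above noise: the class is a single type
        return ClusterModel(
            cell_ids=norm.cell_ids, labels=np.zeros(n_class, dtype=int),
            class_label=class_name, cluster_names=[f"{class_name}_1"],
        )
    graph = build_graph(emb, k=min(k, n_class - 1))
    labels = louvain_cluster(graph, seed=seed, resolution=resolution)
    merged, Z = merge_clusters(labels, norm, hvg_ids=hvgs, **(merge_kwargs or {}))
    names = [f"{class_name}_{i + 1}" for i in range(len(np.unique(merged)))]
    return ClusterModel(
        cell_ids=norm.cell_ids, labels=merged, class_label=class_name,
        dendrogram=Z, cluster_names=names,
    )
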