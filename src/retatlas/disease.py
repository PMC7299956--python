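"""Disease-gene expression screening and figure-ready summaries.

A gene "robustly expressed" in the retina is one detected in more than 20%
of the cells of at least one cell class in either region, with mean
log-normalized expression above 0.5 in that stratum (both strict
inequalities). Screened genes are summarized as row-scaled class heatmaps,
dot-plot statistics per type (detection percentage and mean within
expressing cells), and fovea-versus-periphery stratum profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .de import de_test
from .io import ValidationError
from .preprocess import NormalizedMatrix


def _stratum_stats(norm: NormalizedMatrix, gene_rows: np.ndarray, mask: np.ndarray):
    """Detection %, mean over all cells and mean within expressing cells."""
    vals = norm.values[gene_rows][:, mask]
    if sp.issparse(vals):
        vals = vals.toarray()
    n = vals.shape[1]
    det = (vals > 0).sum(axis=1)
    pct = 100.0 * det / n
    mean_all = vals.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_expr = np.where(det > 0, vals.sum(axis=1) / np.maximum(det, 1), 0.0)
    return pct, mean_all, mean_expr


def screen_genes(
    gene_list: pd.DataFrame,
    norm: NormalizedMatrix,
    class_labels,
    region_labels,
    pct_min: float = 20.0,
    expr_min: float = 0.5,
    overrides=None,
    mean_mode: str = "all",
) -> pd.DataFrame:
    """Screen a disease-gene list for robust expression.

    A gene passes when some (class × region) stratum has detection strictly
    above ``pct_min`` percent *and* mean expression strictly above
    ``expr_min``. ``mean_mode`` selects the mean over all stratum cells
    ("all", default) or within expressing cells only ("expressing").
    ``overrides`` (iterable of gene ids, merged with the list's override
    column) force inclusion with a flag. Genes absent from the matrix are
    recorded as absent, not failed.
    """
    if mean_mode not in ("all", "expressing"):
        raise ValueError("mean_mode must be 'all' or 'expressing'")
    classes = np.asarray(class_labels, dtype=object)
    regions = np.asarray(region_labels, dtype=object)
    overrides = set(overrides or ())
    if "override" in gene_list.columns:
        overrides |= set(gene_list.loc[gene_list["override"].astype(bool), "gene"])

    lookup = {g: i for i, g in enumerate(norm.gene_ids)}
    strata = [
        (cls, region, (classes == cls) & (regions == region))
        for cls in sorted(set(classes))
        for region in sorted(set(regions))
        if ((classes == cls) & (regions == region)).any()
    ]

    genes = list(dict.fromkeys(gene_list["gene"]))
    present = [g for g in genes if g in lookup]
    rows_idx = np.array([lookup[g] for g in present], dtype=int)
    stats = {}
    for cls, region, mask in strata:
        pct, mean_all, mean_expr = _stratum_stats(norm, rows_idx, mask)
        stats[(cls, region)] = (pct, mean_all if mean_mode == "all" else mean_expr)

    group_of = dict(zip(gene_list["gene"], gene_list["group"]))
    out = []
    for j, g in enumerate(genes):
        if g not in lookup:
            out.append({"gene": g, "group": group_of.get(g), "present": False,
                        "max_detection_pct": np.nan, "mean_expression": np.nan,
                        "best_class": None, "best_region": None,
                        "passes": False, "override": g in overrides})
            continue
        i = present.index(g)
        best = None
        passes = False
        for (cls, region), (pct, mean) in stats.items():
            if best is None or pct[i] > best[0]:
                best = (pct[i], mean[i], cls, region)
            if pct[i] > pct_min and mean[i] > expr_min:
                passes = True
        out.append({
            "gene": g, "group": group_of.get(g), "present": True,
            "max_detection_pct": float(best[0]), "mean_expression": float(best[1]),
            "best_class": best[2], "best_region": best[3],
            "passes": passes, "override": g in overrides,
        })
    res = pd.DataFrame(out)
    res["included"] = res["passes"] | res["override"]
    return res


@dataclass
class ExpressionSummary:
    """Gene × group expression summary in three flavours."""

    detection_pct: pd.DataFrame
    mean_expression: pd.DataFrame     # over all cells of the group
    mean_expressing: pd.DataFrame     # within expressing cells only
    scaled: pd.DataFrame | None = None
    flags: pd.Series | None = None    # e.g. all-zero or uninformative rows


def _summary_by_group(norm: NormalizedMatrix, genes, labels) -> ExpressionSummary:
    labels = np.asarray(labels, dtype=object)
    lookup = {g: i for i, g in enumerate(norm.gene_ids)}
    missing = [g for g in genes if g not in lookup]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing[:5]}")
    rows_idx = np.array([lookup[g] for g in genes], dtype=int)
    groups = sorted(set(labels))
    pct, mean_all, mean_expr = {}, {}, {}
    for grp in groups:
        mask = labels == grp
        p, ma, me = _stratum_stats(norm, rows_idx, mask)
        pct[grp], mean_all[grp], mean_expr[grp] = p, ma, me
    idx = pd.Index(genes, name="gene")
    return ExpressionSummary(
        detection_pct=pd.DataFrame(pct, index=idx),
        mean_expression=pd.DataFrame(mean_all, index=idx),
        mean_expressing=pd.DataFrame(mean_expr, index=idx),
    )


def class_heatmap(genes, norm: NormalizedMatrix, class_labels,
                  scale: str = "max") -> ExpressionSummary:
    """Row-scaled per-class mean expression for a heat map.

    With ``scale='max'`` each gene's class means are divided by the row
    maximum (preserving rank order within the row); ``scale='z'`` z-scores
    each row instead. All-zero rows are emitted as zeros and flagged, as
    are constant rows (uninformative after scaling).
    """
    if scale not in ("max", "z"):
        raise ValueError("scale must be 'max' or 'z'")
    summ = _summary_by_group(norm, list(genes), class_labels)
    means = summ.mean_expression
    flags = pd.Series("", index=means.index, dtype=object)
    row_max = means.max(axis=1)
    row_min = means.min(axis=1)
    flags[row_max == 0] = "all_zero"
    flags[(row_max > 0) & (row_max == row_min)] = "uninformative"
    if scale == "max":
        denom = row_max.replace(0, 1.0)
        scaled = means.div(denom, axis=0)
        scaled[row_max == 0] = 0.0
    else:
        sd = means.std(axis=1, ddof=0).replace(0, 1.0)
        scaled = means.sub(means.mean(axis=1), axis=0).div(sd, axis=0)
    summ.scaled = scaled
    summ.flags = flags
    return summ


def dotplot_stats(genes, norm: NormalizedMatrix, cluster_labels) -> pd.DataFrame:
    """Long-format dot-plot statistics per (gene, cluster).

    ``pct_nonzero`` is the percentage of the cluster's cells with non-zero
    expression; ``mean_expressing`` averages over strictly positive values
    only (0 when the gene is absent from the cluster).
    """
    summ = _summary_by_group(norm, list(genes), cluster_labels)
    long = (
        summ.detection_pct.reset_index()
        .melt(id_vars="gene", var_name="cluster", value_name="pct_nonzero")
        .merge(
            summ.mean_expressing.reset_index()
            .melt(id_vars="gene", var_name="cluster", value_name="mean_expressing"),
            on=["gene", "cluster"],
        )
    )
    return long


def regional_disease_profile(
    genes,
    norm: NormalizedMatrix,
    class_labels,
    region_labels,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Fovea-vs-periphery means and adjusted p-values per (gene, class).

    Classes missing from one region are reported with ``skipped=True``
    rather than zero-filled. Adjustment is Benjamini-Hochberg within each
    class contrast, over all genes of the matrix as in the DE engine.
    """
    classes = np.asarray(class_labels, dtype=object)
    regions = np.asarray(region_labels, dtype=object)
    genes = list(genes)
    lookup = {g: i for i, g in enumerate(norm.gene_ids)}
    out = []
    for cls in sorted(set(classes)):
        fov = (classes == cls) & (regions == "fovea")
        per = (classes == cls) & (regions == "periphery")
        if fov.sum() < 3 or per.sum() < 3:
            for g in genes:
                out.append({"gene": g, "class": cls, "fovea_mean": np.nan,
                            "periphery_mean": np.nan, "p_adj": np.nan, "skipped": True})
            continue
        res = de_test(norm, fov, per).set_index("gene")
        for g in genes:
            if g not in lookup:
                out.append({"gene": g, "class": cls, "fovea_mean": np.nan,
                            "periphery_mean": np.nan, "p_adj": np.nan, "skipped": True})
                continue
            row = res.loc[g]
            fmask = norm.values[lookup[g], :]
            fvals = fmask.toarray().ravel() if sp.issparse(fmask) else np.asarray(fmask).ravel()
            out.append({
                "gene": g, "class": cls,
                "fovea_mean": float(fvals[fov].mean()),
                "periphery_mean": float(fvals[per].mean()),
                "p_adj": float(row["p_adj"]) if np.isfinite(row["p_adj"]) else np.nan,
                "skipped": False,
            })
    return pd.DataFrame(out)
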