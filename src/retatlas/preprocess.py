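"""Cell filtering, normalization, HVG selection, batch regression and RMT-PCA.

Normalized expression for gene *i* in cell *j* is
``E_ij = ln(1 + c_ij * s / T_j)`` where ``T_j`` is the cell's total UMI count
and ``s`` is the median library size across cells (the recorded scale
factor). All downstream log-fold-change thresholds are interpreted on this
natural-log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, ValidationError


def compute_qc(counts: CountMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC metrics: detected genes, total transcripts, mito fraction."""
    mat = counts.counts
    n_transcripts = np.asarray(mat.sum(axis=0)).ravel()
    n_genes = np.asarray((mat > 0).sum(axis=0)).ravel()
    mito_mask = np.array([str(g).startswith(mito_prefix) for g in counts.gene_ids])
    mito = np.asarray(mat[mito_mask, :].sum(axis=0)).ravel() if mito_mask.any() \
        else np.zeros_like(n_transcripts)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_transcripts > 0, mito / np.maximum(n_transcripts, 1), 0.0)
    return pd.DataFrame({
        "cell_id": counts.cell_ids,
        "n_genes_detected": n_genes.astype(int),
        "n_transcripts": n_transcripts.astype(int),
        "mito_fraction": frac,
    })


def filter_cells(counts: CountMatrix, min_genes: int = 600) -> CountMatrix:
    """Keep cells with at least ``min_genes`` detected genes (inclusive floor)."""
    if min_genes < 0:
        raise ValueError("min_genes must be non-negative")
    detected = np.asarray((counts.counts > 0).sum(axis=0)).ravel()
    keep = detected >= min_genes
    if not keep.any():
        raise ValidationError(
            f"all {counts.n_cells} cells removed at min_genes={min_genes} "
            f"(max detected: {int(detected.max()) if len(detected) else 0})"
        )
    return counts.subset_cells(keep)


@dataclass
class NormalizedMatrix:
    """Log-normalized expression E_ij, genes x cells (sparse or dense)."""

    values: sp.spmatrix | np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale_factor: float
    hvg_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("normalized values shape mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        return self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values)

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask_or_idx) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(self.values[:, idx], self.gene_ids, self.cell_ids[idx],
                                self.scale_factor, self.hvg_ids)

    def subset_genes(self, genes) -> "NormalizedMatrix":
        idx = self.gene_index(genes)
        return NormalizedMatrix(self.values[idx, :], self.gene_ids[idx], self.cell_ids,
                                self.scale_factor, None)


def normalize_log(counts: CountMatrix, scale: float | str = "median") -> NormalizedMatrix:
    """Median-library-size normalization followed by ln(1 + x).

    ``scale`` may be "median" (default) or an explicit positive number.
    Zeros stay exactly zero, so sparsity is preserved.
    """
    totals = np.asarray(counts.counts.sum(axis=0)).ravel().astype(float)
    if np.any(totals == 0):
        raise ValidationError("zero-total cell encountered; run filter_cells first")
    s = float(np.median(totals)) if scale == "median" else float(scale)
    if s <= 0:
        raise ValueError("scale factor must be positive")
    mat = sp.csc_matrix(counts.counts, copy=True).astype(float)
    # scale each column by s/T_j, then log1p on the stored nonzeros
    mat = mat @ sp.diags(s / totals)
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(mat, counts.gene_ids.copy(), counts.cell_ids.copy(), s)


def _row_mean_var(values) -> tuple[np.ndarray, np.ndarray]:
    if sp.issparse(values):
        n = values.shape[1]
        mean = np.asarray(values.mean(axis=1)).ravel()
        sq = np.asarray(values.multiply(values).mean(axis=1)).ravel()
        var = (sq - mean**2) * n / max(n - 1, 1)
    else:
        mean = values.mean(axis=1)
        var = values.var(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros(values.shape[0])
    return mean, np.maximum(var, 0.0)


def select_hvgs(norm: NormalizedMatrix, n_top: int, n_bins: int = 20) -> list[str]:
    """Top ``n_top`` genes by dispersion z-score within mean-expression bins.

    Dispersion is ``log(var/mean)`` of the normalized values; z-scores are
    taken within 20 equal-frequency bins of the mean so highly expressed
    genes are compared against their peers. Ties break by gene id.
    """
    if norm.n_cells < 2:
        raise ValidationError("need at least 2 cells to estimate dispersion")
    if n_top > norm.n_genes:
        raise ValueError("n_top exceeds gene count")
    mean, var = _row_mean_var(norm.values)
    expressed = mean > 0
    eps = 1e-12
    disp = np.full(norm.n_genes, -np.inf)
    disp[expressed] = np.log((var[expressed] + eps) / (mean[expressed] + eps))

    z = np.full(norm.n_genes, -np.inf)
    idx = np.flatnonzero(expressed)
    if len(idx):
        bins = pd.qcut(mean[idx], q=min(n_bins, len(idx)), duplicates="drop", labels=False)
        d = disp[idx]
        for b in np.unique(bins):
            members = idx[bins == b]
            dm = disp[members]
            sd = dm.std(ddof=1) if len(members) > 1 else 0.0
            z[members] = (dm - dm.mean()) / sd if sd > 0 else 0.0
    order = sorted(range(norm.n_genes), key=lambda i: (-z[i], str(norm.gene_ids[i])))
    return [str(norm.gene_ids[i]) for i in order[:n_top]]


def regress_batch(norm: NormalizedMatrix, batch_labels) -> NormalizedMatrix:
    """Remove additive per-batch offsets by least squares, per gene.

    With an intercept plus batch indicators the OLS fit reduces to
    subtracting each batch's mean and adding back the gene's grand mean.
    Residual output may be negative; downstream PCA standardizes anyway.
    """
    batch_labels = np.asarray(batch_labels)
    if len(batch_labels) != norm.n_cells:
        raise ValidationError("batch labels do not cover all cells")
    uniq = np.unique(batch_labels)
    dense = norm.dense().astype(float)
    grand = dense.mean(axis=1, keepdims=True)
    out = dense.copy()
    for b in uniq:
        cols = batch_labels == b
        if not cols.any():
            raise ValidationError(f"batch {b!r} has no cells")
        out[:, cols] += grand - dense[:, cols].mean(axis=1, keepdims=True)
    return NormalizedMatrix(out, norm.gene_ids, norm.cell_ids, norm.scale_factor, norm.hvg_ids)


#: upper-tail quantiles of the Tracy-Widom beta=1 distribution
_TW1_QUANTILES = {0.05: 0.9793, 0.01: 2.0234, 0.001: 3.2724}


@dataclass
class Embedding:
    """PCA scores restricted to the statistically significant components."""

    scores: np.ndarray          # cells x n_sig
    loadings: np.ndarray        # genes x n_sig
    eigenvalues: np.ndarray     # descending, full retained spectrum
    n_sig: int
    mp_edge: float
    threshold: float
    gene_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))


def marchenko_pastur_edge(p: int, n: int) -> float:
    """Upper edge of the Marchenko-Pastur law for a standardized p x n matrix."""
    return (1.0 + np.sqrt(p / n)) ** 2


def _tw_allowance(p: int, n: int, alpha: float) -> float:
    """Tracy-Widom finite-size allowance above the MP edge at level ``alpha``."""
    if alpha is None or alpha <= 0:
        return 0.0
    mu = (np.sqrt(n - 1) + np.sqrt(p)) ** 2 / n
    sigma = (np.sqrt(n - 1) + np.sqrt(p)) / n * (1 / np.sqrt(n - 1) + 1 / np.sqrt(p)) ** (1 / 3)
    q = _TW1_QUANTILES.get(alpha)
    if q is None:
        raise ValueError(f"alpha must be one of {sorted(_TW1_QUANTILES)}")
    return max(mu - marchenko_pastur_edge(p, n), 0.0) + sigma * q


def pca_rmt(norm: NormalizedMatrix, n_components_max: int = 50,
            tw_alpha: float | None = 0.01) -> Embedding:
    """PCA with the number of significant components set by random matrix theory.

    Genes are standardized (mean 0, unit variance across cells); eigenvalues
    of the gene-gene covariance ``X X^T / n`` exceeding the Marchenko-Pastur
    upper edge ``(1 + sqrt(p/n))^2`` — plus a Tracy-Widom finite-size
    allowance at level ``tw_alpha`` (set ``None`` to use the bare edge) —
    count as significant. Scores are restricted to those components.
    """
    n = norm.n_cells
    if n < 3:
        raise ValidationError("need at least 3 cells for PCA")
    X = norm.dense().astype(float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    keep = sd.ravel() > 0
    Xs = (X[keep] - mean[keep]) / sd[keep]
    p = Xs.shape[0]
    if p == 0:
        raise ValidationError("all genes have zero variance")

    # economy SVD: eigenvalues of X X^T / n are s^2 / n
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    eigenvalues = s**2 / n
    edge = marchenko_pastur_edge(p, n)
    threshold = edge + _tw_allowance(p, n, tw_alpha)
    n_sig = int(min(np.sum(eigenvalues > threshold), n_components_max))

    scores = (Vt[:n_sig, :] * s[:n_sig, None]).T       # cells x n_sig
    loadings = U[:, :n_sig]
    return Embedding(
        scores=scores, loadings=loadings, eigenvalues=eigenvalues,
        n_sig=n_sig, mp_edge=edge, threshold=threshold,
        gene_ids=norm.gene_ids[keep],
    )
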