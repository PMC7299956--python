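"""Readers, writers and in-memory containers for count matrices and metadata.

The pipeline works on digital gene expression matrices with genes as rows and
cells as columns, mirroring the layout written by droplet-sequencing pipelines
(a Matrix Market triplet directory with ``matrix.mtx`` plus gene and barcode
annotation files), and on plain TSV side tables (per-cell metadata, 1:1
ortholog pairs, disease gene lists, marker panels).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

REGIONS = ("fovea", "periphery")
ENRICHMENTS = ("none", "CD73_depleted", "CD90_enriched")
METADATA_COLUMNS = ("cell_id", "donor", "region", "enrichment", "batch", "species")


class FormatError(ValueError):
    """A file does not have the expected on-disk layout."""


class ValidationError(ValueError):
    """Contents parsed but violate an invariant (negative counts, duplicates...)."""


def _dedupe_symbols(symbols: Sequence[str]) -> list[str]:
    """Disambiguate duplicate gene symbols with ``.1``, ``.2`` suffixes in file order."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


@dataclass
class CountMatrix:
    """Sparse UMI count matrix, genes (rows) by cells (columns).

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(len(gene_ids), len(cell_ids))``.
    gene_ids, cell_ids
        Unique, ordered identifiers for each axis.
    """

    counts: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.cell_ids)} cells)"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell_ids are not unique")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("counts contain non-integer entries")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.counts[:, idx], self.gene_ids, self.cell_ids[idx])

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = self.gene_index(genes)
        return CountMatrix(self.counts[idx, :], self.gene_ids[idx], self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.gene_ids, columns=self.cell_ids
        )


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find_companion(directory: Path, names: Sequence[str]) -> Path:
    for name in names:
        for cand in (directory / name, directory / f"{name}.gz"):
            if cand.exists():
                return cand
    raise FormatError(f"none of {names} found in {directory}")


def load_counts(path: str | Path) -> CountMatrix:
    """Load a count matrix from a 10x-style triplet directory or a dense TSV.

    A directory must contain ``matrix.mtx``, ``genes.tsv`` or ``features.tsv``,
    and ``barcodes.tsv`` (optionally gzipped). A ``.tsv`` file is read as a
    dense matrix with gene rows (first column) and cell columns (header row).
    Duplicate gene symbols are disambiguated with ``.1``, ``.2`` suffixes in
    file order.
    """
    path = Path(path)
    if path.is_dir():
        mtx = _find_companion(path, ["matrix.mtx"])
        genes_f = _find_companion(path, ["genes.tsv", "features.tsv"])
        barcodes_f = _find_companion(path, ["barcodes.tsv"])
        with _open_maybe_gz(mtx) as fh:
            mat = scipy.io.mmread(fh)
        genes_tab = pd.read_csv(genes_f, sep="\t", header=None, dtype=str)
        # 10x features files carry (id, symbol[, type]); prefer the symbol.
        symbols = genes_tab.iloc[:, 1] if genes_tab.shape[1] >= 2 else genes_tab.iloc[:, 0]
        barcodes = pd.read_csv(barcodes_f, sep="\t", header=None, dtype=str).iloc[:, 0]
        gene_ids = _dedupe_symbols(list(symbols))
        mat = sp.csc_matrix(mat)
        if np.any(mat.data != np.round(mat.data)):
            raise ValidationError(f"{mtx} contains non-integer entries")
        return CountMatrix(mat, np.array(gene_ids, dtype=object), barcodes.to_numpy(object))
    if path.suffix in (".tsv", ".txt") or path.suffixes[-2:] == [".tsv", ".gz"]:
        frame = pd.read_csv(path, sep="\t", index_col=0)
        gene_ids = _dedupe_symbols([str(g) for g in frame.index])
        values = frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError(f"{path} contains non-numeric entries")
        return CountMatrix(
            sp.csc_matrix(values),
            np.array(gene_ids, dtype=object),
            frame.columns.to_numpy(object),
        )
    raise FormatError(f"{path} is neither a triplet directory nor a .tsv file")


def save_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as a triplet directory (or dense TSV for ``.tsv`` paths)."""
    path = Path(path)
    if path.suffix == ".tsv":
        cm.to_frame().to_csv(path, sep="\t", index_label="gene")
        return
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(cm.counts))
    pd.DataFrame({0: cm.gene_ids, 1: cm.gene_ids}).to_csv(
        path / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(cm.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)


def merge_samples(
    matrices: Sequence[CountMatrix],
    metas: Sequence[pd.DataFrame],
    sample_names: Sequence[str] | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Pool samples: union of gene sets (zero-filled), concatenated cells.

    Cell ids are namespaced ``<sample>_<barcode>`` so barcodes reused across
    channels stay distinct.
    """
    if not matrices:
        raise ValidationError("need at least one sample")
    if len(matrices) != len(metas):
        raise ValidationError("matrices and metadata lists differ in length")
    if sample_names is None:
        sample_names = [f"S{i + 1}" for i in range(len(matrices))]

    union_genes: list[str] = []
    seen: set[str] = set()
    for cm in matrices:
        for g in cm.gene_ids:
            if g not in seen:
                seen.add(g)
                union_genes.append(g)
    gene_pos = {g: i for i, g in enumerate(union_genes)}

    blocks, all_cells, metas_out = [], [], []
    for name, cm, meta in zip(sample_names, matrices, metas):
        rows = np.array([gene_pos[g] for g in cm.gene_ids])
        coo = sp.coo_matrix(cm.counts)
        block = sp.coo_matrix(
            (coo.data, (rows[coo.row], coo.col)),
            shape=(len(union_genes), cm.n_cells),
        )
        blocks.append(block)
        all_cells.extend(f"{name}_{c}" for c in cm.cell_ids)
        m = meta.copy()
        m["cell_id"] = [f"{name}_{c}" for c in m["cell_id"]]
        metas_out.append(m)
    if len(set(all_cells)) != len(all_cells):
        raise ValidationError("cell ids collide after sample prefixing")
    merged = CountMatrix(
        sp.hstack(blocks), np.array(union_genes, dtype=object), np.array(all_cells, dtype=object)
    )
    return merged, pd.concat(metas_out, ignore_index=True)


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Load per-cell metadata; requires cell_id/donor/region/enrichment/batch/species."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing columns {missing}")
    bad = set(meta["region"]) - set(REGIONS)
    if bad:
        raise ValidationError(f"unknown region labels {sorted(bad)}")
    if meta["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell_id rows in metadata")
    return meta


@dataclass
class MarkerPanel:
    """Canonical class markers: class name -> list of gene symbols."""

    classes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, markers in self.classes.items():
            if not markers:
                raise ValidationError(f"class {cls!r} has no markers")

    def class_names(self) -> list[str]:
        return list(self.classes)

    def all_markers(self) -> list[str]:
        return [g for markers in self.classes.values() for g in markers]


def load_marker_panel(path: str | Path) -> MarkerPanel:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise FormatError(f"{path} must map class names to marker lists")
    return MarkerPanel({str(k): [str(g) for g in v] for k, v in raw.items()})


def save_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(panel.classes, fh)


@dataclass
class OrthologTable:
    """Strictly 1:1 ortholog pairs between two species' gene namespaces."""

    pairs: pd.DataFrame  # columns: gene_a, gene_b

    def __post_init__(self) -> None:
        self.pairs = self.pairs.reset_index(drop=True)
        if list(self.pairs.columns[:2]) != ["gene_a", "gene_b"]:
            self.pairs = self.pairs.iloc[:, :2].set_axis(["gene_a", "gene_b"], axis=1)
        if self.pairs["gene_a"].duplicated().any() or self.pairs["gene_b"].duplicated().any():
            raise ValidationError("ortholog table is not 1:1")

    def __len__(self) -> int:
        return len(self.pairs)

    def a_to_b(self) -> dict[str, str]:
        return dict(zip(self.pairs["gene_a"], self.pairs["gene_b"]))

    def b_to_a(self) -> dict[str, str]:
        return dict(zip(self.pairs["gene_b"], self.pairs["gene_a"]))


def load_orthologs(path: str | Path) -> OrthologTable:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if tab.shape[1] < 2:
        raise FormatError("ortholog table needs two columns")
    return OrthologTable(tab)


def save_orthologs(ortho: OrthologTable, path: str | Path) -> None:
    ortho.pairs.to_csv(path, sep="\t", index=False)


def load_gene_list(path: str | Path) -> pd.DataFrame:
    """Load a (gene, group[, override]) TSV, deduplicated in first-seen order.

    The header row is optional; it is detected by the literal column name
    ``gene`` in the first field.
    """
    path = Path(path)
    first = pd.read_csv(path, sep="\t", header=None, nrows=1, dtype=str)
    has_header = str(first.iloc[0, 0]).lower() == "gene"
    tab = pd.read_csv(path, sep="\t", header=0 if has_header else None, dtype=str)
    if tab.empty:
        raise FormatError(f"{path} contains no gene entries")
    cols = ["gene", "group", "override"][: tab.shape[1]]
    tab = tab.set_axis(cols + list(tab.columns[len(cols):]), axis=1)
    if "override" in tab.columns:
        tab["override"] = tab["override"].fillna("false").str.lower().isin(("1", "true", "yes"))
    else:
        tab["override"] = False
    if "group" not in tab.columns:
        tab["group"] = "unspecified"
    tab = tab.drop_duplicates(subset=["gene", "group"], keep="first").reset_index(drop=True)
    return tab[["gene", "group", "override"]]
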