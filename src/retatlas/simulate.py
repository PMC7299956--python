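"""Synthetic retina atlas generator with full ground truth.

Emulates the statistical structure a fovea/periphery single-cell atlas
pipeline has to cope with: six cell classes subdivided into transcriptomic
types, class- and type-specific marker genes, region-dependent type
proportions and region-specific differential expression, doublets,
depth-thinned high-mitochondrial low-quality cells, and a second "species"
whose types share perturbed signatures over a partial 1:1 ortholog set.

Counts are drawn from a gamma-Poisson (negative binomial) model around
type-specific mean profiles with log-normal library sizes, so the generated
matrices show the overdispersion characteristic of UMI data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io import CountMatrix, MarkerPanel, OrthologTable, save_counts, save_marker_panel, save_orthologs

CLASS_NAMES = ("PR", "HC", "BC", "AC", "RGC", "NN")
#: relative abundance of each class in the default configuration
CLASS_WEIGHTS = {"PR": 0.25, "HC": 0.05, "BC": 0.30, "AC": 0.15, "RGC": 0.15, "NN": 0.10}


@dataclass
class SimConfig:
    """Parameters of the synthetic atlas.

    Defaults give 6 classes / 20 types, 8,000 human cells split evenly
    between fovea and periphery, 2,000 genes, 8-fold type markers, and
    e^1.5-fold regional effects on 12 genes per type.
    """

    n_classes: int = 6
    types_per_class: tuple[int, ...] = (3, 2, 6, 4, 3, 2)
    class_names: tuple[str, ...] = CLASS_NAMES
    n_cells_fovea: int = 4000
    n_cells_periphery: int = 4000
    n_genes: int = 2000
    baseline_mean: float = 1.0          # mean of the per-gene Gamma baseline
    baseline_shape: float = 0.6         # Gamma shape of the baseline
    marker_fold: float = 8.0
    n_markers_per_type: int = 20
    n_markers_per_class: int = 10       # shared by all types of a class (the marker panel)
    # 5 regional DE genes per type at fold e^1.5: regional cohorts of a type
    # differ detectably but stay within one type, as in primate retina where
    # nearly all types are shared between fovea and periphery
    region_de_genes_per_type: int = 5
    region_fold: float = float(np.exp(1.5))
    type_proportions_by_region: dict[str, np.ndarray] | None = None
    doublet_rate: float = 0.05
    doublet_rescale: bool = True
    lowq_rate: float = 0.03
    lowq_depth_factor: float = 0.3
    lowq_mito_frac: float = 0.3
    mito_gene_count: int = 13
    mito_baseline_frac: float = 0.05    # mitochondrial share of a healthy library
    frac_low_genes: float = 0.10        # genes forced to near-silent baseline
    low_gene_scale: float = 0.02
    lib_size_mean: float = 4000.0
    lib_size_sigma: float = 0.35
    dispersion_range: tuple[float, float] = (0.1, 1.0)
    n_donors: int = 7
    n_batches: int = 2
    batch_shift_sd: float = 0.0         # per-(batch, gene) log-normal shift
    species_b_perturb_sd: float = 0.1
    ortholog_fraction: float = 0.8
    n_cells_species_b: int = 4000
    species_a: str = "human"
    species_b: str = "macaque"
    seed: int = 0

    # ------------------------------------------------------------------ names
    @property
    def type_names(self) -> list[str]:
        return [
            f"{cls}{i + 1}"
            for cls, k in zip(self.class_names, self.types_per_class)
            for i in range(k)
        ]

    @property
    def n_types(self) -> int:
        return int(sum(self.types_per_class))

    def class_of_type(self) -> dict[str, str]:
        return {
            t: cls
            for cls, k in zip(self.class_names, self.types_per_class)
            for t in [f"{cls}{i + 1}" for i in range(k)]
        }

    # -------------------------------------------------------------- validation
    def validate(self) -> None:
        if len(self.types_per_class) != self.n_classes or len(self.class_names) != self.n_classes:
            raise ValueError("types_per_class/class_names must have n_classes entries")
        for rate in (self.doublet_rate, self.lowq_rate, self.lowq_mito_frac,
                     self.ortholog_fraction, self.frac_low_genes):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if not 0.0 < self.lowq_depth_factor < 1.0:
            raise ValueError("lowq_depth_factor must lie in (0, 1)")
        needed = (
            self.n_types * (self.n_markers_per_type + self.region_de_genes_per_type)
            + self.n_classes * self.n_markers_per_class
            + self.mito_gene_count
        )
        if needed > self.n_genes:
            raise ValueError(
                f"config needs {needed} designated genes but only {self.n_genes} available"
            )
        props = self.proportions()
        for region, p in props.items():
            if len(p) != self.n_types:
                raise ValueError(f"{region} proportions have wrong length")
            if abs(float(np.sum(p)) - 1.0) > 1e-9:
                raise ValueError(f"{region} proportions sum to {np.sum(p)}, not 1")
            if np.any(np.asarray(p) < 0):
                raise ValueError("proportions must be non-negative")

    def proportions(self) -> dict[str, np.ndarray]:
        """Per-region type proportions; defaults tilt within-class abundances
        in opposite directions in fovea and periphery."""
        if self.type_proportions_by_region is not None:
            return {k: np.asarray(v, dtype=float) for k, v in self.type_proportions_by_region.items()}
        out = {}
        for region in ("fovea", "periphery"):
            weights = []
            for cls, k in zip(self.class_names, self.types_per_class):
                w = np.arange(1, k + 1, dtype=float)
                if region == "periphery":
                    w = w[::-1]
                w = w / w.sum() * CLASS_WEIGHTS.get(cls, 1.0 / self.n_classes)
                weights.append(w)
            p = np.concatenate(weights)
            out[region] = p / p.sum()
        return out

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["types_per_class"] = list(self.types_per_class)
        raw["class_names"] = list(self.class_names)
        raw["dispersion_range"] = list(self.dispersion_range)
        if raw["type_proportions_by_region"] is not None:
            raw["type_proportions_by_region"] = {
                k: [float(x) for x in v] for k, v in raw["type_proportions_by_region"].items()
            }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("types_per_class", "class_names", "dispersion_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if raw.get("type_proportions_by_region"):
            raw["type_proportions_by_region"] = {
                k: np.asarray(v, float) for k, v in raw["type_proportions_by_region"].items()
            }
        return cls(**raw)


@dataclass
class GeneDesign:
    """Which genes play which structural role (shared by both species)."""

    gene_ids: np.ndarray
    baseline: np.ndarray               # per-gene Gamma baseline (relative expression)
    dispersion: np.ndarray
    mito_idx: np.ndarray
    low_idx: np.ndarray
    class_markers: dict[str, np.ndarray]   # class -> gene indices
    type_markers: dict[str, np.ndarray]    # type -> gene indices
    region_de: dict[str, tuple[np.ndarray, str]]  # type -> (gene indices, boosted region)


@dataclass
class SimulatedAtlas:
    """Everything :func:`generate_atlas` produced, with full ground truth."""

    counts: CountMatrix
    metadata: pd.DataFrame
    truth: pd.DataFrame
    marker_panel: MarkerPanel
    orthologs: OrthologTable
    counts_b: CountMatrix
    metadata_b: pd.DataFrame
    truth_b: pd.DataFrame
    config: SimConfig
    design: GeneDesign

    def astuple(self):
        return (self.counts, self.metadata, self.truth, self.marker_panel, self.orthologs)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_counts(self.counts, outdir / "counts_a")
        save_counts(self.counts_b, outdir / "counts_b")
        self.metadata.to_csv(outdir / "metadata_a.tsv", sep="\t", index=False)
        self.metadata_b.to_csv(outdir / "metadata_b.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth_a.tsv", sep="\t", index=False)
        self.truth_b.to_csv(outdir / "truth_b.tsv", sep="\t", index=False)
        save_marker_panel(self.marker_panel, outdir / "markers.yaml")
        save_orthologs(self.orthologs, outdir / "orthologs.tsv")
        self.config.to_yaml(outdir / "sim_config.yaml")


def _design_genes(cfg: SimConfig, rng: np.random.Generator) -> GeneDesign:
    n = cfg.n_genes
    names = np.array(
        [f"MT-{i + 1}" for i in range(cfg.mito_gene_count)]
        + [f"G{i:05d}" for i in range(n - cfg.mito_gene_count)],
        dtype=object,
    )
    baseline = rng.gamma(cfg.baseline_shape, cfg.baseline_mean / cfg.baseline_shape, size=n)
    baseline = np.maximum(baseline, 1e-6)
    mito_idx = np.arange(cfg.mito_gene_count)

    pool = rng.permutation(np.arange(cfg.mito_gene_count, n))
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = pool[cursor:cursor + k]
        cursor += k
        return np.sort(out)

    class_markers = {cls: take(cfg.n_markers_per_class) for cls in cfg.class_names}
    type_markers = {t: take(cfg.n_markers_per_type) for t in cfg.type_names}
    region_de = {
        t: (take(cfg.region_de_genes_per_type), "fovea" if i % 2 == 0 else "periphery")
        for i, t in enumerate(cfg.type_names)
    }
    # force designated genes to a healthy baseline so planted effects are visible
    designated = np.concatenate(
        [mito_idx]
        + list(class_markers.values())
        + list(type_markers.values())
        + [idx for idx, _ in region_de.values()]
    )
    lift = baseline[designated] < cfg.baseline_mean * 0.5
    baseline[designated[lift]] = cfg.baseline_mean * rng.uniform(0.5, 1.5, size=int(lift.sum()))

    # a slice of undesignated genes is near-silent (fodder for failing disease genes)
    free = pool[cursor:]
    n_low = int(round(cfg.frac_low_genes * n))
    low_idx = np.sort(free[:n_low])
    baseline[low_idx] *= cfg.low_gene_scale

    # mitochondrial genes get a fixed share of a healthy library
    non_mito_sum = baseline[cfg.mito_gene_count:].sum()
    target = cfg.mito_baseline_frac / (1 - cfg.mito_baseline_frac) * non_mito_sum
    baseline[mito_idx] = target / cfg.mito_gene_count

    lo, hi = cfg.dispersion_range
    dispersion = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    return GeneDesign(
        gene_ids=names,
        baseline=baseline,
        dispersion=dispersion,
        mito_idx=mito_idx,
        low_idx=low_idx,
        class_markers=class_markers,
        type_markers=type_markers,
        region_de=region_de,
    )


def _type_profiles(cfg: SimConfig, design: GeneDesign,
                   gene_factor: np.ndarray | None = None) -> dict[tuple[str, str], np.ndarray]:
    """Expected relative expression per (type, region), normalized to sum 1."""
    class_of = cfg.class_of_type()
    profiles: dict[tuple[str, str], np.ndarray] = {}
    for t in cfg.type_names:
        base = design.baseline.copy()
        if gene_factor is not None:
            base = base * gene_factor
        base[design.class_markers[class_of[t]]] *= cfg.marker_fold
        base[design.type_markers[t]] *= cfg.marker_fold
        de_idx, boosted_region = design.region_de[t]
        for region in ("fovea", "periphery"):
            prof = base.copy()
            if region == boosted_region:
                prof = prof.copy()
                prof[de_idx] *= cfg.region_fold
            profiles[(t, region)] = prof / prof.sum()
    return profiles


def _nb_counts(prof: np.ndarray, lib: np.ndarray, dispersion: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Negative binomial block: mean ``prof*lib``, var ``mu + theta*mu^2``."""
    mu = np.outer(prof, lib)
    shape = (1.0 / dispersion)[:, None]
    lam = rng.gamma(shape, mu / shape)
    return rng.poisson(lam)


def generate_atlas(config: SimConfig | None = None) -> SimulatedAtlas:
    """Generate the two-species synthetic atlas with ground truth.

    All randomness flows from ``config.seed``; identical configs give
    bit-identical outputs.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    design = _design_genes(cfg, rng)

    counts_a, meta_a, truth_a = _generate_species(
        cfg, design, rng, species=cfg.species_a, gene_factor=None,
        n_fovea=cfg.n_cells_fovea, n_periphery=cfg.n_cells_periphery,
        cell_prefix="A",
    )

    # species B: same type profiles with per-gene log-normal perturbation
    factor = rng.lognormal(0.0, cfg.species_b_perturb_sd, size=cfg.n_genes) \
        if cfg.species_b_perturb_sd > 0 else np.ones(cfg.n_genes)
    nb_f = cfg.n_cells_species_b // 2
    counts_b, meta_b, truth_b = _generate_species(
        cfg, design, rng, species=cfg.species_b, gene_factor=factor,
        n_fovea=nb_f, n_periphery=cfg.n_cells_species_b - nb_f,
        cell_prefix="B", artifact_free=True,
    )

    # rename species-B genes and build the partial 1:1 ortholog table
    b_names = np.array([f"m_{g}" for g in design.gene_ids], dtype=object)
    counts_b = CountMatrix(counts_b.counts, b_names, counts_b.cell_ids)
    n_orth = int(round(cfg.ortholog_fraction * cfg.n_genes))
    orth_idx = np.sort(rng.choice(cfg.n_genes, size=n_orth, replace=False))
    orthologs = OrthologTable(pd.DataFrame({
        "gene_a": design.gene_ids[orth_idx],
        "gene_b": b_names[orth_idx],
    }))

    panel = MarkerPanel({
        cls: [str(g) for g in design.gene_ids[idx]]
        for cls, idx in design.class_markers.items()
    })
    return SimulatedAtlas(
        counts=counts_a, metadata=meta_a, truth=truth_a,
        marker_panel=panel, orthologs=orthologs,
        counts_b=counts_b, metadata_b=meta_b, truth_b=truth_b,
        config=cfg, design=design,
    )


def _generate_species(cfg, design, rng, *, species, gene_factor, n_fovea, n_periphery,
                      cell_prefix, artifact_free=False):
    profiles = _type_profiles(cfg, design, gene_factor)
    class_of = cfg.class_of_type()
    props = cfg.proportions()
    type_names = np.array(cfg.type_names, dtype=object)

    regions = np.array(["fovea"] * n_fovea + ["periphery"] * n_periphery, dtype=object)
    n_cells = n_fovea + n_periphery
    types = np.empty(n_cells, dtype=object)
    if n_fovea:
        types[:n_fovea] = rng.choice(type_names, size=n_fovea, p=props["fovea"])
    if n_periphery:
        types[n_fovea:] = rng.choice(type_names, size=n_periphery, p=props["periphery"])

    donors = np.array([f"D{(i % cfg.n_donors) + 1}" for i in range(n_cells)], dtype=object)
    batches = np.array([f"b{(i % cfg.n_batches) + 1}" for i in range(n_cells)], dtype=object)
    enrichment = np.where(
        regions == "fovea", "none",
        np.where(np.arange(n_cells) % 2 == 0, "CD73_depleted", "CD90_enriched"),
    ).astype(object)
    cell_ids = np.array([f"{cell_prefix}{i:06d}" for i in range(n_cells)], dtype=object)

    lib = rng.lognormal(np.log(cfg.lib_size_mean) - cfg.lib_size_sigma**2 / 2,
                        cfg.lib_size_sigma, size=n_cells)

    batch_factor = None
    if cfg.batch_shift_sd > 0:
        batch_factor = {
            b: rng.lognormal(0.0, cfg.batch_shift_sd, size=cfg.n_genes)
            for b in sorted(set(batches))
        }

    # draw singlet counts grouped by (type, region[, batch])
    dense = np.zeros((cfg.n_genes, n_cells), dtype=np.int64)
    frame = pd.DataFrame({"type": types, "region": regions, "batch": batches})
    group_cols = ["type", "region"] + (["batch"] if batch_factor else [])
    for keys, idx in frame.groupby(group_cols, sort=True).groups.items():
        if not isinstance(keys, tuple):
            keys = (keys,)
        prof = profiles[(keys[0], keys[1])]
        if batch_factor:
            prof = prof * batch_factor[keys[2]]
            prof = prof / prof.sum()
        idx = np.asarray(idx)
        dense[:, idx] = _nb_counts(prof, lib[idx], design.dispersion, rng)

    is_doublet = np.zeros(n_cells, dtype=bool)
    is_lowq = np.zeros(n_cells, dtype=bool)
    second_type = np.full(n_cells, "", dtype=object)
    parent_1 = np.full(n_cells, "", dtype=object)
    parent_2 = np.full(n_cells, "", dtype=object)

    if not artifact_free and n_cells >= 4:
        flags = rng.random(n_cells)
        doublet_slots = np.flatnonzero(flags < cfg.doublet_rate)
        lowq_slots = np.flatnonzero((flags >= cfg.doublet_rate)
                                    & (flags < cfg.doublet_rate + cfg.lowq_rate))
        singlets = np.flatnonzero(~np.isin(np.arange(n_cells),
                                           np.concatenate([doublet_slots, lowq_slots])))
        median_lib = float(np.median(lib[singlets])) if len(singlets) else float(np.median(lib))

        for slot in doublet_slots:
            same_region = singlets[regions[singlets] == regions[slot]]
            if len(same_region) < 2:
                same_region = singlets
            p1 = rng.choice(same_region)
            other = same_region[types[same_region] != types[p1]]
            p2 = rng.choice(other if len(other) else same_region)
            combined = dense[:, p1] + dense[:, p2]
            if cfg.doublet_rescale and combined.sum() > 0:
                keep = min(1.0, 1.3 * median_lib / combined.sum())
                combined = rng.binomial(combined, keep)
            dense[:, slot] = combined
            is_doublet[slot] = True
            second_type[slot] = types[p2]
            parent_1[slot], parent_2[slot] = cell_ids[p1], cell_ids[p2]
            types[slot] = types[p1]

        for slot in lowq_slots:
            thinned = rng.binomial(dense[:, slot], cfg.lowq_depth_factor)
            non_mito_total = int(thinned.sum() - thinned[design.mito_idx].sum())
            target_mito = cfg.lowq_mito_frac / (1 - cfg.lowq_mito_frac) * max(non_mito_total, 1)
            thinned[design.mito_idx] = rng.multinomial(
                int(round(target_mito)), np.ones(len(design.mito_idx)) / len(design.mito_idx)
            )
            dense[:, slot] = thinned
            is_lowq[slot] = True

    counts = CountMatrix(sp.csc_matrix(dense), design.gene_ids.copy(), cell_ids)
    metadata = pd.DataFrame({
        "cell_id": cell_ids, "donor": donors, "region": regions,
        "enrichment": enrichment, "batch": batches, "species": species,
    })
    truth = pd.DataFrame({
        "cell_id": cell_ids,
        "true_type": types,
        "true_class": [class_of[t] for t in types],
        "region": regions,
        "donor": donors,
        "batch": batches,
        "is_doublet": is_doublet,
        "second_type": second_type,
        "parent_1": parent_1,
        "parent_2": parent_2,
        "is_low_quality": is_lowq,
        "species": species,
    })
    return counts, metadata, truth


def spike_disease_panel(
    atlas: SimulatedAtlas,
    classes: Sequence[str],
    n_robust: int = 10,
    n_failing: int = 10,
    groups: Sequence[str] = ("RP", "DOA", "AMD", "POAG"),
) -> pd.DataFrame:
    """Build a disease-gene list with known screen outcomes.

    Robust genes are class markers of the requested classes (strongly enriched,
    hence detected in >20% of that class with high mean); failing genes come
    from the generator's near-silent slice. Returns columns
    ``gene, group, override, truth_robust, truth_class``.
    """
    cfg = atlas.config
    for cls in classes:
        if cls not in cfg.class_names:
            raise ValueError(f"unknown class {cls!r}")
    design = atlas.design
    robust_pool = [
        (str(design.gene_ids[g]), cls)
        for cls in classes
        for g in design.class_markers[cls]
    ]
    if n_robust > len(robust_pool):
        raise ValueError(f"requested {n_robust} robust genes, pool has {len(robust_pool)}")
    if n_failing > len(design.low_idx):
        raise ValueError("not enough near-silent genes for the failing set")
    robust = robust_pool[:n_robust]
    failing = [str(design.gene_ids[g]) for g in design.low_idx[:n_failing]]
    rows = []
    for i, (gene, cls) in enumerate(robust):
        rows.append((gene, groups[i % len(groups)], False, True, cls))
    for i, gene in enumerate(failing):
        rows.append((gene, groups[i % len(groups)], False, False, ""))
    return pd.DataFrame(rows, columns=["gene", "group", "override", "truth_robust", "truth_class"])
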