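# retatlas

A tested, reusable pipeline for building cell atlases of primate retina from
droplet single-cell RNA-seq, and for the comparisons such atlases support:
fovea versus peripheral retina, one species' cell types against another's,
and the mapping of blinding-disease genes onto cell classes and types.

It is aimed at computational biologists who need the complete workflow —
from a UMI count matrix to annotated, curated cell types — as a library of
composable functions with explicit, reproducible thresholds, plus a CLI and
a synthetic-retina generator so every stage can be validated against ground
truth without any data download.

## What it computes

**Atlas construction.** Cells passing a detected-genes filter (≥ 600) are
log-normalized, `E_ij = ln(1 + c_ij · s / T_j)` with `s` the median library
size. Highly variable genes (binned dispersion z-scores) feed a PCA whose
dimensionality is set by random matrix theory: components whose eigenvalues
exceed the Marchenko–Pastur edge `(1 + √(p/n))²` (with a Tracy–Widom
finite-size allowance). Cells are clustered by Louvain modularity on a
Jaccard-weighted kNN graph, first into classes (annotated with a canonical
marker panel: rod/cone opsins, *GRM6*/*GRIK1*, *GAD1*/*SLC6A9*,
*RBPMS*/*SLC17A6*, *LHX1*/*ISL1*, ...), then within class into types.
Neighbouring dendrogram clusters are iteratively merged while at most 5
genes separate them at |logFC| ≥ 1.1, adjusted p < 0.001. Doublet-like
clusters (co-expression of two classes' markers, no private marker,
inflated gene counts) and low-quality clusters (shallow, high-mitochondrial)
are flagged and excluded.

**Differential expression.** One hurdle-style engine (detection chi-square
+ Welch t on expressing cells, Fisher-combined, BH-adjusted) backs cluster
merging, marker finding, and all downstream comparisons. logFC is the
natural-log difference of group means with zeros included.

**Cross-species mapping.** Per class, a gradient-boosted classifier trained
on a reference species over 1:1-ortholog features assigns each query cell a
reference type, cluster-agnostic. Confusion matrices (column percentages)
yield near-1:1 correspondences (forward ≥ τ = 50% plus reciprocal
plurality), and signature conservation per matched type is
`pDE_i = 100·|hDE_i ∩ mDE_i| / |hDE_i|`.

**Regional comparison.** Types with ≥ 20 cells in both regions are tested
for fovea/periphery DE (|logFC| ≥ 1, adjusted p < 0.001); per-donor
within-class proportion tables and group ratios complete the picture.

**Disease screen.** A gene list is screened for robust retinal expression
(detected in > 20% of cells of some class in either region, mean > 0.5),
with row-scaled class heatmaps, dot-plot statistics and regional profiles
for the genes that pass.

See `docs/methods.md` for the model, assumptions and all defaults.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from retatlas import SimConfig, generate_atlas, PipelineConfig, run_atlas

atlas = generate_atlas(SimConfig(seed=1))            # 8,000 cells, 6 classes, 20 types
result = run_atlas(atlas.counts, atlas.metadata, atlas.marker_panel,
                   PipelineConfig(seed=1))

labels = result.type_labels                          # flagged cells excluded
truth = atlas.truth.set_index("cell_id")
singlets = truth.index[(~truth.is_doublet) & (~truth.is_low_quality)]
common = labels.index.intersection(singlets)
ari = adjusted_rand_score(truth.loc[common, "true_type"], labels.loc[common])
print(f"recovered {result.n_types()} types (truth: {atlas.config.n_types}), ARI = {ari:.3f}")
```

```
recovered 20 types (truth: 20), ARI = 1.000
```

The pipeline recovered all 20 planted types and the partition of singlet
cells agrees perfectly with ground truth. Continuing with the regional
comparison on the recovered types:

```python
import numpy as np
from retatlas.preprocess import normalize_log
from retatlas.regional import regional_de

norm = normalize_log(atlas.counts)
cells = result.cells.set_index("cell_id")
kept = cells[~cells.doublet & ~cells.low_quality]
meta = atlas.metadata.set_index("cell_id").loc[kept.index]
rep = regional_de(norm.subset_cells(np.isin(norm.cell_ids, kept.index)),
                  kept["type"], meta["region"])
print(rep.summary.head(6).to_string(index=False))
```

```
type  n_fovea  n_periphery  tested  n_de
AC_1      128          162    True     3
AC_2      229           57    True     5
AC_3       53          226    True     4
AC_4      179           93    True     5
BC_1      317          120    True     5
BC_2       45          363    True     4
```

Every type has enough cells in both regions to be tested, and the number of
fovea/periphery DE genes per type (3–5) tracks the 5 regional DE genes the
generator plants per type at fold e^1.5 — a few fall below the |logFC| ≥ 1
threshold after sampling noise.

The same workflow is available from the shell:

```bash
retatlas all --out runs/demo --seed 1          # simulate → cluster → report
retatlas simulate --out runs/sim --seed 1      # artifacts for stage-wise runs
retatlas cluster --counts runs/sim/counts_a --metadata runs/sim/metadata_a.tsv \
    --markers runs/sim/markers.yaml --out runs/atlas
```

Each stage writes plain-text artifacts (Matrix Market counts, TSV labels
and reports) and appends to a `manifest.json` recording every threshold
used, so runs are auditable and repeatable.

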