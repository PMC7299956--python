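import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from conftest import make_norm
from retatlas.io import CountMatrix, ValidationError
from retatlas.preprocess import (
    compute_qc,
    filter_cells,
    normalize_log,
    pca_rmt,
    regress_batch,
    select_hvgs,
)


def _cm(values):
    values = np.asarray(values)
    return CountMatrix(
        sp.csc_matrix(values),
        np.array([f"g{i}" for i in range(values.shape[0])], object),
        np.array([f"c{j}" for j in range(values.shape[1])], object),
    )


class TestQcMetrics:
    def test_all_zero_cell(self):
        cm = CountMatrix(
            sp.csc_matrix(np.array([[0, 1], [0, 2]])),
            np.array(["a", "b"], object), np.array(["c0", "c1"], object),
        )
        qc = compute_qc(cm)
        row = qc.set_index("cell_id").loc["c0"]
        assert (row.n_genes_detected, row.n_transcripts, row.mito_fraction) == (0, 0, 0.0)

    def test_direct_arithmetic_with_mito(self):
        cm = CountMatrix(
            sp.csc_matrix(np.array([[3], [1]])),
            np.array(["GENE1", "MT-1"], object), np.array(["c"], object),
        )
        row = compute_qc(cm).iloc[0]
        assert row.n_genes_detected == 2
        assert row.n_transcripts == 4
        assert row.mito_fraction == pytest.approx(0.25)

    def test_lowq_cells_match_config_mito(self, small_atlas):
        qc = compute_qc(small_atlas.counts).set_index("cell_id")
        truth = small_atlas.truth.set_index("cell_id")
        lowq = qc.loc[truth.index[truth.is_low_quality], "mito_fraction"]
        assert abs(lowq.mean() - small_atlas.config.lowq_mito_frac) < 0.05


class TestFilterCells:
    def test_inclusive_boundary(self):
        # one cell detects 3 genes, the other 2
        cm = _cm([[1, 1], [1, 1], [1, 0]])
        out = filter_cells(cm, min_genes=3)
        assert list(out.cell_ids) == ["c0"]
        out2 = filter_cells(cm, min_genes=2)
        assert out2.n_cells == 2

    def test_idempotent(self, small_atlas):
        once = filter_cells(small_atlas.counts, 300)
        twice = filter_cells(once, 300)
        assert list(once.cell_ids) == list(twice.cell_ids)

    def test_planted_shallow_cells_removed(self):
        rng = np.random.default_rng(0)
        deep = rng.integers(1, 5, size=(100, 40))
        shallow = np.zeros((100, 7), dtype=int)
        shallow[:10, :] = 1  # only 10 genes detected
        cm = _cm(np.hstack([deep, shallow]))
        out = filter_cells(cm, min_genes=50)
        assert out.n_cells == 40

    def test_all_removed_raises_with_diagnostic(self):
        cm = _cm([[1, 1]])
        with pytest.raises(ValidationError, match="all 2 cells removed"):
            filter_cells(cm, min_genes=10)


class TestNormalizeLog:
    def test_zero_count_maps_to_zero(self):
        cm = _cm([[0, 4], [2, 0]])
        norm = normalize_log(cm)
        dense = norm.dense()
        assert dense[0, 0] == 0.0
        assert dense[1, 1] == 0.0

    def test_single_cell_scale_cancels(self):
        cm = _cm([[3], [5]])
        norm = normalize_log(cm)
        np.testing.assert_allclose(norm.dense().ravel(), np.log1p([3, 5]))

    def test_matches_two_line_oracle(self):
        counts = np.array([[1, 0], [4, 2], [0, 7]], dtype=float)
        cm = _cm(counts.astype(int))
        norm = normalize_log(cm)
        totals = counts.sum(axis=0)
        s = np.median(totals)
        expected = np.log1p(counts * s / totals)
        np.testing.assert_allclose(norm.dense(), expected, atol=1e-12)
        assert norm.scale_factor == s

    def test_monotone_within_cell(self, small_norm, small_atlas):
        col = small_norm.values[:, 17].toarray().ravel()
        raw = small_atlas.counts.counts[:, 17].toarray().ravel()
        order = np.argsort(raw)
        assert np.all(np.diff(col[order]) >= 0)

    def test_zero_total_cell_rejected(self):
        cm = _cm([[0, 1], [0, 1]])
        with pytest.raises(ValidationError, match="zero-total"):
            normalize_log(cm)


class TestSelectHvgs:
    def test_constant_gene_ranks_below_overdispersed(self):
        rng = np.random.default_rng(1)
        n_cells = 200
        flat = np.full(n_cells, 3.0)
        noisy = rng.negative_binomial(2, 0.2, size=(30, n_cells)).astype(float)
        vals = np.vstack([flat, noisy])
        norm = make_norm(vals)
        top = select_hvgs(norm, 10)
        assert "g0" not in top

    def test_permuting_cells_leaves_selection_unchanged(self, small_norm):
        top = select_hvgs(small_norm, 50)
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_norm.n_cells)
        top_perm = select_hvgs(small_norm.subset_cells(perm), 50)
        assert top == top_perm

    def test_planted_markers_enriched(self):
        """Planted markers are enriched >=5x over chance in the HVG set.

        Uses a sparse-marker genome (markers are a small fraction of genes)
        so the chance rate is meaningfully low.
        """
        from retatlas.simulate import SimConfig, generate_atlas
        from retatlas.preprocess import normalize_log

        cfg = SimConfig(
            n_cells_fovea=500, n_cells_periphery=500, n_cells_species_b=50,
            n_genes=1500, types_per_class=(1, 1, 1, 1, 1, 1), n_markers_per_type=8,
            n_markers_per_class=6, region_de_genes_per_type=4,
            doublet_rate=0.0, lowq_rate=0.0, seed=7,
        )
        atlas = generate_atlas(cfg)
        norm = normalize_log(atlas.counts)
        d = atlas.design
        markers = {
            str(d.gene_ids[g])
            for idx in list(d.type_markers.values()) + list(d.class_markers.values())
            for g in idx
        }
        n_top = 100
        top = set(select_hvgs(norm, n_top))
        hit_rate = len(top & markers) / n_top
        chance = len(markers) / norm.n_genes
        assert hit_rate >= 5 * chance


class TestRegressBatch:
    def test_single_batch_identity(self, small_norm):
        sub = small_norm.subset_cells(np.arange(50))
        out = regress_batch(sub, np.zeros(50))
        np.testing.assert_allclose(out.dense(), sub.dense(), atol=1e-12)

    def test_pure_batch_offset_removed_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(1.0, 0.2, size=(5, 60))
        batches = np.array(["A"] * 30 + ["B"] * 30)
        shifted = base.copy()
        shifted[:, :30] += 2.0
        out = regress_batch(make_norm(shifted), batches)
        dense = out.dense()
        gap = dense[:, :30].mean(axis=1) - dense[:, 30:].mean(axis=1)
        np.testing.assert_allclose(gap, 0.0, atol=1e-9)

    def test_injected_shift_reduces_batch_separation(self):
        """Batch silhouette in PC space drops after regression."""
        from sklearn.metrics import silhouette_score

        from retatlas.simulate import SimConfig, generate_atlas
        from retatlas.preprocess import normalize_log

        cfg = SimConfig(
            n_cells_fovea=300, n_cells_periphery=300, n_cells_species_b=50,
            n_genes=400, types_per_class=(1, 1, 1, 1, 1, 1), n_markers_per_type=8,
            n_markers_per_class=6, region_de_genes_per_type=4,
            batch_shift_sd=0.6, doublet_rate=0.0, lowq_rate=0.0, seed=5,
        )
        atlas = generate_atlas(cfg)
        norm = normalize_log(atlas.counts)
        batches = atlas.metadata["batch"].to_numpy()

        def batch_sil(n):
            emb = pca_rmt(n, 10)
            k = max(emb.n_sig, 2)
            scores = emb.scores if emb.n_sig >= 2 else pca_rmt(n, 10, tw_alpha=None).scores[:, :2]
            return silhouette_score(scores[:, :k], batches)

        before = batch_sil(norm)
        after = batch_sil(regress_batch(norm, batches))
        assert after < before

    def test_label_length_mismatch_rejected(self, small_norm):
        with pytest.raises(ValidationError):
            regress_batch(small_norm, np.array(["A", "B"]))


class TestPcaRmt:
    def test_trace_conserved(self):
        rng = np.random.default_rng(2)
        norm = make_norm(rng.standard_normal((60, 300)))
        emb = pca_rmt(norm, 60)
        # standardized matrix has total variance = number of retained genes
        assert emb.eigenvalues.sum() == pytest.approx(60, rel=1e-6)

    def test_eigenvalues_descending(self):
        rng = np.random.default_rng(3)
        emb = pca_rmt(make_norm(rng.standard_normal((50, 200))), 50)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-12)

    def test_duplicating_cells_preserves_leading_subspace(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((40, 150)) + 2.0 * np.outer(
            rng.standard_normal(40), rng.standard_normal(150)
        )
        n1 = pca_rmt(make_norm(base), 5, tw_alpha=None)
        n2 = pca_rmt(make_norm(np.hstack([base, base])), 5, tw_alpha=None)
        v1 = n1.loadings[:, 0]
        v2 = n2.loadings[:, 0]
        angle = np.arccos(np.clip(abs(v1 @ v2), 0, 1))
        assert angle < 1e-6

    def test_planted_rank_recovered(self):
        rng = np.random.default_rng(5)
        p, n, k = 150, 1200, 4
        X = rng.standard_normal((p, n)) + 3.0 * (
            rng.standard_normal((p, k)) @ rng.standard_normal((k, n)) / np.sqrt(p)
        )
        emb = pca_rmt(make_norm(X), 20)
        assert emb.n_sig == k

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValidationError):
            pca_rmt(make_norm(np.ones((5, 2))), 2)
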