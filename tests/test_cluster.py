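import numpy as np
import pandas as pd
import pytest

from conftest import make_norm
from retatlas.cluster import (
    assign_classes,
    build_graph,
    dendrogram_to_newick,
    flag_artifact_clusters,
    louvain_cluster,
    merge_clusters,
    subcluster_class,
)
from retatlas.io import MarkerPanel, ValidationError
from retatlas.preprocess import compute_qc, normalize_log


class TestBuildGraph:
    def test_two_blob_jaccard_matches_hand_computation(self):
        """10 points in two tight blobs, k=3: verify weights by brute force."""
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.05, (5, 2)), rng.normal(10, 0.05, (5, 2))])
        k = 3
        graph = build_graph(pts, k=k)
        # brute-force neighbour sets (self included among the k nearest)
        from scipy.spatial.distance import cdist

        d = cdist(pts, pts)
        sets = [set(np.argsort(d[i])[:k]) for i in range(10)]
        expected = {}
        for i in range(10):
            for j in range(i + 1, 10):
                if j in sets[i] or i in sets[j]:
                    w = len(sets[i] & sets[j]) / len(sets[i] | sets[j])
                    if w > 0:
                        expected[(i, j)] = w
        got = {tuple(sorted(e)): w for e, w in zip(map(tuple, graph.edges), graph.weights)}
        assert got.keys() == expected.keys()
        for key in expected:
            assert got[key] == pytest.approx(expected[key])

    def test_identical_neighbor_sets_give_weight_one(self):
        # two coincident points in a tight pair, far from a third blob
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 0.0], [10.1, 0.0], [10.2, 0.0]])
        graph = build_graph(pts, k=2)
        w = {tuple(sorted(e)): w for e, w in zip(map(tuple, graph.edges), graph.weights)}
        assert w[(0, 1)] == pytest.approx(1.0)

    def test_disjoint_blobs_have_no_cross_edges(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(50, 0.1, (20, 3))])
        graph = build_graph(pts, k=5)
        for (i, j) in map(tuple, graph.edges):
            assert (i < 20) == (j < 20)

    def test_k_validation(self):
        pts = np.random.default_rng(2).normal(size=(10, 2))
        with pytest.raises(ValueError):
            build_graph(pts, k=0)
        with pytest.raises(ValidationError):
            build_graph(pts, k=10)


class TestLouvain:
    def test_two_disconnected_cliques(self):
        # k covers each blob entirely, so each blob is a weight-1 clique and
        # the graph has exactly two components
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 0.1, (12, 2)), rng.normal(100, 0.1, (12, 2))])
        graph = build_graph(pts, k=12)
        labels = louvain_cluster(graph, seed=0)
        assert len(set(labels)) == 2
        assert len(set(labels[:12])) == 1
        assert len(set(labels[12:])) == 1

    def test_same_seed_identical_labels(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(200, 5))
        graph = build_graph(pts, k=10)
        l1 = louvain_cluster(graph, seed=7)
        l2 = louvain_cluster(graph, seed=7)
        np.testing.assert_array_equal(l1, l2)

    def test_labels_renumbered_by_size(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.1, (50, 2)), rng.normal(30, 0.1, (10, 2))])
        labels = louvain_cluster(build_graph(pts, k=4), seed=0)
        sizes = pd.Series(labels).value_counts()
        assert sizes.index[0] == 0  # biggest cluster gets label 0


class TestAssignClasses:
    def test_exclusive_markers_assign_with_positive_margin(self):
        # cluster 0 expresses A markers, cluster 1 expresses B markers
        vals = np.zeros((4, 40))
        vals[0:2, :20] = 3.0
        vals[2:4, 20:] = 3.0
        norm = make_norm(vals)
        norm.gene_ids = np.array(["a1", "a2", "b1", "b2"], object)
        labels = np.array([0] * 20 + [1] * 20)
        panel = MarkerPanel({"A": ["a1", "a2"], "B": ["b1", "b2"]})
        out = assign_classes(labels, norm, panel).set_index("cluster")
        assert out.loc[0, "class"] == "A"
        assert out.loc[1, "class"] == "B"
        assert (out["margin"] > 0).all()

    def test_tie_breaks_alphabetically_and_flags(self):
        vals = np.ones((2, 20))
        norm = make_norm(vals)
        norm.gene_ids = np.array(["m1", "m2"], object)
        labels = np.array([0] * 10 + [1] * 10)
        panel = MarkerPanel({"Zeta": ["m1"], "Alpha": ["m2"]})
        out = assign_classes(labels, norm, panel)
        assert (out["class"] == "Alpha").all()
        assert out["ambiguous"].all()

    def test_absent_marker_warns_and_missing_class_errors(self):
        norm = make_norm(np.ones((2, 10)))
        norm.gene_ids = np.array(["m1", "m2"], object)
        labels = np.zeros(10, dtype=int)
        with pytest.warns(UserWarning, match="absent"):
            assign_classes(labels, norm, MarkerPanel({"A": ["m1", "gone"], "B": ["m2"]}))
        with pytest.raises(ValidationError, match="no markers"):
            assign_classes(labels, norm, MarkerPanel({"A": ["gone"], "B": ["m2"]}))

    def test_synthetic_atlas_classes_recovered_via_truth_clusters(
        self, small_atlas, small_norm, singlet_mask
    ):
        """Clustering by true type, class assignment is right for >=99% of singlets."""
        truth = small_atlas.truth
        types = sorted(set(truth.true_type))
        t2i = {t: i for i, t in enumerate(types)}
        labels = np.array([t2i[t] for t in truth.true_type])
        out = assign_classes(labels, small_norm, small_atlas.marker_panel)
        cluster_class = dict(zip(out["cluster"], out["class"]))
        predicted = np.array([cluster_class[l] for l in labels], dtype=object)
        ok = predicted[singlet_mask] == truth.true_class.to_numpy()[singlet_mask]
        assert ok.mean() >= 0.99


@pytest.fixture(scope="module")
def doublet_scene():
    """Eight truth-derived clusters: six pure classes, one PR+BC doublet
    cluster, one depth-thinned high-mito low-quality cluster."""
    from retatlas.simulate import SimConfig, generate_atlas

    cfg = SimConfig(
        n_cells_fovea=600, n_cells_periphery=600, n_cells_species_b=50,
        n_genes=1500, types_per_class=(1, 1, 1, 1, 1, 1), n_markers_per_type=10,
        n_markers_per_class=8, region_de_genes_per_type=4,
        doublet_rate=0.25, lowq_rate=0.10, lowq_depth_factor=0.3,
        doublet_rescale=False, seed=9,
    )
    atlas = generate_atlas(cfg)
    norm = normalize_log(atlas.counts)
    qc = compute_qc(atlas.counts)
    truth = atlas.truth
    labels = np.full(atlas.counts.n_cells, -1)
    classes = sorted(set(truth.true_class))
    for i, cls in enumerate(classes):
        labels[(truth.true_class == cls) & ~truth.is_doublet & ~truth.is_low_quality] = i
    pairs = truth.is_doublet & (
        ((truth.true_class == "PR") & (truth.second_type.str.startswith("BC")))
        | ((truth.true_class == "BC") & (truth.second_type.str.startswith("PR")))
    )
    labels[pairs.to_numpy()] = len(classes)
    labels[truth.is_low_quality.to_numpy()] = len(classes) + 1
    keep = labels >= 0
    return atlas, norm.subset_cells(keep), qc[keep], labels[keep], truth[keep]


class TestFlagArtifacts:
    def test_doublet_cluster_flagged_and_pure_not(self, doublet_scene):
        atlas, norm, qc, labels, truth = doublet_scene
        assignments = assign_classes(labels, norm, atlas.marker_panel)
        flags = flag_artifact_clusters(labels, assignments, qc, norm, atlas.marker_panel)
        flags = flags.set_index("cluster")
        doublet_cluster = labels.max() - 1
        assert bool(flags.loc[doublet_cluster, "doublet"])
        pure = [c for c in flags.index if c < doublet_cluster]
        assert not flags.loc[pure, "doublet"].any()

    def test_lowq_cluster_flagged(self, doublet_scene):
        atlas, norm, qc, labels, truth = doublet_scene
        assignments = assign_classes(labels, norm, atlas.marker_panel)
        flags = flag_artifact_clusters(labels, assignments, qc, norm, atlas.marker_panel)
        flags = flags.set_index("cluster")
        lowq_cluster = labels.max()
        assert bool(flags.loc[lowq_cluster, "low_quality"])
        others = [c for c in flags.index if c != lowq_cluster]
        assert not flags.loc[others, "low_quality"].any()


class TestMergeClusters:
    def test_oversplit_type_is_merged(self, small_atlas, small_norm, singlet_mask):
        """One true type arbitrarily split in two collapses back to one."""
        truth = small_atlas.truth
        mask = (truth.true_type == "BC1").to_numpy() & singlet_mask
        sub = small_norm.subset_cells(mask)
        n = sub.n_cells
        labels = np.zeros(n, dtype=int)
        labels[n // 2:] = 1  # arbitrary split
        merged, _ = merge_clusters(labels, sub)
        assert len(set(merged)) == 1

    def test_distinct_types_never_merged(self, small_atlas, small_norm, singlet_mask):
        truth = small_atlas.truth
        mask = truth.true_type.isin(["BC1", "BC2"]).to_numpy() & singlet_mask
        sub = small_norm.subset_cells(mask)
        labels = (truth.true_type[mask] == "BC2").to_numpy().astype(int)
        merged, _ = merge_clusters(labels, sub)
        assert len(set(merged)) == 2

    def test_merge_is_a_fixed_point(self, small_atlas, small_norm, singlet_mask):
        truth = small_atlas.truth
        mask = (truth.true_class == "AC").to_numpy() & singlet_mask
        sub = small_norm.subset_cells(mask)
        types = sorted(set(truth.true_type[mask]))
        labels = np.array([types.index(t) for t in truth.true_type[mask]])
        once, _ = merge_clusters(labels, sub)
        twice, _ = merge_clusters(once, sub)
        assert len(set(once)) == len(set(twice))
        # same partition (labels may be renumbered)
        assert pd.crosstab(once, twice).astype(bool).sum().sum() == len(set(once))

    def test_cluster_count_nonincreasing_and_partition_preserved(
        self, small_atlas, small_norm, singlet_mask
    ):
        truth = small_atlas.truth
        mask = (truth.true_class == "BC").to_numpy() & singlet_mask
        sub = small_norm.subset_cells(mask)
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 6, size=sub.n_cells)
        merged, _ = merge_clusters(labels, sub)
        assert len(set(merged)) <= 6
        assert len(merged) == sub.n_cells


class TestSubclusterAndNewick:
    def test_subcluster_recovers_planted_types(self, small_atlas, small_norm, singlet_mask):
        truth = small_atlas.truth
        mask = (truth.true_class == "BC").to_numpy() & singlet_mask
        model = subcluster_class(small_atlas.counts, small_norm, "BC", mask, seed=0)
        assert model.n_clusters == 3  # BC has 3 planted types in the fixture
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(truth.true_type[mask], model.labels)
        assert ari >= 0.9

    def test_tiny_class_returns_single_type_with_warning(self, small_atlas, small_norm):
        mask = np.zeros(small_norm.n_cells, dtype=bool)
        mask[:10] = True
        with pytest.warns(UserWarning, match="one type"):
            model = subcluster_class(small_atlas.counts, small_norm, "HC", mask, k=30)
        assert model.n_clusters == 1

    def test_determinism_under_cell_permutation(self, small_atlas, small_norm, singlet_mask):
        truth = small_atlas.truth
        mask = (truth.true_class == "HC").to_numpy() & singlet_mask
        m1 = subcluster_class(small_atlas.counts, small_norm, "HC", mask, seed=1)
        m2 = subcluster_class(small_atlas.counts, small_norm, "HC", mask, seed=1)
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_newick_roundtrip_parses(self):
        from scipy.cluster import hierarchy

        rng = np.random.default_rng(1)
        Z = hierarchy.linkage(rng.normal(size=(5, 3)), method="complete")
        nwk = dendrogram_to_newick(Z, [f"T{i}" for i in range(5)])
        assert nwk.endswith(";")
        # parseable by Biopython
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == [f"T{i}" for i in range(5)]
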