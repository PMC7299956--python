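"""Supervised cross-species type correspondence.

For each cell class a gradient-boosted multi-class classifier is trained on
the reference species' cells over 1:1 ortholog features, then applied to
query cells of the same class, agnostic to their cluster identity. The
query-cluster × reference-type confusion matrix (column percentages) yields
"near 1:1" correspondences; conservation of type signatures is quantified
by pDE — the percentage of a type's query-species marker genes that are
also markers of the corresponding reference type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from xgboost import XGBClassifier

from .de import find_markers
from .io import OrthologTable, ValidationError
from .preprocess import NormalizedMatrix


@dataclass
class TypeClassifier:
    """Trained multi-class model plus the ortholog feature bookkeeping."""

    model: XGBClassifier
    type_names: list[str]
    features_ref: list[str]     # gene ids in the reference namespace
    features_query: list[str]   # the same features in the query namespace
    holdout_accuracy: float

    def predict_types(self, X: np.ndarray) -> np.ndarray:
        idx = self.model.predict(X)
        return np.array([self.type_names[i] for i in idx], dtype=object)


def train_type_classifier(
    ref_norm: NormalizedMatrix,
    ref_type_labels,
    ortho: OrthologTable,
    *,
    ref_is_species_b: bool = True,
    seed: int = 0,
    min_cells_per_type: int = 10,
    max_imbalance: float = 10.0,
    holdout_fraction: float = 0.2,
    n_estimators: int = 60,
    max_depth: int = 4,
    learning_rate: float = 0.3,
) -> TypeClassifier:
    """Train a gradient-boosted type classifier on ortholog expression.

    Features are the 1:1 ortholog genes present in the reference matrix;
    types with fewer than ``min_cells_per_type`` cells are excluded with a
    warning, and class imbalance is capped at ``max_imbalance``:1 by
    deterministic downsampling. Held-out accuracy (stratified
    ``holdout_fraction`` split) is recorded on the returned handle.
    """
    labels = np.asarray(ref_type_labels, dtype=object)
    if len(labels) != ref_norm.n_cells:
        raise ValidationError("type labels do not cover the reference cells")

    pairs = ortho.pairs
    ref_col, query_col = ("gene_b", "gene_a") if ref_is_species_b else ("gene_a", "gene_b")
    present = set(map(str, ref_norm.gene_ids))
    shared = pairs[pairs[ref_col].isin(present)]
    if len(shared) < 20:
        raise ValidationError(f"only {len(shared)} shared orthologs; need at least 20")
    features_ref = list(shared[ref_col])
    features_query = list(shared[query_col])

    counts = pd.Series(labels).value_counts()
    kept_types = sorted(counts[counts >= min_cells_per_type].index)
    dropped = sorted(set(counts.index) - set(kept_types))
    if dropped:
        warnings.warn(f"types excluded with <{min_cells_per_type} cells: {dropped}")
    if len(kept_types) < 2:
        raise ValidationError("need at least 2 reference types with enough cells")

    rng = np.random.default_rng(seed)
    cap = int(np.ceil(max_imbalance * counts[kept_types].min()))
    take = []
    for t in kept_types:
        idx = np.flatnonzero(labels == t)
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        take.append(np.sort(idx))
    take = np.concatenate(take)

    sub = ref_norm.subset_genes(features_ref).subset_cells(take)
    X = sub.dense().T.astype(np.float32)
    y_names = labels[take]
    y = np.array([kept_types.index(t) for t in y_names])

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    # objective left to the wrapper: binary logistic for 2 types,
    # multi-class softprob otherwise
    model = XGBClassifier(
        n_estimators=n_estimators, max_depth=max_depth, learning_rate=learning_rate,
        tree_method="hist", n_jobs=1, random_state=seed, verbosity=0,
    )
    model.fit(X_tr, y_tr)
    acc = float((model.predict(X_te) == y_te).mean())
    return TypeClassifier(
        model=model, type_names=list(kept_types),
        features_ref=features_ref, features_query=features_query,
        holdout_accuracy=acc,
    )


def map_cells(clf: TypeClassifier, query_norm: NormalizedMatrix,
              query_namespace: bool = True) -> np.ndarray:
    """Assign each query cell a reference type label (hard argmax).

    Cluster labels are never consulted. ``query_namespace`` selects which
    gene namespace to look features up in (query by default; set False when
    mapping reference cells back onto themselves).
    """
    feats = clf.features_query if query_namespace else clf.features_ref
    present = set(map(str, query_norm.gene_ids))
    missing = [g for g in feats if g not in present]
    if missing:
        raise ValidationError(
            f"{len(missing)} classifier features missing from query matrix "
            f"(e.g. {missing[:3]})"
        )
    X = query_norm.subset_genes(feats).dense().T.astype(np.float32)
    return clf.predict_types(X)


def confusion(query_cluster_labels, predicted_ref_types) -> pd.DataFrame:
    """Reference-type × query-cluster matrix of column percentages.

    Entry (r, q) is the percentage of query cluster q's cells the
    classifier assigned to reference type r; columns sum to 100.
    """
    q = np.asarray(query_cluster_labels)
    r = np.asarray(predicted_ref_types)
    if len(q) != len(r):
        raise ValidationError("label arrays differ in length")
    tab = pd.crosstab(pd.Series(r, name="ref_type"), pd.Series(q, name="query_cluster"))
    col_sums = tab.sum(axis=0)
    if (col_sums == 0).any():
        raise ValidationError("empty query cluster in confusion matrix")
    return tab / col_sums * 100.0


def call_correspondences(conf: pd.DataFrame, tau: float = 50.0) -> pd.DataFrame:
    """Call near-1:1 matches from a confusion matrix.

    A query cluster q is matched to reference type r iff the forward
    percentage ``conf[r, q] >= tau``, r is the plurality row of column q,
    and q is the plurality column of row r (reciprocal plurality).
    Unmatched clusters are reported with ``matched=False``.
    """
    if not 0 < tau <= 100:
        raise ValueError("tau must lie in (0, 100]")
    best_row = conf.idxmax(axis=0)       # per query cluster
    best_col = conf.idxmax(axis=1)       # per reference type
    rows = []
    for q in conf.columns:
        r = best_row[q]
        forward = float(conf.loc[r, q])
        reciprocal = bool(best_col[r] == q)
        matched = bool(forward >= tau and reciprocal)
        rows.append({
            "query_cluster": q,
            "ref_type": r if matched else None,
            "forward_pct": forward,
            "reciprocal": reciprocal,
            "matched": matched,
        })
    return pd.DataFrame(rows)


def compute_pde(hde, mde, ortho: OrthologTable | None = None) -> float:
    """Shared-marker percentage pDE = 100 · |hDE ∩ mDE| / |hDE|.

    ``hde`` is the query-species (denominator) marker set; ``mde`` the
    reference-species set, translated into the query namespace through the
    1:1 ortholog table when one is given (reference genes without an
    ortholog are dropped from ``mde`` only). An empty ``hde`` is undefined
    and returns NaN, not 0.
    """
    hde = set(hde)
    mde = set(mde)
    if not hde:
        return float("nan")
    if ortho is not None:
        b2a = ortho.b_to_a()
        mde = {b2a[g] for g in mde if g in b2a}
    return 100.0 * len(hde & mde) / len(hde)


def type_markers_for_pde(
    norm: NormalizedMatrix,
    type_labels,
    class_labels,
    *,
    min_pct: float = 0.2,
    min_lfc: float = 0.5,
    alpha: float = 0.001,
) -> dict[str, set[str]]:
    """Type-specific DE gene sets (each type vs the rest of its class)."""
    type_labels = np.asarray(type_labels, dtype=object)
    class_labels = np.asarray(class_labels, dtype=object)
    out: dict[str, set[str]] = {}
    for cls in sorted(set(class_labels)):
        scope = class_labels == cls
        types = sorted(set(type_labels[scope]))
        if len(types) < 2:
            continue
        for t in types:
            if (scope & (type_labels == t)).sum() < 3 or (scope & (type_labels != t)).sum() < 3:
                continue
            markers = find_markers(norm, type_labels, t, scope=scope,
                                   min_pct=min_pct, min_lfc=min_lfc, alpha=alpha)
            out[str(t)] = set(markers["gene"].astype(str))
    return out
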