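"""Biome identification from enrichment-pattern features.

A random forest is trained on the relative abundances of the enriched GO
terms and/or enriched host species taken from a fitted sphere model, and
evaluated by stratified k-fold cross-validation with an inner grid search
(tree depth x features-per-split) on each training fold.  Out-of-fold class
probabilities are pooled into single micro- and macro-averaged ROC/AUC
summaries, and accuracy/F1 come from the pooled out-of-fold hard
predictions -- in single-label multiclass evaluation micro-averaged recall
is identical to overall accuracy.  Stability selection (repeated stratified
half-subsampling, keeping features that repeatedly rank in the importance
top-q) is available for picking a robust feature subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import label_binarize

from enrichsphere.core_io import AbundanceTable
from enrichsphere.spheres import SphereModel

_GRID = {"max_depth": [None, 8, 16], "max_features": ["sqrt", "log2"]}


@dataclass
class FeatureMatrix:
    """Samples x enriched-feature abundance matrix with biome labels."""

    X: pd.DataFrame  # rows = samples, columns = features
    y: list[str]  # biome label per sample
    feature_types: dict[str, str]  # feature id -> "go_term" | "species"

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.y):
            raise ValueError("label count does not match sample count")
        if len(set(self.X.columns)) != self.X.shape[1]:
            raise ValueError("duplicate feature columns")
        if len(set(self.y)) < 2:
            raise ValueError("need at least 2 biome classes")
        if self.X.isna().any().any():
            raise ValueError("missing values in feature matrix")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.y))


@dataclass
class ClassifierReport:
    """Cross-validated evaluation of the biome classifier."""

    accuracy: float
    per_class: dict[str, dict[str, float]]  # precision/recall/f1/auc per biome
    micro: dict[str, float]
    macro: dict[str, float]
    fold_assignments: list[int]
    parameters: dict
    selected_features: list[str] | None = None
    selection_frequencies: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "micro": self.micro,
            "macro": self.macro,
            "fold_assignments": list(self.fold_assignments),
            "parameters": dict(self.parameters),
            "selected_features": self.selected_features,
            "selection_frequencies": self.selection_frequencies,
        }


def build_feature_matrix(
    tables: Sequence[AbundanceTable],
    model: SphereModel | Sequence[str],
    variant: str = "both",
) -> FeatureMatrix:
    """Restrict abundance tables to the model's enriched features.

    `tables` are proportion-stage tables sharing one sample set (typically
    one go_term and one species table).  With a :class:`SphereModel`, the
    term columns are the union of sphere members and the species columns the
    union of linked enriched hosts; an explicit feature-id list can be given
    instead.  ``variant`` picks ``"go"``, ``"species"`` or ``"both"``.
    A feature absent from a table contributes zeros.
    """
    if variant not in ("go", "species", "both"):
        raise ValueError(f"unknown variant {variant!r}")
    if not tables:
        raise ValueError("no abundance tables supplied")
    sample_ids = tables[0].sample_ids
    for t in tables:
        if t.stage != "proportion":
            raise ValueError("feature matrix expects proportion-stage tables")
        if t.sample_ids != sample_ids:
            raise ValueError("tables do not share one sample set")

    if isinstance(model, SphereModel):
        want_terms = model.enriched_terms if variant in ("go", "both") else []
        want_species = model.enriched_hosts if variant in ("species", "both") else []
    else:
        explicit = list(model)
        by_kind: dict[str, set[str]] = {"go_term": set(), "species": set()}
        for t in tables:
            by_kind.setdefault(t.kind, set()).update(t.feature_ids)
        want_terms = (
            [f for f in explicit if f in by_kind["go_term"]]
            if variant in ("go", "both")
            else []
        )
        want_species = (
            [f for f in explicit if f in by_kind["species"]]
            if variant in ("species", "both")
            else []
        )

    columns: dict[str, np.ndarray] = {}
    types: dict[str, str] = {}
    zeros = np.zeros(len(sample_ids))
    for kind, wanted in (("go_term", want_terms), ("species", want_species)):
        source = next((t for t in tables if t.kind == kind), None)
        for f in wanted:
            if source is not None and f in source.feature_ids:
                columns[f] = source.values[source.feature_ids.index(f), :]
            else:
                columns[f] = zeros
            types[f] = kind
    if not columns:
        raise ValueError("zero enriched features for this variant")
    X = pd.DataFrame(columns, index=sample_ids)
    y = [s.biome for s in tables[0].samples]
    return FeatureMatrix(X=X, y=y, feature_types=types)


def stability_select(
    matrix: FeatureMatrix,
    subsamples: int = 50,
    top_q: int = 20,
    threshold: float = 0.6,
    trees: int = 100,
    seed: int = 0,
) -> tuple[list[str], dict[str, float]]:
    """Stability selection by repeated stratified half-subsampling.

    Each round fits a random forest on a stratified half of the samples and
    records the `top_q` features by impurity importance; a feature is
    selected when its recording frequency reaches `threshold`.  Returns the
    selected list (sorted) and all per-feature frequencies.
    """
    if subsamples < 2:
        raise ValueError("subsamples must be >= 2")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    n_features = matrix.X.shape[1]
    if top_q >= n_features:
        raise ValueError(
            f"top_q ({top_q}) must be smaller than n_features ({n_features})"
        )
    rng = np.random.default_rng(seed)
    y = np.asarray(matrix.y)
    hits = dict.fromkeys(matrix.X.columns, 0)
    for _ in range(subsamples):
        idx: list[int] = []
        for c in matrix.classes:
            members = np.flatnonzero(y == c)
            take = max(1, len(members) // 2)
            idx.extend(rng.choice(members, size=take, replace=False))
        idx = sorted(idx)
        forest = RandomForestClassifier(
            n_estimators=trees, random_state=int(rng.integers(2**31))
        )
        forest.fit(matrix.X.iloc[idx], y[idx])
        top = np.argsort(forest.feature_importances_)[::-1][:top_q]
        for f in matrix.X.columns[top]:
            hits[f] += 1
    freqs = {f: h / subsamples for f, h in hits.items()}
    selected = sorted(f for f, fr in freqs.items() if fr >= threshold)
    return selected, freqs


def train_evaluate(
    matrix: FeatureMatrix,
    trees: int = 100,
    folds: int = 10,
    seed: int = 0,
) -> ClassifierReport:
    """Stratified k-fold evaluation of the biome random forest.

    Within each training fold a grid search over (max_depth in {None, 8, 16},
    max_features in {sqrt, log2}) is scored by inner 3-fold accuracy.
    Out-of-fold probabilities are pooled for per-class one-vs-rest ROC/AUC
    plus micro (all (sample, class) decisions pooled) and macro (unweighted
    class mean) averages; accuracy and F1 come from pooled hard predictions.
    Fully seeded and reproducible.
    """
    y = np.asarray(matrix.y)
    classes = matrix.classes
    counts = {c: int((y == c).sum()) for c in classes}
    too_small = {c: n for c, n in counts.items() if n < folds}
    if too_small:
        raise ValueError(
            f"classes with fewer samples than folds={folds}: {too_small}; "
            "use fewer folds"
        )
    ss = np.random.SeedSequence(seed)
    outer_seed, inner_seed, forest_seed = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
    )
    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=outer_seed)
    X = matrix.X.to_numpy()
    proba = np.zeros((len(y), len(classes)))
    pred = np.empty(len(y), dtype=object)
    fold_assignments = np.zeros(len(y), dtype=int)
    for fold, (train, test) in enumerate(outer.split(X, y)):
        search = GridSearchCV(
            RandomForestClassifier(n_estimators=trees, random_state=forest_seed),
            param_grid=_GRID,
            scoring="accuracy",
            cv=StratifiedKFold(n_splits=3, shuffle=True, random_state=inner_seed),
        )
        search.fit(X[train], y[train])
        est = search.best_estimator_
        p = est.predict_proba(X[test])
        # align estimator class order to the report's sorted class order
        order = [list(est.classes_).index(c) for c in classes]
        proba[test] = p[:, order]
        pred[test] = est.predict(X[test])
        fold_assignments[test] = fold

    accuracy = float((pred == y).mean())
    y_bin = label_binarize(y, classes=classes)
    if y_bin.shape[1] == 1:  # two classes: binarize to two explicit columns
        y_bin = np.column_stack([1 - y_bin[:, 0], y_bin[:, 0]])
    prec, rec, f1, _ = precision_recall_fscore_support(
        y, pred.astype(str), labels=classes, zero_division=0
    )
    per_class: dict[str, dict[str, float]] = {}
    aucs = []
    for i, c in enumerate(classes):
        if len(np.unique(proba[:, i])) == 1:
            auc = 0.5  # constant score: every threshold ties, AUC is 1/2
        else:
            auc = float(roc_auc_score(y_bin[:, i], proba[:, i]))
        aucs.append(auc)
        per_class[c] = {
            "precision": float(prec[i]),
            "recall": float(rec[i]),
            "f1": float(f1[i]),
            "auc": auc,
        }
    mprec, mrec, mf1, _ = precision_recall_fscore_support(
        y, pred.astype(str), labels=classes, average="micro", zero_division=0
    )
    micro = {
        "precision": float(mprec),
        "recall": float(mrec),
        "f1": float(mf1),
        "auc": float(roc_auc_score(y_bin.ravel(), proba.ravel())),
    }
    macro = {
        "precision": float(np.mean(prec)),
        "recall": float(np.mean(rec)),
        "f1": float(np.mean(f1)),
        "auc": float(np.mean(aucs)),
    }
    return ClassifierReport(
        accuracy=accuracy,
        per_class=per_class,
        micro=micro,
        macro=macro,
        fold_assignments=fold_assignments.tolist(),
        parameters={
            "trees": trees,
            "folds": folds,
            "seed": seed,
            "grid": {k: [str(v) for v in vs] for k, vs in _GRID.items()},
        },
    )
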