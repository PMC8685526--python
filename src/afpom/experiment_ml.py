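"""Design grid, Random-Forest inducibility classifier, decision-path mining.

The experiment grid is the full Cartesian product of accepted profiles, the
two tissue sizes and the four pharmacological conditions.  Drugs enter the
feature space only through the *effective* multipliers (profile multipliers
scaled by the drug's conductance factors), so all conditions share one
10-dimensional feature space: the nine effective multipliers plus the tissue
area in cm^2.

Prediction uses a Random Forest (500 trees, sqrt-features per split) with a
stratified 80/20 train/test split and 5-fold cross-validation on the training
portion.  Interpretability comes from a single depth-limited CART tree fitted
on all rows, whose root-to-leaf paths export as a sunburst-style nested
structure (ring i = depth-i split, leaves colored by label).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .cell_model import MULTIPLIER_NAMES, IonicProfile
from .drug_model import CONDITION_ORDER, DrugSpec, condition_drug, effective_multipliers
from .errors import DegenerateLabelError, RangeError, SchemaError
from .synthetic_data import SIZE_AREAS, GeneratorRule

FEATURES = list(MULTIPLIER_NAMES) + ["tissue_area"]
LABELS = ("induced", "non_inducible")


# ---------------------------------------------------------------------------
# design grid
# ---------------------------------------------------------------------------

def build_design(profiles: Sequence[IonicProfile],
                 sizes: Sequence[str] = ("normal", "dilated"),
                 conditions: Sequence[str] = CONDITION_ORDER,
                 drug_library: dict[str, DrugSpec] | None = None) -> pd.DataFrame:
    """Unlabeled design table: one row per (profile, size, condition).

    Multiplier columns hold the post-drug effective values; ordering is
    deterministic (profile-major, then size, then condition).
    """
    if not profiles or not sizes or not conditions:
        raise RangeError("profiles, sizes and conditions must be non-empty")
    ids = [p.profile_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise RangeError("duplicate profile_id in the population")
    rows = []
    for prof in profiles:
        base = prof.as_array()
        for size in sizes:
            if size not in SIZE_AREAS:
                raise RangeError(f"unknown tissue size {size!r}")
            for cond in conditions:
                drug = condition_drug(cond, drug_library)
                eff = effective_multipliers(base, drug, MULTIPLIER_NAMES)
                row = {"profile_id": prof.profile_id, "tissue": size,
                       "tissue_area": SIZE_AREAS[size], "condition": cond}
                row.update(dict(zip(MULTIPLIER_NAMES, eff)))
                rows.append(row)
    return pd.DataFrame(rows, columns=["profile_id", "tissue", "tissue_area",
                                       "condition", *MULTIPLIER_NAMES])


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    forest: RandomForestClassifier
    features: list[str]
    importances: pd.Series          # non-negative, sums to 1
    cv_scores: np.ndarray           # k fold accuracies on the training split
    holdout_accuracy: float
    split_seed: int
    n_train: int
    n_test: int


def _validate_labeled(table: pd.DataFrame, features: Sequence[str]) -> None:
    missing = [c for c in list(features) + ["label"] if c not in table.columns]
    if missing:
        raise SchemaError(f"table lacks required columns: {missing}")
    classes = set(table["label"].unique())
    if len(classes) < 2:
        raise DegenerateLabelError(
            f"training table has a single outcome class {classes}; "
            "cannot fit a classifier")


def train_classifier(table: pd.DataFrame, train_frac: float = 0.8, k: int = 5,
                     seed: int = 0, n_estimators: int = 500,
                     drop_features: Sequence[str] = ()) -> TrainedClassifier:
    """Stratified 80/20 split, k-fold CV on the training part, fit, evaluate."""
    if not (0.0 < train_frac < 1.0):
        raise RangeError("train_frac must be in (0, 1)")
    features = [f for f in FEATURES if f not in set(drop_features)]
    _validate_labeled(table, features)
    X = table[features].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_frac, stratify=y, random_state=seed)
    forest = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt", random_state=seed,
        n_jobs=1)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    cv_scores = cross_val_score(forest, X_tr, y_tr, cv=cv)
    forest.fit(X_tr, y_tr)
    holdout = float(forest.score(X_te, y_te))
    importances = pd.Series(forest.feature_importances_, index=features)
    return TrainedClassifier(forest=forest, features=features,
                             importances=importances, cv_scores=cv_scores,
                             holdout_accuracy=holdout, split_seed=seed,
                             n_train=len(y_tr), n_test=len(y_te))


def predict_inducibility(clf: TrainedClassifier, row) -> tuple[str, float]:
    """Label and induced-class probability for one design row."""
    if isinstance(row, pd.DataFrame):
        data = row
    elif isinstance(row, pd.Series):
        data = row.to_frame().T
    else:
        data = pd.DataFrame([row])
    missing = [f for f in clf.features if f not in data.columns]
    if missing:
        raise SchemaError(f"row lacks features {missing}")
    X = data[clf.features].to_numpy(dtype=float)
    label = str(clf.forest.predict(X)[0])
    proba = clf.forest.predict_proba(X)[0]
    p_induced = float(proba[list(clf.forest.classes_).index("induced")])
    return label, p_induced


# ---------------------------------------------------------------------------
# interpretability tree and sunburst export
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathStep:
    feature: str
    threshold: float
    direction: str  # 'le' (went left, value <= threshold) or 'gt'


@dataclass
class DecisionPath:
    steps: tuple[PathStep, ...]
    leaf_label: str
    support: int
    leaf_id: int

    @property
    def depth(self) -> int:
        return len(self.steps)


@dataclass
class DecisionTreeSummary:
    tree: DecisionTreeClassifier
    features: list[str]
    paths: list[DecisionPath]
    sunburst: dict
    root_feature: str | None
    root_threshold: float | None


def extract_decision_paths(table: pd.DataFrame, max_depth: int = 7,
                           seed: int = 0,
                           drop_features: Sequence[str] = ()) -> DecisionTreeSummary:
    """Fit one CART tree (Gini, depth <= max_depth) on all rows and enumerate
    its root-to-leaf paths plus the nested sunburst structure."""
    features = [f for f in FEATURES if f not in set(drop_features)]
    _validate_labeled(table, features)
    X = table[features].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    tree = DecisionTreeClassifier(max_depth=max_depth, criterion="gini",
                                  random_state=seed)
    tree.fit(X, y)
    t = tree.tree_
    classes = list(tree.classes_)

    paths: list[DecisionPath] = []

    def node_dict(node: int, steps: tuple[PathStep, ...]) -> dict:
        if t.children_left[node] == -1:  # leaf
            counts = t.value[node][0]
            label = classes[int(np.argmax(counts))]
            support = int(counts.sum())
            paths.append(DecisionPath(steps=steps, leaf_label=str(label),
                                      support=support, leaf_id=node))
            return {"name": "leaf", "label": str(label), "support": support}
        feat = features[t.feature[node]]
        thr = float(t.threshold[node])
        left = node_dict(t.children_left[node],
                         steps + (PathStep(feat, thr, "le"),))
        right = node_dict(t.children_right[node],
                          steps + (PathStep(feat, thr, "gt"),))
        return {"name": feat, "threshold": thr, "children": [left, right]}

    sunburst = node_dict(0, ())
    if t.children_left[0] != -1:
        root_feature = features[t.feature[0]]
        root_threshold = float(t.threshold[0])
    else:
        root_feature = root_threshold = None
    return DecisionTreeSummary(tree=tree, features=features, paths=paths,
                               sunburst=sunburst, root_feature=root_feature,
                               root_threshold=root_threshold)


def archetypes_recovered(summary: DecisionTreeSummary, table: pd.DataFrame,
                         rule: GeneratorRule, min_purity: float = 0.5) -> list[bool]:
    """For each AND-clause of ``rule``: does some induced leaf collect rows
    that are mostly (``> min_purity``) inside that clause's region?"""
    X = table[summary.features].to_numpy(dtype=float)
    leaf_of_row = summary.tree.apply(X)
    results = []
    for clause in rule.clauses:
        mask = np.ones(len(table), dtype=bool)
        for c in clause:
            col = table[c.feature].to_numpy()
            mask &= (col > c.threshold) if c.direction == "gt" else (col < c.threshold)
        found = False
        for path in summary.paths:
            if path.leaf_label != "induced":
                continue
            in_leaf = leaf_of_row == path.leaf_id
            if in_leaf.sum() == 0:
                continue
            if mask[in_leaf].mean() > min_purity:
                found = True
                break
        results.append(found)
    return results
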