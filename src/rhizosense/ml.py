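"""Predicting binned normalized uptake from salt descriptors.

The normalized rate of uptake of a salt is discretized into 2-6 ranges (two
ranges is plain "uptake vs no uptake", split at ratio = 1) and predicted from
physicochemical descriptors of the salt's ions — identity, charge, mass,
periodic-table group, and nutrient class — with a gradient-boosted
decision-tree classifier evaluated by 5-fold cross-validation.  Performance
is summarized by per-fold confusion matrices and the F1 score
F1 = 2 * precision * recall / (precision + recall), macro-averaged over
classes for multi-range models and averaged over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from xgboost import XGBClassifier

from . import ions

__all__ = [
    "SaltFeatureVector",
    "ClassificationReport",
    "MLError",
    "BOOSTER_DEFAULTS",
    "build_feature_table",
    "encode_features",
    "bin_uptake",
    "f1_from_confusion",
    "crossval_classify",
]


class MLError(ValueError):
    pass


#: Booster hyperparameters: shallow trees, 100 rounds, learning rate 0.3.
BOOSTER_DEFAULTS = dict(
    max_depth=3,
    n_estimators=100,
    learning_rate=0.3,
    n_jobs=1,
    tree_method="hist",
    verbosity=0,
)


@dataclass(frozen=True)
class SaltFeatureVector:
    """Physicochemical and nutrient-category descriptors of one salt."""

    salt_name: str
    cation_symbol: str
    anion_symbol: str
    cation_charge: int
    anion_charge: int
    cation_count: int
    anion_count: int
    cation_mass: float
    anion_mass: float
    salt_molar_mass: float
    cation_group: int
    anion_group: int
    cation_nutrient_class: str
    anion_nutrient_class: str

    def __post_init__(self):
        if self.cation_charge <= 0 or self.anion_charge >= 0:
            raise MLError("cation charge must be positive, anion negative")
        if min(self.cation_mass, self.anion_mass, self.salt_molar_mass) <= 0:
            raise MLError("masses must be positive")
        if (
            self.cation_count * self.cation_charge
            + self.anion_count * self.anion_charge
            != 0
        ):
            raise MLError(f"salt {self.salt_name!r} is not charge-neutral")


def build_feature_vector(salt_name: str) -> SaltFeatureVector:
    cat_sym, an_sym, n_cat, n_an = ions.parse_salt(salt_name)
    cat, an = ions.CATIONS[cat_sym], ions.ANIONS[an_sym]
    return SaltFeatureVector(
        salt_name=salt_name,
        cation_symbol=cat_sym,
        anion_symbol=an_sym,
        cation_charge=cat.charge,
        anion_charge=an.charge,
        cation_count=n_cat,
        anion_count=n_an,
        cation_mass=cat.mass,
        anion_mass=an.mass,
        salt_molar_mass=n_cat * cat.mass + n_an * an.mass,
        cation_group=cat.group,
        anion_group=an.group,
        cation_nutrient_class=cat.nutrient_class,
        anion_nutrient_class=an.nutrient_class,
    )


def build_feature_table(salt_names: Sequence[str]) -> pd.DataFrame:
    """Deterministic descriptor table, one row per salt name (repeats allowed)."""
    if len(salt_names) == 0:
        raise MLError("empty salt list")
    rows = [vars(build_feature_vector(s)) for s in salt_names]
    return pd.DataFrame(rows)


_CATEGORICAL = (
    "cation_symbol",
    "anion_symbol",
    "cation_nutrient_class",
    "anion_nutrient_class",
)


def encode_features(table: pd.DataFrame) -> np.ndarray:
    """Numeric design matrix: numeric columns pass through, categoricals are
    ordinal-coded against their sorted global vocabulary (deterministic)."""
    cols = []
    for col in table.columns:
        if col == "salt_name":
            continue
        s = table[col]
        if col in _CATEGORICAL or s.dtype == object:
            vocab = {v: i for i, v in enumerate(sorted(s.astype(str).unique()))}
            cols.append(s.astype(str).map(vocab).to_numpy(dtype=float))
        else:
            cols.append(s.to_numpy(dtype=float))
    return np.column_stack(cols)


def bin_uptake(
    ratios: Sequence[float],
    n_ranges: int,
    boundaries: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Discretize normalized uptake ratios into ``n_ranges`` ordinal labels.

    Two ranges split uptake (ratio > 1, label 1) from no uptake (ratio <= 1,
    label 0).  For 3-6 ranges the first boundary stays at 1 and the remaining
    bins are equal-width between 1 and the observed maximum, top bin
    right-closed; an explicit ``boundaries`` list (the inner edges) overrides
    that rule.
    """
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise MLError("empty ratio list")
    if not np.all(np.isfinite(r)):
        raise MLError("ratios must be finite")
    if n_ranges not in (2, 3, 4, 5, 6):
        raise MLError("n_ranges must be in 2..6")
    if boundaries is not None:
        edges = np.asarray(boundaries, dtype=float)
        if len(edges) != n_ranges - 1 or np.any(np.diff(edges) <= 0):
            raise MLError("boundaries must be n_ranges-1 increasing values")
    else:
        rmax = float(r.max())
        if n_ranges == 2 or rmax <= 1.0:
            edges = np.ones(1)
        else:
            width = (rmax - 1.0) / (n_ranges - 1)
            edges = 1.0 + width * np.arange(n_ranges - 1)
    # label = number of edges strictly below the value; bins are (e, e'] and
    # values beyond the last edge land in the top bin
    labels = np.searchsorted(edges, r, side="left")
    return np.minimum(labels, n_ranges - 1).astype(int)


def f1_from_confusion(confusion, averaging: str = "macro") -> float:
    """F1 from a confusion matrix (rows = true class, columns = predicted).

    Per class, precision = TP/predicted and recall = TP/actual with the
    0/0 -> 0 convention; F1 = 2PR/(P+R).  ``macro`` averages per-class F1,
    skipping classes absent from both axes; ``micro`` pools counts;
    ``binary`` is the plain two-class formula with class 1 as positive.
    """
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or C.size == 0:
        raise MLError("confusion matrix must be square and non-empty")
    if np.any(C < 0):
        raise MLError("confusion matrix entries must be non-negative")
    tp = np.diag(C)
    pred = C.sum(axis=0)
    actual = C.sum(axis=1)

    def _f1(p, r):
        return 0.0 if p + r == 0 else 2 * p * r / (p + r)

    if averaging == "binary":
        if C.shape[0] != 2:
            raise MLError("binary averaging needs a 2x2 matrix")
        p = tp[1] / pred[1] if pred[1] > 0 else 0.0
        r = tp[1] / actual[1] if actual[1] > 0 else 0.0
        return float(_f1(p, r))
    if averaging == "micro":
        total = C.sum()
        return float(tp.sum() / total) if total > 0 else 0.0
    if averaging != "macro":
        raise MLError(f"unknown averaging {averaging!r}")
    f1s = []
    for i in range(C.shape[0]):
        if pred[i] == 0 and actual[i] == 0:
            continue  # class never present, never predicted
        p = tp[i] / pred[i] if pred[i] > 0 else 0.0
        r = tp[i] / actual[i] if actual[i] > 0 else 0.0
        f1s.append(_f1(p, r))
    if not f1s:
        raise MLError("no class present in confusion matrix")
    return float(np.mean(f1s))


@dataclass
class ClassificationReport:
    """Cross-validated classification outcome for one range count."""

    n_ranges: int
    per_fold_confusions: List[np.ndarray]
    pooled_confusion: np.ndarray
    fold_f1s: List[float]
    f1: float
    degenerate_folds: List[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_ranges": self.n_ranges,
            "per_fold_confusions": [c.tolist() for c in self.per_fold_confusions],
            "pooled_confusion": self.pooled_confusion.tolist(),
            "fold_f1s": self.fold_f1s,
            "f1": self.f1,
            "degenerate_folds": self.degenerate_folds,
        }


def crossval_classify(
    features,
    labels: Sequence[int],
    n_folds: int = 5,
    seed: int = 0,
    booster_params: Optional[Dict] = None,
) -> ClassificationReport:
    """Seeded k-fold cross-validation of the boosted-tree range classifier.

    Folds are stratified when every class has at least ``n_folds`` members,
    otherwise plain shuffled folds.  The model is trained on the training
    folds only; each held-out fold contributes one confusion matrix.  F1 is
    the two-class formula for binary labels and the macro average otherwise,
    averaged over folds.  Folds whose training part misses a class are
    recorded as degenerate.
    """
    X = encode_features(features) if isinstance(features, pd.DataFrame) else np.asarray(
        features, dtype=float
    )
    y = np.asarray(labels, dtype=int)
    if len(X) != len(y):
        raise MLError("features and labels differ in length")
    if len(y) < n_folds:
        raise MLError(f"need >= {n_folds} samples")
    classes = np.unique(y)
    n_classes = len(classes)
    remap = {c: i for i, c in enumerate(classes)}
    y01 = np.array([remap[c] for c in y])

    counts = np.bincount(y01)
    if counts.min() >= n_folds:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, y01)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X)

    params = dict(BOOSTER_DEFAULTS)
    if booster_params:
        params.update(booster_params)

    per_fold = []
    fold_f1s = []
    degenerate = []
    averaging = "binary" if n_classes == 2 else "macro"
    for fold_i, (train, test) in enumerate(splits):
        y_tr = y01[train]
        seen = np.unique(y_tr)
        if len(seen) < n_classes:
            degenerate.append(fold_i)
        inner = {c: i for i, c in enumerate(seen)}
        model = XGBClassifier(random_state=seed, **params)
        model.fit(X[train], np.array([inner[c] for c in y_tr]))
        pred_inner = model.predict(X[test])
        pred = seen[pred_inner]
        C = np.zeros((n_classes, n_classes), dtype=int)
        for t, p in zip(y01[test], pred):
            C[t, p] += 1
        per_fold.append(C)
        fold_f1s.append(f1_from_confusion(C, averaging=averaging))
    pooled = np.sum(per_fold, axis=0)
    return ClassificationReport(
        n_ranges=n_classes,
        per_fold_confusions=per_fold,
        pooled_confusion=pooled,
        fold_f1s=fold_f1s,
        f1=float(np.mean(fold_f1s)),
        degenerate_folds=degenerate,
    )
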