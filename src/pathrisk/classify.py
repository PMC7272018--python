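"""Linear-SVM classification of samples from pathway-score features.

Recursive feature elimination (SVM-RFE) picks the feature-set size with the
best stratified cross-validated accuracy; clinical covariates can then be
appended as additional features; final performance is reported as per-fold
ROC/AUC from 5-fold cross-validation.  Features are standardised inside each
training fold only — held-out samples are scaled with the training fold's
mean and SD, never their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

CLINICAL_NUMERIC = ("age", "smoking_duration", "smoking_index", "nodule_size")
CLINICAL_BINARY = ("gender", "lymphadenopathy")


@dataclass
class FeatureTable:
    values: pd.DataFrame     # feature × sample
    provenance: pd.Series    # feature -> {"pathway", "clinical"}

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("feature table contains missing values")

    def append(self, other: "FeatureTable") -> "FeatureTable":
        if not self.values.columns.equals(other.values.columns):
            other_vals = other.values[self.values.columns]
        else:
            other_vals = other.values
        return FeatureTable(
            values=pd.concat([self.values, other_vals]),
            provenance=pd.concat([self.provenance, other.provenance]),
        )


@dataclass
class RFECurve:
    sizes: list[int]
    accuracies: list[float]
    retained: list[list[str]]      # feature names at each evaluated size
    optimum_size: int
    optimum_features: list[str]


@dataclass
class CVReport:
    fold_rocs: list[tuple]         # (fpr array, tpr array) per fold
    fold_aucs: list[float]
    fold_accuracies: list[float]
    mean_auc: float
    mean_accuracy: float
    predictions: pd.Series = field(default=None)  # decision score per sample


def pathway_features(scores: pd.DataFrame) -> FeatureTable:
    """Wrap a term×sample score matrix as the pathway feature block."""
    return FeatureTable(
        values=scores.copy(),
        provenance=pd.Series("pathway", index=scores.index),
    )


def encode_clinical(annotations: pd.DataFrame) -> FeatureTable:
    """Encode the six clinical covariates as a numeric feature block.

    Gender and lymphadenopathy become 0/1; age, smoking duration, smoking
    index and nodule size are taken as numbers.  A missing value raises with
    the offending sample and field, since samples with incomplete clinical
    records are expected to be excluded upstream.
    """
    rows = {}
    for col in CLINICAL_NUMERIC + CLINICAL_BINARY:
        if col not in annotations.columns:
            raise ValueError(f"clinical field {col!r} missing from annotations")
        series = annotations[col]
        if series.isna().any():
            bad = series.index[series.isna()][0]
            raise ValueError(f"sample {bad!r} has missing clinical field {col!r}")
        if col in CLINICAL_BINARY:
            vals = series
            if vals.dtype == object:
                mapping = {"male": 1, "female": 0, "yes": 1, "no": 0, "1": 1, "0": 0}
                vals = vals.astype(str).str.lower().map(mapping)
                if vals.isna().any():
                    bad = series.index[vals.isna()][0]
                    raise ValueError(f"sample {bad!r}: cannot encode {col!r}")
            rows[col] = vals.astype(float)
        else:
            rows[col] = pd.to_numeric(series, errors="raise").astype(float)
    block = pd.DataFrame(rows).T
    block.columns = annotations.index
    return FeatureTable(values=block, provenance=pd.Series("clinical", index=block.index))


def _as_arrays(features: FeatureTable, labels) -> tuple[np.ndarray, np.ndarray]:
    labels = pd.Series(labels)
    if labels.index.inferred_type != "integer":
        labels = labels.reindex(features.values.columns)
        if labels.isna().any():
            raise ValueError("labels missing for some samples")
    y = (labels.to_numpy() == "case").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return features.values.to_numpy(float).T, y   # samples × features


def _fold_standardise(X_train, X_test):
    """Scale by training-fold statistics; drop training-zero-variance features."""
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    keep = sd > 0
    return (X_train[:, keep] - mu[keep]) / sd[keep], (X_test[:, keep] - mu[keep]) / sd[keep]


def _cv_accuracy(X, y, folds, seed, C) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        Xtr, Xte = _fold_standardise(X[tr], X[te])
        clf = SVC(kernel="linear", C=C).fit(Xtr, y[tr])
        accs.append(float((clf.predict(Xte) == y[te]).mean()))
    return float(np.mean(accs))


def rfe_select(
    features: FeatureTable,
    labels,
    step: int = 1,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> RFECurve:
    """SVM-RFE: rank by squared coefficient, drop ``step`` lowest, record CV
    accuracy at each feature-set size; the optimum is the size with maximal
    mean accuracy, ties broken toward fewer features."""
    X, y = _as_arrays(features, labels)
    names = list(features.values.index)
    if len(names) < 2:
        raise ValueError("RFE needs at least 2 features")
    if step >= len(names):
        raise ValueError("step must be smaller than the feature count")

    sizes, accs, retained = [], [], []
    current = list(range(len(names)))
    while True:
        sizes.append(len(current))
        retained.append([names[i] for i in current])
        accs.append(_cv_accuracy(X[:, current], y, folds, seed, C))
        if len(current) == 1:
            break
        mu = X[:, current].mean(axis=0)
        sd = X[:, current].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=C).fit((X[:, current] - mu) / sd, y)
        ranks = np.argsort(clf.coef_[0] ** 2)  # ascending importance
        n_drop = min(step, len(current) - 1)
        drop = set(ranks[:n_drop])
        current = [idx for i, idx in enumerate(current) if i not in drop]

    best_acc = max(accs)
    candidates = [i for i, a in enumerate(accs) if abs(a - best_acc) < 1e-12]
    best = min(candidates, key=lambda i: sizes[i])
    logger.info("RFE optimum: %d features, CV accuracy %.3f", sizes[best], accs[best])
    return RFECurve(
        sizes=sizes,
        accuracies=accs,
        retained=retained,
        optimum_size=sizes[best],
        optimum_features=retained[best],
    )


def svm_cv(
    features: FeatureTable,
    labels,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> CVReport:
    """Stratified k-fold linear-SVM evaluation with per-fold ROC and AUC.

    Samples are randomly permuted (seeded) and stratified into ``folds``
    parts; each part is predicted exactly once by a model trained on the
    rest.  ROC curves are built from decision-function scores, AUC by the
    trapezoidal rule; label prediction thresholds the decision function at 0.
    """
    X, y = _as_arrays(features, labels)
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {folds} folds; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rocs, aucs, accs = [], [], []
    scores = np.full(len(y), np.nan)
    for tr, te in skf.split(X, y):
        Xtr, Xte = _fold_standardise(X[tr], X[te])
        clf = SVC(kernel="linear", C=C).fit(Xtr, y[tr])
        dec = clf.decision_function(Xte)
        scores[te] = dec
        fpr, tpr, _ = roc_curve(y[te], dec)
        rocs.append((fpr, tpr))
        aucs.append(float(auc(fpr, tpr)))
        accs.append(float(((dec > 0).astype(int) == y[te]).mean()))
    return CVReport(
        fold_rocs=rocs,
        fold_aucs=aucs,
        fold_accuracies=accs,
        mean_auc=float(np.mean(aucs)),
        mean_accuracy=float(np.mean(accs)),
        predictions=pd.Series(scores, index=features.values.columns),
    )
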