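"""Class-masked odor decoding with a rank-based all-to-all AUC.

Decoders (LDA, kNN, linear SVM) are read-out proxies: trials are feature
vectors of per-cell response sizes with cells outside the requested
reliability class zeroed per odor.  Performance is reported as k-fold
accuracy and as the all-to-all AUC — for each ordered odor pair (i, j) the
Mann–Whitney probability, computed from rank sums of the predicted
probability of class i, that a class-i trial outscores a class-j trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .analysis import RELIABLE, SignificanceMask, UNRELIABLE


@dataclass
class PredictionMatrix:
    """Pooled test-set class probabilities with true labels.

    ``probabilities[t, k]`` is the predicted probability that test trial t
    belongs to odor class k; rows are non-negative and sum to one.
    """

    probabilities: np.ndarray
    true_labels: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < -1e-9):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        self.probabilities = p


def mask_by_class(
    mask: SignificanceMask, table: pd.DataFrame, cls: str
) -> np.ndarray:
    """Zero all cells outside the requested class, per odor.

    ``cls`` is ``"reliable"``, ``"unreliable"`` or ``"all"`` (all
    significantly responding cells).  A cell kept for one odor may be
    zeroed for another: class membership is per (cell, odor).  Idempotent.
    Returns response sizes of shape (cell, odor, trial) with
    non-significant trials zeroed as well.
    """
    if cls not in ("reliable", "unreliable", "all"):
        raise ValueError("cls must be 'reliable', 'unreliable' or 'all'")
    sizes = np.where(mask.responded, mask.response_size, 0.0)
    lab = table.pivot(index="cell", columns="odor", values="label").to_numpy()
    if cls == "all":
        keep = (lab == RELIABLE) | (lab == UNRELIABLE)
    else:
        keep = lab == cls
    return np.where(keep[:, :, None], sizes, 0.0)


def build_trial_matrix(masked_sizes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten (cell, odor, trial) activity into decoder rows.

    Returns X of shape (n_odors*n_trials, n_cells) and integer odor labels.
    """
    n_cells, n_odors, n_trials = masked_sizes.shape
    X = masked_sizes.transpose(1, 2, 0).reshape(n_odors * n_trials, n_cells)
    y = np.repeat(np.arange(n_odors), n_trials)
    return X, y


def _make_model(decoder: str, knn_k: int, svm_c: float):
    if decoder == "lda":
        return LinearDiscriminantAnalysis()
    if decoder == "knn":
        return KNeighborsClassifier(n_neighbors=knn_k)
    if decoder == "svm":
        return SVC(kernel="linear", C=svm_c, decision_function_shape="ovr")
    raise ValueError("decoder must be 'lda', 'knn' or 'svm'")


def _predict_proba(model, decoder: str, X: np.ndarray, n_classes: int,
                   classes_seen: np.ndarray) -> np.ndarray:
    """Class probabilities on the full label set, decoder-appropriate.

    kNN uses neighbour-vote fractions, LDA posterior probabilities, and the
    SVM a softmax over its decision values.
    """
    if decoder == "svm":
        d = model.decision_function(X)
        if d.ndim == 1:
            d = np.column_stack([-d, d])
        d = d - d.max(axis=1, keepdims=True)
        local = np.exp(d)
        local /= local.sum(axis=1, keepdims=True)
    else:
        local = model.predict_proba(X)
    proba = np.zeros((X.shape[0], n_classes))
    proba[:, classes_seen] = local
    return proba


def kfold_evaluate(
    masked_sizes: np.ndarray,
    decoder: str = "lda",
    fold_fraction: float = 0.2,
    seed: int = 0,
    knn_k: int = 3,
    svm_c: float = 1.0,
) -> tuple[float, PredictionMatrix]:
    """Stratified k-fold decoding; returns accuracy and pooled predictions.

    Folds hold out ``fold_fraction`` of trials (20% -> 5 folds), stratified
    so every odor appears in every fold; accuracy is the fraction of test
    trials whose predicted odor equals the truth, pooled over folds.
    """
    X, y = build_trial_matrix(masked_sizes)
    n_classes = masked_sizes.shape[1]
    n_splits = max(int(round(1.0 / fold_fraction)), 2)
    counts = np.bincount(y)
    if counts.min() < n_splits:
        raise ValueError(
            f"each odor needs at least {n_splits} trials for {n_splits}-fold splits"
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    proba = np.zeros((len(y), n_classes))
    predicted = np.zeros(len(y), dtype=int)
    for train, test in skf.split(X, y):
        model = _make_model(decoder, knn_k, svm_c)
        model.fit(X[train], y[train])
        proba[test] = _predict_proba(
            model, decoder, X[test], n_classes, model.classes_
        )
        predicted[test] = model.predict(X[test])
    accuracy = float((predicted == y).mean())
    return accuracy, PredictionMatrix(
        probabilities=proba, true_labels=y, classes=np.arange(n_classes)
    )


def pairwise_auc(pred: PredictionMatrix, i: int, j: int) -> dict:
    """Rank-sum AUC for an ordered odor pair and its symmetrized mean.

    AUC(i|j) ranks the pooled probabilities-of-being-class-i over the test
    trials of classes i and j (midranks on ties); with S_i the rank sum of
    the class-i trials, AUC(i|j) = (S_i − n_i(n_i+1)/2) / (n_i n_j) — the
    Mann–Whitney probability that a class-i trial outscores a class-j one.
    """
    def one_direction(a: int, b: int) -> float:
        sel_a = pred.true_labels == a
        sel_b = pred.true_labels == b
        n_a, n_b = int(sel_a.sum()), int(sel_b.sum())
        if n_a == 0 or n_b == 0:
            raise ValueError("need at least one test trial of each class")
        scores = np.concatenate(
            [pred.probabilities[sel_a, a], pred.probabilities[sel_b, a]]
        )
        ranks = rankdata(scores)
        s_a = ranks[:n_a].sum()
        return float((s_a - n_a * (n_a + 1) / 2) / (n_a * n_b))

    auc_ij = one_direction(i, j)
    auc_ji = one_direction(j, i)
    return {"auc_ij": auc_ij, "auc_ji": auc_ji, "mean": 0.5 * (auc_ij + auc_ji)}


def a2a_auc(pred: PredictionMatrix) -> float:
    """All-to-all AUC: unweighted mean of A(i,j) over unordered class pairs."""
    classes = np.unique(pred.true_labels)
    if classes.size < 2:
        raise ValueError("all-to-all AUC needs at least two classes")
    return float(
        np.mean([pairwise_auc(pred, i, j)["mean"] for i, j in combinations(classes, 2)])
    )
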