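"""Cross-validated shallow-network ensemble with ROC-based thresholds.

The classifier trains one shallow network per cross-validation fold (k=10
by default).  Within each fold, a stratified 15% validation part drives
early stopping, several random initialisations compete and the best one by
validation MCC is kept.  Each fold then receives its own decision threshold
chosen on the validation ROC curve, by one of two rules:

* **Approach A** - the first point of the ROC curve touched by a line of
  slope ``n_negative / n_positive`` sliding down from the ideal corner
  (FPR, TPR) = (0, 1); equivalently the point maximising
  ``TPR - slope * FPR``.
* **Approach B** (default) - the point minimising the Euclidean distance
  ``sqrt((1 - sensitivity)^2 + (1 - specificity)^2)`` to the ideal corner.

Prediction is a hard majority vote of the fold networks, each voting
positive (sclerotic) when its positive-class score reaches its threshold;
vote ties go to the positive class, since missing disease is the costlier
error.  Hidden-layer size can be selected by sweeping candidate sizes and
maximising the mean validation MCC across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from .metrics import confusion_matrix, mcc_score
from .network import ShallowNet, TrainingHistory, train_network


@dataclass(frozen=True)
class NetworkConfig:
    """Fixed training parameters of the shallow network ensemble."""

    hidden_size: int = 27
    early_stop_window: int = 6
    max_epochs: int = 1000
    inits_per_fold: int = 5

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.early_stop_window < 1:
            raise ValueError("early_stop_window must be >= 1")


@dataclass
class FoldModel:
    network: ShallowNet
    threshold: float
    fold_index: int
    validation_mcc: float


@dataclass(frozen=True)
class ROCCurve:
    """Counting-based ROC curve, one point per distinct score threshold.

    Thresholds are decreasing; a sample is predicted positive when its
    score is >= the threshold.  Sensitivity (TPR) is non-decreasing along
    the arrays, specificity (TNR) non-increasing; the degenerate endpoints
    (sens, spec) = (0, 1) and (1, 0) are always present.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC curve by direct counting at every distinct score threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC curve requires both classes in the labels")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # keep the last index of each run of equal scores
    distinct = np.nonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])[0]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    sens = np.r_[0.0, tp[distinct] / n_pos]
    spec = np.r_[1.0, 1.0 - fp[distinct] / n_neg]
    return ROCCurve(thresholds, sens, spec)


def threshold_approach_a(roc: ROCCurve, n_negative: int, n_positive: int) -> float:
    """Iso-performance line threshold for imbalanced classes.

    Selects the curve point first touched by a line of slope
    ``n_negative / n_positive`` sliding down from (FPR, TPR) = (0, 1),
    i.e. the maximiser of ``TPR - slope * FPR``; ties go to the
    higher-sensitivity point.
    """
    if n_negative <= 0 or n_positive <= 0:
        raise ValueError("class counts must be positive")
    slope = n_negative / n_positive
    objective = roc.sensitivity - slope * roc.fpr
    best = np.flatnonzero(objective >= objective.max() - 1e-12)
    idx = best[np.argmax(roc.sensitivity[best])]
    return float(roc.thresholds[idx])


def threshold_approach_b(roc: ROCCurve) -> float:
    """Minimum-distance-to-corner threshold.

    Selects the point minimising
    ``sqrt((1 - sensitivity)^2 + (1 - specificity)^2)``; ties go to the
    higher-sensitivity point.
    """
    dist = np.hypot(1.0 - roc.sensitivity, 1.0 - roc.specificity)
    best = np.flatnonzero(dist <= dist.min() + 1e-12)
    idx = best[np.argmax(roc.sensitivity[best])]
    return float(roc.thresholds[idx])


def _decision_threshold(t: float, scores: np.ndarray) -> float:
    """Fold decision threshold realising a ROC operating point robustly.

    The ROC point threshold ``t`` is a validation score value; any cut in
    the open interval down to the next distinct score below realises the
    same validation operating point.  The midpoint of that margin is used,
    which keeps the selected sensitivity/specificity on the validation set
    while maximising the score margin on unseen data (scores of confident
    networks saturate, so cutting exactly at a score value is brittle).
    """
    if not np.isfinite(t):
        t = float(np.max(scores))
    below = scores[scores < t]
    lower = float(below.max()) if below.size else 0.0
    return float(min(max((t + lower) / 2.0, 0.0), 1.0))


class ShallowEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """K-fold shallow-network ensemble with per-fold ROC thresholds.

    Parameters
    ----------
    hidden_size : neurons in the single hidden layer.
    k : number of cross-validation folds (also the ensemble size).
    inits_per_fold : random initialisations trained per fold; the best by
        validation MCC is kept.
    val_fraction : stratified share of each training fold held out for
        early stopping and threshold selection.
    threshold_method : "a" (iso-performance line) or "b" (minimum distance
        to the ideal corner, default).
    pos_label : label treated as the positive (sclerotic) class; defaults
        to ``classes_[1]`` after fitting.

    Attributes
    ----------
    fold_models_ : list of :class:`FoldModel` (network, threshold,
        validation MCC).
    classes_ : the two class labels.
    """

    def __init__(
        self,
        hidden_size: int = 27,
        k: int = 10,
        inits_per_fold: int = 5,
        val_fraction: float = 0.15,
        early_stop_window: int = 6,
        max_epochs: int = 1000,
        threshold_method: str = "b",
        pos_label=None,
        random_state: int | None = 0,
    ):
        self.hidden_size = hidden_size
        self.k = k
        self.inits_per_fold = inits_per_fold
        self.val_fraction = val_fraction
        self.early_stop_window = early_stop_window
        self.max_epochs = max_epochs
        self.threshold_method = threshold_method
        self.pos_label = pos_label
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.threshold_method not in ("a", "b"):
            raise ValueError("threshold_method must be 'a' or 'b'")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required")
        pos = self.pos_label if self.pos_label is not None else self.classes_[1]
        if pos not in self.classes_:
            raise ValueError(f"pos_label {pos!r} not among classes {self.classes_}")
        self.pos_label_ = pos
        yb = (y == pos).astype(int)

        root = np.random.SeedSequence(self.random_state)
        fold_seqs = root.spawn(self.k)
        skf = StratifiedKFold(
            n_splits=self.k, shuffle=True,
            random_state=np.random.RandomState(int(root.generate_state(1)[0])),
        )
        self.fold_models_ = []
        for fold_index, (train_idx, _hold_idx) in enumerate(skf.split(X, yb)):
            model = self._fit_fold(
                X[train_idx], yb[train_idx], fold_index, fold_seqs[fold_index]
            )
            self.fold_models_.append(model)
        self.n_features_in_ = X.shape[1]
        return self

    def _fit_fold(self, X, yb, fold_index, seed_seq) -> FoldModel:
        rng = np.random.default_rng(seed_seq)
        split_seed = int(rng.integers(2**31))
        for attempt in range(3):  # stratification retry
            X_tr, X_val, y_tr, y_val = train_test_split(
                X, yb, test_size=self.val_fraction,
                stratify=yb, random_state=split_seed + attempt,
            )
            if len(np.unique(y_tr)) == 2 and len(np.unique(y_val)) == 2:
                break
        else:
            raise ValueError(f"fold {fold_index}: could not stratify both classes")

        best = None
        for _ in range(self.inits_per_fold):
            net, _hist = train_network(
                X_tr, y_tr, X_val, y_val,
                hidden_size=self.hidden_size, rng=rng,
                max_epochs=self.max_epochs,
                early_stop_window=self.early_stop_window,
            )
            val_scores = net.predict_proba(X_val)[:, 1]
            m = mcc_score(confusion_matrix(y_val, (val_scores >= 0.5).astype(int)))
            if best is None or m > best[0]:
                best = (m, net, val_scores)
        _, net, val_scores = best
        roc = roc_curve(val_scores, y_val)
        if self.threshold_method == "a":
            thr = threshold_approach_a(
                roc, int((y_val == 0).sum()), int((y_val == 1).sum())
            )
        else:
            thr = threshold_approach_b(roc)
        thr = _decision_threshold(thr, val_scores)
        val_mcc = mcc_score(confusion_matrix(y_val, (val_scores >= thr).astype(int)))
        return FoldModel(net, thr, fold_index, val_mcc)

    # -------------------------------------------------------------- predict
    def vote_matrix(self, X) -> np.ndarray:
        """Per-fold binary votes, shape (n_samples, k)."""
        check_is_fitted(self, "fold_models_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"input width {X.shape[1]} does not match fitted width "
                f"{self.n_features_in_}"
            )
        votes = [
            (fm.network.predict_proba(X)[:, 1] >= fm.threshold).astype(int)
            for fm in self.fold_models_
        ]
        return np.column_stack(votes)

    def predict(self, X):
        votes = self.vote_matrix(X)
        k = votes.shape[1]
        positive = votes.sum(axis=1) * 2 >= k  # ties go to the positive class
        neg = self.classes_[self.classes_ != self.pos_label_][0]
        return np.where(positive, self.pos_label_, neg)

    def predict_proba(self, X):
        check_is_fitted(self, "fold_models_")
        X = np.asarray(X, dtype=float)
        p = np.mean([fm.network.predict_proba(X)[:, 1] for fm in self.fold_models_], axis=0)
        proba = np.column_stack([1 - p, p])
        if self.classes_[1] != self.pos_label_:
            proba = proba[:, ::-1]
        return proba


def train_ensemble(
    X, y, k: int = 10, config: NetworkConfig = NetworkConfig(),
    threshold_method: str = "b", random_state: int | None = 0,
) -> ShallowEnsembleClassifier:
    """Functional wrapper around :class:`ShallowEnsembleClassifier`."""
    clf = ShallowEnsembleClassifier(
        hidden_size=config.hidden_size,
        k=k,
        inits_per_fold=config.inits_per_fold,
        early_stop_window=config.early_stop_window,
        max_epochs=config.max_epochs,
        threshold_method=threshold_method,
        random_state=random_state,
    )
    return clf.fit(X, y)


def predict(ensemble: ShallowEnsembleClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Hard-voting prediction; returns (labels, per-fold vote matrix)."""
    return ensemble.predict(X), ensemble.vote_matrix(X)


def select_hidden_size(
    X, y, sizes, k: int = 10, inits_per_fold: int = 1,
    max_epochs: int = 1000, early_stop_window: int = 6,
    random_state: int | None = 0,
) -> tuple[int, pd.DataFrame]:
    """Hidden-layer size sweep selected by mean cross-validated MCC.

    For each candidate size, a k-fold ensemble is trained with fresh seeded
    initialisations and the mean fold validation MCC recorded.  Returns the
    size with the highest mean MCC (ties broken toward the smaller size)
    together with the full (size, mean_mcc, mean_accuracy) trace.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes:
        raise ValueError("size range must be non-empty")
    rows = []
    from .metrics import classification_metrics

    for size in sizes:
        clf = ShallowEnsembleClassifier(
            hidden_size=size, k=k, inits_per_fold=inits_per_fold,
            early_stop_window=early_stop_window, max_epochs=max_epochs,
            random_state=random_state,
        ).fit(X, y)
        mccs, accs = [], []
        for fm in clf.fold_models_:
            mccs.append(fm.validation_mcc)
        preds = clf.predict(X)
        summary = classification_metrics(
            confusion_matrix(y, preds, pos_label=clf.pos_label_)
        )
        accs.append(summary["accuracy"])
        rows.append(
            {"size": size, "mean_mcc": float(np.mean(mccs)),
             "mean_accuracy": float(np.mean(accs))}
        )
    trace = pd.DataFrame(rows)
    best_idx = int(trace["mean_mcc"].round(12).idxmax())  # ties -> smaller size
    return int(trace.loc[best_idx, "size"]), trace
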