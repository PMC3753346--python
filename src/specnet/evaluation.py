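"""Cross-validated classification of subjects from network topology.

Per threshold, each subject is represented by the topological metric vector
of their binarized network, and subjects are classified patient vs control
with one of two tracks: a linear support vector machine (hard labels,
scored by precision, recall and F-measure with patient as the positive
class) or a probabilistic neural network (Parzen-window class-conditional
density classifier, additionally scored by the area under the ROC curve of
its posterior patient probabilities).

The F-measure is the harmonic mean

    F = 2 * precision * recall / (precision + recall),

0 by convention when precision + recall = 0.

Leakage control: the pairwise linear models that define edge weights are
themselves fitted on labeled subjects, so within every cross-validation
fold they are refit on the training fold only, and the networks and metric
vectors of held-out subjects are rebuilt from those fold-specific models.
Training metric vectors are standardized with training-fold statistics
only.  Feature selection by binning or shared-information ranking never
looks at class labels, so it is applied once, outside the folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.metrics import precision_score, recall_score, roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .network_model import build_subject_network, fit_pair_models
from .spectra_io import CONTROL, PATIENT, SpectraDataset
from .topology_metrics import (
    N_METRICS,
    ThresholdGrid,
    compute_metrics,
    default_grid,
)


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvaluationCurve:
    """Classification quality as a function of the binarization threshold."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f_measure: np.ndarray
    auroc: np.ndarray | None = None  # probabilistic track only
    method: str | None = None  # feature-selection label
    k: int | None = None  # network size

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        for name in ("precision", "recall", "f_measure"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.thresholds.shape:
                raise ValueError(f"{name} does not match the threshold grid")
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")
        if self.auroc is not None:
            self.auroc = np.asarray(self.auroc, dtype=float)
            if self.auroc.shape != self.thresholds.shape:
                raise ValueError("auroc does not match the threshold grid")

    def best(self, score: str = "precision") -> float:
        arr = getattr(self, score)
        if arr is None or arr.size == 0:
            raise ValueError(f"curve has no {score} values")
        return float(np.max(arr))


def make_folds(labels, protocol="loo", seed: int = 0):
    """Cross-validation folds as (train_rows, test_rows) index arrays.

    ``protocol`` is ``"loo"`` (leave-one-out, deterministic, the default
    for small cohorts) or an integer number of stratified folds (shuffled
    with ``seed``).  Every training fold must contain both classes.
    """
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if protocol == "loo":
        folds = [
            (np.delete(np.arange(n), i), np.array([i])) for i in range(n)
        ]
    else:
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(
            n_splits=int(protocol), shuffle=True, random_state=seed
        )
        folds = [
            (tr, te) for tr, te in skf.split(np.zeros(n), labels.astype(str))
        ]
    for tr, _ in folds:
        present = set(labels[tr])
        if present != {CONTROL, PATIENT}:
            raise ValueError(
                "a cross-validation training fold contains a single class"
            )
    return folds


def _metric_array(models, dataset: SpectraDataset, rows, grid) -> np.ndarray:
    """Metric vectors, shape (n_thresholds, len(rows), N_METRICS)."""
    taus = np.asarray(grid.values)
    out = np.empty((len(taus), len(rows), N_METRICS))
    for r_pos, r in enumerate(rows):
        net = build_subject_network(
            models, dataset.intensities[r], dataset.subject_ids[r]
        )
        w = net.weight_matrix()
        for t_pos, tau in enumerate(taus):
            adj = w > tau
            np.fill_diagonal(adj, False)
            out[t_pos, r_pos] = compute_metrics(adj, tau=tau).values
    return out


def svm_predict(train_X, train_y, test_X, C: float = 1.0):
    """Linear-SVM fold predictor on standardized metric vectors."""
    scaler = StandardScaler().fit(train_X)
    clf = SVC(kernel="linear", C=C)
    clf.fit(scaler.transform(train_X), train_y)
    return clf.predict(scaler.transform(test_X))


def pnn_posteriors(train_X, train_y, test_X, sigma: float | None = None):
    """Parzen-window posterior patient probabilities for held-out vectors.

    The class score of a test vector is the mean Gaussian kernel of width
    ``sigma`` over that class's training vectors; the posterior is the
    patient score normalized by the sum of both class scores.  By default
    ``sigma`` is the median pairwise distance among the (standardized)
    training vectors — a scale-free heuristic requiring no tuning loop.
    """
    if sigma is not None and sigma <= 0:
        raise ValueError("sigma must be positive")
    scaler = StandardScaler().fit(train_X)
    tr = scaler.transform(train_X)
    te = scaler.transform(test_X)
    if sigma is None:
        d = pdist(tr)
        sigma = float(np.median(d)) if d.size else 1.0
        if sigma <= 0:
            sigma = 1.0
    train_y = np.asarray(train_y, dtype=object)
    scores = {}
    for lab in (CONTROL, PATIENT):
        pts = tr[train_y == lab]
        d2 = cdist(te, pts, "sqeuclidean")
        scores[lab] = np.exp(-d2 / (2.0 * sigma**2)).mean(axis=1)
    total = scores[CONTROL] + scores[PATIENT]
    post = np.full(len(te), 0.5)
    ok = total > 0
    post[ok] = scores[PATIENT][ok] / total[ok]
    return post


def _cross_validated_outputs(
    dataset: SpectraDataset,
    selected,
    grid: ThresholdGrid,
    folds,
    fold_fn,
):
    """Run fold_fn(train_X, train_y, test_X) per threshold per fold.

    Returns (y_true, outputs) where outputs has shape
    (n_thresholds, n_subjects) aligned with the pooled test order.
    """
    taus = grid.values
    n = dataset.n_subjects
    outputs = np.empty((len(taus), n), dtype=object)
    y_true = np.empty(n, dtype=object)
    for train_idx, test_idx in folds:
        models = fit_pair_models(dataset.subset(train_idx), selected)
        train_T = _metric_array(models, dataset, train_idx, grid)
        test_T = _metric_array(models, dataset, test_idx, grid)
        y_train = dataset.labels[train_idx]
        y_true[test_idx] = dataset.labels[test_idx]
        for t in range(len(taus)):
            outputs[t, test_idx] = fold_fn(train_T[t], y_train, test_T[t])
    return y_true, outputs


def _prf(y_true, y_pred):
    p = precision_score(
        y_true.astype(str), y_pred.astype(str), pos_label=PATIENT, zero_division=0
    )
    r = recall_score(
        y_true.astype(str), y_pred.astype(str), pos_label=PATIENT, zero_division=0
    )
    return p, r, f_measure(p, r)


def evaluate_svm(
    dataset: SpectraDataset,
    selected,
    grid: ThresholdGrid | None = None,
    protocol="loo",
    C: float = 1.0,
    seed: int = 0,
    method: str | None = None,
) -> EvaluationCurve:
    """Cross-validated SVM precision/recall/F per threshold.

    Pair models are refit inside each fold (see module docstring) and
    held-out predictions are pooled over folds before scoring, so each
    subject contributes exactly one prediction per threshold.
    """
    if grid is None:
        grid = default_grid()
    folds = make_folds(dataset.labels, protocol, seed)
    y_true, preds = _cross_validated_outputs(
        dataset, selected, grid, folds,
        lambda trX, trY, teX: svm_predict(trX, trY, teX, C=C),
    )
    prec, rec, f = [], [], []
    for t in range(len(grid)):
        p, r, fm = _prf(y_true, preds[t])
        prec.append(p)
        rec.append(r)
        f.append(fm)
    return EvaluationCurve(
        thresholds=grid.values,
        precision=np.array(prec),
        recall=np.array(rec),
        f_measure=np.array(f),
        method=method,
        k=len(np.atleast_1d(selected)),
    )


def evaluate_pnn(
    dataset: SpectraDataset,
    selected,
    grid: ThresholdGrid | None = None,
    protocol="loo",
    sigma: float | None = None,
    seed: int = 0,
    method: str | None = None,
) -> EvaluationCurve:
    """Cross-validated PNN curve with AUROC of pooled posteriors.

    AUROC is the Mann-Whitney rank statistic: the probability that a random
    patient's posterior exceeds a random control's, ties counting one half.
    """
    if sigma is not None and sigma <= 0:
        raise ValueError("sigma must be positive")
    if grid is None:
        grid = default_grid()
    folds = make_folds(dataset.labels, protocol, seed)
    y_true, posts = _cross_validated_outputs(
        dataset, selected, grid, folds,
        lambda trX, trY, teX: pnn_posteriors(trX, trY, teX, sigma=sigma),
    )
    y01 = (y_true.astype(str) == PATIENT).astype(int)
    prec, rec, f, auc = [], [], [], []
    for t in range(len(grid)):
        post = posts[t].astype(float)
        y_pred = np.where(post > 0.5, PATIENT, CONTROL).astype(object)
        p, r, fm = _prf(y_true, y_pred)
        prec.append(p)
        rec.append(r)
        f.append(fm)
        if post.std() == 0:
            auc.append(0.5)  # all posteriors tied
        else:
            auc.append(roc_auc_score(y01, post))
    return EvaluationCurve(
        thresholds=grid.values,
        precision=np.array(prec),
        recall=np.array(rec),
        f_measure=np.array(f),
        auroc=np.array(auc),
        method=method,
        k=len(np.atleast_1d(selected)),
    )


def best_scores(curves, score: str = "precision"):
    """Best-over-thresholds score table, rows = network size k, columns =
    feature-selection method (the layout of a best-classification summary).
    """
    import pandas as pd

    cells = {}
    for curve in curves:
        cells[(curve.k, curve.method)] = curve.best(score)
    if not cells:
        raise ValueError("no curves given")
    ks = sorted({k for k, _ in cells}, reverse=True)
    methods = sorted({m for _, m in cells if m is not None} | set())
    if not methods:
        methods = [None]
    table = pd.DataFrame(index=ks, columns=methods, dtype=float)
    for (k, m), v in cells.items():
        table.loc[k, m] = v
    table.index.name = "k"
    return table
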