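"""Biomarker-panel evaluation: PCA and linear-SVM ROC/AUC.

A panel is a small set of differential features; its expression submatrix
is transformed (log2(RPM+1), centered, unit-scaled by default) and then
(i) projected by PCA with per-component variance explained, and (ii) fed
to a soft-margin linear SVM whose decision scores — resubstitution or
leave-one-out cross-validated — are summarized by an ROC curve and its
AUC. The ROC is built by an explicit threshold sweep; the trapezoidal AUC
equals the Mann-Whitney U statistic scaled by n1*n2 (ties half-credited).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import ValidationError
from .quantify import GROUP_HIGH

DEFAULT_POSITIVE = GROUP_HIGH


@dataclass
class PanelMatrix:
    """Transformed expression of a biomarker panel (samples x features)."""

    X: np.ndarray
    samples: list[str]
    features: list[str]
    labels: np.ndarray              # group label per sample
    positive_label: str = DEFAULT_POSITIVE

    @property
    def y(self) -> np.ndarray:
        return (self.labels == self.positive_label).astype(int)


def make_panel(
    rpm: pd.DataFrame,
    features: Sequence[str],
    groups: pd.Series,
    log2_transform: bool = True,
    center: bool = True,
    scale: bool = True,
    positive_label: str = DEFAULT_POSITIVE,
) -> PanelMatrix:
    """Build the transformed panel matrix from an RPM matrix and group labels."""
    features = list(features)
    if not features:
        raise ValidationError("empty biomarker panel")
    samples = [s for s in rpm.columns if groups.get(s) in (GROUP_HIGH, "L-GQE")]
    X = rpm.loc[features, samples].to_numpy(dtype=float).T
    if log2_transform:
        X = np.log2(X + 1.0)
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    labels = np.array([groups[s] for s in samples])
    return PanelMatrix(X=X, samples=samples, features=features, labels=labels,
                       positive_label=positive_label)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray               # samples x components
    loadings: np.ndarray             # components x features
    variance_explained: np.ndarray   # percent, over all components


def pca(X: np.ndarray, n_components: Optional[int] = None) -> PcaResult:
    """PCA of a samples x features matrix via SVD of the centered data.

    variance_explained covers all min(n-1, p) components and sums to 100%.
    Component signs are fixed by making each loading vector's
    largest-magnitude entry positive, so results are deterministic.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2 or p < 1:
        raise ValidationError("PCA needs >= 2 samples and >= 1 feature")
    Xc = X - X.mean(axis=0)
    k = min(n - 1, p)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    var = S**2 / (n - 1)
    total = var.sum()
    if total == 0:
        raise ValidationError("zero-variance matrix")
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U * S
    if n_components is not None:
        scores = scores[:, :n_components]
        Vt = Vt[:n_components]
    return PcaResult(
        scores=scores, loadings=Vt, variance_explained=100.0 * var / total
    )


# ---------------------------------------------------------------------------
# Linear SVM
# ---------------------------------------------------------------------------

@dataclass
class LinearSvmModel:
    weights: np.ndarray
    bias: float

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias


def train_linear_svm(
    panel: PanelMatrix, C: float = 1.0, tol: float = 1e-3
) -> LinearSvmModel:
    """Fit a soft-margin linear SVM; positive scores favor the positive class.

    ``tol`` is the dual-optimality stopping tolerance; tighten it when the
    primal objective itself must be accurate.
    """
    y = panel.y
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present to train an SVM")
    clf = SVC(kernel="linear", C=C, tol=tol)
    clf.fit(panel.X, y)
    return LinearSvmModel(weights=clf.coef_.ravel().copy(), bias=float(clf.intercept_[0]))


def crossval_scores(panel: PanelMatrix, C: float = 1.0) -> np.ndarray:
    """Leave-one-out decision scores: each sample scored by a model trained
    on the remaining n-1 samples. Deterministic given data and C."""
    n = len(panel.samples)
    if n < 3:
        raise ValidationError("leave-one-out needs at least 3 samples")
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sub = PanelMatrix(
            X=panel.X[mask], samples=[], features=panel.features,
            labels=panel.labels[mask], positive_label=panel.positive_label,
        )
        y_train = sub.y
        if len(np.unique(y_train)) < 2:
            # single-class training fold (only possible at tiny n): the
            # fold's constant prediction is the class it saw
            scores[i] = 1.0 if y_train[0] == 1 else -1.0
            continue
        model = train_linear_svm(sub, C=C)
        scores[i] = model.decision_scores(panel.X[i : i + 1])[0]
    return scores


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    scheme: str = "resubstitution"


def _auc_mannwhitney(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U with half credit for ties."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[str],
    positive_label: str = DEFAULT_POSITIVE,
    scheme: str = "resubstitution",
) -> RocResult:
    """ROC curve by sweeping thresholds over the unique scores.

    Tied scores move FPR and TPR together, contributing diagonal segments.
    The AUC is the trapezoidal area under the stored points.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = (labels == positive_label).astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both labels must be present")
    order = np.argsort(-scores, kind="stable")
    fpr = [0.0]
    tpr = [0.0]
    tp = fp = 0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[order[j]] == scores[order[i]]:
            tp += y[order[j]]
            fp += 1 - y[order[j]]
            j += 1
        fpr.append(fp / n_neg)
        tpr.append(tp / n_pos)
        i = j
    fpr = np.array(fpr)
    tpr = np.array(tpr)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(scores=scores, labels=labels, fpr=fpr, tpr=tpr, auc=auc,
                     scheme=scheme)


def evaluate_panel(
    rpm: pd.DataFrame,
    features: Sequence[str],
    groups: pd.Series,
    C: float = 1.0,
    scale: bool = True,
    n_components: int = 2,
) -> dict:
    """PCA + SVM/ROC evaluation of one biomarker panel.

    Returns a dict with the panel, the PcaResult, and RocResults for both
    leave-one-out and resubstitution decision scores.
    """
    panel = make_panel(rpm, features, groups, scale=scale)
    pca_res = pca(panel.X, n_components=n_components)
    model = train_linear_svm(panel, C=C)
    resub = roc_auc(model.decision_scores(panel.X), panel.labels,
                    panel.positive_label, scheme="resubstitution")
    loo = roc_auc(crossval_scores(panel, C=C), panel.labels,
                  panel.positive_label, scheme="leave-one-out")
    return {"panel": panel, "pca": pca_res, "roc_loo": loo, "roc_resub": resub}
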