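"""CSP + linear SVM brain-switch decoding.

Common spatial patterns (CSP) finds spatial filters w maximizing the
variance ratio w' C_A w / w' C_B w between two trial classes, via joint
diagonalization of the class-mean covariances.  Features are the
log-variance of the first and last ``n_select`` CSP components; a linear
SVM (C = 1) classifies them.  Evaluation follows a paired leave-one-out
scheme: the trials of the two classes are randomly paired into sets of one
trial per class, and each fold holds out one set, refitting CSP, the
feature scaler and the SVM on the remaining trials only.

Both :class:`CSP` and :class:`CSPDecoder` are scikit-learn estimators, so
they compose with sklearn pipelines and model selection.  Trial arrays are
``(n_trials, n_channels, n_samples)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted


def _validate_trials(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected trials x channels x samples array")
    return X


def trial_covariances(X: np.ndarray) -> np.ndarray:
    """Per-trial sample covariance, trace-normalized.

    Trace normalization equalizes trial power before class averaging, the
    standard CSP practice.
    """
    X = _validate_trials(X)
    Xc = X - X.mean(axis=2, keepdims=True)
    covs = np.einsum("tcs,tds->tcd", Xc, Xc) / (X.shape[2] - 1)
    traces = np.trace(covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise ValueError("zero-variance trial encountered")
    return covs / traces[:, None, None]


class CSP(BaseEstimator, TransformerMixin):
    """Common-spatial-patterns transformer.

    Parameters
    ----------
    n_select : int
        Components kept from *each* end of the eigenvalue spectrum; the
        feature dimension is ``2 * n_select``.

    Attributes
    ----------
    filters_ : ndarray, (n_components, n_channels)
        Spatial filters, rows ordered by descending eigenvalue.
    patterns_ : ndarray, (n_channels, n_components)
        Corresponding spatial patterns (pinv of ``filters_``).
    eigenvalues_ : ndarray, (n_components,)
        Generalized eigenvalues in [0, 1]; lambda_j + lambda_{K+1-j} of the
        swapped-class problem equals 1.
    """

    def __init__(self, n_select: int = 4):
        self.n_select = n_select

    def fit(self, X, y):
        X = _validate_trials(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("CSP is defined for exactly two classes")
        covs = trial_covariances(X)
        c_a = covs[y == self.classes_[0]].mean(axis=0)
        c_b = covs[y == self.classes_[1]].mean(axis=0)
        if (y == self.classes_[0]).sum() < 2 or (y == self.classes_[1]).sum() < 2:
            raise ValueError("need at least 2 trials per class")
        self._fit_from_covariances(c_a, c_b, X.shape[1], X.shape[2] * min(
            (y == self.classes_[0]).sum(), (y == self.classes_[1]).sum()
        ))
        return self

    def _fit_from_covariances(self, c_a, c_b, n_channels, n_obs) -> None:
        composite = c_a + c_b
        # whiten the composite covariance, then eigendecompose the whitened
        # class-A covariance: numerically stabler than a direct generalized
        # eigenproblem and provably equivalent
        evals, evecs = linalg.eigh(composite)
        tol = evals.max() * n_channels * np.finfo(float).eps
        if evals.min() < tol:
            raise np.linalg.LinAlgError(
                f"rank-deficient pooled covariance ({n_channels} channels, "
                f"{n_obs} samples); reduce channels or lengthen trials"
            )
        whitener = evecs @ np.diag(evals**-0.5) @ evecs.T
        s_a = whitener @ c_a @ whitener.T
        lam, u = linalg.eigh(s_a)
        order = np.argsort(lam)[::-1]
        lam = lam[order]
        u = u[:, order]
        self.filters_ = u.T @ whitener
        self.patterns_ = linalg.pinv(self.filters_)
        self.eigenvalues_ = np.clip(lam, 0.0, 1.0)
        if 2 * self.n_select > len(lam):
            raise ValueError("n_select too large for the channel count")
        k = self.n_select
        self.selected_ = np.r_[np.arange(k), np.arange(len(lam) - k, len(lam))]
        return None

    def transform(self, X) -> np.ndarray:
        """Log-variance of the selected CSP components: (trials, 2*n_select)."""
        check_is_fitted(self, "filters_")
        X = _validate_trials(X)
        w = self.filters_[self.selected_]
        proj = np.einsum("kc,tcs->tks", w, X)
        var = proj.var(axis=2, ddof=1)
        if np.any(var <= 0):
            raise ValueError("zero-variance projected signal")
        return np.log(var)


def csp_from_covariances(c_a: np.ndarray, c_b: np.ndarray, n_select: int = 4) -> CSP:
    """Fit CSP directly from two class-mean covariance matrices."""
    c_a = np.asarray(c_a, dtype=float)
    c_b = np.asarray(c_b, dtype=float)
    model = CSP(n_select=n_select)
    model.classes_ = np.array([0, 1])
    model._fit_from_covariances(c_a, c_b, c_a.shape[0], 0)
    return model


def fit_csp(X_a: np.ndarray, X_b: np.ndarray, n_select: int = 4) -> CSP:
    """Fit CSP from two per-class trial arrays (thin wrapper)."""
    X = np.concatenate([X_a, X_b], axis=0)
    y = np.r_[np.zeros(len(X_a), dtype=int), np.ones(len(X_b), dtype=int)]
    return CSP(n_select=n_select).fit(X, y)


def csp_features(X: np.ndarray, model: CSP) -> np.ndarray:
    return model.transform(X)


class CSPDecoder(BaseEstimator, ClassifierMixin):
    """CSP -> standardized log-variance features -> linear SVM (C = 1)."""

    def __init__(self, n_select: int = 4, svm_C: float = 1.0):
        self.n_select = n_select
        self.svm_C = svm_C

    def fit(self, X, y):
        if self.svm_C <= 0:
            raise ValueError("svm_C must be positive")
        self.pipeline_ = make_pipeline(
            CSP(n_select=self.n_select),
            StandardScaler(),
            SVC(kernel="linear", C=self.svm_C),
        )
        self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_[-1].classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(X)

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


@dataclass(frozen=True)
class FoldPlan:
    """Paired leave-one-out plan: each set holds one trial per class."""

    sets: tuple[tuple[int, int], ...]  # (index into class A, index into class B)

    @property
    def n_folds(self) -> int:
        return len(self.sets)


def make_fold_plan(n_a: int, n_b: int, seed: int) -> FoldPlan:
    """Randomly pair off ``min(n_a, n_b)`` trials per class into LOO sets.

    With 40 trials per class this is the study's "forty sets, one sample of
    each class" scheme.  Surplus trials of the larger class are not paired;
    they join every training fold.
    """
    rng = np.random.default_rng(seed)
    n_sets = min(n_a, n_b)
    order_a = rng.permutation(n_a)[:n_sets]
    order_b = rng.permutation(n_b)[:n_sets]
    return FoldPlan(sets=tuple(zip(map(int, order_a), map(int, order_b))))


def loo_accuracy(
    X_a: np.ndarray,
    X_b: np.ndarray,
    n_select: int = 4,
    svm_C: float = 1.0,
    seed: int = 0,
) -> tuple[float, list[dict]]:
    """Paired leave-one-out accuracy of the CSP+SVM decoder.

    CSP, the feature scaler and the SVM are refit inside every fold on the
    training trials only; the held-out pair never influences the model.
    Returns the overall accuracy (fraction of held-out trials classified
    correctly) and a per-fold record.
    """
    X_a, X_b = _validate_trials(X_a), _validate_trials(X_b)
    if len(X_a) < 4 or len(X_b) < 4:
        raise ValueError("need at least 4 trials per class")
    plan = make_fold_plan(len(X_a), len(X_b), seed)
    X = np.concatenate([X_a, X_b], axis=0)
    y = np.r_[np.zeros(len(X_a), dtype=int), np.ones(len(X_b), dtype=int)]
    offset_b = len(X_a)

    # log-variance of a CSP projection equals log(w' Sigma w) with Sigma the
    # per-trial sample covariance, so covariances are cached once and every
    # fold only refits the (cheap) eigendecomposition, scaler and SVM on its
    # training trials -- numerically identical to refitting from raw trials
    covs_norm = trial_covariances(X)
    Xc = X - X.mean(axis=2, keepdims=True)
    covs_raw = np.einsum("tcs,tds->tcd", Xc, Xc) / (X.shape[2] - 1)
    n_channels = X.shape[1]

    records = []
    n_correct = 0
    for fold, (ia, ib) in enumerate(plan.sets):
        test_idx = np.array([ia, offset_b + ib])
        train_mask = np.ones(len(X), dtype=bool)
        train_mask[test_idx] = False
        y_tr = y[train_mask]
        c_a = covs_norm[train_mask][y_tr == 0].mean(axis=0)
        c_b = covs_norm[train_mask][y_tr == 1].mean(axis=0)
        csp = CSP(n_select=n_select)
        csp.classes_ = np.array([0, 1])
        csp._fit_from_covariances(c_a, c_b, n_channels, int(train_mask.sum()))
        w = csp.filters_[csp.selected_]
        feats = np.log(np.einsum("kc,tcd,kd->tk", w, covs_raw, w))
        scaler = StandardScaler().fit(feats[train_mask])
        svm = SVC(kernel="linear", C=svm_C).fit(scaler.transform(feats[train_mask]), y_tr)
        pred = svm.predict(scaler.transform(feats[test_idx]))
        correct = int((pred == y[test_idx]).sum())
        n_correct += correct
        records.append(
            {"fold": fold, "test_a": ia, "test_b": ib, "n_correct": correct}
        )
    accuracy = n_correct / (2 * plan.n_folds)
    return accuracy, records


def stratify_performers(accuracy_mi_vs_rest: float, threshold: float = 0.80) -> str:
    """HIGH iff the MI-vs-Rest decoding accuracy strictly exceeds the
    threshold (default 80%); otherwise LOW."""
    if not (0.0 <= accuracy_mi_vs_rest <= 1.0):
        raise ValueError("accuracy must lie in [0, 1]")
    return "HIGH" if accuracy_mi_vs_rest > threshold else "LOW"
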