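"""One-vs-one multiclass linear SVM with error-correcting output codes.

For n classes, n(n-1)/2 binary soft-margin linear SVMs are trained, one per
unordered class pair, each only on that pair's samples. Prediction is by
majority vote over the pairwise decision signs, with ties broken by
average hinge-loss decoding over the coding matrix. Posterior class
probabilities come from per-learner Platt sigmoids combined by pairwise
coupling (least-squares consistency on the probability simplex).

The per-pair binary solver is sklearn's ``SVC(kernel='linear')``; the
coding design, decoding, calibration and coupling live here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

FORMAT_VERSION = 1


class ModelConfigError(ValueError):
    pass


class ModelStateError(RuntimeError):
    pass


class ModelIOError(ValueError):
    pass


def n_binary_learners(n_classes: int) -> int:
    """Number of one-vs-one binary learners: n(n-1)/2."""
    if n_classes < 2:
        raise ModelConfigError(f"need at least 2 classes, got {n_classes}")
    return n_classes * (n_classes - 1) // 2


def one_vs_one_coding(n_classes: int) -> np.ndarray:
    """Coding matrix of shape (n_classes, L): per column one +1, one -1.

    Column order: pairs (i, j) with i < j in lexicographic order; class i
    is the +1 class of its column.
    """
    L = n_binary_learners(n_classes)
    coding = np.zeros((n_classes, L), dtype=np.int8)
    col = 0
    for i in range(n_classes):
        for j in range(i + 1, n_classes):
            coding[i, col] = 1
            coding[j, col] = -1
            col += 1
    return coding


def fit_platt(decisions: np.ndarray, y: np.ndarray, max_iter: int = 100) -> tuple[float, float]:
    """Fit the Platt sigmoid P(y=+1 | d) = 1 / (1 + exp(A d + B)).

    Newton's method with backtracking on the regularized maximum-likelihood
    targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2); y holds +1/-1.
    """
    decisions = np.asarray(decisions, dtype=np.float64)
    y = np.asarray(y)
    pos, neg = np.sum(y > 0), np.sum(y <= 0)
    t = np.where(y > 0, (pos + 1.0) / (pos + 2.0), 1.0 / (neg + 2.0))
    A, B = 0.0, np.log((neg + 1.0) / (pos + 1.0))
    sigma = 1e-12
    eps = 1e-5

    def fval(A, B):
        z = A * decisions + B
        # stable log(1 + exp(z)) formulation of the cross entropy
        return np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)),
                               (t - 1) * z + np.log1p(np.exp(z))))

    F = fval(A, B)
    for _ in range(max_iter):
        z = A * decisions + B
        p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
        d1 = t - p
        d2 = p * (1 - p)
        g1 = np.sum(decisions * d1)
        g2 = np.sum(d1)
        if abs(g1) < eps and abs(g2) < eps:
            break
        h11 = np.sum(decisions * decisions * d2) + sigma
        h22 = np.sum(d2) + sigma
        h21 = np.sum(decisions * d2)
        det = h11 * h22 - h21 * h21
        dA = -(h22 * g1 - h21 * g2) / det
        dB = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * dA + g2 * dB
        step = 1.0
        while step >= 1e-10:
            A2, B2 = A + step * dA, B + step * dB
            F2 = fval(A2, B2)
            if F2 < F + 1e-4 * step * gd:
                A, B, F = A2, B2, F2
                break
            step /= 2.0
        else:
            break
    return float(A), float(B)


def pairwise_coupling(R: np.ndarray) -> np.ndarray:
    """Combine pairwise probabilities into a class-posterior simplex vector.

    R[i, j] estimates P(class i | class i or j); solves the least-squares
    consistency system min_p sum_{i<j} (R[j,i] p_i - R[i,j] p_j)^2 subject
    to sum(p) = 1, p >= 0 (second method of Wu, Lin & Weng).
    """
    n = R.shape[0]
    Q = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                Q[i, i] = sum(R[j2, i] ** 2 for j2 in range(n) if j2 != i)
            else:
                Q[i, j] = -R[j, i] * R[i, j]
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = Q
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    b = np.zeros(n + 1)
    b[n] = 1.0
    sol = np.linalg.lstsq(A, b, rcond=None)[0]
    p = np.clip(sol[:n], 0.0, None)
    total = p.sum()
    return p / total if total > 0 else np.full(n, 1.0 / n)


class PairwiseLinearSVM(ClassifierMixin, BaseEstimator):
    """One-vs-one ECOC multiclass linear SVM.

    Parameters
    ----------
    C : float
        Soft-margin box constraint shared by all pairwise learners.
    standardize : bool
        Standardize features to zero mean / unit variance (statistics from
        the training set). Off by default: HOG/LBP blocks are already
        locally normalized.
    fit_posterior : bool
        Fit per-learner Platt sigmoids on the training decisions so that
        :meth:`predict_proba` is available.
    tol : float
        Solver stopping tolerance of the binary SVMs.

    Attributes (after fit)
    ----------------------
    classes_ : ordered class labels (sorted).
    coding_ : (n, L) one-vs-one coding matrix over {+1, -1, 0}.
    weights_ : (L, d) per-learner weight vectors; biases_ : (L,).
    platt_ : (L, 2) sigmoid parameters (A, B) or None.
    """

    def __init__(
        self,
        C: float = 1.0,
        standardize: bool = False,
        fit_posterior: bool = True,
        tol: float = 1e-6,
    ):
        self.C = C
        self.standardize = standardize
        self.fit_posterior = fit_posterior
        self.tol = tol

    def fit(self, X, y, fingerprint: dict | None = None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ModelConfigError(f"X must be 2-D (n_samples, n_features), got {X.shape}")
        if len(y) != X.shape[0]:
            raise ModelConfigError(f"{X.shape[0]} samples but {len(y)} labels")
        self.classes_ = np.array(sorted(set(y.tolist())))
        n = len(self.classes_)
        if n < 2:
            raise ModelConfigError("training requires at least 2 classes")
        self.feature_dim_ = X.shape[1]
        self.fingerprint_ = dict(fingerprint) if fingerprint else {}

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0.0] = 1.0
            self.scale_ = scale
            X = (X - self.mean_) / self.scale_
        else:
            self.mean_ = None
            self.scale_ = None

        self.coding_ = one_vs_one_coding(n)
        L = self.coding_.shape[1]
        self.weights_ = np.zeros((L, self.feature_dim_))
        self.biases_ = np.zeros(L)
        platt = np.zeros((L, 2)) if self.fit_posterior else None

        label_index = {c: k for k, c in enumerate(self.classes_)}
        yi = np.array([label_index[lab] for lab in y.tolist()])
        col = 0
        for i in range(n):
            for j in range(i + 1, n):
                mask = (yi == i) | (yi == j)
                if np.sum(yi == i) < 1 or np.sum(yi == j) < 1:
                    raise ModelConfigError("every class needs at least one sample")
                Xp = X[mask]
                # +1 for class i, -1 for class j
                yp = np.where(yi[mask] == i, 1, -1)
                svc = SVC(kernel="linear", C=self.C, tol=self.tol)
                svc.fit(Xp, yp)
                # sklearn orders binary classes as (-1, +1); decision > 0 means +1
                self.weights_[col] = svc.coef_[0]
                self.biases_[col] = svc.intercept_[0]
                if platt is not None:
                    d = Xp @ self.weights_[col] + self.biases_[col]
                    platt[col] = fit_platt(d, yp)
                col += 1
        self.platt_ = platt
        return self

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise ModelStateError("model is not fitted")

    def _prepare(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.feature_dim_:
            raise ModelConfigError(
                f"feature dimension {X.shape[1]} does not match the "
                f"model's training dimension {self.feature_dim_}"
            )
        if self.mean_ is not None:
            X = (X - self.mean_) / self.scale_
        return X

    def decision_function(self, X) -> np.ndarray:
        """Per-learner decision values, shape (n_samples, L)."""
        X = self._prepare(X)
        return X @ self.weights_.T + self.biases_

    def predict(self, X) -> np.ndarray:
        """Majority vote over pairwise decisions; hinge decoding breaks ties."""
        X = self._prepare(X)
        D = X @ self.weights_.T + self.biases_
        n = len(self.classes_)
        signs = np.where(D >= 0, 1, -1)  # (m, L)
        pos = (self.coding_ == 1)
        neg = (self.coding_ == -1)
        votes = (signs[:, None, :] == 1) & pos[None, :, :]
        votes = votes.sum(axis=2) + (((signs[:, None, :] == -1) & neg[None, :, :]).sum(axis=2))
        # average hinge loss over the non-zero coding entries per class
        M = self.coding_.astype(np.float64)  # (n, L)
        margins = M[None, :, :] * D[:, None, :]
        hinge = np.maximum(0.0, 1.0 - margins) * (M != 0)[None, :, :]
        loss = hinge.sum(axis=2) / np.maximum((M != 0).sum(axis=1), 1)[None, :]
        best = np.empty(X.shape[0], dtype=np.intp)
        for s in range(X.shape[0]):
            top = votes[s].max()
            tied = np.flatnonzero(votes[s] == top)
            best[s] = tied[np.argmin(loss[s, tied])]
        return self.classes_[best]

    def predict_proba(self, X) -> np.ndarray:
        """Posterior class probabilities via Platt sigmoids + pairwise coupling."""
        self._check_fitted()
        if self.platt_ is None:
            raise ModelStateError(
                "model was fitted with fit_posterior=False; posteriors unavailable"
            )
        X = self._prepare(X)
        D = X @ self.weights_.T + self.biases_
        A, B = self.platt_[:, 0], self.platt_[:, 1]
        P = 1.0 / (1.0 + np.exp(np.clip(A[None, :] * D + B[None, :], -500, 500)))
        P = np.clip(P, 1e-12, 1.0 - 1e-12)
        n = len(self.classes_)
        out = np.empty((X.shape[0], n))
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        for s in range(X.shape[0]):
            R = np.zeros((n, n))
            for col, (i, j) in enumerate(pairs):
                R[i, j] = P[s, col]      # P(i | i or j)
                R[j, i] = 1.0 - P[s, col]
            out[s] = pairwise_coupling(R)
        return out


def save_model(model: PairwiseLinearSVM, path: str | Path) -> None:
    """Serialize a fitted model to a single JSON file (versioned)."""
    model._check_fitted()
    payload = {
        "format": "morphsvm-model",
        "format_version": FORMAT_VERSION,
        "classes": [str(c) for c in model.classes_.tolist()],
        "params": {
            "C": model.C,
            "standardize": model.standardize,
            "fit_posterior": model.fit_posterior,
            "tol": model.tol,
        },
        "fingerprint": model.fingerprint_,
        "feature_dim": int(model.feature_dim_),
        "coding": model.coding_.tolist(),
        "weights": model.weights_.tolist(),
        "biases": model.biases_.tolist(),
        "platt": model.platt_.tolist() if model.platt_ is not None else None,
        "mean": model.mean_.tolist() if model.mean_ is not None else None,
        "scale": model.scale_.tolist() if model.scale_ is not None else None,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path, expected_fingerprint: dict | None = None) -> PairwiseLinearSVM:
    """Load a model saved by :func:`save_model`; verifies structure and version."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "morphsvm-model":
        raise ModelIOError(f"{path} is not a morphsvm model file")
    if payload.get("format_version") != FORMAT_VERSION:
        raise ModelIOError(
            f"model format version {payload.get('format_version')} "
            f"!= supported version {FORMAT_VERSION}"
        )
    try:
        params = payload["params"]
        model = PairwiseLinearSVM(**params)
        model.classes_ = np.array(payload["classes"])
        model.feature_dim_ = int(payload["feature_dim"])
        model.fingerprint_ = payload.get("fingerprint") or {}
        model.coding_ = np.array(payload["coding"], dtype=np.int8)
        model.weights_ = np.array(payload["weights"], dtype=np.float64)
        model.biases_ = np.array(payload["biases"], dtype=np.float64)
        model.platt_ = (
            np.array(payload["platt"], dtype=np.float64)
            if payload["platt"] is not None else None
        )
        model.mean_ = np.array(payload["mean"]) if payload["mean"] is not None else None
        model.scale_ = np.array(payload["scale"]) if payload["scale"] is not None else None
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelIOError(f"model file {path} is corrupt: {exc}") from exc
    n, L = model.coding_.shape
    if L != n_binary_learners(n) or model.weights_.shape != (L, model.feature_dim_):
        raise ModelIOError(f"model file {path} has inconsistent shapes")
    if expected_fingerprint is not None and model.fingerprint_ != expected_fingerprint:
        raise ModelIOError(
            "descriptor fingerprint mismatch: model was trained with "
            f"{model.fingerprint_}, expected {expected_fingerprint}"
        )
    return model
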