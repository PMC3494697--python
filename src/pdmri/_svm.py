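"""Thin wrapper around libsvm for sigmoid-kernel C-SVC with precomputed Gram.

The nested grid search evaluates 441 (C, G) pairs by exact leave-one-out on
every training fold, i.e. hundreds of thousands of small SVM fits per run.
scikit-learn's public ``SVC.fit`` spends most of its time in per-call
validation at this problem size, so when available the low-level libsvm
binding bundled with scikit-learn is used directly (~30x faster); otherwise
the public estimator is used with identical results.

Label convention throughout: y in {+1 (case), -1 (control)}; oriented
decision values are positive for the case class. libsvm itself orients its
decision function by the first label it encounters in the training data, so
the sign is calibrated against libsvm's own class predictions.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
    HAVE_LOWLEVEL = True
except Exception:  # pragma: no cover
    _libsvm = None
    HAVE_LOWLEVEL = False

from sklearn.svm import SVC

__all__ = ["PrecomputedSVM", "loo_accuracy", "fit_predict_label",
           "sigmoid_kernel", "HAVE_LOWLEVEL"]


def sigmoid_kernel(gram: np.ndarray, gamma: float, coef0: float = 0.0) -> np.ndarray:
    """Hyperbolic-tangent kernel tanh(gamma * <u, v> + coef0) on a Gram matrix."""
    return np.tanh(gamma * gram + coef0)


class PrecomputedSVM:
    """C-SVC on a precomputed kernel with case-oriented decision values."""

    def __init__(self, C: float = 1.0, use_lowlevel: bool | None = None):
        self.C = float(C)
        self.use_lowlevel = HAVE_LOWLEVEL if use_lowlevel is None else use_lowlevel

    def fit(self, K: np.ndarray, y: np.ndarray) -> "PrecomputedSVM":
        K = np.asarray(K, dtype=np.float64, order="C")
        y = np.asarray(y, dtype=np.float64)
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        if self.use_lowlevel:
            self._model = _libsvm.fit(K, y, svm_type=0, kernel="precomputed",
                                      C=self.C)
            self._K_train = K
            self._classes = np.unique(y)  # sorted ascending
            self._sign = None  # calibrated lazily on first decision() call
        else:
            self._svc = SVC(C=self.C, kernel="precomputed").fit(K, y)
        return self

    def _calibrate_sign(self, K_train: np.ndarray) -> float:
        dec = _libsvm.decision_function(K_train, *self._model[:7], svm_type=0,
                                        kernel="precomputed").ravel()
        j = int(np.argmax(np.abs(dec)))
        if dec[j] == 0.0:
            return 1.0
        # predict returns the class index into the sorted unique labels;
        # index 1 is the larger label (+1 = case), the "positive" side
        idx = int(_libsvm.predict(K_train[j:j + 1], *self._model[:7],
                                  svm_type=0, kernel="precomputed")[0])
        return 1.0 if (dec[j] > 0) == (idx == 1) else -1.0

    def decision(self, K_rows: np.ndarray) -> np.ndarray:
        """Signed decision values for kernel rows against the training set."""
        K_rows = np.asarray(K_rows, dtype=np.float64, order="C")
        if K_rows.ndim == 1:
            K_rows = K_rows[None, :]
        if self.use_lowlevel:
            if self._sign is None:
                self._sign = self._calibrate_sign(self._K_train)
            dec = _libsvm.decision_function(K_rows, *self._model[:7],
                                            svm_type=0,
                                            kernel="precomputed").ravel()
            return self._sign * dec
        return self._svc.decision_function(K_rows)

    def predict(self, K_rows: np.ndarray) -> np.ndarray:
        """+1 (case) where the decision value is > 0, else -1 (control).

        A decision value of exactly 0 is resolved to control (conservative).
        """
        return np.where(self.decision(K_rows) > 0, 1.0, -1.0)


def fit_predict_label(K_sub: np.ndarray, y_sub: np.ndarray,
                      K_row: np.ndarray, C: float,
                      use_lowlevel: bool | None = None) -> float:
    """Fit a C-SVC on a kernel submatrix and predict one test kernel row.

    Hot path of the grid search: no estimator object, no sign calibration —
    libsvm's own class prediction is returned directly.
    """
    use = HAVE_LOWLEVEL if use_lowlevel is None else use_lowlevel
    if use:
        model = _libsvm.fit(K_sub, y_sub, svm_type=0, kernel="precomputed",
                            C=float(C))
        # the low-level predict returns the class *index* into the sorted
        # unique labels, not the label itself
        idx = int(_libsvm.predict(K_row, *model[:7], svm_type=0,
                                  kernel="precomputed")[0])
        return float(np.unique(y_sub)[idx])
    svc = SVC(C=C, kernel="precomputed").fit(K_sub, y_sub)
    return float(svc.predict(K_row)[0])


def loo_accuracy(K: np.ndarray, y: np.ndarray, C: float,
                 use_lowlevel: bool | None = None) -> float:
    """Exact leave-one-out accuracy of a C-SVC on a precomputed kernel."""
    K = np.asarray(K, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    idx = np.arange(n)
    correct = 0
    for i in range(n):
        keep = idx != i
        sub = np.ascontiguousarray(K[np.ix_(keep, keep)])
        row = np.ascontiguousarray(K[i, keep][None, :])
        pred = fit_predict_label(sub, y[keep], row, C,
                                 use_lowlevel=use_lowlevel)
        correct += pred == y[i]
    return correct / n
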