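"""Linear maximum-margin classifier via dual coordinate descent.

Solves the L1-hinge soft-margin SVM dual (the liblinear algorithm) on tiny
per-time-point problems. The bias is carried as an augmented constant
feature. JIT-compiled with numba: decoding runs millions of these fits, so
per-fit overhead is the budget driver; a pure-NumPy scikit-learn fit would
be ~50x slower end to end.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

__all__ = ["svm_train", "svm_decision", "_HAVE_NUMBA"]

MAX_EPOCHS = 80
TOL = 1e-3


@njit(cache=True)
def _train_dcd(X, y, C, max_epochs, tol):  # pragma: no cover - jitted
    n, d = X.shape
    w = np.zeros(d)
    alpha = np.zeros(n)
    qii = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(d):
            s += X[i, j] * X[i, j]
        qii[i] = s if s > 1e-12 else 1e-12
    for _ in range(max_epochs):
        max_pg = 0.0
        for i in range(n):
            g = -1.0
            for j in range(d):
                g += y[i] * w[j] * X[i, j]
            if alpha[i] <= 0.0:
                pg = g if g < 0.0 else 0.0
            elif alpha[i] >= C:
                pg = g if g > 0.0 else 0.0
            else:
                pg = g
            apg = -pg if pg < 0.0 else pg
            if apg > max_pg:
                max_pg = apg
            if apg > 1e-14:
                a_old = alpha[i]
                a_new = a_old - g / qii[i]
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > C:
                    a_new = C
                delta = (a_new - a_old) * y[i]
                if delta != 0.0:
                    alpha[i] = a_new
                    for j in range(d):
                        w[j] += delta * X[i, j]
        if max_pg < tol:
            break
    return w


def svm_train(X: np.ndarray, y: np.ndarray, C: float = 1.0,
              max_epochs: int = MAX_EPOCHS, tol: float = TOL) -> np.ndarray:
    """Train on (n, d) features with labels in {-1, +1}; returns w of length
    d + 1 (last entry is the bias weight for an implicit constant feature)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    Xb = np.hstack([X, np.ones((X.shape[0], 1))])
    return _train_dcd(Xb, y, float(C), max_epochs, tol)


def svm_decision(w: np.ndarray, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    return X @ w[:-1] + w[-1]
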