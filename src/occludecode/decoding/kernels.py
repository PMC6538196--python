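"""JIT-compiled decoding inner loops.

Per repetition: hold out one random trial per condition, train the linear
maximum-margin classifier on the remaining N-1 per condition (features =
sensors at one time point, standardized by training-fold statistics), test
on the held-out pair. Accuracy is the mean over repetitions and the two
held-out tests.
"""

from __future__ import annotations

import numpy as np

from .svm import njit, _train_dcd

__all__ = ["decode_curve_kernel", "decode_tgm_kernel"]


@njit(cache=True)
def _fill_fold(Xa, Xb, ia, ib, t, Xtr, ytr, standardize):  # pragma: no cover
    """Assemble the standardized training fold at time t; returns (mu, sd)."""
    n, d, _ = Xa.shape
    row = 0
    for i in range(n):
        if i != ia:
            for j in range(d):
                Xtr[row, j] = Xa[i, j, t]
            ytr[row] = 1.0
            row += 1
    for i in range(n):
        if i != ib:
            for j in range(d):
                Xtr[row, j] = Xb[i, j, t]
            ytr[row] = -1.0
            row += 1
    ntr = row
    mu = np.zeros(d)
    sd = np.ones(d)
    if standardize:
        for j in range(d):
            s = 0.0
            for i in range(ntr):
                s += Xtr[i, j]
            m = s / ntr
            v = 0.0
            for i in range(ntr):
                diff = Xtr[i, j] - m
                v += diff * diff
            v = np.sqrt(v / ntr)
            if v < 1e-12:
                v = 1.0
            mu[j] = m
            sd[j] = v
            for i in range(ntr):
                Xtr[i, j] = (Xtr[i, j] - m) / v
    for i in range(ntr):
        Xtr[i, d] = 1.0
    return mu, sd


@njit(cache=True)
def decode_curve_kernel(Xa, Xb, hoa, hob, C, max_epochs, tol,
                        standardize):  # pragma: no cover - jitted
    """Accuracy (fraction correct) per time point. Xa, Xb: (n, d, T)."""
    n, d, T = Xa.shape
    reps = hoa.shape[0]
    ntr = 2 * (n - 1)
    acc = np.zeros(T)
    Xtr = np.empty((ntr, d + 1))
    ytr = np.empty(ntr)
    for r in range(reps):
        ia = hoa[r]
        ib = hob[r]
        for t in range(T):
            mu, sd = _fill_fold(Xa, Xb, ia, ib, t, Xtr, ytr, standardize)
            w = _train_dcd(Xtr, ytr, C, max_epochs, tol)
            sa = w[d]
            sb = w[d]
            for j in range(d):
                sa += w[j] * (Xa[ia, j, t] - mu[j]) / sd[j]
                sb += w[j] * (Xb[ib, j, t] - mu[j]) / sd[j]
            if sa > 0.0:
                acc[t] += 0.5
            if sb < 0.0:
                acc[t] += 0.5
    return acc / reps


@njit(cache=True)
def decode_tgm_kernel(XaTr, XbTr, XaTe, XbTe, hoa, hob, C, max_epochs, tol,
                      standardize):  # pragma: no cover - jitted
    """Train-time × test-time accuracy.

    Training folds come from (XaTr, XbTr) excluding the held-out index; test
    vectors are the held-out trials of (XaTe, XbTe). Test features at t_test
    are standardized with training-fold statistics at t_test.
    """
    n, d, T = XaTr.shape
    reps = hoa.shape[0]
    ntr = 2 * (n - 1)
    acc = np.zeros((T, T))
    Xtr = np.empty((ntr, d + 1))
    ytr = np.empty(ntr)
    mu_all = np.empty((d, T))
    sd_all = np.empty((d, T))
    za = np.empty(T)
    zb = np.empty(T)
    for r in range(reps):
        ia = hoa[r]
        ib = hob[r]
        # training-fold stats at every time point (for test-side mapping)
        for t in range(T):
            for j in range(d):
                s = 0.0
                cnt = 0
                for i in range(n):
                    if i != ia:
                        s += XaTr[i, j, t]
                        cnt += 1
                    if i != ib:
                        s += XbTr[i, j, t]
                        cnt += 1
                m = s / cnt
                v = 0.0
                for i in range(n):
                    if i != ia:
                        diff = XaTr[i, j, t] - m
                        v += diff * diff
                    if i != ib:
                        diff = XbTr[i, j, t] - m
                        v += diff * diff
                v = np.sqrt(v / cnt)
                if v < 1e-12 or not standardize:
                    if standardize:
                        v = 1.0
                    else:
                        m = 0.0
                        v = 1.0
                mu_all[j, t] = m
                sd_all[j, t] = v
        for ttr in range(T):
            mu, sd = _fill_fold(XaTr, XbTr, ia, ib, ttr, Xtr, ytr, standardize)
            w = _train_dcd(Xtr, ytr, C, max_epochs, tol)
            for tte in range(T):
                sa = w[d]
                sb = w[d]
                for j in range(d):
                    sa += w[j] * (XaTe[ia, j, tte] - mu_all[j, tte]) / sd_all[j, tte]
                    sb += w[j] * (XbTe[ib, j, tte] - mu_all[j, tte]) / sd_all[j, tte]
                if sa > 0.0:
                    acc[ttr, tte] += 0.5
                if sb < 0.0:
                    acc[ttr, tte] += 0.5
    return acc / reps
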