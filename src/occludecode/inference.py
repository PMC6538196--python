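"""Group-level nonparametric inference.

Wilcoxon signed-rank tests (exact null for small n, normal approximation
with tie correction otherwise), Benjamini–Hochberg FDR adjustment, onset and
peak latency extraction, leave-one-subject-out jackknife dispersion, paired
curve comparison, and temporal-generalization summary statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError

__all__ = [
    "SignificanceMask",
    "LatencyEstimate",
    "signrank_p",
    "fdr_adjust",
    "onset_latency",
    "peak_latency",
    "group_onset",
    "jackknife_latency",
    "compare_curves",
    "diagonal_asymmetry",
]

EXACT_N_MAX = 25


@dataclass
class SignificanceMask:
    """Raw and FDR-adjusted p-values over one correction family."""

    p: np.ndarray
    q: np.ndarray
    alpha: float = 0.05
    sided: str = "right"
    correction_scope: str = "time"

    @property
    def mask(self) -> np.ndarray:
        return self.q < self.alpha


@dataclass
class LatencyEstimate:
    onset_mean_ms: Optional[float]
    onset_sd_ms: Optional[float]
    peak_mean_ms: Optional[float]
    peak_sd_ms: Optional[float]
    n_folds: int


def _exact_signrank_sf(ranks2: np.ndarray, w2: int) -> float:
    """P(W+ >= w) under the exact sign-flip null, conditioned on the ranks.

    ``ranks2`` are the (mid)ranks doubled so ties stay integral. Dynamic
    programming over the distribution of the doubled positive-rank sum.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    if w2 <= 0:
        return 1.0
    return float(dist[min(w2, total):].sum())


def signrank_p(values, mu0: float = 0.0, sided: str = "right") -> float:
    """Wilcoxon signed-rank p-value of ``values`` against location ``mu0``.

    Zero differences are discarded (Wilcoxon convention); ties get midranks.
    Exact sign-flip null (conditional on the observed ranks) for n <= 25,
    normal approximation with tie correction and continuity correction
    above. ``sided`` is ``"right"`` (location > mu0) or ``"two"``.
    """
    if sided not in ("right", "two"):
        raise ConfigurationError("sided must be 'right' or 'two'")
    d = np.asarray(values, dtype=float) - mu0
    if np.isnan(d).any():
        raise ConfigurationError("NaN values passed to signrank_p")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; returning p = 1", stacklevel=2)
        return 1.0

    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())

    if n <= EXACT_N_MAX:
        ranks2 = np.round(2.0 * ranks).astype(int)
        p_right = _exact_signrank_sf(ranks2, int(round(2.0 * w_pos)))
        if sided == "right":
            return p_right
        p_left = _exact_signrank_sf(ranks2, int(round(2.0 * w_neg)))
        return min(1.0, 2.0 * min(p_right, p_left))

    mean = n * (n + 1) / 4.0
    # variance with tie correction
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_pos - mean - 0.5) / np.sqrt(var)
    p_right = float(sps.norm.sf(z))
    if sided == "right":
        return p_right
    z2 = (abs(w_pos - mean) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(z2)))


def fdr_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ConfigurationError("NaN p-values passed to fdr_adjust")
    if ((p < 0) | (p > 1)).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    shape = p.shape
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat, kind="mergesort")
    ranked = flat[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.reshape(shape)


def onset_latency(mask, time_ms, min_run_ms: float = 10.0) -> Optional[float]:
    """Earliest time starting a run of >= ``min_run_ms`` consecutive
    significant samples, or None. Coarser grids convert the run length to
    ``ceil(min_run_ms / dt)`` samples."""
    mask = np.asarray(mask, dtype=bool)
    time_ms = np.asarray(time_ms, dtype=float)
    if mask.size == 0:
        raise ConfigurationError("empty significance mask")
    if mask.shape != time_ms.shape:
        raise ConfigurationError("mask and time axis shapes differ")
    dt = float(np.median(np.diff(time_ms))) if time_ms.size > 1 else 1.0
    min_run = max(1, int(np.ceil(min_run_ms / dt)))
    run = 0
    for i, sig in enumerate(mask):
        run = run + 1 if sig else 0
        if run >= min_run:
            return float(time_ms[i - min_run + 1])
    return None


def peak_latency(mean_curve, time_ms) -> float:
    """Time of the curve maximum; ties broken by the earliest time."""
    curve = np.asarray(mean_curve, dtype=float)
    if curve.size == 0:
        raise ConfigurationError("empty curve")
    return float(np.asarray(time_ms, dtype=float)[int(np.argmax(curve))])


def group_onset(
    curves: np.ndarray,
    time_ms,
    chance: float = 50.0,
    alpha: float = 0.05,
    min_run_ms: float = 10.0,
) -> Tuple[Optional[float], SignificanceMask]:
    """Group onset from per-subject curves (subjects × time).

    Right-sided sign-rank vs chance per time point, FDR across time, then
    the consecutive-run onset rule on the group significance mask.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    p = np.array([signrank_p(curves[:, t], mu0=chance, sided="right")
                  for t in range(curves.shape[1])])
    q = fdr_adjust(p)
    sig = SignificanceMask(p=p, q=q, alpha=alpha, sided="right", correction_scope="time")
    return onset_latency(sig.mask, time_ms, min_run_ms), sig


def jackknife_latency(
    per_subject_curves: np.ndarray,
    time_ms,
    statistic: str = "onset",
    chance: float = 50.0,
    alpha: float = 0.05,
    min_run_ms: float = 10.0,
) -> LatencyEstimate:
    """Leave-one-subject-out mean and SD of onset or peak latency.

    Onset folds recompute the group sign-rank + FDR mask without the held-out
    subject; peak folds take the argmax of the leave-one-out group mean
    curve. Folds with no qualifying onset are recorded as missing and the
    estimate is reported over the available folds with a warning.
    """
    curves = np.atleast_2d(np.asarray(per_subject_curves, dtype=float))
    n = curves.shape[0]
    if n < 3:
        raise ConfigurationError(f"jackknife requires >= 3 subjects, got {n}")
    if statistic not in ("onset", "peak"):
        raise ConfigurationError("statistic must be 'onset' or 'peak'")

    vals = []
    missing = 0
    for leave in range(n):
        rest = np.delete(curves, leave, axis=0)
        if statistic == "peak":
            vals.append(peak_latency(rest.mean(axis=0), time_ms))
        else:
            onset, _ = group_onset(rest, time_ms, chance=chance, alpha=alpha,
                                   min_run_ms=min_run_ms)
            if onset is None:
                missing += 1
            else:
                vals.append(onset)
    if missing:
        warnings.warn(f"{missing}/{n} jackknife folds yielded no onset", stacklevel=2)
    if not vals:
        est = (None, None)
    else:
        arr = np.asarray(vals)
        est = (float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0)

    if statistic == "peak":
        return LatencyEstimate(None, None, est[0], est[1], n_folds=len(vals))
    return LatencyEstimate(est[0], est[1], None, None, n_folds=len(vals))


def compare_curves(curves_a: np.ndarray, curves_b: np.ndarray,
                   alpha: float = 0.05) -> SignificanceMask:
    """Paired two-sided sign-rank between two per-subject curve stacks,
    FDR-corrected across time."""
    a = np.atleast_2d(np.asarray(curves_a, dtype=float))
    b = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if a.shape != b.shape:
        raise ConfigurationError(f"curve stacks differ in shape: {a.shape} vs {b.shape}")
    diffs = a - b
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = np.array([signrank_p(diffs[:, t], mu0=0.0, sided="two")
                      for t in range(diffs.shape[1])])
    return SignificanceMask(p=p, q=fdr_adjust(p), alpha=alpha, sided="two",
                            correction_scope="time")


def diagonal_asymmetry(mask: np.ndarray) -> Tuple[Optional[float], Optional[float]]:
    """Fractions of significant TGM cells strictly above / below the diagonal.

    ``mask[train, test]``; a cell with test later than train counts as
    *above*. Fractions are taken over all significant cells (so above +
    below + diagonal share = 1). Returns (None, None) with a warning when
    nothing is significant.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ConfigurationError("diagonal_asymmetry requires a square mask")
    total = int(mask.sum())
    if total == 0:
        warnings.warn("no significant cells; asymmetry undefined", stacklevel=2)
        return None, None
    train, test = np.nonzero(mask)
    above = int((test > train).sum())
    below = int((test < train).sum())
    return above / total, below / total
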