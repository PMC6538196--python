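"""Representational similarity analysis.

Time-resolved representational dissimilarity matrices (RDMs), model–brain
rank correlation time-courses, time-bin RDM averaging, semipartial variance
partitioning, and split-half replicability as a noise-level proxy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats as sps

from . import inference
from .errors import ConfigurationError
from .synthgen.generator import EpochedDataset
from .synthgen import split_half as _split_half

__all__ = [
    "RDM",
    "RDMSeries",
    "SemipartialResult",
    "compute_rdm",
    "meg_rdm_series",
    "rdm_correlation_timecourse",
    "bin_rdm",
    "semipartial",
    "semipartial_rdm",
    "split_half_replicability",
    "lower_triangle",
]

METRICS = ("one_minus_spearman", "one_minus_pearson")


@dataclass
class RDM:
    """Symmetric dissimilarity matrix with zero diagonal, entries in [0, 2]."""

    d: np.ndarray
    metric: str = "one_minus_spearman"

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ConfigurationError("RDM must be square")
        self.d = d

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def triangle(self) -> np.ndarray:
        return lower_triangle(self.d)


@dataclass
class RDMSeries:
    """Per-subject, per-time stack of RDMs: values (subject, time, k, k)."""

    values: np.ndarray
    time_ms: np.ndarray
    metric: str = "one_minus_spearman"

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class SemipartialResult:
    r12: float
    r13: float
    r23: float
    r_sp: float


def lower_triangle(mat: np.ndarray) -> np.ndarray:
    """Strictly-lower-triangle entries, row-major order (fixed convention)."""
    mat = np.asarray(mat)
    i, j = np.tril_indices(mat.shape[0], k=-1)
    return mat[i, j]


def _corr_matrix(patterns: np.ndarray, metric: str) -> np.ndarray:
    x = np.asarray(patterns, dtype=float)
    sd = x.std(axis=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ConfigurationError(f"zero-variance pattern for condition index {bad[0]}")
    if metric == "one_minus_spearman":
        x = np.apply_along_axis(sps.rankdata, 1, x)
    return np.corrcoef(x)


def compute_rdm(patterns, metric: str = "one_minus_spearman") -> RDM:
    """RDM from k condition pattern vectors: d[i, j] = 1 - correlation."""
    if metric not in METRICS:
        raise ConfigurationError(f"metric must be one of {METRICS}")
    x = np.asarray(patterns, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ConfigurationError("need >= 2 patterns of length >= 2")
    d = 1.0 - _corr_matrix(x, metric)
    np.fill_diagonal(d, 0.0)
    return RDM(d=0.5 * (d + d.T), metric=metric)


def meg_rdm_series(
    ds: EpochedDataset,
    metric: str = "one_minus_spearman",
    condition_indices: Optional[np.ndarray] = None,
) -> RDMSeries:
    """Per-subject, per-time RDMs from trial-averaged sensor patterns."""
    cond = (np.arange(ds.data.shape[1]) if condition_indices is None
            else np.asarray(condition_indices, dtype=int))
    mean = ds.data[:, cond].mean(axis=2)  # (subject, condition, sensor, time)
    n_s, k, _, n_t = mean.shape
    out = np.empty((n_s, n_t, k, k))
    for s in range(n_s):
        for t in range(n_t):
            out[s, t] = compute_rdm(mean[s, :, :, t], metric=metric).d
    return RDMSeries(values=out, time_ms=np.asarray(ds.time_ms, dtype=float), metric=metric)


def _spearman_triangles(a: np.ndarray, b: np.ndarray) -> float:
    ra, rb = sps.rankdata(a), sps.rankdata(b)
    if ra.std() == 0 or rb.std() == 0:
        raise ConfigurationError("zero-variance triangle; correlation undefined")
    return float(np.corrcoef(ra, rb)[0, 1])


def rdm_correlation_timecourse(
    series: RDMSeries, model: RDM, alpha: float = 0.05
) -> Tuple[np.ndarray, inference.SignificanceMask]:
    """Spearman correlation of each RDM slice's lower triangle with a model
    RDM; group inference via right-sided sign-rank vs 0, FDR across time."""
    if series.values.shape[-1] != model.n:
        raise ConfigurationError("condition-set size mismatch between series and model")
    mt = model.triangle()
    n_s, n_t = series.values.shape[:2]
    r = np.empty((n_s, n_t))
    for s in range(n_s):
        for t in range(n_t):
            r[s, t] = _spearman_triangles(lower_triangle(series.values[s, t]), mt)
    _, sig = inference.group_onset(r, series.time_ms, chance=0.0, alpha=alpha)
    return r, sig


def bin_rdm(series: RDMSeries, window_ms: Tuple[float, float]) -> np.ndarray:
    """Per-subject elementwise mean of RDM slices within a time window."""
    t = series.time_ms
    sel = (t >= window_ms[0]) & (t <= window_ms[1])
    if not sel.any():
        raise ConfigurationError(f"empty window {window_ms} on axis [{t[0]}, {t[-1]}]")
    return series.values[:, sel].mean(axis=1)


def semipartial(r12: float, r13: float, r23: float) -> float:
    """Unique contribution of predictor 2 to target 1, controlling 3:
    (r12 - r13 * r23) / sqrt(1 - r23**2)."""
    if abs(r23) >= 1.0:
        raise ConfigurationError("predictors are collinear (|r23| = 1)")
    return float((r12 - r13 * r23) / np.sqrt(1.0 - r23 ** 2))


def semipartial_rdm(meg: RDM, model1: RDM, model2: RDM
                    ) -> Tuple[SemipartialResult, SemipartialResult]:
    """Unique (semipartial) contribution of each model RDM to the data RDM.

    Correlations are Spearman over lower triangles. Returns the result for
    model1 controlling model2 and the converse.
    """
    if not (meg.n == model1.n == model2.n):
        raise ConfigurationError("condition-set size mismatch")
    mt = meg.triangle()
    t1, t2 = model1.triangle(), model2.triangle()
    r12 = _spearman_triangles(mt, t1)
    r13 = _spearman_triangles(mt, t2)
    r23 = _spearman_triangles(t1, t2)
    res1 = SemipartialResult(r12=r12, r13=r13, r23=r23,
                             r_sp=semipartial(r12, r13, r23))
    res2 = SemipartialResult(r12=r13, r13=r12, r23=r23,
                             r_sp=semipartial(r13, r12, r23))
    return res1, res2


def split_half_replicability(
    ds: EpochedDataset, seed: int, alpha: float = 0.05, mask_state: str = "no_mask"
) -> Dict:
    """Split-half pattern replicability per occlusion level over time.

    Trials are randomly halved per condition; raw trial-mean patterns per
    half give per-time distance matrices (1 - Pearson); replicability is the
    Spearman correlation between the halves' distance entries. Per-level
    curves use the distance entries among that level's object pairs; the
    ``"all"`` curve uses the full lower triangle. Level curves are compared
    pairwise with two-sided sign-rank + FDR.
    """
    if ds.n_trials % 2 != 0:
        raise ConfigurationError("split-half requires an even trial count")
    half_a, half_b = _split_half(ds, seed)

    tab = ds.condition_table
    sel = tab.index[tab["mask"] == mask_state].to_numpy()
    if sel.size == 0:
        sel = tab.index.to_numpy()
    sub = tab.loc[sel].reset_index(drop=True)

    series_a = meg_rdm_series(_subset(half_a, sel), metric="one_minus_pearson")
    series_b = meg_rdm_series(_subset(half_b, sel), metric="one_minus_pearson")

    k = sel.size
    i_all, j_all = np.tril_indices(k, k=-1)
    levels = sorted(sub["occlusion"].unique())
    entry_sets = {"all": (i_all, j_all)}
    for lv in levels:
        members = set(sub.index[sub["occlusion"] == lv])
        keep = np.array([(i in members) and (j in members) for i, j in zip(i_all, j_all)])
        entry_sets[lv] = (i_all[keep], j_all[keep])

    n_s, n_t = series_a.values.shape[:2]
    curves = {key: np.empty((n_s, n_t)) for key in entry_sets}
    for s in range(n_s):
        for t in range(n_t):
            da, db = series_a.values[s, t], series_b.values[s, t]
            for key, (ii, jj) in entry_sets.items():
                curves[key][s, t] = _spearman_triangles(da[ii, jj], db[ii, jj])

    comparisons = {}
    for a_i in range(len(levels)):
        for b_i in range(a_i + 1, len(levels)):
            la, lb = levels[a_i], levels[b_i]
            comparisons[(la, lb)] = inference.compare_curves(
                curves[la], curves[lb], alpha=alpha)
    return {"curves": curves, "comparisons": comparisons, "time_ms": series_a.time_ms}


def _subset(ds: EpochedDataset, condition_indices: np.ndarray) -> EpochedDataset:
    return EpochedDataset(
        data=ds.data[:, condition_indices],
        time_ms=ds.time_ms,
        sample_rate_hz=ds.sample_rate_hz,
        condition_table=ds.condition_table.iloc[condition_indices].reset_index(drop=True),
        sensor_layout=ds.sensor_layout,
        seed=ds.seed,
    )
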