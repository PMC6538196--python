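"""Low-level visual feature control.

Verifies that occlusion level cannot be read out from V1-like Gabor-energy
features or a Gist-style pooled-orientation descriptor: a cross-validated
linear classifier should perform at chance on occlusion-level labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from skimage.filters import gabor_kernel
from skimage.transform import resize
from scipy.signal import fftconvolve
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from ..errors import ConfigurationError

__all__ = ["gabor_gist_features", "lowlevel_control_check", "LowLevelCheckResult"]

#: Gabor bank: 4 scales x 8 orientations; energy pooled on an 8x8 grid.
FREQUENCIES = (0.05, 0.1, 0.2, 0.4)
N_ORIENTATIONS = 8
POOL_GRID = 8
GIST_GRID = 4
FEATURE_SIZE = 64  # images are resized before filtering (speed)


def _kernels():
    ks = []
    for f in FREQUENCIES:
        for o in range(N_ORIENTATIONS):
            ks.append(gabor_kernel(f, theta=np.pi * o / N_ORIENTATIONS))
    return ks


_KERNELS = None


def _pool(energy: np.ndarray, grid: int) -> np.ndarray:
    h, w = energy.shape
    ys = np.array_split(np.arange(h), grid)
    xs = np.array_split(np.arange(w), grid)
    return np.array([[energy[np.ix_(y, x)].mean() for x in xs] for y in ys])


def gabor_gist_features(image: np.ndarray) -> np.ndarray:
    """V1-like Gabor energy maps (8x8 pooled) plus a Gist-style 4x4
    oriented-energy descriptor, concatenated into one feature vector."""
    global _KERNELS
    if _KERNELS is None:
        _KERNELS = _kernels()
    img = np.asarray(image, dtype=float)
    if img.shape[0] != FEATURE_SIZE:
        img = resize(img, (FEATURE_SIZE, FEATURE_SIZE), anti_aliasing=True)
    # global luminance statistics (before mean removal) so plain intensity
    # confounds are visible to the check; spatial detail stays with the
    # oriented-energy features
    feats = [np.array([img.mean(), img.std()])]
    img = img - img.mean()
    for k in _KERNELS:
        real = fftconvolve(img, np.real(k), mode="same")
        imag = fftconvolve(img, np.imag(k), mode="same")
        energy = np.sqrt(real ** 2 + imag ** 2)
        feats.append(_pool(energy, POOL_GRID).ravel())
        feats.append(_pool(energy, GIST_GRID).ravel())
    return np.concatenate(feats)


@dataclass
class LowLevelCheckResult:
    accuracy: float
    chance: float
    ci_low: float
    ci_high: float
    n_images: int

    @property
    def passed(self) -> bool:
        """Set passes when the 95% binomial CI of the accuracy contains chance."""
        return self.ci_low <= self.chance <= self.ci_high


def lowlevel_control_check(images: Sequence[np.ndarray], levels: Sequence,
                           seed: int = 0, n_folds: int = 5) -> LowLevelCheckResult:
    """Cross-validated linear decoding of occlusion level from low-level
    features; returns the accuracy with its 95% Clopper-Pearson interval."""
    levels = np.asarray(levels)
    uniq, counts = np.unique(levels, return_counts=True)
    if uniq.size < 2:
        raise ConfigurationError("need >= 2 occlusion levels")
    if counts.min() != counts.max():
        raise ConfigurationError(f"unbalanced classes: {dict(zip(uniq, counts))}")

    X = np.array([gabor_gist_features(im) for im in images])
    y = levels.astype(str)
    n_folds = min(n_folds, int(counts.min()))
    # center only: per-feature variance scaling would inflate near-zero
    # noise dimensions to the scale of genuinely informative ones and mask
    # gross confounds (e.g. mean-luminance differences)
    clf = make_pipeline(StandardScaler(with_std=False),
                        LogisticRegression(max_iter=2000, C=1.0))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in cv.split(X, y):
        clf.fit(X[tr], y[tr])
        correct += int((clf.predict(X[te]) == y[te]).sum())
    n = len(y)
    acc = correct / n
    ci = sps.binomtest(correct, n).proportion_ci(confidence_level=0.95)
    return LowLevelCheckResult(accuracy=acc, chance=1.0 / uniq.size,
                               ci_low=float(ci.low), ci_high=float(ci.high),
                               n_images=n)
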