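"""Toy training and the readout/evaluation protocols."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from sklearn.svm import LinearSVC

from .._rng import child_rng
from ..errors import ConfigurationError
from .layers import softmax_cross_entropy
from .net import FoldedNet, forward, forward_backward

__all__ = ["TrainSettings", "train_toy", "extract_features",
           "eval_leave_one_level_out", "confusion_and_correlation"]


@dataclass(frozen=True)
class TrainSettings:
    n_epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-2
    stage: int = 0
    #: when set, each batch trains at a stage drawn from this tuple
    #: (stage-sampled training); ``stage`` is then used for monitoring
    stage_sampling: tuple = None
    monitor_fraction: float = 0.2


class _Adam:
    def __init__(self, net: FoldedNet, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.state: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
        self.net = net

    def step(self) -> None:
        self.t += 1
        for layer, name, p in self.net.parameters():
            g = layer.grads[name]
            key = (id(layer), name)
            if key not in self.state:
                self.state[key] = (np.zeros_like(p), np.zeros_like(p))
            m, v = self.state[key]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _resize_images(images: np.ndarray, size: int) -> np.ndarray:
    if images.shape[-1] == size:
        return images
    from skimage.transform import resize

    return np.stack([resize(im, (size, size), anti_aliasing=True) for im in images])


def train_toy(net: FoldedNet, images: np.ndarray, labels: Sequence,
              settings: TrainSettings = TrainSettings(), seed: int = 0
              ) -> Dict[str, list]:
    """Gradient training (Adam) at a fixed readout stage.

    ``labels`` may be strings; they are encoded in sorted order. Returns a
    history dict with per-epoch training loss and monitoring accuracy. The
    monitoring split is held out from the gradient updates.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ConfigurationError("need at least two classes")
    y = np.searchsorted(classes, labels)
    x = _resize_images(np.asarray(images, dtype=float), net.arch.input_size)

    rng = child_rng(seed, 50)
    order = rng.permutation(len(y))
    n_mon = max(1, int(len(y) * settings.monitor_fraction))
    mon, tr = order[:n_mon], order[n_mon:]

    opt = _Adam(net, settings.learning_rate)
    history = {"loss": [], "monitor_accuracy": []}
    for epoch in range(settings.n_epochs):
        perm = rng.permutation(tr)
        losses = []
        for start in range(0, len(perm), settings.batch_size):
            idx = perm[start:start + settings.batch_size]
            stage = settings.stage
            if settings.stage_sampling:
                stage = settings.stage_sampling[
                    rng.integers(len(settings.stage_sampling))]
            net.zero_grads()
            _, _, loss = forward_backward(net, x[idx], stage, labels=y[idx])
            losses.append(loss)
            if settings.learning_rate > 0:
                opt.step()
        _, scores = forward(net, x[mon], settings.stage)
        acc = float((scores.argmax(axis=1) == y[mon]).mean())
        history["loss"].append(float(np.mean(losses)))
        history["monitor_accuracy"].append(acc)
    history["classes"] = classes.tolist()
    return history


def extract_features(net: FoldedNet, images: np.ndarray, stage: int) -> np.ndarray:
    """Penultimate (pre-softmax-head) feature vectors at a readout stage."""
    x = _resize_images(np.asarray(images, dtype=float), net.arch.input_size)
    feats = []
    for start in range(0, len(x), 32):
        f, _ = forward(net, x[start:start + 32], stage)
        feats.append(f)
    return np.concatenate(feats)


def eval_leave_one_level_out(features_by_level: Dict, labels_by_level: Dict,
                             n_reps: int = 15, seed: int = 0,
                             train_fraction: float = 0.8) -> Dict:
    """Generalization across occlusion levels.

    For each held-out level, a multiclass linear SVM is trained on the
    pooled features of the other two levels and tested on the held-out
    level; repeated over ``n_reps`` random subsamples of the training pool.
    """
    levels = sorted(features_by_level)
    if len(levels) < 3:
        raise ConfigurationError("need >= 3 occlusion levels")
    out = {}
    for held in levels:
        train_x = np.concatenate([features_by_level[lv] for lv in levels if lv != held])
        train_y = np.concatenate([np.asarray(labels_by_level[lv])
                                  for lv in levels if lv != held])
        test_x = features_by_level[held]
        test_y = np.asarray(labels_by_level[held])
        accs = []
        for rep in range(n_reps):
            rng = child_rng(seed, 60, rep)
            n_sub = max(2, int(train_fraction * len(train_y)))
            idx = rng.choice(len(train_y), size=n_sub, replace=False)
            if np.unique(train_y[idx]).size < 2:
                continue
            clf = LinearSVC(C=1.0, max_iter=5000)
            clf.fit(train_x[idx], train_y[idx])
            accs.append(float((clf.predict(test_x) == test_y).mean()))
        out[held] = float(np.mean(accs))
    return out


def confusion_and_correlation(preds_truth_a: Tuple, preds_truth_b: Tuple
                              ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Row-normalized percentage confusion matrices for two prediction sets
    and the Spearman correlation of their off-diagonal entries."""
    mats = []
    class_sets = []
    for preds, truth in (preds_truth_a, preds_truth_b):
        preds = np.asarray(preds)
        truth = np.asarray(truth)
        classes = np.unique(np.concatenate([preds, truth]))
        class_sets.append(tuple(classes))
        k = classes.size
        mat = np.zeros((k, k))
        for i, t in enumerate(classes):
            sel = truth == t
            if not sel.any():
                raise ConfigurationError(f"empty class {t!r}")
            for j, p in enumerate(classes):
                mat[i, j] = 100.0 * float((preds[sel] == p).mean())
        mats.append(mat)
    if class_sets[0] != class_sets[1]:
        raise ConfigurationError("prediction sets have different class sets")
    k = mats[0].shape[0]
    off = ~np.eye(k, dtype=bool)
    r = sps.spearmanr(mats[0][off], mats[1][off]).statistic
    return mats[0], mats[1], float(r)
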