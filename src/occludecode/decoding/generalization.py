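"""Temporal generalization and cross-condition generalization matrices."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError
from ..synthgen.generator import EpochedDataset
from .kernels import decode_tgm_kernel
from .params import DecodingParams
from .pairwise import _holdouts, _pair_data, object_pairs

logger = logging.getLogger(__name__)

__all__ = ["TemporalGeneralizationMatrix", "temporal_generalization", "cross_condition_tg"]


@dataclass
class TemporalGeneralizationMatrix:
    """Per-subject train-time × test-time decoding accuracy (percent)."""

    accuracy: np.ndarray  # (subject, train_time, test_time)
    train_time_ms: np.ndarray
    test_time_ms: np.ndarray
    train_label: str
    test_label: str
    n_repetitions: int
    chance: float = 50.0

    def group_mean(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)

    def diagonal(self) -> np.ndarray:
        """Per-subject diagonal (train time == test time)."""
        return np.diagonal(self.accuracy, axis1=1, axis2=2)


def _tg_matrix(ds_train: EpochedDataset, ds_test: EpochedDataset,
               pairs_train, pairs_test, params: DecodingParams,
               train_label: str, test_label: str) -> TemporalGeneralizationMatrix:
    window = ds_train.time_slice(*params.window_ms)
    t_axis = ds_train.time_ms[window]
    n_subj = ds_train.n_subjects
    acc = np.zeros((n_subj, t_axis.size, t_axis.size))
    for (ca_tr, cb_tr), (ca_te, cb_te) in zip(pairs_train, pairs_test):
        xa_tr, xb_tr, n_tr = _pair_data(ds_train, ca_tr, cb_tr, window)
        xa_te, xb_te, n_te = _pair_data(ds_test, ca_te, cb_te, window)
        n = min(n_tr, n_te)
        for s in range(n_subj):
            # hold-outs keyed by the *training* pair so the within-condition
            # matrix and its diagonal share draws with pairwise decoding
            hoa, hob = _holdouts(params, s, ca_tr, cb_tr, n)
            acc[s] += decode_tgm_kernel(
                xa_tr[s, :n], xb_tr[s, :n], xa_te[s, :n], xb_te[s, :n],
                hoa, hob, params.C, params.max_epochs, params.tol,
                params.standardize)
    acc *= 100.0 / len(pairs_train)
    return TemporalGeneralizationMatrix(
        accuracy=acc, train_time_ms=t_axis, test_time_ms=t_axis,
        train_label=train_label, test_label=test_label,
        n_repetitions=params.n_repetitions)


def temporal_generalization(ds: EpochedDataset, occlusion_level: int,
                            params: DecodingParams = DecodingParams(),
                            mask_state: str = "no_mask"
                            ) -> TemporalGeneralizationMatrix:
    """Within-condition time-time decoding: train at t_train, test the
    held-out trials at every t_test, averaged over the six object pairs."""
    pairs = object_pairs(ds, occlusion_level, mask_state)
    label = f"occ{occlusion_level}-{mask_state}"
    return _tg_matrix(ds, ds, pairs, pairs, params, label, label)


def cross_condition_tg(ds: EpochedDataset, train_level: int, test_level: int,
                       params: DecodingParams = DecodingParams(),
                       mask_state: str = "no_mask"
                       ) -> TemporalGeneralizationMatrix:
    """Train classifiers on one occlusion level, test on the other.

    Object pairs are matched across levels; the held-out trial indices index
    the test level's trials.
    """
    if train_level == test_level:
        logger.info("train and test levels identical (%s); delegating to "
                    "temporal_generalization", train_level)
        return temporal_generalization(ds, train_level, params, mask_state)
    pairs_train = object_pairs(ds, train_level, mask_state)
    pairs_test = object_pairs(ds, test_level, mask_state)
    return _tg_matrix(ds, ds, pairs_train, pairs_test, params,
                      f"occ{train_level}-{mask_state}",
                      f"occ{test_level}-{mask_state}")
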