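"""Decoding: preprocessing, pairwise curves, generalization, sensor maps."""

import numpy as np
import pytest

from occludecode.decoding import (
    DecodingParams,
    cross_condition_tg,
    decode_timecourse,
    pairwise_decode,
    preprocess,
    sensorwise_decode,
    temporal_generalization,
)
from occludecode.errors import ConfigurationError
from occludecode.synthgen import generate_epochs
from occludecode.synthgen.envelopes import ConditionEnvelope
from occludecode.synthgen.generator import EpochedDataset

from conftest import tiny_settings

FAST = DecodingParams(n_repetitions=5, window_ms=(-100.0, 348.0), seed=3)


@pytest.fixture(scope="module")
def prep_tiny(tiny_dataset):
    return preprocess(tiny_dataset)


@pytest.fixture(scope="module")
def prep_null(tiny_null_dataset):
    return preprocess(tiny_null_dataset)


@pytest.fixture(scope="module")
def prep_strong():
    """High-SNR sequential signal: clearly decodable during the response."""
    ds = generate_epochs(tiny_settings(snr=6.0, n_subjects=2), seed=9)
    return preprocess(ds)


class TestPreprocess:
    def test_constant_trace_rejected(self, tiny_dataset):
        ds = EpochedDataset(
            data=np.zeros_like(tiny_dataset.data),
            time_ms=tiny_dataset.time_ms,
            sample_rate_hz=tiny_dataset.sample_rate_hz,
            condition_table=tiny_dataset.condition_table,
            sensor_layout=tiny_dataset.sensor_layout,
            seed=0,
        )
        with pytest.raises(ConfigurationError, match="sensor"):
            preprocess(ds)

    def test_baseline_zscore_before_filtering(self, tiny_dataset):
        unfiltered = preprocess(tiny_dataset, lowpass_hz=None)
        base = unfiltered.time_ms < 0
        seg = unfiltered.data[..., base]
        assert np.abs(seg.mean(axis=-1)).max() < 1e-5
        assert np.abs(seg.std(axis=-1) - 1.0).max() < 1e-5

    def test_40hz_attenuated_by_20hz_lowpass(self):
        # FFT oracle at the reference 1 kHz rate: a pure 40 Hz sinusoid
        # loses > 90% of its amplitude; windowing controls leakage
        ds = generate_epochs(tiny_settings(sample_rate_hz=1000.0), seed=4)
        t = ds.time_ms / 1000.0
        sine = np.sin(2 * np.pi * 40.0 * t)
        data = np.broadcast_to(5.0 * sine, ds.data.shape).copy()
        pure = EpochedDataset(
            data=data.astype(np.float32), time_ms=ds.time_ms,
            sample_rate_hz=ds.sample_rate_hz,
            condition_table=ds.condition_table,
            sensor_layout=ds.sensor_layout, seed=0)
        out = preprocess(pure, lowpass_hz=20.0)
        unfilt = preprocess(pure, lowpass_hz=None)

        def amp40(x):
            w = np.hanning(x.size)
            spec = np.abs(np.fft.rfft(x * w))
            freqs = np.fft.rfftfreq(x.size, d=1.0 / ds.sample_rate_hz)
            return spec[np.argmin(np.abs(freqs - 40.0))]

        assert amp40(out.data[0, 0, 0, 0]) < 0.1 * amp40(unfilt.data[0, 0, 0, 0])

    def test_passband_preserved(self, tiny_dataset):
        out = preprocess(tiny_dataset, lowpass_hz=200.0)
        ref = preprocess(tiny_dataset, lowpass_hz=None)
        # generous cutoff changes little
        assert np.abs(out.data - ref.data).mean() < 0.2


class TestPairwiseDecode:
    def test_identical_trial_data_chance(self, prep_null):
        # two pure-noise conditions: no separability
        curve = pairwise_decode(prep_null, 0, 1, FAST)
        m = curve.accuracy.mean()
        assert abs(m - 50.0) < 6.0

    def test_label_shuffle_centers_on_chance(self):
        # decode two conditions whose trials were randomly intermixed; a
        # reasonable trial count keeps the small-n leave-one-out bias of a
        # fixed random split below the Monte-Carlo tolerance
        ds = preprocess(generate_epochs(
            tiny_settings(snr=6.0, n_subjects=2, n_trials_per_condition=24),
            seed=9))
        rng = np.random.default_rng(11)
        data = ds.data.copy()
        pool = np.concatenate([data[:, 0], data[:, 1]], axis=1)
        perm = rng.permutation(pool.shape[1])
        n = data.shape[2]
        data[:, 0] = pool[:, perm[:n]]
        data[:, 1] = pool[:, perm[n:]]
        shuffled = EpochedDataset(
            data=data, time_ms=ds.time_ms, sample_rate_hz=ds.sample_rate_hz,
            condition_table=ds.condition_table,
            sensor_layout=ds.sensor_layout, seed=0)
        curve = pairwise_decode(shuffled, 0, 1,
                                DecodingParams(n_repetitions=20,
                                               window_ms=(-100, 348), seed=4))
        assert abs(curve.accuracy.mean() - 50.0) < 4.0

    def test_separable_patterns_hit_100(self):
        # margin >> noise on every feature (per-feature standardization
        # makes a single-sensor margin fragile by design)
        settings = tiny_settings()
        base = generate_epochs(settings, seed=2)
        data = 0.01 * np.random.default_rng(0).standard_normal(base.data.shape)
        data[:, 0, :, :, :] += 10.0
        data[:, 1, :, :, :] -= 10.0
        ds = EpochedDataset(
            data=data.astype(np.float32), time_ms=base.time_ms,
            sample_rate_hz=base.sample_rate_hz,
            condition_table=base.condition_table,
            sensor_layout=base.sensor_layout, seed=0)
        curve = pairwise_decode(ds, 0, 1, FAST)
        assert (curve.accuracy == 100.0).all()

    def test_pair_symmetry(self, prep_tiny):
        c1 = pairwise_decode(prep_tiny, 0, 2, FAST)
        c2 = pairwise_decode(prep_tiny, 2, 0, FAST)
        np.testing.assert_array_equal(c1.accuracy, c2.accuracy)

    def test_accuracy_bounded(self, prep_tiny):
        c = pairwise_decode(prep_tiny, 0, 3, FAST)
        assert (c.accuracy >= 0).all() and (c.accuracy <= 100).all()

    def test_same_condition_rejected(self, prep_tiny):
        with pytest.raises(ConfigurationError):
            pairwise_decode(prep_tiny, 1, 1, FAST)


class TestDecodeTimecourse:
    def test_six_pairs_enumerated(self, prep_tiny):
        from occludecode.decoding import object_pairs

        pairs = object_pairs(prep_tiny, 0, "no_mask")
        assert len(pairs) == 6
        assert len({frozenset(p) for p in pairs}) == 6

    def test_mean_of_identical_curves_is_the_curve(self, prep_tiny):
        # average property validated through the public API: the
        # timecourse equals the mean of the six pairwise curves
        from occludecode.decoding import object_pairs

        curves = [pairwise_decode(prep_tiny, a, b, FAST).accuracy
                  for a, b in object_pairs(prep_tiny, 0)]
        tc = decode_timecourse(prep_tiny, 0, "no_mask", FAST)
        np.testing.assert_allclose(tc.accuracy, np.mean(curves, axis=0))

    def test_missing_object_rejected(self, prep_tiny):
        broken = EpochedDataset(
            data=prep_tiny.data[:, :11],
            time_ms=prep_tiny.time_ms,
            sample_rate_hz=prep_tiny.sample_rate_hz,
            condition_table=prep_tiny.condition_table.iloc[:11].reset_index(drop=True),
            sensor_layout=prep_tiny.sensor_layout, seed=0)
        with pytest.raises(ConfigurationError):
            decode_timecourse(broken, 80, "no_mask", FAST)


class TestSnrMonotonicity:
    def test_peak_accuracy_non_decreasing_in_amplitude(self):
        means = []
        for snr in (0.0, 1.5, 5.0):
            ds = preprocess(generate_epochs(
                tiny_settings(snr=snr, n_subjects=2, n_trials_per_condition=8),
                seed=13))
            c = decode_timecourse(ds, 0, "no_mask",
                                  DecodingParams(n_repetitions=5,
                                                 window_ms=(100, 200), seed=6))
            means.append(c.accuracy.mean())
        assert means[0] <= means[1] + 2.0
        assert means[1] <= means[2] + 2.0
        assert means[2] > means[0]


class TestTemporalGeneralization:
    def test_matrix_square_and_bounded(self, prep_strong):
        params = DecodingParams(n_repetitions=3, window_ms=(0, 300), seed=1)
        tgm = temporal_generalization(prep_strong, 0, params)
        n_t = tgm.train_time_ms.size
        assert tgm.accuracy.shape[1:] == (n_t, n_t)
        assert (tgm.accuracy >= 0).all() and (tgm.accuracy <= 100).all()

    def test_diagonal_equals_timecourse(self, prep_strong):
        params = DecodingParams(n_repetitions=5, window_ms=(0, 300), seed=2)
        tgm = temporal_generalization(prep_strong, 0, params)
        tc = decode_timecourse(prep_strong, 0, "no_mask", params)
        rms = np.sqrt(np.mean((tgm.diagonal() - tc.accuracy) ** 2))
        assert rms < 2.0

    def test_sustained_code_generalizes_off_diagonal(self):
        from conftest import strong_envelopes

        envs = strong_envelopes("sustained_after_onset")
        settings = tiny_settings(occlusions=(0,), envelopes=envs, snr=4.0,
                                 n_subjects=2)
        ds = preprocess(generate_epochs(settings, seed=10))
        params = DecodingParams(n_repetitions=5, window_ms=(100, 300), seed=3)
        tgm = temporal_generalization(ds, 0, params)
        m = tgm.group_mean()
        t = tgm.train_time_ms
        cell = m[np.argmin(np.abs(t - 160.0)), np.argmin(np.abs(t - 240.0))]
        assert cell > 70.0

    def test_sequential_code_stays_diagonal(self):
        from conftest import strong_envelopes

        envs = strong_envelopes("sequential")
        settings = tiny_settings(occlusions=(0,), envelopes=envs, snr=4.0,
                                 n_subjects=2, code_dwell_ms=20.0)
        ds = preprocess(generate_epochs(settings, seed=10))
        params = DecodingParams(n_repetitions=5, window_ms=(100, 300), seed=3)
        tgm = temporal_generalization(ds, 0, params)
        m = tgm.group_mean()
        t = tgm.train_time_ms
        i1 = np.argmin(np.abs(t - 160.0))
        i2 = np.argmin(np.abs(t - 240.0))
        # on-diagonal decodable, far off-diagonal near chance
        assert m[i1, i1] > 80.0
        assert m[i1, i2] < m[i1, i1] - 20.0


class TestCrossCondition:
    def test_identity_when_test_copies_train(self, prep_strong):
        params = DecodingParams(n_repetitions=4, window_ms=(100, 250), seed=5)
        within = temporal_generalization(prep_strong, 0, params)
        cross = cross_condition_tg(prep_strong, 0, 0, params)
        np.testing.assert_allclose(within.accuracy, cross.accuracy)

    def test_zero_signal_test_level_no_structure(self, prep_null):
        params = DecodingParams(n_repetitions=4, window_ms=(100, 250), seed=6)
        cross = cross_condition_tg(prep_null, 0, 60, params)
        assert abs(cross.accuracy.mean() - 50.0) < 6.0


class TestSensorwise:
    def test_group_count(self, prep_tiny):
        smap = sensorwise_decode(prep_tiny, params=FAST)
        assert smap.accuracy.shape[1] == prep_tiny.sensor_layout.n_groups == 2

    def test_signal_localizes_to_injected_group(self):
        settings = tiny_settings(n_sensors=9, n_active_groups=1, snr=5.0,
                                 n_subjects=2)
        ds = preprocess(generate_epochs(settings, seed=12))
        params = DecodingParams(n_repetitions=5, window_ms=(120, 220), seed=7)
        smap = sensorwise_decode(ds, params=params)
        mean_by_group = smap.accuracy.mean(axis=(0, 2))
        assert mean_by_group.argmax() == 0  # signal lives in group 0
        assert mean_by_group[0] > mean_by_group[1:].max() + 3.0
        assert (smap.peak_group() == 0).mean() > 0.8

    def test_non_triplet_layout_rejected(self, prep_tiny):
        from occludecode.synthgen import SensorLayout

        with pytest.raises(ConfigurationError):
            sensorwise_decode(prep_tiny, layout=SensorLayout(6, 2), params=FAST)
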