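"""Preprocessing chain: referencing, filtering, decimation, artifact
rejection and epoch segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import signal

from dmnpdc.preprocessing import (
    EpochSet,
    Recording,
    bandpass_fir,
    common_average_reference,
    downsample,
    preprocess,
    reject_artifacts,
    segment,
)

LAB2 = ("a", "b")
LAB3 = ("a", "b", "c")


def _rec(data, fs=256.0, labels=None):
    data = np.asarray(data, dtype=float)
    labels = labels or tuple(f"ch{i}" for i in range(data.shape[0]))
    return Recording(data=data, fs=fs, labels=labels)


def _sine(f, fs, dur, n_ch=1):
    t = np.arange(int(dur * fs)) / fs
    return np.tile(np.sin(2 * np.pi * f * t), (n_ch, 1))


class TestCommonAverageReference:
    def test_removes_common_offset(self):
        rec = _rec(np.full((3, 100), 10.0), labels=LAB3)
        out = common_average_reference(rec)
        assert np.allclose(out.data, 0.0)
        assert out.reference == "common_average"

    def test_idempotent_and_channel_sum_zero(self, rng):
        rec = _rec(rng.standard_normal((4, 500)))
        once = common_average_reference(rec)
        twice = common_average_reference(once)
        assert np.allclose(once.data.sum(axis=0), 0.0, atol=1e-12)
        assert np.allclose(once.data, twice.data)

    def test_antisymmetric_pair_unchanged(self, rng):
        a = rng.standard_normal(200)
        rec = _rec(np.stack([a, -a]), labels=LAB2)
        out = common_average_reference(rec)
        assert np.allclose(out.data, rec.data)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            common_average_reference(_rec(np.zeros((1, 10))))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        hnp.arrays(
            np.float64,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=16),
            elements=st.floats(-1e6, 1e6),
        )
    )
    def test_car_properties_hold_for_arbitrary_data(self, data):
        out = common_average_reference(_rec(data))
        scale = max(np.abs(data).max(), 1.0)
        assert np.max(np.abs(out.data.sum(axis=0))) < 1e-9 * scale
        again = common_average_reference(out)
        assert np.allclose(again.data, out.data, atol=1e-9 * scale)


class TestBandpass:
    def test_stopband_sinusoid_removed(self):
        rec = _rec(_sine(60.0, 256, 60))
        out = bandpass_fir(rec, 0.4, 50.0)
        # compare RMS away from the edges
        sl = slice(2560, -2560)
        assert np.sqrt((out.data[0, sl] ** 2).mean()) < 0.01 * np.sqrt(
            (rec.data[0, sl] ** 2).mean()
        )

    def test_passband_sinusoid_preserved(self):
        rec = _rec(_sine(10.0, 256, 60))
        out = bandpass_fir(rec, 0.4, 50.0)
        sl = slice(2560, -2560)
        ratio = np.sqrt((out.data[0, sl] ** 2).mean()) / np.sqrt(
            (rec.data[0, sl] ** 2).mean()
        )
        assert abs(ratio - 1.0) < 0.05

    def test_zero_signal_and_bad_edges(self):
        rec = _rec(np.zeros((2, 4096)), labels=LAB2)
        assert np.allclose(bandpass_fir(rec).data, 0.0)
        with pytest.raises(ValueError):
            bandpass_fir(rec, 50.0, 0.4)
        with pytest.raises(ValueError):
            bandpass_fir(rec, 0.4, 200.0)


class TestDownsample:
    def test_factor_eight_sample_count(self, rng):
        rec = _rec(rng.standard_normal((2, 2048 * 10)), fs=2048.0, labels=LAB2)
        out = downsample(rec, 256.0)
        assert out.fs == 256.0
        assert out.data.shape == (2, 2560)

    def test_identity_when_rates_match(self, rng):
        rec = _rec(rng.standard_normal((2, 1000)), labels=LAB2)
        out = downsample(rec, 256.0)
        assert np.allclose(out.data, rec.data)

    def test_inband_amplitude_preserved(self):
        rec = _rec(_sine(10.0, 2048, 10), fs=2048.0)
        out = downsample(rec, 256.0)
        # spectral peak amplitude within 2%
        sl = slice(256, -256)
        amp_in = np.sqrt(2 * (rec.data[0, sl] ** 2).mean())
        amp_out = np.sqrt(2 * (out.data[0, sl] ** 2).mean())
        assert abs(amp_out - amp_in) / amp_in < 0.02

    def test_non_integer_factor_rejected(self, rng):
        rec = _rec(rng.standard_normal((1, 1000)), fs=1000.0)
        with pytest.raises(ValueError):
            downsample(rec, 256.0)


class TestArtifactRejection:
    def test_clean_recording_unmarked(self, rng):
        rec = _rec(rng.standard_normal((4, 256 * 30)))
        out = reject_artifacts(rec, z_thresh=8.0)
        assert out.bad_spans is not None and not out.bad_spans.any()

    def test_injected_spike_marks_containing_span(self, rng):
        data = rng.standard_normal((4, 256 * 30))
        data[2, 256 * 12 + 7] = 500.0
        out = reject_artifacts(_rec(data), z_thresh=5.0)
        assert out.bad_spans[12]
        assert out.bad_spans.sum() == 1

    def test_infinite_thresholds_mark_nothing(self, rng):
        data = rng.standard_normal((2, 256 * 10)) * 1000
        out = reject_artifacts(_rec(data, labels=LAB2), z_thresh=np.inf)
        assert not out.bad_spans.any()

    def test_nonpositive_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            reject_artifacts(_rec(np.zeros((1, 256))), z_thresh=-1.0)


class TestSegment:
    def test_116_seconds_yield_29_epochs(self, rng):
        rec = _rec(rng.standard_normal((8, 256 * 116)))
        eps = segment(rec, 4.0)
        assert eps.n_epochs == 29
        assert eps.samples_per_epoch == 1024

    def test_incomplete_epoch_is_an_error(self, rng):
        rec = _rec(rng.standard_normal((2, int(256 * 3.9))), labels=LAB2)
        with pytest.raises(ValueError):
            segment(rec, 4.0)

    def test_tiling_reproduces_source_samples(self, rng):
        rec = _rec(rng.standard_normal((2, 256 * 8)), labels=LAB2)
        eps = segment(rec, 4.0)
        assert eps.n_epochs == 2
        recon = np.concatenate(list(eps.epochs), axis=1)
        assert np.array_equal(recon, rec.data)

    def test_bad_spans_excluded(self, rng):
        rec = _rec(rng.standard_normal((2, 256 * 16)), labels=LAB2)
        bad = np.zeros(16, dtype=bool)
        bad[5] = True  # poisons the 4-8 s candidate epoch
        rec.bad_spans = bad
        eps = segment(rec, 4.0)
        assert eps.n_epochs == 3
        assert list(eps.kept_mask) == [True, False, True, True]


class TestFullChain:
    def test_padding_with_silent_epochs_preserves_interior(self, rng):
        data = rng.standard_normal((2, 256 * 24))
        rec = _rec(data, labels=LAB2)
        padded = _rec(
            np.concatenate([np.zeros((2, 256 * 4)), data], axis=1), labels=LAB2
        )
        eps = preprocess(rec, z_thresh=np.inf)
        eps_p = preprocess(padded, z_thresh=np.inf)
        assert eps_p.n_epochs == eps.n_epochs + 1
        # interior epochs (away from the filter edge) match
        for k in range(1, eps.n_epochs - 1):
            assert np.allclose(
                eps.epochs[k], eps_p.epochs[k + 1], atol=1e-6
            )

    def test_inband_spectrum_preserved_through_filter_and_decimation(self, rng):
        # broadband signal at 2048 Hz: PSD over 1-30 Hz agrees within 10%
        # after band-pass + decimation to 256 Hz
        b, a = signal.butter(2, 40 / 1024)
        data = signal.lfilter(b, a, rng.standard_normal((1, 2048 * 60)))
        rec = _rec(data, fs=2048.0)
        out = downsample(bandpass_fir(rec, 0.4, 50.0), 256.0)
        f1, p1 = signal.welch(rec.data[0], fs=2048.0, nperseg=4096)
        f2, p2 = signal.welch(out.data[0], fs=256.0, nperseg=512)
        grid = np.arange(1.0, 30.1, 0.5)
        psd1 = np.interp(grid, f1, p1)
        psd2 = np.interp(grid, f2, p2)
        assert np.all(np.abs(psd2 - psd1) / psd1 < 0.10)

    def test_chain_output_rate_and_epoching(self, rng):
        rec = _rec(rng.standard_normal((3, 2048 * 20)), fs=2048.0, labels=LAB3)
        eps = preprocess(rec, target_fs=256.0, epoch_len_s=4.0, z_thresh=np.inf)
        assert isinstance(eps, EpochSet)
        assert eps.fs == 256.0
        assert eps.n_epochs == 5
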