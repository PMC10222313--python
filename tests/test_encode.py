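"""Signal-to-image encoders: framing arithmetic, DFT oracle, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy import signal

from emgpix import (
    EncodedImage,
    Recording,
    SpectrogramEncoder,
    StftSpec,
    TimeDomainEncoder,
    WindowSpec,
    augment_max_channel,
    encode_spectrogram,
    encode_time_domain,
    segment_recording,
    stft_frames,
    to_grayscale,
)
from emgpix.encode import segment_dataset
from emgpix.exceptions import DataError, DimensionError, DomainError, ParameterError

FS = 2000.0


class TestSegmentation:
    @pytest.mark.parametrize(
        "n_samples,expected",
        [(20_000, 40), (500, 1), (480, 0), (1249, 2)],
    )
    def test_segment_counts(self, n_samples, expected):
        rec = Recording(samples=np.zeros((4, n_samples)), fs=FS, gesture_id=1)
        if expected == 0:
            with pytest.warns(UserWarning):
                segs = segment_recording(rec)
        else:
            segs = segment_recording(rec)
        assert len(segs) == expected
        for s in segs:
            assert s.shape == (4, 500)

    def test_segments_tile_the_recording_without_overlap(self, short_recording):
        segs = segment_recording(short_recording)
        rebuilt = np.concatenate(segs, axis=1)
        n = rebuilt.shape[1]
        assert np.array_equal(rebuilt, short_recording.samples[:, :n])

    def test_segment_dataset_carries_labels_and_provenance(self, short_recording):
        segs, labels, prov = segment_dataset([short_recording])
        assert segs.shape == (4, 16, 500)
        assert np.all(labels == short_recording.gesture_id)
        assert prov == [(0, 0, 0), (0, 0, 1), (0, 0, 2), (0, 0, 3)]

    def test_fractional_sample_window_rejected(self):
        with pytest.raises(ParameterError):
            WindowSpec(segment_ms=250, window_ms=100, hop_ms=50).samples(fs=999.0)


class TestStft:
    def test_250ms_segment_gives_4_frames_129_bins(self):
        x = np.random.default_rng(0).standard_normal(500)
        m = stft_frames(x, fs=FS)
        assert m.shape == (4, 129)

    def test_all_zero_segment_gives_zero_magnitudes(self):
        assert np.allclose(stft_frames(np.zeros(500), fs=FS), 0.0)

    def test_magnitudes_match_direct_dft_oracle(self, rng):
        """Each frame equals |sum_n w[n] x[n] exp(-2pi i k n / 256)|."""
        x = rng.standard_normal(500)
        m = stft_frames(x, fs=FS)
        win = signal.get_window("hann", 200, fftbins=True)
        n_idx = np.arange(256)
        k_idx = np.arange(129)
        dft = np.exp(-2j * np.pi * np.outer(k_idx, n_idx) / 256)
        for frame in range(4):
            seg = np.zeros(256)
            seg[:200] = x[frame * 100: frame * 100 + 200] * win
            ref = np.abs(dft @ seg)
            np.testing.assert_allclose(m[frame], ref, rtol=1e-9, atol=1e-12)

    def test_parseval_energy_identity(self, rng):
        """Two-sided magnitude energy = nfft x windowed-sample energy."""
        x = rng.standard_normal(500)
        full = stft_frames(x, s=StftSpec(one_sided=False), fs=FS)
        win = signal.get_window("hann", 200, fftbins=True)
        for frame in range(4):
            w = x[frame * 100: frame * 100 + 200] * win
            assert full[frame].__pow__(2).sum() == pytest.approx(
                256 * (w**2).sum(), rel=1e-9
            )

    def test_nfft_smaller_than_window_rejected(self):
        with pytest.raises(ParameterError):
            stft_frames(np.zeros(500), s=StftSpec(nfft=128), fs=FS)

    def test_wrong_segment_length_rejected(self):
        with pytest.raises(DimensionError):
            stft_frames(np.zeros(400), fs=FS)


class TestSpectrogramImages:
    @pytest.mark.parametrize("channels,rows", [(8, 32), (16, 64), (9, 36), (17, 68)])
    def test_stacked_image_dimensions(self, channels, rows, rng):
        seg = rng.standard_normal((channels, 500))
        img = encode_spectrogram(seg, fs=FS)
        assert img.shape == (rows, 129)
        expected = "enhanced_spectrogram" if channels in (9, 17) else "spectrogram"
        assert img.encoder == expected

    def test_channel_permutation_permutes_row_blocks(self, rng):
        seg = rng.standard_normal((8, 500))
        perm = np.array([3, 1, 0, 2, 7, 6, 4, 5])
        # compare raw stacked magnitudes (normalization is permutation-invariant
        # only up to the global min/max, so check pre-normalized blocks)
        base = np.vstack([stft_frames(ch, fs=FS) for ch in seg])
        permuted = np.vstack([stft_frames(ch, fs=FS) for ch in seg[perm]])
        for out_block, src in enumerate(perm):
            np.testing.assert_array_equal(
                permuted[4 * out_block: 4 * out_block + 4],
                base[4 * src: 4 * src + 4],
            )

    def test_determinism(self, segment_500):
        a = encode_spectrogram(segment_500, fs=FS).pixels
        b = encode_spectrogram(segment_500, fs=FS).pixels
        assert np.array_equal(a, b)

    def test_batch_encoder_matches_single(self, segment_500):
        batch = SpectrogramEncoder(fs=FS).fit_transform(segment_500[None])
        single = encode_spectrogram(segment_500, fs=FS).pixels
        assert np.array_equal(batch[0], single)

    def test_enhanced_batch_encoder_appends_max_channel(self, segment_500):
        batch = SpectrogramEncoder(fs=FS, enhanced=True).fit_transform(segment_500[None])
        assert batch.shape == (1, 68, 129)


class TestMaxChannelAugmentation:
    @pytest.mark.parametrize("channels,out_channels", [(8, 9), (16, 17)])
    def test_channel_counts(self, channels, out_channels, rng):
        seg = rng.standard_normal((channels, 500))
        out = augment_max_channel(seg)
        assert out.shape == (out_channels, 500)
        np.testing.assert_array_equal(out[:channels], seg)

    def test_constant_channels_give_constant_max(self):
        seg = np.tile(np.arange(1.0, 9.0)[:, None], (1, 500))
        out = augment_max_channel(seg)
        assert np.all(out[-1] == 8.0)

    def test_auxiliary_row_dominates_every_channel(self, segment_500):
        out = augment_max_channel(segment_500)
        assert np.all(out[-1][None, :] >= out[:-1])

    def test_unsupported_channel_count_rejected(self, rng):
        with pytest.raises(DomainError):
            augment_max_channel(rng.standard_normal((10, 500)))


class TestTimeDomainImages:
    @pytest.mark.parametrize("channels", [8, 16])
    def test_image_dimensions(self, channels, rng):
        seg = rng.standard_normal((channels, 500))
        img = encode_time_domain(seg, fs=FS)
        assert img.shape == (channels, 250)
        assert img.encoder == "time_domain"

    def test_constant_segment_maps_to_zero_pixels(self):
        img = encode_time_domain(np.full((8, 500), 3.3), fs=FS)
        assert np.allclose(img.pixels, 0.0)

    def test_odd_segment_length_rejected(self, rng):
        with pytest.raises(DimensionError):
            encode_time_domain(rng.standard_normal((8, 501)), fs=FS)

    def test_batch_encoder_matches_single(self, segment_500):
        batch = TimeDomainEncoder(fs=FS).fit_transform(segment_500[None])
        single = encode_time_domain(segment_500, fs=FS).pixels
        assert np.array_equal(batch[0], single)


class TestGrayscale:
    def test_worked_example(self):
        out = to_grayscale(np.array([[0.0, 1.0], [2.0, 4.0]]))
        np.testing.assert_allclose(out, [[0.0, 0.25], [0.5, 1.0]])

    def test_constant_matrix_maps_to_zero(self):
        assert np.array_equal(to_grayscale(np.full((3, 3), 9.9)), np.zeros((3, 3)))

    def test_output_spans_unit_interval(self, rng):
        out = to_grayscale(rng.standard_normal((10, 10)))
        assert out.min() == 0.0 and out.max() == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            dtype=np.float64,
            shape=hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=12),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    def test_normalization_properties_hold_for_any_matrix(self, m):
        out = to_grayscale(m)
        assert out.shape == m.shape
        assert out.min() >= 0.0 and out.max() <= 1.0
        # idempotence: renormalizing a normalized image changes nothing
        np.testing.assert_allclose(to_grayscale(out), out, atol=1e-12)
        # order preservation
        flat_in, flat_out = m.ravel(), out.ravel()
        i, j = np.argmin(flat_in), np.argmax(flat_in)
        assert flat_out[i] == out.min() and flat_out[j] == out.max()

    def test_nonfinite_rejected(self):
        with pytest.raises(DataError):
            to_grayscale(np.array([[1.0, np.inf]]))

    def test_encoded_image_validates_pixel_range(self):
        with pytest.raises(DataError):
            EncodedImage(pixels=np.array([[2.0]]), encoder="time_domain",
                         n_channels_source=8, label=0)
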