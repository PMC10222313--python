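"""Signal-to-image encoders for CNN classification.

Myoelectric control must respond within ~300 ms, so classification operates
on 250 ms records.  Each 250 ms, 2000 sps multi-channel segment is turned
into one of three grayscale images:

``time_domain``
    each channel anti-alias decimated from 500 to 250 samples and stacked as
    an image row: 16x250 (or 8x250) pixels.
``spectrogram``
    per channel, a Hann-window STFT with a 100 ms window and 50 ms hop gives
    a 4x129 magnitude matrix (nfft 256, one-sided); channel matrices are
    concatenated row-wise into a 64x129 (16 ch) or 32x129 (8 ch) image.
``enhanced_spectrogram``
    the spectrogram encoder applied after appending an auxiliary channel,
    the pointwise maximum across channels, giving 17- or 9-channel input and
    a 68x129 or 36x129 image.

All images are min-max normalized to [0, 1] per image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DataError, DimensionError, DomainError, ParameterError
from .simulate import EIGHT_CHANNEL_SUBSET, Recording

__all__ = [
    "WindowSpec",
    "StftSpec",
    "EncodedImage",
    "segment_recording",
    "segment_dataset",
    "stft_frames",
    "encode_spectrogram",
    "encode_time_domain",
    "augment_max_channel",
    "to_grayscale",
    "TimeDomainEncoder",
    "SpectrogramEncoder",
    "EIGHT_CHANNEL_SUBSET",
]


@dataclass(frozen=True)
class WindowSpec:
    """Segment/window/hop durations in milliseconds.

    The 250 ms segment is the classification record; the 100 ms window with
    50 ms hop slides *within* a segment to form STFT frames.  Dataset
    construction uses non-overlapping consecutive segments so that train and
    test segments never share samples.
    """

    segment_ms: float = 250.0
    window_ms: float = 100.0
    hop_ms: float = 50.0

    def __post_init__(self) -> None:
        if min(self.segment_ms, self.window_ms, self.hop_ms) <= 0:
            raise ParameterError("all durations must be > 0")
        if self.window_ms > self.segment_ms:
            raise ParameterError("window_ms must be <= segment_ms")
        if self.hop_ms > self.window_ms:
            raise ParameterError("hop_ms must be <= window_ms")

    def samples(self, fs: float) -> tuple[int, int, int]:
        """(segment, window, hop) lengths in samples; must be integral."""
        out = []
        for ms in (self.segment_ms, self.window_ms, self.hop_ms):
            n = ms * fs / 1000.0
            if abs(n - round(n)) > 1e-9:
                raise ParameterError(f"{ms} ms is not an integer number of samples at fs={fs}")
            out.append(int(round(n)))
        return tuple(out)


@dataclass(frozen=True)
class StftSpec:
    """Short-time Fourier transform parameters (Hann window, one-sided)."""

    window_fn: str = "hann"
    nfft: int = 256
    one_sided: bool = True
    log_magnitude: bool = False

    def __post_init__(self) -> None:
        n = self.nfft
        if n < 1 or (n & (n - 1)) != 0:
            raise ParameterError(f"nfft must be a power of two, got {n}")


@dataclass
class EncodedImage:
    """One CNN input: a [0,1] pixel matrix plus label and provenance."""

    pixels: np.ndarray  # (rows, cols) in [0, 1]
    encoder: str  # time_domain | spectrogram | enhanced_spectrogram
    n_channels_source: int  # 8, 9, 16 or 17
    label: int
    subject_id: int = 0
    repetition: int = 0
    segment_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise DataError("image contains non-finite pixels")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise DataError("pixels must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def to_grayscale(matrix: np.ndarray) -> np.ndarray:
    """Per-image min-max normalization to [0, 1]; a constant image maps to 0."""
    m = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(m)):
        raise DataError("matrix contains non-finite entries")
    lo, hi = m.min(), m.max()
    # degenerate range, up to float round-off from upstream filtering
    if hi - lo <= 1e-12 * max(1.0, abs(hi), abs(lo)):
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def segment_recording(rec: Recording, w: WindowSpec | None = None) -> list[np.ndarray]:
    """Split a recording into consecutive non-overlapping 250 ms segments.

    Returns ``floor(n_samples / segment_samples)`` arrays of shape
    ``(n_channels, segment_samples)``; a recording shorter than one segment
    yields an empty list with a warning.
    """
    w = w or WindowSpec()
    seg_n, _, _ = w.samples(rec.fs)
    n = rec.n_samples // seg_n
    if n == 0:
        warnings.warn(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{seg_n}-sample segment; no segments produced",
            stacklevel=2,
        )
        return []
    return [rec.samples[:, i * seg_n:(i + 1) * seg_n].copy() for i in range(n)]


def segment_dataset(
    recordings: Iterable[Recording], w: WindowSpec | None = None
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, int]]]:
    """Segment many recordings into a batch.

    Returns ``(segments, labels, provenance)`` where ``segments`` has shape
    ``(n, n_channels, segment_samples)`` and provenance rows are
    ``(subject_id, repetition, segment_index)``.
    """
    segs, labels, prov = [], [], []
    for rec in recordings:
        for i, s in enumerate(segment_recording(rec, w)):
            segs.append(s)
            labels.append(rec.gesture_id)
            prov.append((rec.subject_id, rec.repetition, i))
    if not segs:
        raise DataError("no segments produced from the given recordings")
    return np.stack(segs), np.asarray(labels), prov


def _hann(n: int) -> np.ndarray:
    return signal.get_window("hann", n, fftbins=True)


def stft_frames(
    channel_segment: np.ndarray,
    w: WindowSpec | None = None,
    s: StftSpec | None = None,
    fs: float = 2000.0,
) -> np.ndarray:
    """Hann-window STFT magnitudes of one channel's segment.

    A 500-sample segment with a 200-sample window and 100-sample hop yields
    ``(500-200)/100 + 1 = 4`` frames; with nfft 256 one-sided there are
    ``256/2 + 1 = 129`` frequency bins, hence a 4x129 matrix.  Frames start
    flush at the segment edges with no zero-padding.
    """
    w = w or WindowSpec()
    s = s or StftSpec()
    x = np.asarray(channel_segment, dtype=float)
    if x.ndim != 1:
        raise DimensionError(f"expected a 1-D channel segment, got shape {x.shape}")
    seg_n, win_n, hop_n = w.samples(fs)
    if x.shape[0] != seg_n:
        raise DimensionError(f"segment must have {seg_n} samples, got {x.shape[0]}")
    if s.nfft < win_n:
        raise ParameterError(f"nfft={s.nfft} must be >= window length {win_n}")
    frames = sliding_window_view(x, win_n)[::hop_n] * _hann(win_n)
    if s.one_sided:
        spectrum = np.fft.rfft(frames, n=s.nfft, axis=-1)
    else:
        spectrum = np.fft.fft(frames, n=s.nfft, axis=-1)
    return np.abs(spectrum)


_SPECTRO_CHANNELS = (8, 9, 16, 17)


def encode_spectrogram(
    segment: np.ndarray,
    w: WindowSpec | None = None,
    s: StftSpec | None = None,
    fs: float = 2000.0,
    label: int = -1,
    subject_id: int = 0,
    repetition: int = 0,
    segment_index: int = 0,
) -> EncodedImage:
    """Stack per-channel STFT magnitude matrices into one grayscale image.

    Channel ``c`` occupies rows ``4c .. 4c+3`` (ascending channel order, the
    auxiliary max channel, when present, last), giving ``(4*C) x 129``
    pixels: 32x129 / 64x129 for plain 8/16-channel input and 36x129 / 68x129
    for the feature-enhanced 9/17-channel input.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 2 or seg.shape[0] not in _SPECTRO_CHANNELS:
        raise DimensionError(
            f"expected (C, segment_samples) with C in {_SPECTRO_CHANNELS}, got {seg.shape}"
        )
    s = s or StftSpec()
    stacked = np.vstack([stft_frames(ch, w, s, fs) for ch in seg])
    if s.log_magnitude:
        stacked = np.log1p(stacked)
    encoder = "enhanced_spectrogram" if seg.shape[0] in (9, 17) else "spectrogram"
    return EncodedImage(
        pixels=to_grayscale(stacked),
        encoder=encoder,
        n_channels_source=seg.shape[0],
        label=label,
        subject_id=subject_id,
        repetition=repetition,
        segment_index=segment_index,
    )


def augment_max_channel(segment: np.ndarray) -> np.ndarray:
    """Append the pointwise cross-channel maximum as an auxiliary channel.

    The auxiliary row ``r[t] = max_c segment[c, t]`` dominates every original
    channel at every sample and summarizes the momentary strongest muscle
    activity; 8-channel input becomes 9-channel, 16 becomes 17.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 2 or seg.shape[0] not in (8, 16):
        raise DomainError(f"expected 8 or 16 channels, got shape {seg.shape}")
    return np.vstack([seg, seg.max(axis=0)])


def encode_time_domain(
    segment: np.ndarray,
    fs: float = 2000.0,
    label: int = -1,
    subject_id: int = 0,
    repetition: int = 0,
    segment_index: int = 0,
) -> EncodedImage:
    """Render a segment directly as a channels x time grayscale image.

    Each channel is decimated by 2 (zero-phase anti-alias low-pass, then
    every 2nd sample) so a 250 ms segment at 2000 sps maps to 250 image
    columns; rows are channels, giving 16x250 or 8x250 pixels.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 2 or seg.shape[0] not in (8, 16):
        raise DimensionError(f"expected (C, n) with C in (8, 16), got {seg.shape}")
    if seg.shape[1] % 2:
        raise DimensionError(f"segment length must be even for 2x decimation, got {seg.shape[1]}")
    if seg.shape[1] < 56:  # scipy's default order-8 IIR needs >3*(order+1)*... samples
        raise DimensionError("segment too short to decimate")
    dec = signal.decimate(seg, 2, axis=-1, zero_phase=True)
    return EncodedImage(
        pixels=to_grayscale(dec),
        encoder="time_domain",
        n_channels_source=seg.shape[0],
        label=label,
        subject_id=subject_id,
        repetition=repetition,
        segment_index=segment_index,
    )


class TimeDomainEncoder(BaseEstimator, TransformerMixin):
    """Batch transformer: segments ``(n, C, L)`` -> images ``(n, C, L/2)``."""

    def __init__(self, fs: float = 2000.0):
        self.fs = fs

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise DimensionError(f"expected (n, C, L), got {X.shape}")
        return np.stack([encode_time_domain(seg, fs=self.fs).pixels for seg in X])


class SpectrogramEncoder(BaseEstimator, TransformerMixin):
    """Batch transformer: segments ``(n, C, L)`` -> stacked spectrogram images.

    With ``enhanced=True`` the pointwise-max auxiliary channel is appended
    before encoding.
    """

    def __init__(self, fs: float = 2000.0, window: WindowSpec | None = None,
                 stft: StftSpec | None = None, enhanced: bool = False):
        self.fs = fs
        self.window = window
        self.stft = stft
        self.enhanced = enhanced

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise DimensionError(f"expected (n, C, L), got {X.shape}")
        out = []
        for seg in X:
            if self.enhanced:
                seg = augment_max_channel(seg)
            out.append(encode_spectrogram(seg, self.window, self.stft, self.fs).pixels)
        return np.stack(out)
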