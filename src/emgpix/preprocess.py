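"""Software noise-reduction chain: DC-offset removal and 50 Hz notch.

Mains interference couples capacitively into surface-EMG electrodes; in a
50 Hz grid region it appears as a narrow spectral line that can rival the
EMG itself.  The chain applied here mirrors a typical acquisition pipeline:

1. a single-pole high-pass ("DC blocker", cutoff 2 Hz) removing the residual
   amplifier offset, then
2. a 4th-order Butterworth band-stop with stop band 49-51 Hz removing the
   powerline component.

Filters run forward-backward (zero-phase) by default so that window
alignment downstream is not distorted by group delay; a causal mode is
available for streaming parity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DataError, ParameterError
from .simulate import Recording

__all__ = [
    "FilterSpec",
    "NotchFilter",
    "DCBlocker",
    "notch_filter",
    "dc_block",
    "band_limit",
    "preprocess_chain",
    "notch_frequency_response",
    "dc_block_frequency_response",
]

_KINDS = ("notch", "dc_block", "band_limit")


@dataclass(frozen=True)
class FilterSpec:
    """Parameters of one filter stage.

    ``fc1``/``fc2`` bound the notch stop band (or band-limit pass band);
    ``order`` is the overall Butterworth order; ``dc_cutoff`` is the corner
    of the single-pole DC blocker.  Validation against the sampling rate
    happens at application time.
    """

    kind: str = "notch"
    fc1: float = 49.0
    fc2: float = 51.0
    order: int = 4
    dc_cutoff: float = 2.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if not (0 < self.fc1 < self.fc2):
            raise ParameterError(f"need 0 < fc1 < fc2, got fc1={self.fc1} fc2={self.fc2}")
        if self.order < 1:
            raise ParameterError(f"order must be >= 1, got {self.order}")
        if self.dc_cutoff <= 0:
            raise ParameterError(f"dc_cutoff must be > 0, got {self.dc_cutoff}")


def _check_band(fc2: float, fs: float) -> None:
    if fc2 >= fs / 2:
        raise ParameterError(f"upper cutoff {fc2} Hz must be < Nyquist ({fs / 2} Hz)")


def _check_finite(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise DataError("samples contain non-finite values")


def _bandstop_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    # butter's N is the prototype (per-edge) order; overall order is 2N.
    _check_band(spec.fc2, fs)
    if spec.order % 2:
        raise ParameterError("band-stop order must be even (order/2 poles per edge)")
    return signal.butter(
        spec.order // 2, [spec.fc1, spec.fc2], btype="bandstop", fs=fs, output="sos"
    )


def _bandpass_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    _check_band(spec.fc2, fs)
    if spec.order % 2:
        raise ParameterError("band-pass order must be even")
    return signal.butter(
        spec.order // 2, [spec.fc1, spec.fc2], btype="bandpass", fs=fs, output="sos"
    )


def _dc_ba(spec: FilterSpec, fs: float) -> tuple[np.ndarray, np.ndarray]:
    # First-order Butterworth high-pass == single-pole recursive DC blocker.
    _check_band(spec.dc_cutoff, fs)
    b, a = signal.butter(1, spec.dc_cutoff, btype="highpass", fs=fs)
    return b, a


def _apply_sos(x: np.ndarray, sos: np.ndarray, zero_phase: bool) -> np.ndarray:
    _check_finite(x)
    if x.shape[-1] == 0:
        raise ParameterError("cannot filter an empty signal")
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


class NotchFilter(BaseEstimator, TransformerMixin):
    """Butterworth band-stop powerline filter as a stateless transformer.

    Operates on arrays whose last axis is time (``(n_samples,)``,
    ``(n_channels, n_samples)`` or batches thereof), channel by channel.
    """

    def __init__(self, fs: float = 2000.0, fc1: float = 49.0, fc2: float = 51.0,
                 order: int = 4, zero_phase: bool = True):
        self.fs = fs
        self.fc1 = fc1
        self.fc2 = fc2
        self.order = order
        self.zero_phase = zero_phase

    def _spec(self) -> FilterSpec:
        return FilterSpec(kind="notch", fc1=self.fc1, fc2=self.fc2,
                          order=self.order, zero_phase=self.zero_phase)

    def fit(self, X=None, y=None):
        self.sos_ = _bandstop_sos(self._spec(), self.fs)
        return self

    def transform(self, X):
        if not hasattr(self, "sos_"):
            self.fit()
        return _apply_sos(np.asarray(X, dtype=float), self.sos_, self.zero_phase)

    def frequency_response(self, freqs) -> np.ndarray:
        """|H(f)| of the designed filter (squared in zero-phase mode)."""
        if not hasattr(self, "sos_"):
            self.fit()
        _, h = signal.sosfreqz(self.sos_, worN=np.atleast_1d(freqs), fs=self.fs)
        mag = np.abs(h)
        return mag**2 if self.zero_phase else mag


class DCBlocker(BaseEstimator, TransformerMixin):
    """Single-pole recursive high-pass removing constant offset voltage."""

    def __init__(self, fs: float = 2000.0, cutoff: float = 2.0, zero_phase: bool = True):
        self.fs = fs
        self.cutoff = cutoff
        self.zero_phase = zero_phase

    def fit(self, X=None, y=None):
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be > 0")
        self.b_, self.a_ = _dc_ba(FilterSpec(kind="dc_block", dc_cutoff=self.cutoff),
                                  self.fs)
        return self

    def transform(self, X):
        if not hasattr(self, "b_"):
            self.fit()
        x = np.asarray(X, dtype=float)
        _check_finite(x)
        if x.shape[-1] == 0:
            raise ParameterError("cannot filter an empty signal")
        if self.zero_phase:
            return signal.filtfilt(self.b_, self.a_, x, axis=-1)
        return signal.lfilter(self.b_, self.a_, x, axis=-1)

    def frequency_response(self, freqs) -> np.ndarray:
        if not hasattr(self, "b_"):
            self.fit()
        _, h = signal.freqz(self.b_, self.a_, worN=np.atleast_1d(freqs), fs=self.fs)
        mag = np.abs(h)
        return mag**2 if self.zero_phase else mag


def notch_filter(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Apply the 50 Hz Butterworth notch to every channel of a recording."""
    spec = spec or FilterSpec(kind="notch")
    if spec.kind != "notch":
        raise ParameterError(f"expected a notch spec, got kind={spec.kind!r}")
    f = NotchFilter(fs=rec.fs, fc1=spec.fc1, fc2=spec.fc2,
                    order=spec.order, zero_phase=spec.zero_phase).fit()
    return rec.with_samples(f.transform(rec.samples))


def dc_block(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Remove residual DC offset with a single-pole high-pass."""
    spec = spec or FilterSpec(kind="dc_block")
    if spec.kind != "dc_block":
        raise ParameterError(f"expected a dc_block spec, got kind={spec.kind!r}")
    f = DCBlocker(fs=rec.fs, cutoff=spec.dc_cutoff, zero_phase=spec.zero_phase).fit()
    return rec.with_samples(f.transform(rec.samples))


def band_limit(rec: Recording, spec: FilterSpec) -> Recording:
    """Butterworth band-pass to [fc1, fc2] (software stand-in for the
    acquisition bandwidth; rarely needed when fc2 approaches Nyquist)."""
    if spec.kind != "band_limit":
        raise ParameterError(f"expected a band_limit spec, got kind={spec.kind!r}")
    sos = _bandpass_sos(spec, rec.fs)
    return rec.with_samples(_apply_sos(rec.samples, sos, spec.zero_phase))


_APPLY = {"notch": notch_filter, "dc_block": dc_block, "band_limit": band_limit}


def default_chain() -> list[FilterSpec]:
    """DC block then notch — the default software chain."""
    return [FilterSpec(kind="dc_block"), FilterSpec(kind="notch")]


def preprocess_chain(rec: Recording, specs: list[FilterSpec] | None = None) -> Recording:
    """Apply a sequence of filter stages in order (default: DC block, notch)."""
    if specs is None:
        specs = default_chain()
    if not specs:
        raise ParameterError("specs must be nonempty")
    if rec.n_samples == 0:
        raise ParameterError("cannot preprocess an empty recording")
    for spec in specs:
        rec = _APPLY[spec.kind](rec, spec)
    return rec


def notch_frequency_response(spec: FilterSpec, fs: float, freqs) -> np.ndarray:
    """|H(f)| magnitude of the designed notch (squared when zero-phase)."""
    f = NotchFilter(fs=fs, fc1=spec.fc1, fc2=spec.fc2, order=spec.order,
                    zero_phase=spec.zero_phase).fit()
    return f.frequency_response(freqs)


def dc_block_frequency_response(spec: FilterSpec, fs: float, freqs) -> np.ndarray:
    f = DCBlocker(fs=fs, cutoff=spec.dc_cutoff, zero_phase=spec.zero_phase).fit()
    return f.frequency_response(freqs)
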