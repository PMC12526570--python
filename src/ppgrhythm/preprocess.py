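"""Signal conditioning for raw PPG records.

The chain, applied in order: a fourth-order Butterworth bandpass
(0.05-30 Hz) run forward-backward for zero net phase shift, a short
moving-average smoother, a hybrid baseline correction (wavelet
approximation plus a cubic spline through knot-spaced medians of the
residual trend), and min-max scaling to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal
from scipy.interpolate import CubicSpline

from .exceptions import (
    DegenerateSignalError,
    InvalidParameterError,
    SignalTooShortError,
)
from .synth import PPGRecord

__all__ = [
    "PreprocessConfig",
    "bandpass_zero_phase",
    "moving_average",
    "baseline_correct",
    "minmax_normalize",
    "preprocess_record",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning-chain parameters.

    ``decomp_level=None`` selects the smallest wavelet level whose
    approximation band falls below 0.5 Hz for the record's sampling rate,
    i.e. the smallest J with fs / 2**(J+1) < 0.5.
    """

    band_low_hz: float = 0.05
    band_high_hz: float = 30.0
    filter_order: int = 4
    ma_window_s: float = 0.04
    wavelet_name: str = "db4"
    decomp_level: int | None = None
    spline_knot_spacing_s: float = 1.0
    normalize: bool = True

    def validate(self, fs: float) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz < fs / 2):
            raise InvalidParameterError(
                f"need 0 < band_low < band_high < fs/2; got "
                f"({self.band_low_hz}, {self.band_high_hz}) at fs={fs}")
        if self.filter_order < 1:
            raise InvalidParameterError("filter_order must be >= 1")
        if self.ma_window_s < 1.0 / fs:
            raise InvalidParameterError(
                "ma_window_s must cover at least one sample")


def _auto_level(fs: float) -> int:
    level = 1
    while fs / 2 ** (level + 1) >= 0.5:
        level += 1
    return level


def bandpass_zero_phase(samples: np.ndarray, fs: float,
                        cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Zero-phase Butterworth bandpass via forward-backward filtering.

    Uses second-order sections for numerical stability and reflect padding
    at the edges.  Raises :class:`SignalTooShortError` rather than silently
    truncating when the signal cannot support the filter's padding.
    """
    cfg.validate(fs)
    x = np.asarray(samples, dtype=np.float64)
    sos = signal.butter(cfg.filter_order,
                        [cfg.band_low_hz, cfg.band_high_hz],
                        btype="bandpass", fs=fs, output="sos")
    min_len = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= 2 * min_len:
        raise SignalTooShortError(
            f"signal of length {len(x)} too short for zero-phase filtering "
            f"(needs > {2 * min_len} samples)")
    # the 0.05 Hz edge has a very long transient: pad generously so the
    # forward-backward passes settle inside the signal
    padlen = int(min(len(x) - 1, max(min_len, 3 * fs / cfg.band_low_hz)))
    return signal.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def moving_average(samples: np.ndarray, fs: float,
                   window_s: float) -> np.ndarray:
    """Centered moving average; edge windows shrink symmetrically so the
    output stays within the input range and a constant signal is unchanged.

    An even sample count is widened by one to keep the window centered.
    """
    x = np.asarray(samples, dtype=np.float64)
    w = int(round(window_s * fs))
    if w < 1:
        raise InvalidParameterError(
            f"window of {window_s} s spans no samples at fs={fs}")
    if w > len(x):
        raise InvalidParameterError(
            f"window of {w} samples longer than signal ({len(x)})")
    if w % 2 == 0:
        w += 1
    if w == 1:
        return x.copy()
    half = w // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = len(x)
    idx = np.arange(n)
    h = np.minimum(np.minimum(idx, n - 1 - idx), half)
    lo, hi = idx - h, idx + h
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def baseline_correct(samples: np.ndarray, fs: float,
                     cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Remove residual drift with a wavelet approximation plus cubic spline.

    The drift estimate is the wavelet approximation at ``decomp_level``
    (slow components only) plus a cubic spline through knot-spaced medians
    of the residual trend.  The corrected signal is input minus drift, so
    its mean sits near zero.
    """
    x = np.asarray(samples, dtype=np.float64)
    if len(x) < 2 * fs:
        raise SignalTooShortError(
            "baseline correction needs at least two seconds of signal")
    level = cfg.decomp_level if cfg.decomp_level is not None else _auto_level(fs)
    wavelet = pywt.Wavelet(cfg.wavelet_name)
    max_level = pywt.dwt_max_level(len(x), wavelet.dec_len)
    if level > max_level:
        raise InvalidParameterError(
            f"decomposition level {level} infeasible for signal length "
            f"{len(x)} (max {max_level})")
    # estimate the slow component on the beat-averaged trend so pulse
    # transients do not leak into the wavelet approximation; reflect
    # padding keeps the decomposition's edge transients out of the record
    slow = moving_average(x, fs, cfg.spline_knot_spacing_s)
    pad = min(len(x) - 1, int(4 * cfg.spline_knot_spacing_s * fs))
    slow_p = np.pad(slow, pad, mode="reflect")
    coeffs = pywt.wavedec(slow_p, wavelet, level=level)
    # zero every detail band -> approximation-only reconstruction
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    drift = pywt.waverec(coeffs, wavelet)[pad: pad + len(x)]

    resid = x - drift
    # spline through knot-spaced medians of the residual *trend* (its
    # moving average), so pulse morphology does not bias the knots
    trend = moving_average(resid, fs,
                           min(4.0 * cfg.spline_knot_spacing_s,
                               len(x) / fs))
    knot_step = max(1, int(round(cfg.spline_knot_spacing_s * fs)))
    edges = np.arange(0, len(x), knot_step)
    knots_t, knots_v = [], []
    for lo in edges:
        seg = trend[lo: lo + knot_step]
        knots_t.append(lo + 0.5 * (len(seg) - 1))
        knots_v.append(np.median(seg))
    if len(knots_t) >= 2:
        spline = CubicSpline(np.asarray(knots_t), np.asarray(knots_v))
        drift = drift + spline(np.arange(len(x)))
    return x - drift


def minmax_normalize(samples: np.ndarray) -> np.ndarray:
    """Scale to [0, 1].  A constant input has no meaningful scale and raises
    :class:`DegenerateSignalError` instead of emitting NaN."""
    x = np.asarray(samples, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("samples must be finite")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateSignalError(
            "constant signal cannot be min-max normalized")
    return (x - lo) / (hi - lo)


def preprocess_record(record: PPGRecord,
                      cfg: PreprocessConfig = PreprocessConfig()) -> PPGRecord:
    """Apply the full chain (bandpass -> moving average -> baseline
    correction -> min-max) and return a new record with label/fs/id kept."""
    x = bandpass_zero_phase(record.samples, record.fs, cfg)
    x = moving_average(x, record.fs, cfg.ma_window_s)
    x = baseline_correct(x, record.fs, cfg)
    if cfg.normalize:
        x = minmax_normalize(x)
    return PPGRecord(samples=x, fs=record.fs, label=record.label,
                     record_id=record.record_id,
                     meta={**record.meta, "preprocessed": True})
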