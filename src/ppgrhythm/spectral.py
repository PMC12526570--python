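"""Frequency-domain feature construction.

The frequency branch of the classifier consumes, per 10 s window:

1. a Welch power spectral density — the window is cut into K tapered,
   overlapping segments of length L; each segment's periodogram is
   P_k(f) = |FFT(x_k w)|^2 / U with U = (1/L) sum w^2(n), and the final
   estimate is the pointwise mean over the K segments (averaging reduces
   the single-periodogram variance);
2. an arctan compression mapping band energies from [0, inf) into
   [0, pi/2), bounding the influence of local energy spikes while
   preserving the energy ranking;
3. a self-similarity matrix S = X X^T over band-by-segment energy vectors,
   lifting the 1-D spectral structure into a 2-D similarity map whose
   entry (i, j) measures energy similarity between frequency bands i and j.

A standard interleaved sine/cosine positional encoding (with a learnable
depthwise-conv adjustment living in the network layers) is also provided
here in its deterministic form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "WelchConfig",
    "PSD",
    "SSMatrix",
    "welch_psd",
    "arctan_compress",
    "band_energies",
    "build_ssm",
    "positional_encoding",
]


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimator parameters.

    The defaults (L=256 ~ 1 s at 250 Hz, 50 % overlap, Hann taper) yield
    K=18 averaged segments on a 10 s window — enough averaging for a
    visibly lower-variance estimate than a single periodogram.
    """

    seg_len: int = 256
    overlap: float = 0.5
    window_fn: str = "hann"
    n_bands: int = 32
    ssm_mode: str = "bands"   # "bands" (default) or "bins"

    @property
    def n_freq_bins(self) -> int:
        return self.seg_len // 2 + 1

    def validate(self) -> None:
        if self.seg_len < 1:
            raise InvalidParameterError("seg_len must be >= 1")
        if not 0 <= self.overlap < 1:
            raise InvalidParameterError("overlap must be in [0, 1)")
        if self.ssm_mode not in ("bands", "bins"):
            raise InvalidParameterError("ssm_mode must be 'bands' or 'bins'")


@dataclass
class PSD:
    """One-sided Welch power spectral density."""

    freqs: np.ndarray
    power: np.ndarray
    k_segments: int
    #: per-segment one-sided periodograms, [K, n_freq_bins]
    segment_power: np.ndarray


@dataclass
class SSMatrix:
    """Self-similarity (Gram) matrix over spectral vectors."""

    s: np.ndarray           # [B, B], symmetric positive semidefinite
    band_edges: np.ndarray  # Hz boundaries, length B + 1
    x: np.ndarray           # [B, K] band-by-segment energy matrix


def _taper(name: str, length: int) -> np.ndarray:
    if name == "hann":
        return np.hanning(length)
    if name in ("boxcar", "rect", "rectangular"):
        return np.ones(length)
    if name == "hamming":
        return np.hamming(length)
    raise InvalidParameterError(f"unknown taper {name!r}")


def welch_psd(window: np.ndarray, fs: float,
              cfg: WelchConfig = WelchConfig()) -> PSD:
    """Averaged-periodogram spectral estimate of one signal window.

    Segments of length L start every (1 - overlap) * L samples; each is
    multiplied by the taper, its one-sided periodogram is normalized by the
    window energy U = (1/L) sum w^2, and the K periodograms are averaged
    pointwise along the frequency axis.
    """
    cfg.validate()
    x = np.asarray(window, dtype=np.float64)
    L = cfg.seg_len
    if L > len(x):
        raise InvalidParameterError(
            f"seg_len {L} exceeds window length {len(x)}")
    hop = max(1, int(round((1 - cfg.overlap) * L)))
    n_seg = (len(x) - L) // hop + 1
    starts = np.arange(n_seg) * hop
    segs = np.stack([x[s: s + L] for s in starts])          # [K, L]
    w = _taper(cfg.window_fn, L)
    u = np.sum(w ** 2) / L
    spec = np.fft.rfft(segs * w, axis=1)                    # [K, L//2+1]
    pk = (np.abs(spec) ** 2) / u
    power = pk.mean(axis=0)
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    return PSD(freqs=freqs, power=power, k_segments=n_seg, segment_power=pk)


def arctan_compress(power: np.ndarray) -> np.ndarray:
    """Elementwise arctan: [0, inf) -> [0, pi/2), strictly order-preserving,
    bounding the influence of any single energy spike."""
    p = np.asarray(power, dtype=np.float64)
    if np.any(p < 0):
        raise InvalidParameterError("power values must be nonnegative")
    return np.arctan(p)


def band_energies(segment_power: np.ndarray, n_bands: int) -> np.ndarray:
    """Sum one-sided per-segment periodograms into B contiguous equal-width
    frequency bands.  Returns [B, K]."""
    n_bins = segment_power.shape[1]
    if n_bands < 2:
        raise InvalidParameterError("need at least 2 bands")
    if n_bands > n_bins:
        raise InvalidParameterError(
            f"n_bands {n_bands} exceeds number of frequency bins {n_bins}")
    parts = np.array_split(np.arange(n_bins), n_bands)
    return np.stack([segment_power[:, idx].sum(axis=1) for idx in parts])


def build_ssm(window: np.ndarray, fs: float,
              cfg: WelchConfig = WelchConfig(),
              n_bands: int | None = None) -> SSMatrix:
    """Self-similarity matrix of a window's spectral vectors.

    In the default "bands" mode, X[b, k] is the arctan-compressed energy of
    frequency band b in Welch segment k (B contiguous equal-width bands of
    the one-sided spectrum), and S = X X^T is the B x B Gram matrix.  The
    "bins" mode instead uses the raw PSD bins as spectral vectors
    (one token per frequency bin).
    """
    cfg.validate()
    b = cfg.n_bands if n_bands is None else n_bands
    psd = welch_psd(window, fs, cfg)
    if cfg.ssm_mode == "bands":
        x = arctan_compress(band_energies(psd.segment_power, b))     # [B, K]
        edges = np.linspace(0, fs / 2, b + 1)
    else:
        x = arctan_compress(psd.segment_power.T)                     # [bins, K]
        edges = np.concatenate([psd.freqs, [fs / 2]])
    s = x @ x.T
    s = 0.5 * (s + s.T)  # exact symmetry against floating-point drift
    return SSMatrix(s=s, band_edges=edges, x=x)


def ssm_batch(windows: np.ndarray, fs: float,
              cfg: WelchConfig = WelchConfig()) -> np.ndarray:
    """Stack of SSMs for a [n_windows, window_samples] matrix."""
    return np.stack([build_ssm(w, fs, cfg).s for w in windows])


def positional_encoding(length: int, dim: int) -> np.ndarray:
    """Standard interleaved sinusoidal positional encoding, [length, dim].

    PE[p, 2i] = sin(p / 10000^(2i/dim)), PE[p, 2i+1] = cos(same angle).
    """
    if length < 1 or dim < 1:
        raise InvalidParameterError("length and dim must be >= 1")
    pos = np.arange(length)[:, None]
    i = np.arange(0, dim, 2)[None, :]
    angle = pos / np.power(10000.0, i / dim)
    pe = np.zeros((length, dim))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : pe[:, 1::2].shape[1]])
    return pe
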