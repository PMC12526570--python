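"""Synthetic single-channel PPG generator for four arrhythmia rhythm classes.

The generator emulates 250 Hz, 5-minute pulse-oximeter records whose rhythm
semantics follow the standard critical-alarm definitions: extreme bradycardia
(heart rate below 40 bpm), extreme tachycardia (above 140 bpm), ventricular
tachycardia (ventricular beats at or above 100 bpm, morphologically distinct
pulses), and ventricular flutter/fibrillation (a sustained oscillatory
waveform with dominant energy in the 4-7 Hz band and no discernible pulse
train).  Each pulsatile beat is modelled as a systolic Gaussian plus a
delayed, smaller dicrotic Gaussian; VF is an amplitude-modulated sinusoid
whose instantaneous frequency drifts inside the oscillation band.  Records
carry additive Gaussian noise and a slow sinusoidal baseline wander so that
the preprocessing chain has realistic work to do.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "RhythmClass",
    "SimParams",
    "PPGRecord",
    "simulate_record",
    "make_dataset",
    "save_dataset",
    "load_dataset",
    "read_wfdb_record",
]


class RhythmClass(IntEnum):
    """The four target rhythm classes with their stable integer encoding."""

    BRADYCARDIA = 0
    TACHYCARDIA = 1
    VENTRICULAR_TACHYCARDIA = 2
    VENTRICULAR_FLUTTER_FIB = 3

    @property
    def short_name(self) -> str:
        return _SHORT_NAMES[self]


_SHORT_NAMES = {
    RhythmClass.BRADYCARDIA: "Brady",
    RhythmClass.TACHYCARDIA: "Tachy",
    RhythmClass.VENTRICULAR_TACHYCARDIA: "VT",
    RhythmClass.VENTRICULAR_FLUTTER_FIB: "VF",
}

#: Per-class heart-rate sampling intervals (bpm).  Bounds respect the rhythm
#: definitions: bradycardia < 40 bpm, tachycardia > 140 bpm, VT >= 100 bpm.
DEFAULT_HR_RANGES: dict[RhythmClass, tuple[float, float]] = {
    RhythmClass.BRADYCARDIA: (25.0, 38.0),
    RhythmClass.TACHYCARDIA: (142.0, 180.0),
    RhythmClass.VENTRICULAR_TACHYCARDIA: (110.0, 180.0),
}


@dataclass(frozen=True)
class PulseTemplate:
    """Shape of one pulsatile beat (dimensionless amplitudes, widths relative
    to the inter-beat interval)."""

    sys_amp: float = 1.0
    sys_width_frac: float = 0.10   # systolic Gaussian sd / inter-beat interval
    dicrotic_amp: float = 0.35
    dicrotic_delay_frac: float = 0.38
    dicrotic_width_frac: float = 0.14


#: Ventricular beats: wider systolic upstroke, nearly absent dicrotic notch.
VT_TEMPLATE = PulseTemplate(
    sys_amp=1.0, sys_width_frac=0.20, dicrotic_amp=0.05,
    dicrotic_delay_frac=0.45, dicrotic_width_frac=0.18,
)


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic-record generator.

    Defaults are the study conditions: 250 Hz sampling, 5-minute records,
    heart-rate intervals respecting the class definitions, a 4-7 Hz VF
    oscillation band, 0.05 Hz baseline wander at 30 % of the pulse amplitude
    (removable by the 0.05-30 Hz bandpass), and additive Gaussian noise at
    2 % of the pulse amplitude.
    """

    fs: float = 250.0
    duration_s: float = 300.0
    hr_bpm_range: dict[RhythmClass, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HR_RANGES))
    pulse_template: PulseTemplate = PulseTemplate()
    vt_template: PulseTemplate = VT_TEMPLATE
    vf_osc_band_hz: tuple[float, float] = (4.0, 7.0)
    baseline_wander_amp: float = 0.30
    baseline_wander_hz: float = 0.05
    noise_sd: float = 0.02
    amp_jitter_sd: float = 0.05       # lognormal sd of per-beat amplitude
    hr_jitter_sd: float = 0.03        # beat-to-beat interval jitter (sd, fraction)
    vt_hr_jitter_sd: float = 0.08     # VT rhythm irregularity
    seed: int = 0

    def validate(self) -> None:
        if not self.fs > 0:
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")
        if not self.duration_s > 0:
            raise InvalidParameterError(
                f"duration_s must be positive, got {self.duration_s}")
        lo, hi = self.vf_osc_band_hz
        if not (0 < lo < hi < self.fs / 2):
            raise InvalidParameterError(
                f"vf_osc_band_hz must lie within (0, fs/2), got {self.vf_osc_band_hz}")
        if self.baseline_wander_hz > 0.1:
            raise InvalidParameterError(
                "baseline wander frequency must be <= 0.1 Hz")
        ranges = self.hr_bpm_range
        b = ranges[RhythmClass.BRADYCARDIA]
        t = ranges[RhythmClass.TACHYCARDIA]
        v = ranges[RhythmClass.VENTRICULAR_TACHYCARDIA]
        if b[1] >= 40:
            raise InvalidParameterError(
                f"bradycardia HR range must stay below 40 bpm, got {b}")
        if t[0] <= 140:
            raise InvalidParameterError(
                f"tachycardia HR range must stay above 140 bpm, got {t}")
        if v[0] < 100:
            raise InvalidParameterError(
                f"VT HR range must be >= 100 bpm, got {v}")
        for lo_, hi_ in (b, t, v):
            if not lo_ < hi_:
                raise InvalidParameterError("HR range bounds must satisfy lo < hi")


@dataclass
class PPGRecord:
    """One labeled single-channel waveform."""

    samples: np.ndarray
    fs: float
    label: RhythmClass
    record_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InvalidParameterError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def _pulse_train(rng: np.random.Generator, n: int, fs: float, hr_bpm: float,
                 template: PulseTemplate, jitter_sd: float,
                 amp_jitter_sd: float) -> np.ndarray:
    """Quasi-periodic pulse train: per beat, a systolic Gaussian plus a
    delayed dicrotic Gaussian, with jittered inter-beat intervals and
    lognormal amplitude jitter."""
    x = np.zeros(n)
    t_axis = np.arange(n) / fs
    mean_interval = 60.0 / hr_bpm
    t = mean_interval * 0.5
    while t < n / fs + mean_interval:
        interval = mean_interval * float(
            np.exp(rng.normal(0.0, jitter_sd)))
        amp = template.sys_amp * float(np.exp(rng.normal(0.0, amp_jitter_sd)))
        sw = template.sys_width_frac * interval
        # evaluate only a local neighbourhood of the beat for speed
        lo = max(0, int((t - 4 * interval) * fs))
        hi = min(n, int((t + 4 * interval) * fs) + 1)
        if lo < hi:
            tt = t_axis[lo:hi]
            x[lo:hi] += amp * np.exp(-0.5 * ((tt - t) / sw) ** 2)
            dt = t + template.dicrotic_delay_frac * interval
            dw = template.dicrotic_width_frac * interval
            x[lo:hi] += (amp * template.dicrotic_amp
                         * np.exp(-0.5 * ((tt - dt) / dw) ** 2))
        t += interval
    return x


def _vf_waveform(rng: np.random.Generator, n: int, fs: float,
                 band: tuple[float, float]) -> np.ndarray:
    """Band-limited oscillation: amplitude-modulated sinusoid whose
    instantaneous frequency performs a slow, clipped random walk inside the
    oscillation band.  No discernible pulse train."""
    lo, hi = band
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    # Ornstein-Uhlenbeck-like drift of the instantaneous frequency
    f = np.empty(n)
    f[0] = rng.uniform(lo + 0.2 * half, hi - 0.2 * half)
    steps = rng.normal(0.0, 0.5 / np.sqrt(fs), size=n)
    for i in range(1, n):
        f[i] = f[i - 1] + steps[i] - 0.001 * (f[i - 1] - mid)
    f = np.clip(f, lo + 0.05, hi - 0.05)
    phase = 2 * np.pi * np.cumsum(f) / fs
    t = np.arange(n) / fs
    am = 1.0 + 0.3 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    return 0.6 * am * np.sin(phase)


def simulate_record(label: RhythmClass, params: SimParams,
                    record_id: str | None = None,
                    seed: int | None = None) -> PPGRecord:
    """Generate one labeled synthetic PPG record.

    Bradycardia/tachycardia/VT are quasi-periodic pulse trains whose
    inter-beat interval matches the class heart-rate range; VT additionally
    uses a wider, low-dicrotic pulse template and larger rhythm jitter.
    VF is a band-limited oscillation with no pulse train.  Identical
    (label, params, seed) yields bitwise-identical samples.
    """
    params.validate()
    label = RhythmClass(label)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = int(round(params.fs * params.duration_s))

    if label is RhythmClass.VENTRICULAR_FLUTTER_FIB:
        x = _vf_waveform(rng, n, params.fs, params.vf_osc_band_hz)
        hr = float("nan")
    else:
        lo, hi = params.hr_bpm_range[label]
        hr = float(rng.uniform(lo, hi))
        if label is RhythmClass.VENTRICULAR_TACHYCARDIA:
            template, jitter = params.vt_template, params.vt_hr_jitter_sd
        else:
            template, jitter = params.pulse_template, params.hr_jitter_sd
        x = _pulse_train(rng, n, params.fs, hr, template, jitter,
                         params.amp_jitter_sd)

    t = np.arange(n) / params.fs
    wander_phase = rng.uniform(0, 2 * np.pi)
    x = x + params.baseline_wander_amp * np.sin(
        2 * np.pi * params.baseline_wander_hz * t + wander_phase)
    x = x + rng.normal(0.0, params.noise_sd, size=n)

    rid = record_id if record_id is not None else f"{label.short_name}-{rng.integers(1 << 30)}"
    return PPGRecord(samples=x, fs=params.fs, label=label, record_id=rid,
                     meta={"hr_bpm": hr, "synthetic": True})


def make_dataset(n_per_class: int, params: SimParams) -> list[PPGRecord]:
    """Generate ``4 * n_per_class`` records with unique ids and exact
    per-class counts, deterministic under ``params.seed``."""
    if n_per_class < 1:
        raise InvalidParameterError(
            f"n_per_class must be >= 1, got {n_per_class}")
    params.validate()
    seed_rng = np.random.default_rng(params.seed)
    records: list[PPGRecord] = []
    for label in RhythmClass:
        for i in range(n_per_class):
            rec_seed = int(seed_rng.integers(0, 2**31 - 1))
            rid = f"{label.short_name}-{i:04d}"
            records.append(
                simulate_record(label, params, record_id=rid, seed=rec_seed))
    return records


# ---------------------------------------------------------------------------
# Dataset container I/O: one compressed array archive + plain-text manifest.

def save_dataset(records: list[PPGRecord], path: str | Path) -> None:
    """Write a dataset as a single ``.npz`` archive plus a ``.manifest.csv``
    (record_id, label, fs, duration) next to it."""
    path = Path(path)
    arrays = {f"samples_{i}": r.samples for i, r in enumerate(records)}
    arrays["fs"] = np.array([r.fs for r in records])
    arrays["labels"] = np.array([int(r.label) for r in records])
    arrays["record_ids"] = np.array([r.record_id for r in records])
    np.savez_compressed(path, **arrays)
    manifest = path.with_suffix(".manifest.csv")
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "label", "fs", "duration_s"])
        for r in records:
            w.writerow([r.record_id, r.label.short_name, r.fs, r.duration_s])


def load_dataset(path: str | Path) -> list[PPGRecord]:
    path = Path(path)
    if path.suffix != ".npz" and not path.exists():
        path = path.with_suffix(".npz")
    with np.load(path, allow_pickle=False) as z:
        fs = z["fs"]
        labels = z["labels"]
        rids = z["record_ids"]
        return [
            PPGRecord(samples=z[f"samples_{i}"], fs=float(fs[i]),
                      label=RhythmClass(int(labels[i])), record_id=str(rids[i]))
            for i in range(len(labels))
        ]


def read_wfdb_record(record_path: str, label: RhythmClass) -> PPGRecord:
    """Read a WFDB-format record's PPG/PLETH channel (external-data path).

    Requires the optional ``wfdb`` package; raises ImportError with guidance
    when it is absent.  This path is not exercised by the shipped tests,
    which run entirely on synthetic data.
    """
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install wfdb); the synthetic generator needs no downloads"
        ) from exc
    rec = wfdb.rdrecord(record_path)  # pragma: no cover
    names = [n.upper() for n in rec.sig_name]  # pragma: no cover
    for cand in ("PLETH", "PPG"):  # pragma: no cover
        if cand in names:
            idx = names.index(cand)
            return PPGRecord(
                samples=np.asarray(rec.p_signal[:, idx], dtype=np.float64),
                fs=float(rec.fs), label=label,
                record_id=Path(record_path).name,
                meta={"source": "wfdb", "channel": rec.sig_name[idx]})
    raise InvalidParameterError(  # pragma: no cover
        f"no PLETH/PPG channel in {record_path}: {rec.sig_name}")
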