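"""Record-level stratified splitting and weight-aware sliding-window (WASW)
augmentation.

Splitting happens at the *record* level before any window is cut, so no
record contributes windows to two splits (leakage freedom).  Augmentation
then densifies rare classes: each class's stride is

    S_c = clip(round(S_ref / w_c**beta), S_min, S_max)

where w_c is the inverse-frequency class weight normalized to mean 1, so a
balanced dataset reproduces the reference stride.  Strides are computed
from the *training* split's class counts only; the validation split uses
the fixed reference stride and the test split uses non-overlapping windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError
from .synth import PPGRecord, RhythmClass

__all__ = [
    "SplitAssignment",
    "AugmentConfig",
    "ClassWeights",
    "WindowSet",
    "stratified_split",
    "compute_class_weights",
    "stride_for_class",
    "slide_windows",
    "build_window_sets",
]

SPLITS = ("train", "val", "test")


@dataclass
class SplitAssignment:
    """record_id -> split tag, produced at record level."""

    assignment: dict[str, str]
    seed: int
    all_splits_guaranteed: bool = True

    def ids(self, split: str) -> list[str]:
        return [rid for rid, s in self.assignment.items() if s == split]


@dataclass(frozen=True)
class AugmentConfig:
    """WASW parameters; the defaults are the published stride rule
    (reference stride 1 s = 250 samples, bounds 0.5-2 s)."""

    window_s: float = 10.0
    s_ref: int = 250
    s_min: int = 125
    s_max: int = 500
    beta: float = 1.0
    val_stride: str = "ref"        # "ref" or "window"
    test_stride: str = "window"    # non-overlapping test windows by default

    def validate(self) -> None:
        if not (0 < self.s_min <= self.s_ref <= self.s_max):
            raise InvalidParameterError(
                f"need 0 < s_min <= s_ref <= s_max, got "
                f"({self.s_min}, {self.s_ref}, {self.s_max})")
        if not self.beta > 0:
            raise InvalidParameterError("beta must be positive")
        if self.val_stride not in ("ref", "window"):
            raise InvalidParameterError("val_stride must be 'ref' or 'window'")
        if self.test_stride not in ("ref", "window"):
            raise InvalidParameterError("test_stride must be 'ref' or 'window'")


@dataclass
class ClassWeights:
    """Inverse-frequency class weights, rescaled to mean 1 so that a
    balanced dataset maps every class to the reference stride."""

    weights: dict[RhythmClass, float]

    def __getitem__(self, label: RhythmClass) -> float:
        return self.weights[RhythmClass(label)]


@dataclass
class WindowSet:
    """Fixed-length labeled windows with per-window provenance."""

    windows: np.ndarray          # [n_windows, window_samples]
    labels: np.ndarray           # [n_windows] int
    source_ids: np.ndarray       # [n_windows] str
    split: str
    fs: float

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.source_ids = np.asarray(self.source_ids)
        if not (len(self.windows) == len(self.labels) == len(self.source_ids)):
            raise InvalidParameterError("window/label/source_id lengths differ")

    def __len__(self) -> int:
        return len(self.windows)

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        split = sets[0].split
        return WindowSet(
            windows=np.concatenate([s.windows for s in sets], axis=0),
            labels=np.concatenate([s.labels for s in sets]),
            source_ids=np.concatenate([s.source_ids for s in sets]),
            split=split, fs=sets[0].fs)


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Integer partition of n by ratios via largest-remainder rounding;
    ties broken by split order (train, val, test)."""
    quotas = [n * r for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(ratios)),
                   key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def stratified_split(records: list[PPGRecord],
                     ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                     seed: int = 0) -> SplitAssignment:
    """Per-class shuffle-then-partition into train/val/test at record level.

    Every class is present in every split whenever it has >= 3 records
    (repaired from the largest split if largest-remainder rounding left a
    split empty).  Classes with fewer than 3 records trigger a warning and
    clear the ``all_splits_guaranteed`` flag.
    """
    if (len(ratios) != 3 or any(r <= 0 for r in ratios)
            or abs(sum(ratios) - 1) > 1e-9):
        raise InvalidParameterError(
            f"ratios must be three positive values summing to 1: {ratios}")
    by_class: dict[RhythmClass, list[str]] = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec.record_id)
    if not by_class:
        raise InvalidParameterError("no records to split")

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    guaranteed = True
    for label in sorted(by_class):
        rids = sorted(by_class[label])
        rng.shuffle(rids)
        n = len(rids)
        counts = _largest_remainder(n, ratios)
        if n >= 3:
            # repair empty splits by borrowing from the largest one
            while min(counts) == 0:
                counts[int(np.argmax(counts))] -= 1
                counts[int(np.argmin(counts))] += 1
        else:
            guaranteed = False
            warnings.warn(
                f"class {RhythmClass(label).short_name} has only {n} record(s); "
                "not all splits can contain it", stacklevel=2)
        pos = 0
        for split, c in zip(SPLITS, counts):
            for rid in rids[pos: pos + c]:
                assignment[rid] = split
            pos += c
    return SplitAssignment(assignment=assignment, seed=seed,
                           all_splits_guaranteed=guaranteed)


def compute_class_weights(counts: dict[RhythmClass, int]) -> ClassWeights:
    """w_c proportional to 1/count_c, rescaled to mean 1; rarer classes get
    larger weights."""
    if not counts:
        raise InvalidParameterError("empty class counts")
    for label, c in counts.items():
        if c < 1:
            raise InvalidParameterError(
                f"class {label} has non-positive count {c}")
    inv = {RhythmClass(l): 1.0 / c for l, c in counts.items()}
    mean = float(np.mean(list(inv.values())))
    return ClassWeights({l: v / mean for l, v in inv.items()})


def stride_for_class(w_c: float, cfg: AugmentConfig = AugmentConfig()) -> int:
    """Class-weight-guided stride: clip(round(S_ref / w_c**beta), S_min, S_max).

    Rounding is half-away-from-zero; the result is monotone non-increasing
    in the class weight, so rarer (higher-weight) classes slide with smaller
    strides and produce more windows.
    """
    cfg.validate()
    if not w_c > 0:
        raise InvalidParameterError(f"class weight must be positive, got {w_c}")
    raw = cfg.s_ref / w_c ** cfg.beta
    rounded = int(np.floor(raw + 0.5))  # half-away-from-zero for positive raw
    return int(np.clip(rounded, cfg.s_min, cfg.s_max))


def slide_windows(record: PPGRecord, stride: int,
                  window_s: float = 10.0) -> WindowSet:
    """Cut contiguous windows starting at 0, stride, 2*stride, ...

    Produces floor((L - W) / stride) + 1 windows, each labeled with the
    record's class.  A record shorter than one window yields an empty set
    with a warning.
    """
    if stride < 1:
        raise InvalidParameterError(f"stride must be >= 1, got {stride}")
    w = int(round(window_s * record.fs))
    x = record.samples
    if len(x) < w:
        warnings.warn(
            f"record {record.record_id} shorter than one window; "
            "returning empty window set", stacklevel=2)
        return WindowSet(windows=np.empty((0, w)), labels=np.empty(0, int),
                         source_ids=np.empty(0, dtype="<U1"),
                         split="", fs=record.fs)
    n_win = (len(x) - w) // stride + 1
    starts = np.arange(n_win) * stride
    windows = np.stack([x[s: s + w] for s in starts])
    return WindowSet(
        windows=windows,
        labels=np.full(n_win, int(record.label)),
        source_ids=np.full(n_win, record.record_id),
        split="", fs=record.fs)


def build_window_sets(records: list[PPGRecord],
                      assignment: SplitAssignment,
                      cfg: AugmentConfig = AugmentConfig(),
                      ) -> dict[str, WindowSet]:
    """Cut windows for all three splits.

    Training strides follow the WASW rule computed from the training
    split's class counts only; validation/test strides are fixed by the
    config (reference stride and non-overlapping by default), so no
    augmentation choice leaks into evaluation.
    """
    cfg.validate()
    by_split: dict[str, list[PPGRecord]] = {s: [] for s in SPLITS}
    for rec in records:
        split = assignment.assignment.get(rec.record_id)
        if split is not None:
            by_split[split].append(rec)

    train_counts: dict[RhythmClass, int] = {}
    for rec in by_split["train"]:
        train_counts[rec.label] = train_counts.get(rec.label, 0) + 1
    weights = compute_class_weights(train_counts)

    out: dict[str, WindowSet] = {}
    for split in SPLITS:
        recs = by_split[split]
        sets = []
        for rec in recs:
            if split == "train":
                stride = stride_for_class(weights[rec.label], cfg)
            else:
                mode = cfg.val_stride if split == "val" else cfg.test_stride
                stride = (cfg.s_ref if mode == "ref"
                          else int(round(cfg.window_s * rec.fs)))
            ws = slide_windows(rec, stride, cfg.window_s)
            if len(ws):
                sets.append(ws)
        if sets:
            merged = WindowSet.concatenate(sets)
            merged.split = split
        else:
            w = int(round(cfg.window_s * (recs[0].fs if recs else 250.0)))
            merged = WindowSet(np.empty((0, w)), np.empty(0, int),
                               np.empty(0, dtype="<U1"), split,
                               recs[0].fs if recs else 250.0)
        out[split] = merged
    return out
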