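"""Split, class-weight and stride-rule contracts, including the
leakage-freedom property and the literal three-branch clip oracle for the
weight-guided stride."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_stub_record
from ppgrhythm.exceptions import InvalidParameterError
from ppgrhythm.synth import PPGRecord, RhythmClass, SimParams, simulate_record
from ppgrhythm.windowing import (
    AugmentConfig,
    build_window_sets,
    compute_class_weights,
    slide_windows,
    stratified_split,
    stride_for_class,
)


def stub_dataset(counts: dict[RhythmClass, int]) -> list:
    recs = []
    for label, n in counts.items():
        for i in range(n):
            recs.append(make_stub_record(f"{label.name}-{i}", label))
    return recs


class TestStratifiedSplit:
    def test_exact_622_per_class(self):
        recs = stub_dataset({c: 10 for c in RhythmClass})
        a = stratified_split(recs, seed=0)
        for c in RhythmClass:
            ids = [r.record_id for r in recs if r.label == c]
            tags = [a.assignment[i] for i in ids]
            assert (tags.count("train"), tags.count("val"),
                    tags.count("test")) == (6, 2, 2)

    def test_five_records_split_311(self):
        # largest-remainder oracle: 5 * (0.6, 0.2, 0.2) -> (3, 1, 1)
        recs = stub_dataset({RhythmClass.BRADYCARDIA: 5})
        a = stratified_split(recs, seed=1)
        tags = list(a.assignment.values())
        assert (tags.count("train"), tags.count("val"),
                tags.count("test")) == (3, 1, 1)

    def test_deterministic_under_seed(self):
        recs = stub_dataset({c: 7 for c in RhythmClass})
        assert (stratified_split(recs, seed=42).assignment
                == stratified_split(recs, seed=42).assignment)

    def test_every_class_in_every_split_when_count_ge_3(self):
        for n in (3, 4, 6, 9):
            recs = stub_dataset({c: n for c in RhythmClass})
            a = stratified_split(recs, seed=n)
            for c in RhythmClass:
                ids = {r.record_id for r in recs if r.label == c}
                tags = {a.assignment[i] for i in ids}
                assert tags == {"train", "val", "test"}

    def test_small_class_warns_and_flags(self):
        recs = stub_dataset({RhythmClass.BRADYCARDIA: 2,
                             RhythmClass.TACHYCARDIA: 6})
        with pytest.warns(UserWarning):
            a = stratified_split(recs, seed=0)
        assert not a.all_splits_guaranteed

    def test_leakage_freedom_on_random_datasets(self):
        """Source-id sets of the three splits are pairwise disjoint for 100
        random class-count configurations."""
        rng = np.random.default_rng(7)
        for trial in range(100):
            counts = {c: int(rng.integers(1, 12)) for c in RhythmClass}
            recs = stub_dataset(counts)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a = stratified_split(recs, seed=trial)
            train, val, test = (set(a.ids(s)) for s in ("train", "val",
                                                        "test"))
            assert not (train & val) and not (train & test) \
                and not (val & test)
            assert len(train | val | test) == len(recs)


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        w = compute_class_weights({c: 10 for c in RhythmClass})
        assert all(abs(w[c] - 1.0) < 1e-12 for c in RhythmClass)

    def test_two_class_inverse_frequency(self):
        w = compute_class_weights({RhythmClass.BRADYCARDIA: 10,
                                   RhythmClass.TACHYCARDIA: 30})
        assert w[RhythmClass.BRADYCARDIA] == pytest.approx(1.5)
        assert w[RhythmClass.TACHYCARDIA] == pytest.approx(0.5)

    def test_monotonicity(self):
        w = compute_class_weights({RhythmClass.BRADYCARDIA: 4,
                                   RhythmClass.TACHYCARDIA: 9,
                                   RhythmClass.VENTRICULAR_TACHYCARDIA: 20})
        assert (w[RhythmClass.BRADYCARDIA] > w[RhythmClass.TACHYCARDIA]
                > w[RhythmClass.VENTRICULAR_TACHYCARDIA])

    def test_zero_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            compute_class_weights({RhythmClass.BRADYCARDIA: 0})


class TestStrideRule:
    @pytest.mark.parametrize("w,expected", [
        (1.0, 250),     # reference stride
        (4.0, 125),     # 62.5 clipped to lower bound
        (0.25, 500),    # 1000 clipped to upper bound
        (1.25, 200),    # 250 / 1.25, inside bounds
    ])
    def test_printed_parameter_examples(self, w, expected):
        assert stride_for_class(w) == expected

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(InvalidParameterError):
            stride_for_class(0.0)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_equals_literal_clip_oracle(self, w):
        cfg = AugmentConfig()
        raw = cfg.s_ref / w ** cfg.beta
        rounded = int(np.floor(raw + 0.5))
        if rounded < cfg.s_min:
            expected = cfg.s_min
        elif rounded > cfg.s_max:
            expected = cfg.s_max
        else:
            expected = rounded
        assert stride_for_class(w, cfg) == expected

    def test_monotone_nonincreasing_in_weight(self):
        ws = np.linspace(0.05, 10, 200)
        strides = [stride_for_class(float(w)) for w in ws]
        assert all(a >= b for a, b in zip(strides, strides[1:]))


class TestSlideWindows:
    def _record(self, seconds, fs=250.0):
        return PPGRecord(samples=np.arange(int(seconds * fs), dtype=float),
                         fs=fs, label=RhythmClass.BRADYCARDIA, record_id="r")

    def test_300s_stride_250_gives_291(self):
        ws = slide_windows(self._record(300), 250)
        assert len(ws) == 291  # floor((75000 - 2500) / 250) + 1

    def test_300s_stride_500_gives_146(self):
        assert len(slide_windows(self._record(300), 500)) == 146

    def test_exact_window_length_record_gives_one(self):
        assert len(slide_windows(self._record(10), 250)) == 1

    def test_windows_are_contiguous_slices(self):
        rec = self._record(30)
        ws = slide_windows(rec, 300)
        for i, row in enumerate(ws.windows):
            assert np.array_equal(row, rec.samples[i * 300: i * 300 + 2500])

    def test_short_record_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            ws = slide_windows(self._record(5), 250)
        assert len(ws) == 0


@pytest.fixture(scope="module")
def imbalanced():
    params = SimParams(duration_s=20.0, seed=5)
    counts = {RhythmClass.BRADYCARDIA: 12, RhythmClass.TACHYCARDIA: 4,
              RhythmClass.VENTRICULAR_TACHYCARDIA: 6,
              RhythmClass.VENTRICULAR_FLUTTER_FIB: 4}
    recs = []
    for label, n in counts.items():
        for i in range(n):
            recs.append(simulate_record(
                label, params, record_id=f"{label.name}-{i}",
                seed=1000 + 17 * i + int(label)))
    return recs


class TestBuildWindowSets:

    def test_no_source_id_crosses_splits(self, imbalanced):
        a = stratified_split(imbalanced, seed=0)
        sets = build_window_sets(imbalanced, a, AugmentConfig())
        ids = {s: set(map(str, sets[s].source_ids)) for s in sets}
        assert not (ids["train"] & ids["val"])
        assert not (ids["train"] & ids["test"])
        assert not (ids["val"] & ids["test"])

    def test_wasw_equalizes_class_window_counts(self, imbalanced):
        """The max/min ratio of per-class training-window counts after
        weight-aware striding is no worse than before (fixed stride)."""
        a = stratified_split(imbalanced, seed=0)
        wasw = build_window_sets(imbalanced, a, AugmentConfig())

        def ratio(labels):
            counts = np.bincount(labels, minlength=4)
            counts = counts[counts > 0]
            return counts.max() / counts.min()

        fixed = build_window_sets(
            imbalanced, a,
            AugmentConfig(s_min=250, s_ref=250, s_max=250))
        assert ratio(wasw["train"].labels) <= ratio(fixed["train"].labels)
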