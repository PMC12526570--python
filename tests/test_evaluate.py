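"""Metric-suite contracts: hand-counted confusion matrices, the one-vs-rest
formula set against a literal per-formula oracle on random matrices,
harmonic-mean F1 values reproduced from printed precision/sensitivity
pairs, and ROC AUC against the pairwise-concordance (Mann-Whitney)
identity."""

import numpy as np
import pytest

from ppgrhythm.evaluate import (
    ConfusionMatrix,
    confusion,
    evaluate_predictions,
    f1_from_pre_sen,
    per_class_metrics,
    roc_pr,
    round2,
)
from ppgrhythm.exceptions import InvalidParameterError
from ppgrhythm.synth import RhythmClass


class TestConfusion:
    def test_perfect_prediction_diagonal(self):
        y = np.repeat(np.arange(4), 3)
        cm = confusion(y, y)
        assert np.array_equal(cm.counts, np.diag([3, 3, 3, 3]))

    def test_all_predicted_class_zero(self):
        y = np.repeat(np.arange(4), 2)
        cm = confusion(y, np.zeros_like(y))
        assert np.array_equal(cm.counts[:, 0], [2, 2, 2, 2])
        assert cm.counts[:, 1:].sum() == 0

    def test_hand_counted_example(self):
        cm = confusion([0, 0, 1, 1, 2], [0, 1, 1, 1, 2])
        assert np.array_equal(cm.counts[0], [1, 1, 0, 0])
        assert np.array_equal(cm.counts[1], [0, 2, 0, 0])
        assert np.array_equal(cm.counts[2], [0, 0, 1, 0])

    def test_unknown_label_rejected(self):
        with pytest.raises(InvalidParameterError):
            confusion([0, 5], [0, 1])


class TestPerClassMetrics:
    def test_printed_f1_reproduced_from_printed_pre_sen(self):
        # harmonic mean of the published per-class precision/sensitivity
        assert round2(f1_from_pre_sen(98.41, 100.00)) == 99.20
        assert round2(f1_from_pre_sen(100.00, 96.00)) == 97.96
        assert round2(f1_from_pre_sen(98.02, 100.00)) == 99.00

    def test_perfect_matrix_all_100(self):
        cm = ConfusionMatrix(np.diag([5, 5, 5, 5]))
        rep = per_class_metrics(cm)
        for m in rep.per_class.values():
            for key in ("Pre", "Sen", "Spe", "F1", "Acc"):
                assert m[key] == pytest.approx(100.0)
        assert rep.overall["Acc"] == pytest.approx(100.0)

    def test_binary_block_hand_computation(self):
        # classes 0/1 only: [[5,1],[2,4]]; class 0: TP=5 FP=2 FN=1 TN=4
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0], counts[0, 1] = 5, 1
        counts[1, 0], counts[1, 1] = 2, 4
        rep = per_class_metrics(ConfusionMatrix(counts))
        m = rep.per_class[RhythmClass(0)]
        assert (m["TP"], m["FP"], m["FN"], m["TN"]) == (5, 2, 1, 4)
        assert m["Pre"] == pytest.approx(100 * 5 / 7, abs=5e-3)
        assert m["Sen"] == pytest.approx(100 * 5 / 6, abs=5e-3)
        assert m["Spe"] == pytest.approx(100 * 4 / 6, abs=5e-3)
        assert m["Acc"] == pytest.approx(75.0)

    def test_matches_literal_formula_oracle_on_random_matrices(self, rng):
        """500 random confusion matrices against one-line-per-formula
        definitions (1e-12 before rounding)."""
        for _ in range(500):
            counts = rng.integers(0, 30, size=(4, 4))
            if counts.sum() == 0:
                counts[0, 0] = 1
            rep = per_class_metrics(ConfusionMatrix(counts))
            total = counts.sum()
            for c in range(4):
                tp = counts[c, c]
                fp = counts[:, c].sum() - tp
                fn = counts[c, :].sum() - tp
                tn = total - tp - fp - fn
                m = rep.per_class[RhythmClass(c)]
                if tp + fp:
                    assert abs(m["Pre"] - 100 * tp / (tp + fp)) < 1e-12
                else:
                    assert m["Pre"] is None
                if tp + fn:
                    assert abs(m["Sen"] - 100 * tp / (tp + fn)) < 1e-12
                else:
                    assert m["Sen"] is None
                if fp + tn:
                    assert abs(m["Spe"] - 100 * tn / (fp + tn)) < 1e-12
                assert abs(m["Acc"] - 100 * (tp + tn) / total) < 1e-12
                if m["Pre"] is not None and m["Sen"] is not None \
                        and m["Pre"] + m["Sen"] > 0:
                    f1 = 2 * m["Pre"] * m["Sen"] / (m["Pre"] + m["Sen"])
                    assert abs(m["F1"] - f1) < 1e-12

    def test_zero_denominator_returns_marker_not_nan(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 10  # classes 1-3 never occur nor get predicted
        rep = per_class_metrics(ConfusionMatrix(counts))
        m = rep.per_class[RhythmClass(1)]
        assert m["Pre"] is None and m["Sen"] is None
        assert not any(isinstance(v, float) and np.isnan(v)
                       for v in m.values())

    def test_empty_matrix_rejected(self):
        with pytest.raises(InvalidParameterError):
            per_class_metrics(ConfusionMatrix(np.zeros((4, 4), dtype=int)))


def concordance_auc(pos_scores, neg_scores):
    """Brute-force pairwise-concordance oracle (ties count half)."""
    wins = ties = 0
    for p in pos_scores:
        for n in neg_scores:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


class TestRocPr:
    def make_scores(self, y, col_scores):
        s = np.zeros((len(y), 4))
        s[:, 0] = col_scores
        rest = (1 - s[:, 0]) / 3
        s[:, 1:] = rest[:, None]
        return s

    def test_perfect_separation_auc_one(self):
        y = np.array([0, 0, 1, 2, 3, 1])
        scores = np.eye(4)[y] * 0.97 + 0.01
        per_class, micro_auc, micro_ap = roc_pr(y, scores)
        for c in np.unique(y):
            assert per_class[RhythmClass(int(c))] == pytest.approx(1.0)
        assert micro_auc == pytest.approx(1.0)
        assert micro_ap == pytest.approx(1.0)

    def test_label_independent_scores_give_chance_micro_auc(self):
        y = np.repeat(np.arange(4), 5)
        scores = np.full((20, 4), 0.25)
        _, micro_auc, _ = roc_pr(y, scores)
        assert micro_auc == pytest.approx(0.5)

    def test_single_inversion_gives_auc_0875(self):
        # 4 negatives, 2 positives, one discordant pair -> 7/8
        y = np.array([1, 1, 1, 1, 0, 0])  # class 0 is the positive class
        col = np.array([0.1, 0.2, 0.3, 0.6, 0.5, 0.9])
        scores = self.make_scores(y, col)
        per_class, _, _ = roc_pr(y, scores)
        assert per_class[RhythmClass(0)] == pytest.approx(0.875)
        assert concordance_auc(col[y == 0], col[y == 1]) == 0.875

    def test_auc_equals_concordance_on_exhaustive_toys(self, rng):
        """All toy score sets of <= 8 points match the Mann-Whitney
        pairwise-concordance statistic."""
        for _ in range(50):
            n = int(rng.integers(4, 9))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            col = rng.choice(np.linspace(0, 1, 5), size=n)
            labels = np.where(y == 1, 0, 1)  # positive -> class 0
            scores = self.make_scores(labels, col)
            per_class, _, _ = roc_pr(labels, scores)
            oracle = concordance_auc(col[labels == 0], col[labels == 1])
            assert per_class[RhythmClass(0)] == pytest.approx(oracle)

    def test_absent_class_marked_undefined(self):
        y = np.array([0, 0, 1])
        scores = np.full((3, 4), 0.25)
        per_class, _, _ = roc_pr(y, scores)
        assert per_class[RhythmClass(3)] is None


class TestReportAssembly:
    def test_full_report_counts_and_range(self, rng):
        y = rng.integers(0, 4, size=60)
        scores = rng.dirichlet(np.ones(4), size=60)
        rep = evaluate_predictions(y, scores)
        assert rep.cm.total == 60
        for m in rep.per_class.values():
            assert m["TP"] + m["FP"] + m["TN"] + m["FN"] == 60
            for key in ("Pre", "Sen", "Spe", "F1", "Acc"):
                if m[key] is not None:
                    assert 0.0 <= m[key] <= 100.0
        df = rep.to_dataframe()
        assert list(df["class"]) == ["Brady", "Tachy", "VT", "VF", "Overall"]

    def test_round2_is_half_up(self):
        assert round2(99.195) == 99.20
        assert round2(97.955) == 97.96
        assert round2(2.675) == 2.68
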