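"""ROC machinery: AUC identities, DeLong, Venkatraman-Begg, thresholds.

The DeLong and Venkatraman-Begg fixtures carry expected values computed
independently with R's pROC package (roc.test / ci.auc) on the identical,
seed-reconstructible score vectors.
"""

import numpy as np
import pytest

from petnodule.roc_stats import (average_thresholds, classify, compare_scores,
                                 confusion_metrics, constrained_threshold,
                                 curves_cross, delong_ci, delong_paired_test,
                                 empirical_roc, mann_whitney_auc,
                                 venkatraman_begg_test, youden_threshold,
                                 RocCurve)


def _proc_fixture():
    """Paired scores for n = 40 subjects; pROC reference values frozen in
    the tests below were computed on exactly these arrays."""
    rng = np.random.default_rng(42)
    n = 40
    y = rng.integers(0, 2, n)
    y[:3] = [1, 0, 1]
    a = rng.normal(size=n) + 0.8 * y
    b = rng.normal(size=n) + 0.5 * y
    return a, b, y


class TestEmpiricalRoc:
    def test_perfect_separation_gives_auc_one(self):
        assert empirical_roc([3, 4, 1, 2], [1, 1, 0, 0]).auc == 1.0

    def test_pair_counting_example(self):
        # pos {0.9, 0.4}, neg {0.8, 0.1}: 3 of 4 pairs concordant
        assert empirical_roc([0.9, 0.4, 0.8, 0.1],
                             [1, 1, 0, 0]).auc == pytest.approx(0.75)

    def test_all_scores_equal_gives_half(self):
        assert empirical_roc([2, 2, 2, 2], [1, 0, 1, 0]).auc == \
            pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc([1, 2], [1, 1])

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(1)
        c = empirical_roc(rng.normal(size=30), rng.integers(0, 2, 30))
        assert c.fpr[0] == 0 and c.tpr[0] == 0
        assert c.fpr[-1] == 1 and c.tpr[-1] == 1
        assert np.all(np.diff(c.fpr) >= 0)
        assert np.all(np.diff(c.tpr) >= 0)

    def test_trapezoid_equals_mann_whitney_on_500_instances(self):
        """The trapezoidal AUC is the pair-counting statistic exactly
        (ties 1/2), checked over 500 random tied instances."""
        rng = np.random.default_rng(2)
        for _ in range(500):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.normal(size=n), 1)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert empirical_roc(scores, labels).auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12)


class TestDelong:
    def test_ci_matches_pROC_reference(self):
        a, _, y = _proc_fixture()
        res = delong_ci(a, y)
        assert res.auc == pytest.approx(0.8491049, abs=1e-6)
        assert res.ci_low == pytest.approx(0.7334, abs=1e-4)
        assert res.ci_high == pytest.approx(0.9648, abs=1e-4)

    def test_paired_test_matches_pROC_reference(self):
        a, b, y = _proc_fixture()
        res = delong_paired_test(a, b, y)
        assert res.z == pytest.approx(2.5889, abs=1e-4)
        assert res.p_value == pytest.approx(0.009627, abs=1e-5)

    def test_perfect_separation_truncates_to_one(self):
        with pytest.warns(RuntimeWarning):
            res = delong_ci([3, 4, 1, 2], [1, 1, 0, 0])
        assert res.auc == 1.0 and res.ci_high == 1.0 and res.truncated

    def test_ci_covers_half_for_exchangeable_scores(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=500)
        labels = np.r_[np.ones(250), np.zeros(250)].astype(int)
        res = delong_ci(scores, labels)
        assert res.ci_low <= 0.5 <= res.ci_high

    def test_auc_consistent_with_empirical_roc(self):
        a, _, y = _proc_fixture()
        assert delong_ci(a, y).auc == pytest.approx(
            empirical_roc(a, y).auc, abs=1e-12)

    def test_identical_scores_give_z_zero_p_one(self):
        a, _, y = _proc_fixture()
        res = delong_paired_test(a, a, y)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_swapping_scorers_flips_z_keeps_p(self):
        a, b, y = _proc_fixture()
        r1 = delong_paired_test(a, b, y)
        r2 = delong_paired_test(b, a, y)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_variance_shrinks_with_sample_size(self):
        rng = np.random.default_rng(4)
        widths = []
        for n in (50, 200, 800):
            y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
            s = rng.normal(size=n) + 0.8 * y
            res = delong_ci(s, y)
            assert res.variance >= 0
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_informative_vs_noise_scorer_is_detected(self):
        """Power check: a real signal against pure noise at n = 200 is
        significant in at least 90% of 100 replicates."""
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(100):
            y = np.r_[np.ones(100), np.zeros(100)].astype(int)
            informative = rng.normal(size=200) + 1.2 * y
            noise = rng.normal(size=200)
            if delong_paired_test(informative, noise, y).p_value < 0.05:
                hits += 1
        assert hits >= 90


class TestCurvesCross:
    def test_curve_does_not_cross_itself(self):
        a, _, y = _proc_fixture()
        c = empirical_roc(a, y)
        assert curves_cross(c, c) is False

    def test_uniform_dominance_is_not_a_crossing(self):
        hi = RocCurve(fpr=np.array([0, 0, 0.5, 1.0]),
                      tpr=np.array([0, 0.8, 1.0, 1.0]),
                      thresholds=np.array([np.inf, 3, 2, 1]), auc=0.9)
        lo = RocCurve(fpr=np.array([0, 0.5, 1.0]),
                      tpr=np.array([0, 0.5, 1.0]),
                      thresholds=np.array([np.inf, 2, 1]), auc=0.5)
        assert curves_cross(hi, lo) is False

    def test_sign_change_detected_on_hand_built_curves(self):
        a = RocCurve(fpr=np.array([0, 0.2, 0.6, 1.0]),
                     tpr=np.array([0, 0.7, 0.8, 1.0]),
                     thresholds=np.array([np.inf, 3, 2, 1]), auc=0.8)
        b = RocCurve(fpr=np.array([0, 0.2, 0.6, 1.0]),
                     tpr=np.array([0, 0.3, 0.95, 1.0]),
                     thresholds=np.array([np.inf, 3, 2, 1]), auc=0.75)
        assert curves_cross(a, b) is True


class TestVenkatramanBegg:
    def test_identical_modalities_give_zero_E_p_one(self):
        _, _, y = _proc_fixture()
        x = np.arange(len(y), dtype=float)
        res = venkatraman_begg_test(x, x, y, n_permutations=50, seed=0)
        assert res.e_stat == 0.0 and res.p_value == 1.0

    def test_E_matches_pROC_reference(self):
        a, b, y = _proc_fixture()
        res = venkatraman_begg_test(a, b, y, n_permutations=200, seed=7)
        assert res.e_stat == 226.0  # pROC roc.test(method="venkatraman")

    def test_wholesale_exchange_leaves_E_unchanged(self):
        a, b, y = _proc_fixture()
        e1 = venkatraman_begg_test(a, b, y, 10, seed=1).e_stat
        e2 = venkatraman_begg_test(b, a, y, 10, seed=1).e_stat
        assert e1 == e2

    def test_E_invariant_under_monotone_transforms(self):
        a, b, y = _proc_fixture()
        e1 = venkatraman_begg_test(a, b, y, 10, seed=2).e_stat
        e2 = venkatraman_begg_test(np.exp(a), 5 * b - 3, y, 10,
                                   seed=2).e_stat
        assert e1 == e2

    def test_p_value_seed_stable(self):
        a, b, y = _proc_fixture()
        p1 = venkatraman_begg_test(a, b, y, 300, seed=9).p_value
        p2 = venkatraman_begg_test(a, b, y, 300, seed=9).p_value
        assert p1 == p2

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            venkatraman_begg_test([1, 2, 3], [1, 2], [1, 0, 1])


class TestThresholds:
    def test_separated_toy_example(self):
        res = youden_threshold([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert res.threshold == 0.8
        assert res.youden_j == pytest.approx(1.0)

    def test_youden_matches_exhaustive_oracle_on_100_instances(self):
        """Brute force over all observed cutpoints, ties toward the lower
        threshold (higher sensitivity)."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            scores = np.round(rng.uniform(size=30), 2)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            res = youden_threshold(scores, labels)
            best_j, best_t = -np.inf, None
            for t in np.unique(scores):  # ascending: first kept on ties
                sens = (scores[labels == 1] >= t).mean()
                spec = (scores[labels == 0] < t).mean()
                if sens + spec - 1 > best_j + 1e-12:
                    best_j, best_t = sens + spec - 1, t
            assert res.threshold == best_t
            assert res.youden_j == pytest.approx(best_j)

    def test_constrained_matches_exhaustive_oracle_on_100_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            scores = np.round(rng.uniform(size=30), 2)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            res = constrained_threshold(scores, labels, min_sens=0.95)
            assert res.sensitivity >= 0.95
            best_spec, best_t = -np.inf, None
            for t in np.unique(scores):
                sens = (scores[labels == 1] >= t).mean()
                spec = (scores[labels == 0] < t).mean()
                if sens >= 0.95 and spec > best_spec + 1e-12:
                    best_spec, best_t = spec, t
            assert res.threshold == best_t
            assert res.specificity == pytest.approx(best_spec)

    def test_min_sens_zero_reduces_to_max_specificity(self):
        scores = [0.9, 0.7, 0.4, 0.2]
        labels = [1, 0, 1, 0]
        res = constrained_threshold(scores, labels, min_sens=0.0)
        specs = [(np.array(scores)[np.array(labels) == 0] < t).mean()
                 for t in np.unique(scores)]
        assert res.specificity == max(specs)

    def test_perfect_separation_same_threshold_as_youden(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        assert constrained_threshold(scores, labels).threshold == \
            youden_threshold(scores, labels).threshold


class TestDecision:
    def test_average_of_four_thresholds(self):
        assert average_thresholds([0.4, 0.5, 0.6, 0.5]) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            average_thresholds([0.5, 0.5])

    def test_probability_equal_to_threshold_is_malignant(self):
        assert classify([0.5], 0.5)[0] == 1
        assert classify([0.4999], 0.5)[0] == 0

    def test_confusion_metrics_match_study_test_set(self):
        """TP=8, FN=2, TN=9, FP=4 reproduce sens 80.0%, spec 69.2%,
        acc 73.9% on a 23-subject test set."""
        labels = np.r_[np.ones(10), np.zeros(13)].astype(int)
        preds = np.r_[np.ones(8), np.zeros(2), np.ones(4), np.zeros(9)] \
            .astype(int)
        m = confusion_metrics(preds, labels)
        assert m["tp"] == 8 and m["fn"] == 2 and m["fp"] == 4 and m["tn"] == 9
        assert round(100 * m["sensitivity"], 1) == 80.0
        assert round(100 * m["specificity"], 1) == 69.2
        assert round(100 * m["accuracy"], 1) == 73.9


def test_csv_round_trip_of_scores_and_curve(tmp_path):
    from petnodule.roc_stats import read_scores_csv, write_roc_csv
    (tmp_path / "s.csv").write_text(
        "score,label\n0.9,1\n0.2,0\n0.7,1\n0.4,0\n")
    scores, labels = read_scores_csv(tmp_path / "s.csv")
    curve = empirical_roc(scores, labels)
    assert curve.auc == 1.0
    write_roc_csv(curve, tmp_path / "roc.csv")
    lines = (tmp_path / "roc.csv").read_text().strip().splitlines()
    assert lines[0] == "threshold,fpr,tpr"
    assert len(lines) == len(curve.fpr) + 1
    with pytest.raises(ValueError, match="label"):
        (tmp_path / "bad.csv").write_text("score\n1.0\n")
        read_scores_csv(tmp_path / "bad.csv")


def test_compare_scores_dispatches_on_crossing():
    a, b, y = _proc_fixture()
    out = compare_scores(a, b, y, n_permutations=100, seed=0)
    assert out["test"] in ("delong", "venkatraman_begg")
    if out["curves_cross"]:
        assert out["test"] == "venkatraman_begg"
        assert "e_stat" in out
    else:
        assert out["test"] == "delong"
        assert "z" in out
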