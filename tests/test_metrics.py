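import numpy as np
import pandas as pd
import pytest

from segpatch import confusion_counts, count_concordance, metrics_as_printed


def table_from(pred_map):
    return pd.DataFrame(
        {"image_id": "img", "object_id": list(pred_map), "class": list(pred_map.values()),
         "confidence": 1.0}
    )


def brute_force_counts(truth, pred):
    """Independent oracle: explicit double loop over (truth, pred) pairs."""
    classes = sorted(set(truth.values()) | set(pred.values()))
    out = {}
    for cls in classes:
        tp = fp = fn = tn = n = 0
        for oid in truth:
            t, p = truth[oid], pred[oid]
            if t == cls:
                n += 1
            if t == cls and p == cls:
                tp += 1
            elif t != cls and p == cls:
                fp += 1
            elif t == cls and p != cls:
                fn += 1
            else:
                tn += 1
        out[cls] = dict(n=n, tp=tp, fp=fp, fn=fn, tn=tn)
    return out


def brute_force_metrics(counts):
    """The displayed formulas, written independently and literally."""
    N = len(counts)
    precision = sum(
        (c["n"] * c["tp"]) / (c["n"] * c["tp"] + c["fp"])
        if (c["n"] * c["tp"] + c["fp"]) else 0.0
        for c in counts.values()
    ) / N
    recall = sum(
        (c["n"] * c["tp"]) / (c["n"] * c["tp"] + c["fn"])
        if (c["n"] * c["tp"] + c["fn"]) else 0.0
        for c in counts.values()
    ) / N
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = sum(
        (c["tp"] + c["tn"]) / (c["tp"] + c["fp"] + c["tn"] + c["fn"])
        for c in counts.values()
    ) / N
    return precision, recall, f1, accuracy


class TestConfusionCounts:
    def test_perfect_prediction_has_no_errors(self):
        truth = {i: 1 + i % 3 for i in range(30)}
        counts = confusion_counts(truth, table_from(truth))
        assert (counts["fp"] == 0).all() and (counts["fn"] == 0).all()
        assert (counts["tp"] == counts["n"]).all()

    def test_hand_counted_two_class_example(self):
        # confusion [[8,2],[1,9]]: 10 objects per class
        truth = {i: 1 for i in range(10)} | {i: 2 for i in range(10, 20)}
        pred = dict(truth)
        pred.update({8: 2, 9: 2, 10: 1})  # 2 class-1 -> 2; 1 class-2 -> 1
        counts = confusion_counts(truth, table_from(pred))
        assert counts.loc[1].tolist() == [10, 8, 1, 2, 9]   # n, tp, fp, fn, tn
        assert counts.loc[2].tolist() == [10, 9, 2, 1, 8]

    def test_single_object(self):
        counts = confusion_counts({1: 2}, table_from({1: 2}))
        row = counts.loc[2]
        assert row["tp"] + row["fp"] + row["fn"] + row["tn"] == 1

    def test_coverage_mismatch_fails(self):
        with pytest.raises(ValueError, match="missing"):
            confusion_counts({1: 1, 2: 1}, table_from({1: 1}))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 1000))
            k = int(rng.integers(2, 6))
            truth = {i: int(rng.integers(1, k + 1)) for i in range(n)}
            pred = {i: int(rng.integers(1, k + 1)) for i in range(n)}
            counts = confusion_counts(truth, table_from(pred))
            expected = brute_force_counts(truth, pred)
            for cls, row in expected.items():
                assert counts.loc[cls].to_dict() == row


class TestMetricsAsPrinted:
    def counts_8219(self):
        truth = {i: 1 for i in range(10)} | {i: 2 for i in range(10, 20)}
        pred = dict(truth)
        pred.update({8: 2, 9: 2, 10: 1})
        return confusion_counts(truth, table_from(pred))

    def test_perfect_classifier_all_ones(self):
        truth = {i: 1 + i % 4 for i in range(40)}
        report = metrics_as_printed(confusion_counts(truth, table_from(truth)))
        assert report.precision == report.recall == report.f1 == report.accuracy == 1.0
        assert report.weighted_precision == report.weighted_f1 == 1.0

    def test_hand_arithmetic_on_8219_case(self):
        report = metrics_as_printed(self.counts_8219())
        assert report.precision == pytest.approx(0.5 * (80 / 81 + 90 / 92), abs=1e-12)
        assert report.recall == pytest.approx(0.5 * (80 / 82 + 90 / 91), abs=1e-12)
        p, r = report.precision, report.recall
        assert report.f1 == pytest.approx(2 * p * r / (p + r), abs=1e-12)
        assert report.accuracy == pytest.approx(0.85, abs=1e-12)

    def test_printed_and_standard_weighted_differ_on_8219(self):
        report = metrics_as_printed(self.counts_8219())
        std_p = 0.5 * (8 / 9) + 0.5 * (9 / 11)
        assert report.weighted_precision == pytest.approx(std_p, abs=1e-12)
        assert abs(report.precision - report.weighted_precision) > 1e-3

    def test_degenerate_all_predicted_class_1_gives_half_accuracy(self):
        truth = {i: 1 for i in range(10)} | {i: 2 for i in range(10, 20)}
        pred = {i: 1 for i in range(20)}
        report = metrics_as_printed(confusion_counts(truth, table_from(pred)))
        assert report.accuracy == pytest.approx(0.5, abs=1e-12)

    def test_zero_denominator_term_warns_and_counts_zero(self):
        truth = {1: 1, 2: 2}
        pred = {1: 1, 2: 1}  # class 2 never predicted: its precision term is 0/0
        counts = confusion_counts(truth, table_from(pred))
        with pytest.warns(UserWarning, match="zero denominator"):
            report = metrics_as_printed(counts)
        assert np.isfinite(report.precision)

    def test_standard_weighted_matches_sklearn(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(20, 200))
            t = rng.integers(1, 4, size=n)
            p = rng.integers(1, 4, size=n)
            # ensure every true class appears
            t[:3] = [1, 2, 3]
            truth = {i: int(t[i]) for i in range(n)}
            pred = {i: int(p[i]) for i in range(n)}
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = metrics_as_printed(confusion_counts(truth, table_from(pred)))
                sk_p, sk_r, sk_f, _ = precision_recall_fscore_support(
                    t, p, average="weighted", labels=[1, 2, 3], zero_division=0
                )
            assert report.weighted_precision == pytest.approx(sk_p, abs=1e-12)
            assert report.weighted_recall == pytest.approx(sk_r, abs=1e-12)
            assert report.weighted_f1 == pytest.approx(sk_f, abs=1e-12)


class TestCountConcordance:
    def test_identical_counts_give_r2_one(self):
        assert count_concordance([5, 8, 13], [5, 8, 13]) == 1.0

    def test_hand_value_for_doubled_counts(self):
        # manual (1,2,3), predicted (2,4,6): ss_res = 1+4+9 = 14, ss_tot = 2
        assert count_concordance([2, 4, 6], [1, 2, 3]) == pytest.approx(1 - 14 / 2)

    def test_constant_manual_counts_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            count_concordance([1, 2, 3], [4, 4, 4])

    def test_needs_two_images(self):
        with pytest.raises(ValueError, match="2"):
            count_concordance([1], [1])
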