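"""Confusion counts and the seven segmentation metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lcanet.metrics import (
    ConfusionCounts,
    aggregate_metrics,
    compute_metrics,
    confusion_counts,
    write_report_csv,
    write_summary_json,
)


def brute_force_counts(pred, true):
    """Independent per-pixel recount with explicit loops."""
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = pred[i, j], true[i, j]
            if p == 1 and t == 1:
                tp += 1
            elif p == 1 and t == 0:
                fp += 1
            elif p == 0 and t == 1:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


class TestConfusionCounts:
    def test_identity_prediction_has_no_errors(self):
        rng = np.random.default_rng(0)
        m = (rng.random((12, 9)) > 0.7).astype(int)
        c = confusion_counts(m, m)
        assert c.fp == 0 and c.fn == 0
        assert c.tp == int(m.sum())

    def test_all_positive_pred_against_all_negative_truth(self):
        c = confusion_counts(np.ones((10, 10), int), np.zeros((10, 10), int))
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 100, 0, 0)

    def test_hand_constructed_counts_on_10x10(self):
        # truth: 8 positives; prediction overlaps 6, adds 2 false alarms
        true = np.zeros((10, 10), int)
        true[2:4, 2:6] = 1                      # 8 positive pixels
        pred = np.zeros((10, 10), int)
        pred[2:4, 2:5] = 1                      # 6 true positives
        pred[7, 7] = pred[8, 8] = 1             # 2 false positives
        c = confusion_counts(pred, true)
        assert (c.tp, c.fp, c.fn, c.tn) == (6, 2, 2, 90)
        assert (c.tp, c.fp, c.fn, c.tn) == brute_force_counts(pred, true)

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pred = (rng.random((16, 16)) > 0.5).astype(int)
            true = (rng.random((16, 16)) > 0.8).astype(int)
            c = confusion_counts(pred, true)
            assert (c.tp, c.fp, c.fn, c.tn) == brute_force_counts(pred, true)
            assert c.total == 256

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            confusion_counts(np.zeros((4, 4), int), np.zeros((4, 5), int))

    def test_non_binary_rejected(self):
        bad = np.full((3, 3), 2)
        with pytest.raises(ValueError, match="0 or 1"):
            confusion_counts(bad, np.zeros((3, 3), int))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


class TestComputeMetrics:
    def test_hand_derived_values(self):
        r = compute_metrics(ConfusionCounts(tp=6, fp=2, fn=2, tn=90))
        assert r.dice == pytest.approx(75.0)
        assert r.pa == pytest.approx(96.0)
        assert r.jaccard == pytest.approx(60.0)
        assert r.precision == pytest.approx(0.75)
        assert r.recall == pytest.approx(0.75)
        assert r.fpr == pytest.approx(2 / 92)
        assert r.fnr == pytest.approx(0.25)

    def test_perfect_prediction(self):
        r = compute_metrics(ConfusionCounts(tp=37, fp=0, fn=0, tn=219))
        assert r.dice == 100.0 and r.pa == 100.0 and r.jaccard == 100.0
        assert r.fpr == 0.0 and r.fnr == 0.0

    def test_dice_jaccard_identity_hand_case(self):
        r = compute_metrics(ConfusionCounts(tp=1, fp=1, fn=1, tn=0))
        assert r.dice == pytest.approx(50.0)
        assert r.jaccard == pytest.approx(100 / 3)
        j = r.jaccard / 100
        assert r.dice / 100 == pytest.approx(2 * j / (1 + j))

    def test_zero_denominators_reported_as_nan_not_crash(self):
        r = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=25))
        assert math.isnan(r.precision) and math.isnan(r.recall)
        assert math.isnan(r.fnr) and math.isnan(r.jaccard) and math.isnan(r.dice)
        assert r.pa == 100.0 and r.fpr == 0.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_identities_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            pred = (rng.random((8, 8)) > rng.uniform(0.2, 0.8)).astype(int)
            true = (rng.random((8, 8)) > rng.uniform(0.2, 0.8)).astype(int)
            c = confusion_counts(pred, true)
            r = compute_metrics(c)
            if not math.isnan(r.jaccard):
                j = r.jaccard / 100
                assert abs(r.dice / 100 - 2 * j / (1 + j)) < 1e-12
            if c.tp + c.fn > 0:
                assert abs(r.recall + r.fnr - 1.0) < 1e-12

    def test_swapping_pred_and_true_preserves_overlap_scores(self):
        rng = np.random.default_rng(5)
        pred = (rng.random((10, 10)) > 0.5).astype(int)
        true = (rng.random((10, 10)) > 0.5).astype(int)
        a = compute_metrics(confusion_counts(pred, true))
        b = compute_metrics(confusion_counts(true, pred))
        assert a.dice == b.dice and a.pa == b.pa and a.jaccard == b.jaccard
        assert a.precision == pytest.approx(b.recall)


class TestAggregate:
    @staticmethod
    def _pair(seed, shape=(6, 6)):
        rng = np.random.default_rng(seed)
        return ((rng.random(shape) > 0.5).astype(int),
                (rng.random(shape) > 0.5).astype(int))

    def test_single_pair_both_modes_agree(self):
        pair = self._pair(1)
        single = compute_metrics(confusion_counts(*pair))
        for mode in ("per-image-mean", "pooled"):
            agg = aggregate_metrics([pair], mode=mode)
            assert agg.dice == pytest.approx(single.dice)
            assert agg.fpr == pytest.approx(single.fpr)

    def test_two_identical_pairs_equal_single(self):
        pair = self._pair(2)
        single = compute_metrics(confusion_counts(*pair))
        for mode in ("per-image-mean", "pooled"):
            agg = aggregate_metrics([pair, pair], mode=mode)
            assert agg.dice == pytest.approx(single.dice)

    def test_pooled_differs_from_mean_and_matches_hand_arithmetic(self):
        # image A: tp=1, fp=0, fn=0, tn=15  -> dice 100
        # image B: tp=2, fp=2, fn=2, tn=10  -> dice 50
        a_pred = np.zeros((4, 4), int); a_pred[0, 0] = 1
        a_true = a_pred.copy()
        b_true = np.zeros((4, 4), int); b_true[0, :4] = 1
        b_pred = np.zeros((4, 4), int); b_pred[0, 2:4] = 1; b_pred[1, 0:2] = 1
        pairs = [(a_pred, a_true), (b_pred, b_true)]
        mean = aggregate_metrics(pairs, mode="per-image-mean")
        pooled = aggregate_metrics(pairs, mode="pooled")
        assert mean.dice == pytest.approx((100.0 + 50.0) / 2)
        # pooled: tp=3, fp=2, fn=2 -> dice = 600/10 = 60
        assert pooled.dice == pytest.approx(60.0)
        assert mean.dice != pooled.dice

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            aggregate_metrics([])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            aggregate_metrics([self._pair(3)], mode="median")


binary_mask = arrays(np.int64, (8, 8), elements=st.integers(0, 1))


@settings(max_examples=60, derandomize=True, deadline=None)
@given(pred=binary_mask, true=binary_mask)
def test_property_counts_partition_and_identities(pred, true):
    """Counts partition the pixels; Dice-Jaccard and recall/FNR identities."""
    c = confusion_counts(pred, true)
    assert c.total == 64
    assert c.tp == int(np.sum(pred & true))
    r = compute_metrics(c)
    if not math.isnan(r.jaccard):
        j = r.jaccard / 100
        assert abs(r.dice / 100 - 2 * j / (1 + j)) < 1e-12
    if c.tp + c.fn > 0:
        assert abs(r.recall + r.fnr - 1.0) < 1e-12
    # symmetry of the overlap scores
    rswap = compute_metrics(confusion_counts(true, pred))
    if not math.isnan(r.dice):
        assert r.dice == pytest.approx(rswap.dice)


def test_report_writers_round_trip(tmp_path):
    pair = ((np.eye(4, dtype=int)), (np.eye(4, dtype=int)))
    rows = [(0, compute_metrics(confusion_counts(*pair)))]
    csv_path = tmp_path / "rows.csv"
    json_path = tmp_path / "summary.json"
    write_report_csv(csv_path, rows)
    write_summary_json(json_path, aggregate_metrics([pair]), extra={"n": 1})
    text = csv_path.read_text()
    assert text.splitlines()[0].startswith("image_id,dice")
    import json
    payload = json.loads(json_path.read_text())
    assert payload["dice"] == 100.0 and payload["n"] == 1
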