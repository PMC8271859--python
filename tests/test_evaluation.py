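"""Pixel metrics, leaf-level matching and trait error tables."""

import numpy as np
import pytest

from herbleaf import (
    classification_metrics,
    confusion_from_masks,
    match_extracted_leaves,
    miou,
    trait_error_table,
)
from herbleaf.components import LeafCandidate
from herbleaf.evaluation import ConfusionMatrix, ExtractionCounts, UndefinedMetricError
from herbleaf.synthetic import InventoryLeaf, LeafInventory
from herbleaf.traits import TRAIT_NAMES


def naive_confusion(pred, gt):
    counts = np.zeros((2, 2), dtype=int)
    for y in range(gt.shape[0]):
        for x in range(gt.shape[1]):
            counts[int(gt[y, x]), int(pred[y, x])] += 1
    return counts


def naive_miou(counts):
    ious = []
    for x in range(counts.shape[0]):
        union = counts[x, :].sum() + counts[:, x].sum() - counts[x, x]
        if union:
            ious.append(counts[x, x] / union)
    return float(np.mean(ious))


class TestConfusionAndMiou:
    def test_perfect_prediction_has_zero_off_diagonal(self):
        rng = np.random.default_rng(0)
        gt = rng.uniform(size=(16, 16)) < 0.5
        cm = confusion_from_masks(gt, gt)
        assert cm.counts[0, 1] == cm.counts[1, 0] == 0
        assert miou(cm) == 1.0

    def test_complement_prediction_has_zero_diagonal(self):
        rng = np.random.default_rng(1)
        gt = rng.uniform(size=(16, 16)) < 0.5
        cm = confusion_from_masks(~gt, gt)
        assert cm.counts[0, 0] == cm.counts[1, 1] == 0
        assert miou(cm) == 0.0

    def test_matches_per_pixel_oracle_on_random_masks(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            pred = rng.uniform(size=(8, 8)) < 0.5
            gt = rng.uniform(size=(8, 8)) < 0.5
            cm = confusion_from_masks(pred, gt)
            oracle = naive_confusion(pred, gt)
            np.testing.assert_array_equal(cm.counts, oracle)
            assert miou(cm) == pytest.approx(naive_miou(oracle))

    def test_miou_symmetric_for_binary_masks(self):
        rng = np.random.default_rng(3)
        pred = rng.uniform(size=(12, 12)) < 0.4
        gt = rng.uniform(size=(12, 12)) < 0.4
        assert miou(confusion_from_masks(pred, gt)) == pytest.approx(
            miou(confusion_from_masks(gt, pred))
        )

    def test_absent_class_skipped_not_zeroed(self):
        # background never occurs nor is predicted: its empty-union IoU is
        # dropped from the mean instead of counting as zero
        cm = ConfusionMatrix(counts=np.array([[0, 0], [0, 8]]))
        assert miou(cm) == 1.0
        assert miou(cm, skip_absent=False) == 0.5

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_masks(np.zeros((4, 4)), np.zeros((5, 5)))


class TestClassificationMetrics:
    def test_leaf_level_counts_from_inhouse_dataset(self):
        m = classification_metrics(tp=168, fp=7, fn=7)
        assert round(m["precision"], 2) == 0.96
        assert round(m["recall"], 2) == 0.96
        assert round(m["f1"], 2) == 0.96

    def test_leaf_level_counts_from_public_dataset(self):
        m = classification_metrics(tp=232, fp=10, fn=24)
        assert m["f1"] == pytest.approx(464 / 498)
        assert round(m["f1"], 2) == 0.93

    def test_f1_is_harmonic_mean_of_precision_recall(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            tp, fp, fn = (int(v) for v in rng.integers(1, 50, size=3))
            m = classification_metrics(tp, fp, fn)
            harmonic = 2 / (1 / m["precision"] + 1 / m["recall"])
            assert m["f1"] == pytest.approx(harmonic)

    def test_all_zero_counts_raise(self):
        with pytest.raises(UndefinedMetricError):
            classification_metrics(0, 0, 0)

    def test_accuracy_needs_true_negatives(self):
        assert np.isnan(classification_metrics(5, 1, 2)["accuracy"])
        assert classification_metrics(5, 1, 2, tn=12)["accuracy"] == pytest.approx(0.85)


def _leaf(leaf_id, y0, x0, h, w, category="intact"):
    return InventoryLeaf(id=leaf_id, category=category, bbox=(x0, y0, x0 + w, y0 + h),
                         mask_crop=np.ones((h, w), dtype=bool), traits={})


def _cand(cand_id, y0, x0, h, w):
    return LeafCandidate(id=cand_id, bbox=(x0, y0, x0 + w, y0 + h),
                         image_crop=np.zeros((h, w, 3), dtype=np.uint8),
                         mask_crop=np.ones((h, w), dtype=bool), area=h * w)


class TestLeafMatching:
    def test_exact_match_kept_is_tp(self):
        inv = LeafInventory(leaves=[_leaf(0, 10, 10, 20, 20)])
        cand = _cand(1, 10, 10, 20, 20)
        counts = match_extracted_leaves([cand], [cand], inv)
        assert (counts.tp, counts.fp, counts.fn, counts.undetected) == (1, 0, 0, 0)

    def test_kept_candidate_without_match_is_fp(self):
        inv = LeafInventory(leaves=[_leaf(0, 10, 10, 20, 20)])
        stray = _cand(1, 200, 200, 20, 20)
        counts = match_extracted_leaves([stray], [stray], inv)
        assert counts.fp == 1 and counts.undetected == 1

    def test_matched_but_rejected_is_fn(self):
        inv = LeafInventory(leaves=[_leaf(0, 10, 10, 20, 20)])
        cand = _cand(1, 10, 10, 20, 20)
        counts = match_extracted_leaves([cand], [], inv)
        assert counts.fn == 1 and counts.tp == 0
        assert counts.total_extracted == 1

    def test_non_intact_leaves_are_not_match_targets(self):
        inv = LeafInventory(leaves=[_leaf(0, 10, 10, 20, 20, category="damaged")])
        cand = _cand(1, 10, 10, 20, 20)
        counts = match_extracted_leaves([cand], [cand], inv)
        assert counts.fp == 1 and counts.total_expected == 0

    def test_bookkeeping_identities_hold(self):
        inv = LeafInventory(
            leaves=[_leaf(0, 10, 10, 20, 20), _leaf(1, 50, 50, 20, 20),
                    _leaf(2, 100, 100, 20, 20)]
        )
        cands = [_cand(1, 10, 10, 20, 20), _cand(2, 50, 50, 20, 20),
                 _cand(3, 300, 300, 20, 20)]
        counts = match_extracted_leaves(cands, cands[:1] + cands[2:], inv)
        assert counts.total_expected == counts.tp + counts.fn + counts.undetected == 3
        assert counts.total_extracted == counts.tp + counts.fn == 2


class TestExtractionCounts:
    def test_derived_totals(self):
        counts = ExtractionCounts(tp=168, fp=7, fn=7, undetected=15)
        assert counts.total_expected == 190
        assert counts.total_extracted == 175

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ExtractionCounts(tp=-1, fp=0, fn=0, undetected=0)


class TestTraitErrorTable:
    def test_identical_inputs_give_zero_errors(self):
        traits = {name: float(i) for i, name in enumerate(TRAIT_NAMES)}
        table = trait_error_table({0: traits, 1: traits}, {0: traits, 1: traits})
        assert (table.to_numpy() == 0).all()

    def test_single_leaf_known_error(self):
        gt = {name: 10.0 for name in TRAIT_NAMES}
        pred = dict(gt)
        pred["area"] = 15.0
        table = trait_error_table({0: pred}, {0: gt})
        assert table.loc["area", "MAE"] == 5.0
        assert table.loc["area", "MSE"] == 25.0
        assert table.loc["area", "RMSE"] == 5.0

    def test_rmse_is_sqrt_of_mse(self):
        rng = np.random.default_rng(5)
        pred = {i: {n: float(rng.normal(100, 10)) for n in TRAIT_NAMES} for i in range(6)}
        gt = {i: {n: float(rng.normal(100, 10)) for n in TRAIT_NAMES} for i in range(6)}
        table = trait_error_table(pred, gt)
        np.testing.assert_allclose(table["RMSE"], np.sqrt(table["MSE"]))

    def test_disjoint_ids_rejected(self):
        traits = {name: 1.0 for name in TRAIT_NAMES}
        with pytest.raises(ValueError):
            trait_error_table({0: traits}, {1: traits})
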