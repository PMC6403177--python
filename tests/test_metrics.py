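"""Overlap and surface-distance metrics against brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from vesselseg.metrics import (
    ERROR_MAP_CODES,
    EmptyMaskError,
    avd,
    confusion_counts,
    dice_binary,
    error_map,
    evaluate_case,
    evaluate_cohort,
    hd95,
)


def brute_force_directed(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs nearest-neighbor distances from A's voxels to B's."""
    pa = np.argwhere(a)
    pb = np.argwhere(b)
    return cdist(pa, pb).min(axis=1)


def brute_force_hd95(a, b):
    return max(
        np.percentile(brute_force_directed(a, b), 95),
        np.percentile(brute_force_directed(b, a), 95),
    )


def brute_force_avd(a, b):
    return max(
        brute_force_directed(a, b).mean(),
        brute_force_directed(b, a).mean(),
    )


def _random_mask_pairs(n, rng, max_side=6, density=0.2):
    pairs = []
    while len(pairs) < n:
        shape = tuple(rng.integers(2, max_side + 1, size=3))
        a = rng.random(shape) < density
        b = rng.random(shape) < density
        if a.any() and b.any():
            pairs.append((a, b))
    return pairs


def test_confusion_counts_examples():
    truth = np.zeros((4, 4, 4), dtype=bool)
    truth[:2, 0, 0] = True
    assert confusion_counts(truth, truth) == (2, 0, 0, 62)
    tp, fp, fn, tn = confusion_counts(~truth, truth)
    assert tp == 0 and tn == 0 and fp + fn == 64


def test_confusion_counts_match_per_voxel_loop(rng):
    pred = rng.random((4, 4, 4)) < 0.5
    truth = rng.random((4, 4, 4)) < 0.5
    tp = fp = fn = tn = 0
    for p, g in zip(pred.ravel(), truth.ravel()):
        tp += p and g
        fp += p and not g
        fn += g and not p
        tn += not p and not g
    assert confusion_counts(pred, truth) == (tp, fp, fn, tn)


def test_dice_binary_examples():
    a = np.zeros((3, 3, 3), dtype=bool)
    a[0] = True
    assert dice_binary(a, a) == 1.0
    b = np.zeros_like(a)
    b[2] = True
    assert dice_binary(a, b) == 0.0
    # TP=2, FP=1, FN=1 -> 4/6
    pred = np.array([1, 1, 1, 0], dtype=bool)
    truth = np.array([1, 1, 0, 1], dtype=bool)
    assert dice_binary(pred, truth) == pytest.approx(2 / 3)
    assert dice_binary(np.zeros((2, 2)), np.zeros((2, 2))) == 1.0


def test_distance_examples():
    a = np.zeros((6, 6, 6), dtype=bool)
    b = np.zeros_like(a)
    a[0, 0, 0] = True
    b[3, 4, 0] = True
    assert hd95(a, b) == pytest.approx(5.0)
    assert avd(a, b) == pytest.approx(5.0)
    assert hd95(a, a) == 0.0
    assert avd(b, b) == 0.0


def test_distances_match_brute_force_oracle(rng):
    for a, b in _random_mask_pairs(200, rng):
        assert hd95(a, b) == pytest.approx(brute_force_hd95(a, b), abs=1e-9)
        assert avd(a, b) == pytest.approx(brute_force_avd(a, b), abs=1e-9)


def test_distances_symmetric_and_translation_invariant(rng):
    for a, b in _random_mask_pairs(20, rng):
        assert hd95(a, b) == pytest.approx(hd95(b, a))
        assert avd(a, b) == pytest.approx(avd(b, a))
        pad = [(1, 2), (2, 1), (0, 3)]
        a2 = np.pad(a, pad)
        b2 = np.pad(b, pad)
        assert hd95(a2, b2) == pytest.approx(hd95(a, b))
        assert avd(a2, b2) == pytest.approx(avd(a, b))


def test_hd95_bounded_by_exact_hausdorff(rng):
    for a, b in _random_mask_pairs(30, rng):
        exact_hd = max(
            brute_force_directed(a, b).max(), brute_force_directed(b, a).max()
        )
        assert hd95(a, b) <= exact_hd + 1e-12


def test_empty_mask_raises():
    a = np.zeros((3, 3, 3), dtype=bool)
    b = np.ones_like(a)
    with pytest.raises(EmptyMaskError):
        hd95(a, b)
    with pytest.raises(EmptyMaskError):
        avd(b, a)


def test_error_map_codes_and_histogram(rng):
    pred = rng.random((5, 5, 5)) < 0.4
    truth = rng.random((5, 5, 5)) < 0.4
    emap = error_map(pred, truth)
    tp, fp, fn, tn = confusion_counts(pred, truth)
    counts = np.bincount(emap.ravel(), minlength=4)
    assert counts[ERROR_MAP_CODES["TN"]] == tn
    assert counts[ERROR_MAP_CODES["TP"]] == tp
    assert counts[ERROR_MAP_CODES["FP"]] == fp
    assert counts[ERROR_MAP_CODES["FN"]] == fn
    assert set(np.unique(error_map(truth, truth))) <= {0, 1}
    assert np.all(error_map(np.ones((2, 2)), np.zeros((2, 2))) == 2)


def test_evaluate_case_perfect_prediction():
    truth = np.zeros((5, 5, 5), dtype=bool)
    truth[2, 2, 2] = True
    report = evaluate_case(truth, truth)
    assert (report.dice, report.hd95, report.avd) == (1.0, 0.0, 0.0)


def test_cohort_mean_is_unweighted():
    a = np.zeros((4, 4, 4), dtype=bool)
    a[0] = True
    half = a.copy()
    half[0, :2] = False  # dice 2*8/(16+8)... construct dice 0.5 another way
    b = np.zeros_like(a)
    b[0, 0] = True  # |b|=4, |a|=16, overlap 4 -> dice 2*4/20 = 0.4
    frame = evaluate_cohort([(a, a), (b, a)])
    assert frame.loc["case0", "dice"] == 1.0
    assert frame.loc["mean", "dice"] == pytest.approx(
        (1.0 + frame.loc["case1", "dice"]) / 2
    )
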