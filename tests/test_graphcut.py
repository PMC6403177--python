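"""Graph-cut baseline: MAP capacities and exact energy minimization."""

import itertools

import numpy as np
import pytest

from vesselseg.graphcut import (
    CAP_INF,
    GraphCutConfig,
    labeling_energy,
    segment_slice,
    segment_volume,
    unary_capacities,
)
from vesselseg.volume_io import BinaryVolume


def exhaustive_minimum(source_cap, sink_cap, weights):
    """Global MRF minimum by enumerating all 2^(H*W) labelings."""
    H, W = source_cap.shape
    best_energy, best_labels = np.inf, None
    for bits in itertools.product([0, 1], repeat=H * W):
        labels = np.array(bits).reshape(H, W)
        e = labeling_energy(labels, source_cap, sink_cap, weights)
        if e < best_energy:
            best_energy, best_labels = e, labels
    return best_energy, best_labels


def test_capacity_formulas_and_limits():
    slice_ = np.array([[0.0, 0.5, 1.0]])
    mask = np.ones_like(slice_, dtype=bool)
    src, snk = unary_capacities(slice_, mask)
    # u=0.5: equal evidence
    assert src[0, 1] == pytest.approx(snk[0, 1], rel=1e-4)
    # brightest pixel strongly bound to the vessel terminal; its vessel
    # cost clips to zero
    assert src[0, 2] == pytest.approx(-np.log(1e-6), rel=1e-6)
    assert snk[0, 2] == 0.0


def test_capacities_monotone_in_intensity(rng):
    slice_ = rng.normal(100, 20, size=(12, 12))
    mask = np.ones_like(slice_, dtype=bool)
    src, snk = unary_capacities(slice_, mask)
    assert np.all(np.isfinite(src)) and np.all(np.isfinite(snk))
    assert np.all(src >= 0) and np.all(snk >= 0)
    order = np.argsort(slice_.ravel())
    assert np.all(np.diff(src.ravel()[order]) >= -1e-12)  # source grows with u
    assert np.all(np.diff(snk.ravel()[order]) <= 1e-12)  # sink falls with u


def test_constant_slice_has_no_vessel_evidence():
    src, snk = unary_capacities(np.full((4, 4), 5.0), np.ones((4, 4), dtype=bool))
    assert np.allclose(src, 0.0)  # u = 0 everywhere: no vessel attachment
    assert np.allclose(snk, -np.log(1e-6))


def test_outside_mask_pinned_to_background():
    slice_ = np.array([[0.0, 100.0]])
    mask = np.array([[True, False]])
    _, snk = unary_capacities(slice_, mask)
    assert snk[0, 1] == CAP_INF
    labels = segment_slice(slice_, mask, GraphCutConfig(weights=1.0))
    assert labels[0, 1] == 0


def test_zero_weight_reduces_to_pixelwise_map(rng):
    slice_ = rng.normal(100, 30, size=(10, 10))
    mask = np.ones_like(slice_, dtype=bool)
    src, snk = unary_capacities(slice_, mask)
    labels = segment_slice(slice_, mask, GraphCutConfig(weights=0.0))
    assert np.array_equal(labels.astype(bool), snk < src)


def test_exact_minimum_on_3x3_instances(rng):
    for _ in range(10):
        slice_ = rng.normal(0, 1, size=(3, 3))
        mask = np.ones((3, 3), dtype=bool)
        src, snk = unary_capacities(slice_, mask)
        w = float(rng.uniform(0.1, 2.0))
        labels = segment_slice(slice_, mask, GraphCutConfig(weights=w))
        got = labeling_energy(labels, src, snk, w)
        best, _ = exhaustive_minimum(src, snk, w)
        assert got == pytest.approx(best, abs=1e-9)


def test_exact_minimum_on_4x4_instances(rng):
    for _ in range(6):
        slice_ = rng.normal(0, 1, size=(4, 4))
        mask = np.ones((4, 4), dtype=bool)
        src, snk = unary_capacities(slice_, mask)
        w = float(rng.uniform(0.1, 2.0))
        labels = segment_slice(slice_, mask, GraphCutConfig(weights=w))
        got = labeling_energy(labels, src, snk, w)
        best, _ = exhaustive_minimum(src, snk, w)
        assert got == pytest.approx(best, abs=1e-9)


def test_returned_energy_beats_reference_labelings(rng):
    slice_ = rng.normal(100, 25, size=(16, 16))
    mask = np.ones_like(slice_, dtype=bool)
    src, snk = unary_capacities(slice_, mask)
    w = 2.0
    labels = segment_slice(slice_, mask, GraphCutConfig(weights=w))
    e = labeling_energy(labels, src, snk, w)
    assert e <= labeling_energy(np.zeros_like(labels), src, snk, w) + 1e-9
    assert e <= labeling_energy((snk < src).astype(int), src, snk, w) + 1e-9


def test_huge_weight_forces_constant_labeling(rng):
    slice_ = rng.normal(100, 25, size=(12, 12))
    mask = np.ones_like(slice_, dtype=bool)
    labels = segment_slice(slice_, mask, GraphCutConfig(weights=1000.0))
    assert len(np.unique(labels)) == 1


def test_default_preset_weight():
    assert GraphCutConfig().weights == 10.0


def test_volume_modes_consistent_on_phantom():
    # a phantom in the baseline's working regime (no bias field) and a
    # weight at which the output is non-empty, so the comparison between
    # the two application modes is informative
    from vesselseg.metrics import dice_binary
    from vesselseg.phantom import PhantomConfig, generate_phantom

    volume, mask, _ = generate_phantom(
        PhantomConfig(bias_field_strength=0.0, noise_sigma=10.0, seed=1)
    )
    cfg_slice = GraphCutConfig(weights=3.0, mode="slice")
    cfg_patch = GraphCutConfig(weights=3.0, mode="patch", patch_size=32)
    seg_slice = segment_volume(volume, mask, cfg_slice)
    seg_patch = segment_volume(volume, mask, cfg_patch)
    assert seg_slice.data.sum() > 0
    assert dice_binary(seg_patch.data, seg_slice.data) > 0.9


def test_all_zero_mask_yields_empty_segmentation(phantom_case):
    volume, _, _ = phantom_case
    empty = BinaryVolume(np.zeros(volume.shape))
    assert segment_volume(volume, empty).data.sum() == 0
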