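import numpy as np
import pytest

from spikehough import HoughSpec, make_segment, match_points
from spikehough.network import (
    Ht3dSnnDetector,
    SnnParams,
    build,
    count_neurons,
    hough_spike_counts,
    inject_edges,
    subpattern_spike_counts,
)
from spikehough.reference import accumulate_along_p, vote_first_stage

from conftest import random_edge_image


def reference_accumulated(edge_image, spec, binarize=False):
    ys, xs = np.nonzero(edge_image)
    acc = vote_first_stage(np.column_stack([xs, ys]), spec)
    if binarize:
        acc.votes = np.minimum(acc.votes, 1)
    return accumulate_along_p(acc).votes


def subpattern_expected(H, spec):
    anchors = spec.anchor_rows
    out = np.zeros((spec.n_theta, spec.n_d, spec.n_p, 3), np.int64)
    for typ, span in ((0, spec.delta_p), (1, (spec.eta - 1) * spec.delta_p),
                      (2, spec.eta * spec.delta_p)):
        low = anchors - span
        low_vals = np.where(low[None, None, :] >= 0, H[..., np.maximum(low, 0)], 0)
        out[..., typ] = H[..., anchors] - low_vals
    return out


# ---- structural accounting ----------------------------------------------

def test_neuron_counts_per_layer_type():
    spec = HoughSpec(640, 480)
    c = count_neurons(spec)
    per_pos = spec.n_d * spec.n_p
    assert c["hough"] == spec.n_theta * per_pos * spec.delta_p
    assert c["subpattern"] == spec.n_theta * per_pos * 3
    assert c["pattern"] == spec.n_theta * per_pos * 8
    assert c["endpoint"] == 640 * 480
    assert spec.n_p * spec.delta_p == spec.n_rows


def test_count_ratio_between_operating_points():
    """The coarse configuration needs about one third of the neurons."""
    coarse = count_neurons(HoughSpec(640, 480, delta_d=3, delta_p=2, delta_theta=0.08))
    fine = count_neurons(HoughSpec(640, 480, delta_d=2, delta_p=2, delta_theta=0.04))
    ratio = coarse["total"] / fine["total"]
    assert 0.32 <= ratio <= 0.35


def test_doubling_delta_theta_halves_layer_totals():
    a = count_neurons(HoughSpec(100, 100, delta_theta=0.04))
    b = count_neurons(HoughSpec(100, 100, delta_theta=0.08))
    for key in ("hough", "subpattern", "pattern"):
        assert b[key] * 2 == pytest.approx(a[key], rel=0.03)


def test_derived_weights():
    spec = HoughSpec(64, 64)  # eta=6, delta_p=2
    w = SnnParams().derived_weights(spec)
    assert w["w_uI"] == -12.0
    assert w["w_cI"] == -0.25
    assert w["w_sI"] == -0.25


def test_build_rejects_empty_pattern_support():
    with pytest.raises(ValueError):
        build(HoughSpec(8, 8, delta_p=2, eta=6, delta_theta=0.5))  # eta*dp >= n_rows
    with pytest.raises(ValueError):
        build(HoughSpec(64, 64, delta_d=200, delta_theta=0.5))  # < 3 d-columns


# ---- injection -----------------------------------------------------------

def test_blank_image_stays_silent(small_detector):
    img = np.zeros((48, 48), np.uint8)
    assert inject_edges(img, small_detector.layout) == []
    res = small_detector.run(img)
    assert res.spike_counts.sum() == 0
    assert small_detector.detect(img) == []


def test_single_pixel_excites_every_layer_once(small_detector, small_spec):
    img = np.zeros((48, 48), np.uint8)
    img[20, 11] = 1
    res = small_detector.run(img, serialize=True)
    counts = hough_spike_counts(res, small_detector.layout)
    # per layer: one active column, counts 0 below the vote row and 1 above
    for t in range(small_spec.n_theta):
        active = np.nonzero(counts[t].sum(axis=1))[0]
        assert len(active) == 1
        col = counts[t, active[0]]
        assert col.max() == 1 and np.all(np.diff(col) >= 0)


def test_dimension_mismatch_rejected(small_detector):
    with pytest.raises(ValueError):
        inject_edges(np.zeros((10, 10), np.uint8), small_detector.layout)


# ---- oracle equivalence ---------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1])
def test_spike_counts_equal_reference_votes(small_detector, small_spec, seed):
    """Serialized injection: every Hough neuron's spike count equals the
    accumulated reference vote count; subpattern counts equal the cell
    differences over each neuron's span."""
    img = random_edge_image(48, 40, seed)
    res = small_detector.run(img, serialize=True)
    H = reference_accumulated(img, small_spec)
    np.testing.assert_array_equal(hough_spike_counts(res, small_detector.layout), H)
    np.testing.assert_array_equal(
        subpattern_spike_counts(res, small_detector.layout),
        subpattern_expected(H, small_spec),
    )


def test_simultaneous_injection_counts_binarized_votes(small_detector, small_spec):
    """Tick-0 injection merges coincident votes: spike counts equal the
    accumulated transform of the binarized first-stage votes."""
    img = random_edge_image(48, 45, 5)
    res = small_detector.run(img, serialize=False)
    np.testing.assert_array_equal(
        hough_spike_counts(res, small_detector.layout),
        reference_accumulated(img, small_spec, binarize=True),
    )


def test_adding_pixels_never_decreases_counts(small_detector):
    img = random_edge_image(48, 20, 11)
    more = img.copy()
    more[5, 5] = more[30, 17] = more[40, 41] = 1
    a = hough_spike_counts(small_detector.run(img, serialize=True), small_detector.layout)
    b = hough_spike_counts(small_detector.run(more, serialize=True), small_detector.layout)
    assert np.all(b >= a)


# ---- detection ------------------------------------------------------------

def test_segment_endpoints_detected_small(small_detector):
    sc = make_segment((24, 10), (24, 38), (48, 48))
    dets = small_detector.detect(sc.edge_image)
    m = match_points(dets, sc.ground_truth_points, 3.0)
    assert m.hit_rate == 1.0
    assert all(d.kind == "endpoint" for d in dets)


def test_translation_covariance(small_detector):
    base = make_segment((20, 10), (20, 34), (48, 48))
    shifted = make_segment((23, 12), (23, 36), (48, 48))
    for sc in (base, shifted):
        dets = small_detector.detect(sc.edge_image)
        assert match_points(dets, sc.ground_truth_points, 3.0).hit_rate == 1.0


def test_endpoint_potential_map_supports_winners(small_detector):
    sc = make_segment((24, 10), (24, 38), (48, 48))
    res = small_detector.run(sc.edge_image)
    pot = small_detector.endpoint_potential_map(res)
    dets = small_detector.detect(sc.edge_image)
    thr = small_detector.params.endpoint_threshold
    for d in dets:
        assert pot[int(d.y), int(d.x)] >= thr
        assert pot[int(d.y), int(d.x)] == pytest.approx(d.score)


def test_detection_is_deterministic(small_detector):
    sc = make_segment((10, 12), (40, 30), (48, 48))
    a = small_detector.detect(sc.edge_image)
    b = small_detector.detect(sc.edge_image)
    assert [(d.x, d.y, d.kind, d.score) for d in a] == [
        (d.x, d.y, d.kind, d.score) for d in b]
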