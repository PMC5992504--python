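import numpy as np
import pytest

from spikehough import HoughSpec, make_L, make_rectangle, make_segment, match_points
from spikehough.geometry import image_to_centered, line_params
from spikehough.reference import (
    Detection,
    PatternParams,
    accumulate_along_p,
    detect_patterns,
    detect_reference,
    is_empty_segment,
    is_full_segment,
    localize_in_image,
    min_eigenvalue_map,
    segment_point_count,
    vote_first_stage,
)
from spikehough.scenes import render_intensity


def brute_force_accumulated(edge_points, spec):
    """Independent oracle: every point votes for every cell at p >= its own."""
    H = np.zeros((spec.n_theta, spec.n_d, spec.n_rows), np.int64)
    for px, py in edge_points:
        x, y = image_to_centered(px, py, spec)
        for t, theta in enumerate(spec.theta_values):
            d, p = line_params(x, y, theta)
            d_idx = int(np.clip(np.floor((d + spec.R) / spec.delta_d + 0.5), 0, spec.n_d - 1))
            row = int(np.clip(np.floor(p + spec.R + 0.5), 0, spec.n_rows - 1))
            H[t, d_idx, row:] += 1
    return H


@pytest.fixture(scope="module")
def spec():
    return HoughSpec(32, 32, delta_d=2, delta_p=2, delta_theta=0.4, eta=3)


def test_first_stage_vote_conservation(spec):
    rng = np.random.default_rng(3)
    pts = rng.integers(0, 32, size=(17, 2))
    acc = vote_first_stage(pts, spec)
    # each orientation layer holds exactly one vote per point
    assert np.all(acc.votes.sum(axis=(1, 2)) == len(pts))


def test_empty_input_gives_zero_accumulator(spec):
    assert vote_first_stage([], spec).votes.sum() == 0


def test_vertical_segment_votes_in_one_column(spec):
    sc = make_segment((10, 8), (10, 13), (32, 32))
    ys, xs = np.nonzero(sc.edge_image)
    acc = vote_first_stage(np.column_stack([xs, ys]), spec)
    layer0 = acc.votes[0]  # theta=0 layer contains vertical lines (d = x)
    cols = np.nonzero(layer0.sum(axis=1))[0]
    assert len(cols) == 1
    assert layer0[cols[0]].sum() == 6
    assert np.count_nonzero(layer0[cols[0]]) == 6  # six distinct rows


def test_accumulate_is_prefix_sum(spec):
    acc = vote_first_stage([(5, 5)], spec)
    out = accumulate_along_p(acc)
    col = acc.votes[0, :, :]
    np.testing.assert_array_equal(out.votes[0], np.cumsum(col, axis=1))
    # monotone along p, top row equals total votes in the column
    assert np.all(np.diff(out.votes, axis=2) >= 0)
    np.testing.assert_array_equal(out.votes[..., -1], acc.votes.sum(axis=2))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_accumulated_equals_brute_force(spec, seed):
    """The two-stage scheme equals direct per-(point, cell) voting."""
    rng = np.random.default_rng(seed)
    pts = rng.integers(0, 32, size=(25, 2))
    fast = accumulate_along_p(vote_first_stage(pts, spec)).votes
    np.testing.assert_array_equal(fast, brute_force_accumulated(pts, spec))


def test_segment_point_count(spec):
    sc = make_segment((10, 8), (10, 13), (32, 32))
    ys, xs = np.nonzero(sc.edge_image)
    acc = accumulate_along_p(vote_first_stage(np.column_stack([xs, ys]), spec))
    t, d, rows = 0, None, None
    d = int(np.nonzero(acc.votes[0, :, -1])[0][0])
    row_lo = int(np.nonzero(np.diff(acc.votes[0, d]))[0][0])  # first vote row - ...
    row_hi = row_lo + 7
    full = segment_point_count(acc, 0, d, row_hi, row_lo)
    assert full == acc.votes[0, d, row_hi] - acc.votes[0, d, row_lo]
    assert segment_point_count(acc, 0, d, row_hi, row_hi) == 0
    assert segment_point_count(acc, 0, d, row_lo, row_hi) == full  # symmetric


def test_full_and_empty_segment_thresholds(spec):
    sc = make_segment((10, 8), (10, 19), (32, 32))  # 12 edge pixels
    ys, xs = np.nonzero(sc.edge_image)
    acc = accumulate_along_p(vote_first_stage(np.column_stack([xs, ys]), spec))
    d = int(np.nonzero(acc.votes[0, :, -1])[0][0])
    top = int(np.nonzero(acc.votes[0, d] == acc.votes[0, d].max())[0][0])
    count = segment_point_count(acc, 0, d, top, top - 6)
    assert is_full_segment(acc, 0, d, top, 6, tau_F=count - 1)
    assert not is_full_segment(acc, 0, d, top, 6, tau_F=count)  # strict
    assert is_empty_segment(acc, 0, d, min(top + 6, spec.n_rows - 1), 2, tau_E=1.0)
    with pytest.raises(ValueError):
        is_full_segment(acc, 0, d, 3, 6, tau_F=1)


def test_blank_image_has_no_detections(spec):
    acc = accumulate_along_p(vote_first_stage([], spec))
    assert detect_patterns(acc, PatternParams()) == []


def test_isolated_segment_yields_exactly_two_endpoint_patterns():
    """One normal and one flipped endpoint hit, none elsewhere, when the
    resolution suppresses oblique and near-pi aliasing."""
    spec = HoughSpec(48, 48, delta_d=1, delta_p=2, delta_theta=0.35, eta=3)
    # ends on pattern anchor rows: row = round(y - 23.5 + R) must be odd
    R = spec.R
    y1 = next(y for y in range(24, 34) if round(y - 23.5 + R) % 2 == 1)
    y0 = y1 - 9  # 10 pixels
    sc = make_segment((20, y0), (20, y1), (48, 48))
    ys, xs = np.nonzero(sc.edge_image)
    acc = accumulate_along_p(vote_first_stage(np.column_stack([xs, ys]), spec))
    dets = detect_patterns(acc, PatternParams())
    kinds = sorted((d.kind, d.flipped) for d in dets)
    assert kinds == [("endpoint", False), ("endpoint", True)]
    m = match_points(dets, [(20, y0), (20, y1)], 3.0)
    assert m.hit_rate == 1.0


def test_L_junction_yields_corner():
    spec = HoughSpec(64, 64)
    sc = make_L(22, 90.0, (64, 64), vertex=(20, 20))
    dets = detect_reference(sc.edge_image, spec)
    corners = [d for d in dets if d.kind == "corner"]
    assert corners, "expected at least one corner at the junction"
    m = match_points(corners, [(20, 20)], 3.0)
    assert m.n_correct == 1


def test_reference_rectangle_hits_all_corners():
    spec = HoughSpec(64, 64)
    sc = make_rectangle((64, 64))
    dets = detect_reference(sc.edge_image, spec)
    assert match_points(dets, sc.ground_truth_points, 3.0).hit_rate == 1.0


def test_localization_refines_to_sharp_corner():
    spec = HoughSpec(64, 64)
    sc = make_rectangle((64, 64))
    intensity = render_intensity(sc)
    corner = sc.corners[0][:2]
    det = Detection("corner", False, 0, 0, 0, corner[0] + 2.0, corner[1] + 2.0, 1.0)
    x, y, score = localize_in_image(det, intensity, spec)
    assert abs(x - corner[0]) <= 1 and abs(y - corner[1]) <= 1
    assert score > 0


def test_localization_constant_window_scores_zero():
    spec = HoughSpec(64, 64)
    flat = np.full((64, 64), 77, np.uint8)
    det = Detection("endpoint", False, 0, 0, 0, 30.0, 30.0, 1.0)
    x, y, score = localize_in_image(det, flat, spec)
    assert (x, y, score) == (30.0, 30.0, 0.0)


def test_localization_window_clipped_at_border():
    spec = HoughSpec(64, 64)
    sc = make_rectangle((64, 64))
    intensity = render_intensity(sc)
    det = Detection("endpoint", False, 0, 0, 0, 0.0, 0.0, 1.0)
    assert localize_in_image(det, intensity, spec) is not None


def test_detect_patterns_rotation_covariance():
    """Rotating the scene by 90 degrees (an exact multiple of delta_theta
    for delta_theta = pi/10) rotates endpoint detections accordingly."""
    spec = HoughSpec(48, 48, delta_d=1, delta_p=2, delta_theta=np.pi / 10, eta=3)
    y1 = next(y for y in range(24, 34) if round(y - 23.5 + spec.R) % 2 == 1)
    sc = make_segment((20, y1 - 9), (20, y1), (48, 48))
    rot = np.rot90(sc.edge_image, k=1).copy()  # (x, y) -> (y, 47 - x)
    for img, gt in ((sc.edge_image, [(20, y1 - 9), (20, y1)]),
                    (rot, [(y1 - 9, 47 - 20), (y1, 47 - 20)])):
        ys, xs = np.nonzero(img)
        acc = accumulate_along_p(vote_first_stage(np.column_stack([xs, ys]), spec))
        dets = detect_patterns(acc, PatternParams())
        assert match_points(dets, gt, 3.0).hit_rate == 1.0
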