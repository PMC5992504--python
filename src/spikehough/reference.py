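"""Array-based HT3D: two-stage voting, pattern checks, coarse-to-fine localization.

This is the regular (non-spiking) form of the transform.  Edge pixels vote
once per orientation layer for the first segment they could terminate; a
prefix sum along the position axis then yields, in every cell
``H(theta, d, p)``, the number of edge points of line ``(theta, d)`` at
positions ``<= p``.  Corners and non-intersection segment endpoints appear
as fixed local cell patterns built from *full* and *empty* vertical pieces
of segment, where a piece spanning rows ``(p - l, p]`` is full when
``H(p) - H(p - l)`` exceeds ``tau_F`` and empty when it falls below a
near-zero ``tau_E``.

Besides being a detector in its own right, this module is the independent
oracle for the spiking network: Hough-neuron spike counts must reproduce
the accumulated array exactly, and subpattern spike counts the cell
differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import (
    HoughSpec,
    centered_to_image,
    hough_to_image_center,
    image_to_centered,
    line_params,
)

__all__ = [
    "HoughAccumulator",
    "PatternParams",
    "Detection",
    "vote_first_stage",
    "accumulate_along_p",
    "segment_point_count",
    "is_full_segment",
    "is_empty_segment",
    "detect_patterns",
    "min_eigenvalue_map",
    "localize_in_image",
    "nms_detections",
    "detect_reference",
]


@dataclass
class PatternParams:
    """Thresholds and angle range for corner/endpoint pattern checks.

    ``tau_F``/``tau_E`` default to ``eta*delta_p - 2`` and ``1`` for the
    spec in use (a full piece may miss two votes; an empty piece must hold
    none).  ``lateral_span_cells`` is the length, in cells, of the empty
    lateral run of the corner pattern; the top/bottom cell is excluded, so
    it defaults to ``eta - 1``.
    """

    tau_F: float | None = None
    tau_E: float = 1.0
    phi_min: float = math.radians(35.0)
    phi_max: float = math.radians(145.0)
    lateral_span_cells: int | None = None

    def resolve(self, spec: HoughSpec) -> "PatternParams":
        tau_F = self.tau_F if self.tau_F is not None else spec.eta * spec.delta_p - 2
        lat = self.lateral_span_cells if self.lateral_span_cells is not None else spec.eta - 1
        if not (tau_F > self.tau_E >= 0):
            raise ValueError("need tau_F > tau_E >= 0")
        if not (0 < self.phi_min < self.phi_max < math.pi):
            raise ValueError("corner angle range must satisfy 0 < phi_min < phi_max < pi")
        return replace(self, tau_F=tau_F, lateral_span_cells=lat)


@dataclass
class Detection:
    """A detected feature, in both Hough and image coordinates."""

    kind: Literal["corner", "endpoint"]
    flipped: bool
    theta_idx: int
    d_idx: int
    row_idx: int
    x: float
    y: float
    score: float


@dataclass
class HoughAccumulator:
    """Vote array over (orientation layer, d-column, 1-pixel p-row)."""

    spec: HoughSpec
    votes: np.ndarray
    accumulated: bool = False

    @classmethod
    def zeros(cls, spec: HoughSpec) -> "HoughAccumulator":
        return cls(spec, np.zeros((spec.n_theta, spec.n_d, spec.n_rows), dtype=np.int64))


def vote_first_stage(edge_points, spec: HoughSpec) -> HoughAccumulator:
    """First-stage votes: one vote per point per orientation layer.

    ``edge_points`` is a sequence of ``(px, py)`` pixel positions.  Each
    point votes only for the cell whose ``p`` equals its own position along
    the line (the lowest cell of all it belongs to).
    """
    acc = HoughAccumulator.zeros(spec)
    pts = np.atleast_2d(np.asarray(edge_points, dtype=float))
    if pts.size == 0:
        return acc
    x, y = image_to_centered(pts[:, 0], pts[:, 1], spec)
    for t, theta in enumerate(spec.theta_values):
        d, p = line_params(x, y, theta)
        d_idx = np.clip(
            np.floor((d + spec.R) / spec.delta_d + 0.5).astype(np.int64), 0, spec.n_d - 1
        )
        row = np.clip(np.floor(p + spec.R + 0.5).astype(np.int64), 0, spec.n_rows - 1)
        np.add.at(acc.votes[t], (d_idx, row), 1)
    return acc


def accumulate_along_p(acc: HoughAccumulator) -> HoughAccumulator:
    """In-column prefix sum: each cell absorbs the one below it.

    Equivalent to the complete voting scheme in which every point votes for
    all cells at positions ``>=`` its own.
    """
    out = HoughAccumulator(acc.spec, np.cumsum(acc.votes, axis=2), accumulated=True)
    return out


def _H_at(H: np.ndarray, rows) -> np.ndarray:
    """H sampled at (possibly negative) row indices; rows < 0 read as 0."""
    rows = np.asarray(rows)
    safe = np.clip(rows, 0, H.shape[-1] - 1)
    vals = H[..., safe]
    return np.where(rows >= 0, vals, 0)


def segment_point_count(acc: HoughAccumulator, theta_idx, d_idx, row_i, row_j):
    """Number of edge points on the discrete line between two positions."""
    if not acc.accumulated:
        raise ValueError("accumulator must be accumulated along p first")
    col = acc.votes[theta_idx, d_idx]
    return np.abs(_H_at(col, row_i) - _H_at(col, row_j))


def _check_rows(spec: HoughSpec, row, length_rows):
    row = int(row)
    if row - int(length_rows) < 0 or row >= spec.n_rows:
        raise ValueError("segment rows out of range")
    return row


def is_full_segment(acc, theta_idx, d_idx, row, length_rows, tau_F) -> bool:
    """Piece spanning ``(row - length_rows, row]`` holds more than tau_F votes."""
    row = _check_rows(acc.spec, row, length_rows)
    return bool(segment_point_count(acc, theta_idx, d_idx, row, row - length_rows) > tau_F)


def is_empty_segment(acc, theta_idx, d_idx, row, length_rows, tau_E) -> bool:
    """Piece spanning ``(row - length_rows, row]`` holds fewer than tau_E votes."""
    row = _check_rows(acc.spec, row, length_rows)
    return bool(segment_point_count(acc, theta_idx, d_idx, row, row - length_rows) < tau_E)


# ---- pattern detection --------------------------------------------------

def _piece_tables(acc: HoughAccumulator, params: PatternParams):
    """Boolean full/empty tables over (layer, column, strided cell)."""
    spec = acc.spec
    H = acc.votes
    anchors = spec.anchor_rows
    span_c = spec.eta * spec.delta_p
    span_s = params.lateral_span_cells * spec.delta_p

    def diff(span):
        return _H_at(H, anchors) - _H_at(H, anchors - span)

    c_diff = diff(span_c)
    cfull = c_diff > params.tau_F
    uempty = diff(spec.delta_p) < params.tau_E
    sempty = diff(span_s) < params.tau_E
    return cfull, uempty, sempty, c_diff


def _pattern_masks(acc: HoughAccumulator, params: PatternParams):
    """Endpoint and corner half-pattern hits at every (t, d, cell, version).

    Cell ``k`` covers rows ``[k*dp, (k+1)*dp - 1]``.  The normal version
    anchors a pattern whose full piece lies *below* the cell (the feature is
    the upper end of the vote run); the flipped version mirrors it.  Cells
    whose pattern would overrun the column or the lateral columns are
    skipped rather than zero-padded.
    """
    spec = acc.spec
    eta, n_p, n_d = spec.eta, spec.n_p, spec.n_d
    cfull, uempty, sempty, c_diff = _piece_tables(acc, params)
    anchors = spec.anchor_rows

    def shift(tab, dk):
        """tab[t, d, k + dk], False out of range."""
        out = np.zeros_like(tab)
        if dk == 0:
            return tab.copy()
        if dk > 0:
            out[:, :, : n_p - dk] = tab[:, :, dk:]
        else:
            out[:, :, -dk:] = tab[:, :, :dk]
        return out

    def lateral(tab, dd):
        out = np.zeros_like(tab)
        if dd > 0:
            out[:, : n_d - dd] = tab[:, dd:]
        else:
            out[:, -dd:] = tab[:, :dd]
        return out

    k = np.arange(n_p)
    in_col_n = (anchors >= spec.full_piece_rows) & (k + 1 <= n_p - 1)
    in_col_f = (k >= 1) & (k + eta - 1 <= n_p - 1)
    d_ok = np.zeros((n_d, 1), bool)
    d_ok[1 : n_d - 1] = True

    # endpoint, normal: full run below cell k, cell k+1 empty in all three
    # columns, lateral eta-cell pieces not full
    ep_n = (
        cfull
        & shift(uempty, 1)
        & lateral(shift(uempty, 1), -1)
        & lateral(shift(uempty, 1), 1)
        & ~lateral(cfull, -1)
        & ~lateral(cfull, 1)
        & d_ok
        & in_col_n
    )
    # endpoint, flipped: full run above cell k (c at cell k+eta-1), cell k-1
    # empty in all three columns
    cfull_up = shift(cfull, eta - 1)
    ep_f = (
        cfull_up
        & shift(uempty, -1)
        & lateral(shift(uempty, -1), -1)
        & lateral(shift(uempty, -1), 1)
        & ~lateral(cfull_up, -1)
        & ~lateral(cfull_up, 1)
        & d_ok
        & in_col_f
    )
    # corner half-pattern: central full piece plus at least one empty
    # lateral run of lateral_span_cells cells (excluding the top/bottom cell)
    co_n = (
        cfull
        & (lateral(shift(sempty, -1), -1) | lateral(shift(sempty, -1), 1))
        & d_ok
        & in_col_n
        & (k >= 1)
    )
    s_up = shift(sempty, eta - 1)
    co_f = cfull_up & (lateral(s_up, -1) | lateral(s_up, 1)) & d_ok & in_col_f
    return ep_n, ep_f, co_n, co_f, c_diff


def _cell_positions(spec: HoughSpec, t, d_idx, k, flipped):
    """Image pixel position of the feature cell of a pattern hit."""
    anchors = spec.anchor_rows
    row = anchors[np.asarray(k)]
    # feature sits at the top 1-px row of cell k (normal) or its bottom row
    # (flipped), where the vote run terminates
    p = np.where(flipped, row - (spec.delta_p - 1), row) - spec.R
    d = np.asarray(d_idx) * spec.delta_d - spec.R
    theta = spec.theta_values[np.asarray(t)]
    xc, yc = hough_to_image_center(theta, d, p)
    return centered_to_image(xc, yc, spec)


def detect_patterns(acc: HoughAccumulator, params: PatternParams) -> list[Detection]:
    """Hough-space stage: all endpoint and corner pattern hits.

    A corner requires a half-pattern on a second orientation layer at an
    angular offset within ``[phi_min, phi_max]`` (mod pi) whose cell maps to
    the same image position within ``max(delta_d, delta_p)`` pixels.
    """
    if not acc.accumulated:
        raise ValueError("accumulator must be accumulated along p first")
    spec = acc.spec
    params = params.resolve(spec)
    ep_n, ep_f, co_n, co_f, c_diff = _pattern_masks(acc, params)

    detections: list[Detection] = []

    def central_score(t, d, k, flipped):
        kk = np.where(flipped, np.asarray(k) + spec.eta - 1, k)
        return c_diff[t, d, kk]

    for mask, flipped in ((ep_n, False), (ep_f, True)):
        t, d, k = np.nonzero(mask)
        if t.size == 0:
            continue
        x, y = _cell_positions(spec, t, d, k, flipped)
        sc = central_score(t, d, k, flipped)
        row = spec.anchor_rows[k]
        for i in range(t.size):
            detections.append(
                Detection("endpoint", flipped, int(t[i]), int(d[i]), int(row[i]),
                          float(x[i]), float(y[i]), float(sc[i]))
            )

    # corner half-patterns, then cross-layer support
    cands = []
    for mask, flipped in ((co_n, False), (co_f, True)):
        t, d, k = np.nonzero(mask)
        if t.size == 0:
            continue
        x, y = _cell_positions(spec, t, d, k, flipped)
        sc = central_score(t, d, k, flipped)
        row = spec.anchor_rows[k]
        for i in range(t.size):
            cands.append((int(t[i]), int(d[i]), int(row[i]), bool(flipped),
                          float(x[i]), float(y[i]), float(sc[i])))
    if cands:
        centers = np.array([(c[4], c[5]) for c in cands])
        layers = np.array([c[0] for c in cands])
        tol = max(spec.delta_d, spec.delta_p)
        tree = cKDTree(centers)
        supported = np.zeros(len(cands), bool)
        for i, j in tree.query_pairs(r=tol):
            off = (spec.delta_theta * abs(int(layers[i]) - int(layers[j]))) % math.pi
            if params.phi_min <= off <= params.phi_max:
                supported[i] = supported[j] = True
        for i in np.nonzero(supported)[0]:
            t, d, row, flipped, x, y, sc = cands[i]
            detections.append(Detection("corner", flipped, t, d, row, x, y, sc))
    return detections


# ---- image-space localization ------------------------------------------

def min_eigenvalue_map(intensity: np.ndarray) -> np.ndarray:
    """Smaller eigenvalue of the local gradient covariance at every pixel.

    3x3 Sobel derivatives, covariance summed over a 5x5 neighborhood; the
    standard minimum-eigenvalue corner criterion.
    """
    img = np.asarray(intensity, dtype=float)
    gx = ndimage.sobel(img, axis=1, mode="nearest")
    gy = ndimage.sobel(img, axis=0, mode="nearest")
    sxx = ndimage.uniform_filter(gx * gx, size=5, mode="constant")
    syy = ndimage.uniform_filter(gy * gy, size=5, mode="constant")
    sxy = ndimage.uniform_filter(gx * gy, size=5, mode="constant")
    tr = sxx + syy
    det = sxx * syy - sxy * sxy
    disc = np.sqrt(np.maximum(tr * tr / 4.0 - det, 0.0))
    return tr / 2.0 - disc


def localize_in_image(detection: Detection, intensity_image: np.ndarray, spec: HoughSpec,
                      eig_map: np.ndarray | None = None):
    """Refine a detection inside its image window using the intensity image.

    Searches the window implied by the cell resolutions for the pixel
    maximizing the minimum-eigenvalue criterion.  Returns ``(x, y, score)``
    or ``None`` when the window lies fully outside the image (detection
    dropped).  A featureless window returns the window center with score 0.
    """
    h, w = intensity_image.shape[:2]
    half = int(max(spec.delta_d, spec.delta_p))
    cx, cy = int(round(detection.x)), int(round(detection.y))
    x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
    y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
    if x0 >= x1 or y0 >= y1:
        return None
    if eig_map is None:
        eig_map = min_eigenvalue_map(intensity_image)
    win = eig_map[y0:y1, x0:x1]
    best = float(win.max())
    if best <= 0.0:
        return float(np.clip(cx, x0, x1 - 1)), float(np.clip(cy, y0, y1 - 1)), 0.0
    iy, ix = np.unravel_index(int(np.argmax(win)), win.shape)
    return float(x0 + ix), float(y0 + iy), best


def nms_detections(detections: list[Detection], window: int) -> list[Detection]:
    """Greedy winner-take-all: keep descending-score maxima, suppressing any
    later detection within a window x window neighborhood (ties in raster
    order)."""
    order = sorted(
        range(len(detections)),
        key=lambda i: (-detections[i].score,
                       round(detections[i].y), round(detections[i].x),
                       detections[i].kind, i),
    )
    half = window // 2
    kept: list[Detection] = []
    for i in order:
        d = detections[i]
        if all(abs(d.x - k.x) > half or abs(d.y - k.y) > half for k in kept):
            kept.append(d)
    return kept


def detect_reference(edge_image: np.ndarray, spec: HoughSpec,
                     params: PatternParams | None = None,
                     intensity_image: np.ndarray | None = None,
                     nms_window: int | None = None) -> list[Detection]:
    """Full reference pipeline: vote, accumulate, match patterns, localize, NMS."""
    params = (params or PatternParams()).resolve(spec)
    if edge_image.shape != (spec.height, spec.width):
        raise ValueError("edge image does not match spec dimensions")
    py, px = np.nonzero(edge_image)
    acc = accumulate_along_p(vote_first_stage(np.column_stack([px, py]), spec))
    dets = detect_patterns(acc, params)
    if intensity_image is not None:
        eig = min_eigenvalue_map(intensity_image)
        refined = []
        for d in dets:
            loc = localize_in_image(d, intensity_image, spec, eig_map=eig)
            if loc is None:
                continue
            d.x, d.y, d.score = loc[0], loc[1], d.score + loc[2]
            refined.append(d)
        dets = refined
    else:
        h, w = edge_image.shape
        dets = [d for d in dets if 0 <= round(d.x) < w and 0 <= round(d.y) < h]
    window = nms_window if nms_window is not None else 2 * int(max(spec.delta_d, spec.delta_p)) + 1
    return nms_detections(dets, window)
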