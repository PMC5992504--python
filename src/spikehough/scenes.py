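"""Synthetic edge/intensity scenes with exact corner and endpoint ground truth.

These generators stand in for the upstream edge-detection stage: they emit
clean, one-pixel-wide digital lines (midpoint rasterization, no
anti-aliasing) whose corners and free segment ends are known exactly, so
every stage of the detector can be tested without external data.  All
generators are pure functions of their arguments, including the seed used
by :func:`degrade`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import line as _draw_line
from skimage.draw import polygon as _fill_polygon

__all__ = [
    "Scene",
    "make_segment",
    "make_polyline",
    "make_polygon",
    "make_L",
    "make_rectangle",
    "degrade",
    "render_intensity",
]


@dataclass
class Scene:
    """Binary edge raster plus ground truth and an optional intensity image.

    ``corners`` holds ``(x, y, interior_angle_degrees)`` triples and
    ``endpoints`` holds the free segment ends ``(x, y)``; every ground-truth
    point lies on an edge pixel.
    """

    edge_image: np.ndarray
    intensity_image: np.ndarray | None
    corners: list[tuple[int, int, float]]
    endpoints: list[tuple[int, int]]
    seed: int | None = None
    description: str = ""
    polygon_vertices: list[tuple[int, int]] | None = None
    closed: bool = False

    @property
    def ground_truth_points(self) -> np.ndarray:
        pts = [(x, y) for x, y, _ in self.corners] + list(self.endpoints)
        return np.asarray(pts, dtype=float).reshape(-1, 2)


def _blank(size) -> np.ndarray:
    w, h = size
    return np.zeros((h, w), dtype=np.uint8)


def _check_inside(pts, size):
    w, h = size
    for x, y in pts:
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"point {(x, y)} outside {w}x{h} image")


def _rasterize(img: np.ndarray, p0, p1) -> None:
    rr, cc = _draw_line(int(p0[1]), int(p0[0]), int(p1[1]), int(p1[0]))
    img[rr, cc] = 1


def _interior_angle(prev, v, nxt) -> float:
    a = np.asarray(prev, float) - np.asarray(v, float)
    b = np.asarray(nxt, float) - np.asarray(v, float)
    cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _segment_crossings(vertices, closed):
    """Proper crossings between non-adjacent polyline segments (X-junctions)."""
    pts = [np.asarray(p, float) for p in vertices]
    segs = list(zip(pts[:-1], pts[1:]))
    if closed:
        segs.append((pts[-1], pts[0]))
    out = []
    n = len(segs)
    for i in range(n):
        for j in range(i + 2, n):
            if closed and i == 0 and j == n - 1:
                continue
            (a, b), (c, d) = segs[i], segs[j]
            r, s = b - a, d - c
            denom = r[0] * s[1] - r[1] * s[0]
            if abs(denom) < 1e-12:
                continue
            t = ((c - a)[0] * s[1] - (c - a)[1] * s[0]) / denom
            u = ((c - a)[0] * r[1] - (c - a)[1] * r[0]) / denom
            if 1e-9 < t < 1 - 1e-9 and 1e-9 < u < 1 - 1e-9:
                p = a + t * r
                ang = math.degrees(
                    math.acos(abs(np.dot(r, s)) / (np.linalg.norm(r) * np.linalg.norm(s)))
                )
                out.append((int(round(p[0])), int(round(p[1])), ang))
    return out


def make_segment(p0, p1, size=(64, 64)) -> Scene:
    """A single digital straight segment; ground truth is its two endpoints."""
    if tuple(p0) == tuple(p1):
        raise ValueError("degenerate segment: p0 == p1")
    _check_inside([p0, p1], size)
    img = _blank(size)
    _rasterize(img, p0, p1)
    return Scene(img, None, [], [tuple(map(int, p0)), tuple(map(int, p1))],
                 description=f"segment {p0}-{p1}",
                 polygon_vertices=[tuple(p0), tuple(p1)])


def make_polyline(vertices, size=(64, 64), closed: bool = False) -> Scene:
    """Rasterized open/closed polyline with annotated corners and ends.

    Interior vertices (all vertices when closed) become corners with their
    interior angle; the two free ends of an open polyline are endpoints.
    Self-intersections are allowed and annotated as corners at the crossing.
    """
    if len(vertices) < 2:
        raise ValueError("need at least two vertices")
    _check_inside(vertices, size)
    img = _blank(size)
    vs = [tuple(map(int, v)) for v in vertices]
    pairs = list(zip(vs[:-1], vs[1:])) + ([(vs[-1], vs[0])] if closed else [])
    for a, b in pairs:
        _rasterize(img, a, b)
    corners = []
    if closed:
        n = len(vs)
        for i, v in enumerate(vs):
            corners.append((v[0], v[1], _interior_angle(vs[i - 1], v, vs[(i + 1) % n])))
    else:
        for i in range(1, len(vs) - 1):
            corners.append((vs[i][0], vs[i][1], _interior_angle(vs[i - 1], vs[i], vs[i + 1])))
    corners += _segment_crossings(vs, closed)
    endpoints = [] if closed else [vs[0], vs[-1]]
    return Scene(img, None, corners, endpoints, description="polyline",
                 polygon_vertices=vs, closed=closed)


def make_polygon(vertices, size=(64, 64)) -> Scene:
    scene = make_polyline(vertices, size, closed=True)
    scene.description = "polygon"
    return scene


def make_rectangle(size=(64, 64), inset: int | None = None) -> Scene:
    """Axis-aligned rectangle centered in the image; four 90-degree corners."""
    w, h = size
    inset = inset if inset is not None else max(2, min(w, h) // 4)
    x0, y0, x1, y1 = inset, inset, w - 1 - inset, h - 1 - inset
    scene = make_polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)], size)
    scene.description = "rectangle"
    return scene


def make_L(arm_length: int, angle_deg: float, size=(64, 64),
           vertex=None, orientation_deg: float = 0.0) -> Scene:
    """Two arms meeting at one vertex: one corner and two endpoints.

    ``angle_deg`` is the interior angle between the arms, in (0, 180);
    ``orientation_deg`` rotates the whole figure.
    """
    if not (0.0 < angle_deg < 180.0):
        raise ValueError("angle must be in (0, 180) degrees")
    w, h = size
    vx, vy = vertex if vertex is not None else ((w - 1) // 2, (h - 1) // 2)
    a0 = math.radians(orientation_deg)
    a1 = a0 + math.radians(angle_deg)
    ends = []
    for a in (a0, a1):
        ex = int(round(vx + arm_length * math.cos(a)))
        ey = int(round(vy + arm_length * math.sin(a)))
        ends.append((ex, ey))
    scene = make_polyline([ends[0], (vx, vy), ends[1]], size)
    scene.description = f"L angle={angle_deg}"
    return scene


def degrade(scene: Scene, gap_fraction: float = 0.0, spurious_count: int = 0,
            seed: int = 0) -> Scene:
    """Remove a seeded random fraction of edge pixels and add spurious ones.

    Ground truth is left unchanged; the same seed always yields the same
    degraded scene.
    """
    if not (0.0 <= gap_fraction <= 1.0):
        raise ValueError("gap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    img = scene.edge_image.copy()
    ys, xs = np.nonzero(img)
    n_remove = int(round(gap_fraction * xs.size))
    if n_remove:
        sel = rng.choice(xs.size, size=n_remove, replace=False)
        img[ys[sel], xs[sel]] = 0
    h, w = img.shape
    for _ in range(int(spurious_count)):
        img[rng.integers(0, h), rng.integers(0, w)] = 1
    return replace(scene, edge_image=img, seed=seed,
                   description=scene.description + " (degraded)")


def render_intensity(scene: Scene, foreground: int = 200, background: int = 40,
                     blur: float = 0.0) -> np.ndarray:
    """Grayscale rendering: filled shape (closed) or drawn strokes (open).

    The edge map stays the ground-truth source; this image only feeds the
    intensity-based localization stage.
    """
    if not (0 <= foreground <= 255 and 0 <= background <= 255):
        raise ValueError("levels must be in [0, 255]")
    h, w = scene.edge_image.shape
    img = np.full((h, w), float(background))
    if scene.closed and scene.polygon_vertices:
        xs = [v[0] for v in scene.polygon_vertices]
        ys = [v[1] for v in scene.polygon_vertices]
        rr, cc = _fill_polygon(ys, xs, shape=(h, w))
        img[rr, cc] = float(foreground)
    else:
        img[scene.edge_image > 0] = float(foreground)
    if blur > 0:
        img = ndimage.gaussian_filter(img, blur)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)
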