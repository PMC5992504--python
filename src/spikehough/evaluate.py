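"""Ground-truth matching and detection metrics.

A detection matches a ground-truth point when their Euclidean distance,
rounded to the nearest integer, is at most ``max_dist`` pixels (rounding
approximates the acceptance area by a circular patch).  Matching is
one-to-one: pairs are assigned greedily by ascending distance with
deterministic raster-order tie-breaking, each point used at most once.
The two summary ratios are the hit rate (matched / ground truth) and the
precision ratio (matched / detected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import Detection

__all__ = [
    "MatchResult",
    "match_points",
    "detections_to_frame",
    "frame_to_points",
    "write_detections_csv",
    "read_points_csv",
    "write_ground_truth_csv",
    "harris_corners",
]


@dataclass
class MatchResult:
    n_ground_truth: int
    n_detections: int
    n_correct: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def hit_rate(self) -> float | None:
        """Matched fraction of ground truth; None when there is no ground truth."""
        if self.n_ground_truth == 0:
            return None
        return self.n_correct / self.n_ground_truth

    @property
    def precision_ratio(self) -> float | None:
        if self.n_detections == 0:
            return None
        return self.n_correct / self.n_detections

    def as_dict(self) -> dict:
        return {
            "n_ground_truth": self.n_ground_truth,
            "n_detections": self.n_detections,
            "n_correct": self.n_correct,
            "hit_rate": self.hit_rate,
            "precision_ratio": self.precision_ratio,
        }


def _as_points(obj) -> np.ndarray:
    if len(obj) and isinstance(obj[0], Detection):
        return np.asarray([(d.x, d.y) for d in obj], float)
    return np.asarray(obj, float).reshape(-1, 2)


def match_points(detections, ground_truth, max_dist: float = 3.0) -> MatchResult:
    """One-to-one matching under the rounded-distance criterion.

    Returns the counts and the matched ``(detection_index,
    ground_truth_index, distance)`` pairs.
    """
    det = _as_points(detections)
    gt = _as_points(ground_truth)
    if det.size == 0 or gt.size == 0:
        return MatchResult(len(gt), len(det), 0)
    diff = det[:, None, :] - gt[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    rounded = np.floor(dist + 0.5)
    di, gi = np.nonzero(rounded <= max_dist)
    order = np.lexsort((gi, di, dist[di, gi]))
    used_d = np.zeros(len(det), bool)
    used_g = np.zeros(len(gt), bool)
    pairs = []
    for idx in order:
        i, j = int(di[idx]), int(gi[idx])
        if used_d[i] or used_g[j]:
            continue
        used_d[i] = used_g[j] = True
        pairs.append((i, j, float(dist[i, j])))
    return MatchResult(len(gt), len(det), len(pairs), pairs)


# ---- CSV schemas --------------------------------------------------------

def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x": d.x, "y": d.y, "kind": d.kind, "flipped": int(d.flipped),
                "theta_idx": d.theta_idx, "d_idx": d.d_idx, "row_idx": d.row_idx,
                "score": d.score,
            }
            for d in detections
        ],
        columns=["x", "y", "kind", "flipped", "theta_idx", "d_idx", "row_idx", "score"],
    )


def write_detections_csv(detections: list[Detection], path) -> None:
    detections_to_frame(detections).to_csv(path, index=False)


def frame_to_points(frame: pd.DataFrame) -> np.ndarray:
    return frame[["x", "y"]].to_numpy(float)


def read_points_csv(path) -> np.ndarray:
    """Read any CSV with x,y columns (detections or ground truth)."""
    return frame_to_points(pd.read_csv(path))


def write_ground_truth_csv(scene, path) -> None:
    rows = [{"x": x, "y": y, "kind": "corner", "angle": a} for x, y, a in scene.corners]
    rows += [{"x": x, "y": y, "kind": "endpoint", "angle": ""} for x, y in scene.endpoints]
    pd.DataFrame(rows, columns=["x", "y", "kind", "angle"]).to_csv(path, index=False)


def harris_corners(intensity_image: np.ndarray, window: int = 5, k: float = 0.04,
                   max_points: int = 500) -> np.ndarray:
    """Harris corner baseline (scikit-image backed); ``(x, y)`` array."""
    try:
        from skimage.feature import corner_harris, corner_peaks
    except ImportError:  # pragma: no cover - skimage is a hard dependency
        return np.zeros((0, 2))
    resp = corner_harris(np.asarray(intensity_image, float), k=k,
                         sigma=max(window / 5.0, 1.0))
    peaks = corner_peaks(resp, min_distance=window // 2, num_peaks=max_points)
    return peaks[:, ::-1].astype(float)
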