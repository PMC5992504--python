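"""Coordinate conventions and discretization of the 3D Hough space.

A line through the image is parameterized by its orientation ``theta`` in
``[0, pi)`` and its signed distance ``d`` from the image center.  The third
axis ``p`` is the signed position of a point *along* the line, so a cell
``(theta, d, p)`` stands for the segment of line ``(theta, d)`` that runs
from the lowest position ``-R`` up to ``p``, with ``R`` half the image
diagonal.  Both the array-based reference transform and the spiking network
share these conventions, so the two implementations are comparable cell by
cell.

All functions are vectorized over numpy arrays and pure; ``HoughSpec``
carries the image geometry and quantization steps plus every derived size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HoughSpec",
    "image_to_centered",
    "centered_to_image",
    "line_params",
    "hough_to_image_center",
    "discretize",
    "undiscretize",
    "max_angular_step",
    "num_orientation_steps",
]


def _round_half_away(x):
    """Round halves away from zero (platform-independent, unlike banker's)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def num_orientation_steps(delta_theta: float) -> int:
    """Number of orientation layers needed to cover ``[0, pi)``."""
    if delta_theta <= 0:
        raise ValueError("delta_theta must be positive")
    return int(math.ceil(math.pi / delta_theta))


def max_angular_step(eta: int, delta_p: int) -> float:
    """Coarsest usable angular quantization, ``arctan(1/(eta*delta_p))``.

    A pattern spans ``eta*delta_p`` one-pixel rows along a column; an
    orientation error larger than this angle shifts the far end of the
    span by more than one pixel sideways, off its column.
    """
    if eta * delta_p <= 0:
        raise ValueError("eta * delta_p must be positive")
    return math.atan(1.0 / (eta * delta_p))


@dataclass(frozen=True)
class HoughSpec:
    """Image geometry plus quantization of the (theta, d, p) space.

    Parameters
    ----------
    width, height:
        Image size in pixels.
    delta_d:
        Quantization step of the line distance ``d`` (pixels, >= 1).
    delta_p:
        Stride, in one-pixel rows, between positions at which patterns are
        evaluated (>= 1).  Columns still keep one neuron/cell per pixel row;
        ``delta_p`` only selects which rows feed the pattern stage.
    delta_theta:
        Angular step between orientation layers (radians).
    eta:
        Number of ``delta_p`` cells in a full piece of segment (>= 2).
    """

    width: int
    height: int
    delta_d: float = 2.0
    delta_p: int = 2
    delta_theta: float = 0.04
    eta: int = 6

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        if self.delta_d < 1 or self.delta_p < 1 or self.delta_theta <= 0:
            raise ValueError("quantization steps must be >= 1 (delta_theta > 0)")
        if self.eta < 2:
            raise ValueError("eta must be >= 2")

    # ---- derived sizes -------------------------------------------------
    @property
    def R(self) -> float:
        """Half of the image diagonal; d, p range over [-R, +R]."""
        return 0.5 * math.hypot(self.width, self.height)

    @property
    def n_theta(self) -> int:
        return num_orientation_steps(self.delta_theta)

    @property
    def n_d(self) -> int:
        return int(math.floor(2.0 * self.R / self.delta_d)) + 1

    @property
    def n_rows(self) -> int:
        """One-pixel p-rows per column, rounded up to a multiple of delta_p."""
        raw = int(math.floor(2.0 * self.R)) + 1
        return -(-raw // self.delta_p) * self.delta_p

    @property
    def n_p(self) -> int:
        """Number of delta_p-strided pattern positions per column."""
        return self.n_rows // self.delta_p

    @property
    def theta_values(self) -> np.ndarray:
        """Orientation represented by each layer: ``k * delta_theta``."""
        return np.arange(self.n_theta) * self.delta_theta

    @property
    def anchor_rows(self) -> np.ndarray:
        """Top 1-px row of each strided cell: ``(k+1)*delta_p - 1``."""
        return np.arange(self.n_p) * self.delta_p + (self.delta_p - 1)

    @property
    def full_piece_rows(self) -> int:
        """Length of a full pattern piece in 1-px rows (eta * delta_p)."""
        return self.eta * self.delta_p


# ---- coordinate transforms ---------------------------------------------

def image_to_centered(px, py, spec: HoughSpec):
    """Map pixel indices to coordinates centered on the image midpoint.

    ``y`` grows downward (image-native).  The ``(width-1)/2`` offset makes
    integer grids symmetric about zero for odd-sized images.
    """
    px = np.asarray(px)
    py = np.asarray(py)
    if np.any(px < 0) or np.any(px >= spec.width) or np.any(py < 0) or np.any(py >= spec.height):
        raise ValueError("pixel position outside image bounds")
    return px - (spec.width - 1) / 2.0, py - (spec.height - 1) / 2.0


def centered_to_image(x, y, spec: HoughSpec):
    """Inverse of :func:`image_to_centered` (no bounds check)."""
    return np.asarray(x) + (spec.width - 1) / 2.0, np.asarray(y) + (spec.height - 1) / 2.0


def line_params(x, y, theta):
    """Distance and along-line position of point ``(x, y)`` for angle ``theta``.

    ``d = x cos(t) + y sin(t)``; ``p = -x sin(t) + y cos(t)``.
    """
    ct, st = np.cos(theta), np.sin(theta)
    x = np.asarray(x)
    y = np.asarray(y)
    return x * ct + y * st, -x * st + y * ct


def hough_to_image_center(theta, d, p):
    """Centered image point represented by the Hough coordinates.

    Exact inverse of :func:`line_params` (a rotation).
    """
    ct, st = np.cos(theta), np.sin(theta)
    d = np.asarray(d)
    p = np.asarray(p)
    return d * ct - p * st, d * st + p * ct


# ---- quantization -------------------------------------------------------

def discretize(theta, d, p, spec: HoughSpec):
    """Map continuous ``(theta, d, p)`` to ``(theta_idx, d_idx, row_idx)``.

    theta bins are left-closed ``[k*dt, (k+1)*dt)``; ``d`` is rounded to the
    nearest ``delta_d`` bin and ``p`` to the nearest one-pixel row.  Indices
    are clipped to the valid ranges (|d| can reach R exactly on the image
    diagonal, which would otherwise round one past the last bin).
    """
    theta_idx = np.clip(
        np.floor(np.asarray(theta) / spec.delta_theta).astype(np.int64), 0, spec.n_theta - 1
    )
    d_idx = np.clip(
        _round_half_away((np.asarray(d) + spec.R) / spec.delta_d).astype(np.int64),
        0,
        spec.n_d - 1,
    )
    row_idx = np.clip(
        _round_half_away(np.asarray(p) + spec.R).astype(np.int64), 0, spec.n_rows - 1
    )
    return theta_idx, d_idx, row_idx


def undiscretize(theta_idx, d_idx, row_idx, spec: HoughSpec):
    """Bin-center continuous values for discrete indices.

    theta uses the bin center ``(k + 0.5) * delta_theta`` so the
    quantization error of a discretize/undiscretize round trip is bounded by
    half a step on every axis.  (Orientation *layers* themselves represent
    the left edge ``k * delta_theta``; see ``HoughSpec.theta_values``.)
    """
    theta = (np.asarray(theta_idx) + 0.5) * spec.delta_theta
    d = np.asarray(d_idx) * spec.delta_d - spec.R
    p = np.asarray(row_idx) - spec.R
    return theta, d, p
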