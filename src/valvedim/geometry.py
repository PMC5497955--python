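"""Scalar measurements from digitized structures.

Turns ordered 2-D point sets into the quantities the analysis consumes:
outline areas (shoelace, via shapely), ellipse-based valve length and
height, linear landmark distances, and curve (polyline) versus chord
lengths for podomere curvature.

Valve length ``L`` and height ``H`` are the *full* major and minor axes
of the fitted ellipse (2a, 2b).  Whole-valve lengths in *Cyprideis* run
roughly 900-1200 um, which only the full-axis convention reproduces;
the shape ratio L/H is identical under either convention.  All logs are
natural logs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from skimage.measure import EllipseModel

__all__ = [
    "EllipseFit",
    "ValveMeasurement",
    "polygon_area",
    "fit_ellipse",
    "valve_measurement",
    "polyline_length",
    "chord_length",
    "landmark_distance",
]


@dataclass(frozen=True)
class EllipseFit:
    """Ellipse fitted to a point set.

    ``axis_major``/``axis_minor`` are full axis lengths (2a, 2b) in um;
    ``theta`` is the major-axis orientation in [0, pi).  ``from_moments``
    marks the second-central-moment fallback used when the direct conic
    fit is degenerate or non-elliptical.
    """

    center: tuple[float, float]
    axis_major: float
    axis_minor: float
    theta: float
    from_moments: bool = False

    def __post_init__(self) -> None:
        if not (self.axis_major >= self.axis_minor > 0):
            raise ValueError(
                f"require axis_major >= axis_minor > 0, got "
                f"({self.axis_major}, {self.axis_minor})"
            )
        if not (0.0 <= self.theta < math.pi):
            raise ValueError(f"theta must lie in [0, pi), got {self.theta}")


@dataclass(frozen=True)
class ValveMeasurement:
    """Size and shape of one valve outline.

    ``area`` in um^2, ``length``/``height`` in um; ``log_size`` is
    log(area) and ``log_shape`` is log(length/height) >= 0 (males,
    being more elongate, have larger values).
    """

    specimen_id: str
    side: str
    area: float
    length: float
    height: float

    @property
    def log_size(self) -> float:
        return math.log(self.area)

    @property
    def log_shape(self) -> float:
        return math.log(self.length / self.height)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) point array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    return pts


def polygon_area(outline) -> float:
    """Absolute shoelace area of a closed outline, in um^2.

    The outline closes implicitly onto its first vertex.  Vertex order
    (clockwise vs counter-clockwise) does not matter.  Self-intersecting
    outlines produce a warning; collinear (zero-area) input is an error.
    """
    pts = _as_points(getattr(outline, "points", outline))
    if len(pts) < 3:
        raise ValueError(f"outline needs >= 3 points, got {len(pts)}")
    poly = Polygon(pts)
    if not poly.is_valid:
        warnings.warn("outline is self-intersecting; area uses |shoelace| sum",
                      stacklevel=2)
        # shapely's .area on an invalid ring is the signed-sum magnitude,
        # which is exactly the |shoelace| value we document.
    area = poly.area
    if area <= 0.0:
        raise ValueError("outline has zero area (collinear points)")
    return float(area)


def _moment_ellipse(pts: np.ndarray) -> EllipseFit:
    """Ellipse with the same second central moments as the point cloud.

    For points sampled on an ellipse boundary the moment eigenvalues are
    a^2/2 and b^2/2, hence semi-axes sqrt(2*lambda).
    """
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 0:
        raise ValueError("degenerate point set: zero variance direction")
    a, b = np.sqrt(2.0 * evals)
    theta = math.atan2(evecs[1, 0], evecs[0, 0]) % math.pi
    return EllipseFit(tuple(center), 2.0 * a, 2.0 * b, theta, from_moments=True)


def fit_ellipse(points) -> EllipseFit:
    """Direct least-squares ellipse fit (conic with ellipse constraint).

    Uses the numerically stable Halir-Flusser formulation; deterministic
    for fixed input.  If the conic solution is degenerate or
    non-elliptical, falls back to the second-central-moment ellipse and
    flags it via ``from_moments``.
    """
    pts = _as_points(getattr(points, "points", points))
    if len(pts) < 6:
        raise ValueError(f"ellipse fit needs >= 6 points, got {len(pts)}")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("points are collinear; cannot fit an ellipse")

    try:
        model = EllipseModel.from_estimate(pts)
        params = (np.array([*model.center, *model.axis_lengths, model.theta])
                  if model else None)
    except Exception:
        params = None
    if params is None or not np.all(np.isfinite(params)):
        return _moment_ellipse(pts)
    xc, yc, a, b, theta = params
    if a <= 0 or b <= 0:
        return _moment_ellipse(pts)
    if b > a:
        a, b = b, a
        theta += math.pi / 2.0
    return EllipseFit((float(xc), float(yc)), 2.0 * float(a), 2.0 * float(b),
                      float(theta % math.pi))


def valve_measurement(outline, specimen_id: str = "", side: str = "unknown") -> ValveMeasurement:
    """Measure one valve outline: shoelace area, ellipse L and H."""
    pts = _as_points(getattr(outline, "points", outline))
    specimen_id = specimen_id or getattr(outline, "specimen_id", "")
    side = getattr(outline, "side", side) if hasattr(outline, "side") else side
    area = polygon_area(pts)
    fit = fit_ellipse(pts)
    return ValveMeasurement(specimen_id=specimen_id, side=side, area=area,
                            length=fit.axis_major, height=fit.axis_minor)


def polyline_length(points) -> float:
    """Sum of Euclidean segment lengths along an ordered point path."""
    pts = _as_points(getattr(points, "points", points))
    if len(pts) < 2:
        raise ValueError(f"polyline needs >= 2 points, got {len(pts)}")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def chord_length(points) -> float:
    """Straight-line distance from the first point to the last.

    This is the length the podomere would have if it were not curved;
    always <= :func:`polyline_length`.
    """
    pts = _as_points(getattr(points, "points", points))
    if len(pts) < 2:
        raise ValueError(f"chord needs >= 2 points, got {len(pts)}")
    return float(np.linalg.norm(pts[-1] - pts[0]))


def landmark_distance(landmark_set, i: int, j: int) -> float:
    """Euclidean distance between landmarks ``i`` and ``j`` (0-based)."""
    pts = _as_points(getattr(landmark_set, "points", landmark_set))
    n = len(pts)
    for idx in (i, j):
        if not (-n <= idx < n):
            raise IndexError(f"landmark index {idx} out of range for {n} points")
    return float(np.linalg.norm(pts[j] - pts[i]))
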