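"""Fan geometry: virtual origin, pixel scale, polar conversion, cross-subject alignment.

Coordinate conventions
----------------------
All pixel coordinates are *image* coordinates: x increases rightward,
y increases **downward**.  The polar angle ``theta`` of a point relative
to the virtual origin is ``atan2(dy, dx)`` with ``dy`` measured downward,
so tissue imaged *above* the origin has negative theta.  Under this
convention the tongue surface lives in roughly ``(-2.8, -0.5)`` radians,
with more negative theta more posterior (tongue back at the left when
plotted with the anterior direction at the right).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FanGeometry",
    "VirtualOrigin",
    "AlignmentTransform",
    "ParallelEdgesError",
    "load_fan_geometry",
    "estimate_virtual_origin",
    "estimate_px_scale",
    "to_polar",
    "to_cartesian",
    "compute_alignment",
    "apply_alignment",
]

_PARALLEL_TOL = 1e-9


def _cross2(a, b) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


class ParallelEdgesError(ValueError):
    """Raised when the two fan-edge segments are (numerically) parallel."""


@dataclass(frozen=True)
class VirtualOrigin:
    """Apex of the ultrasound fan in image pixel coordinates (y down)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("virtual origin coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class AlignmentTransform:
    """Rigid polar-space normalization onto a reference subject.

    ``dtheta`` is added to every angle and ``scale`` multiplies every
    radius, mapping a subject's contours into the reference space.
    """

    dtheta: float
    scale: float
    reference_id: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.dtheta) or not np.isfinite(self.scale):
            raise ValueError("transform parameters must be finite")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if not (-np.pi < self.dtheta <= np.pi):
            raise ValueError(f"dtheta must lie in (-pi, pi], got {self.dtheta}")

    def inverse(self) -> "AlignmentTransform":
        return AlignmentTransform(-self.dtheta, 1.0 / self.scale, self.reference_id)


def _as_segment(seg: Sequence[Sequence[float]]) -> np.ndarray:
    arr = np.asarray(seg, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"segment must be two 2-D points, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("segment endpoints must be finite")
    if np.allclose(arr[0], arr[1]):
        raise ValueError("degenerate segment: endpoints coincide")
    return arr


@dataclass(frozen=True)
class FanGeometry:
    """Per-subject annotation of the ultrasound fan on a sample frame.

    Parameters
    ----------
    subject_id:
        Subject identifier.
    edge_left, edge_right:
        Two points each (pixel coordinates) on the left/right slanted
        edges delimiting the fan-shaped scan area.
    depth_ticks:
        Optional ``(y_pixel, depth_cm)`` pairs read off the on-screen
        depth scale; used for the pixel-to-cm conversion.
    scan_depth_cm:
        Machine scan-depth setting, metadata only.
    """

    subject_id: str
    edge_left: tuple = field(default=None)  # type: ignore[assignment]
    edge_right: tuple = field(default=None)  # type: ignore[assignment]
    depth_ticks: tuple = ()
    scan_depth_cm: float | None = None

    def __post_init__(self) -> None:
        left = _as_segment(self.edge_left)
        right = _as_segment(self.edge_right)
        d1 = left[1] - left[0]
        d2 = right[1] - right[0]
        if abs(_cross2(d1, d2)) < _PARALLEL_TOL:
            raise ParallelEdgesError(
                f"fan edges of subject {self.subject_id!r} are parallel"
            )
        ticks = tuple((float(y), float(d)) for y, d in self.depth_ticks)
        if ticks:
            if len(ticks) < 2:
                raise ValueError("depth_ticks needs >= 2 entries when present")
            ys = np.array([t[0] for t in ticks])
            ds = np.array([t[1] for t in ticks])
            if not (np.all(np.diff(ys) > 0) and np.all(np.diff(ds) > 0)):
                raise ValueError("depth_ticks must be strictly increasing in y and depth")
        object.__setattr__(self, "edge_left", tuple(map(tuple, left)))
        object.__setattr__(self, "edge_right", tuple(map(tuple, right)))
        object.__setattr__(self, "depth_ticks", ticks)

    def virtual_origin(self) -> VirtualOrigin:
        return estimate_virtual_origin(self.edge_left, self.edge_right)

    def px_per_cm(self) -> float:
        return estimate_px_scale(self.depth_ticks)


def load_fan_geometry(path) -> FanGeometry:
    """Read a per-subject fan annotation from YAML.

    Schema::

        subject_id: S24
        edge_left:  [[200, 100], [260, 280]]   # two [x, y] pixel points
        edge_right: [[440, 100], [380, 280]]
        depth_ticks: [[100, 1.0], [200, 2.0]]  # [y_pixel, depth_cm]; optional
        scan_depth_cm: 8.0                     # optional
    """
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return FanGeometry(
        subject_id=str(raw["subject_id"]),
        edge_left=raw["edge_left"],
        edge_right=raw["edge_right"],
        depth_ticks=tuple(map(tuple, raw.get("depth_ticks") or ())),
        scan_depth_cm=raw.get("scan_depth_cm"),
    )


def estimate_virtual_origin(edge_left, edge_right) -> VirtualOrigin:
    """Intersect the infinite lines through the two fan-edge segments.

    The intersection (the fan apex) typically lies below the imaged
    tissue and need not lie on either annotated segment.

    Raises
    ------
    ParallelEdgesError
        If the segment directions are parallel within 1e-9.
    """
    p1 = _as_segment(edge_left)
    p2 = _as_segment(edge_right)
    d1 = p1[1] - p1[0]
    d2 = p2[1] - p2[0]
    denom = _cross2(d1, d2)
    if abs(denom) < _PARALLEL_TOL:
        raise ParallelEdgesError("fan edge lines are parallel; no virtual origin")
    # p1[0] + t*d1 = p2[0] + s*d2  ->  solve the 2x2 system for t
    t = _cross2(p2[0] - p1[0], d2) / denom
    pt = p1[0] + t * d1
    return VirtualOrigin(float(pt[0]), float(pt[1]))


def estimate_px_scale(depth_ticks) -> float:
    """Least-squares slope of y-pixel against depth-cm (px per cm)."""
    ticks = np.asarray(list(depth_ticks), dtype=float)
    if ticks.ndim != 2 or ticks.shape[0] < 2 or ticks.shape[1] != 2:
        raise ValueError("need at least 2 (y_pixel, depth_cm) ticks")
    y, d = ticks[:, 0], ticks[:, 1]
    dc = d - d.mean()
    denom = float(dc @ dc)
    if denom == 0:
        raise ValueError("depth ticks have zero depth spread")
    slope = float(dc @ (y - y.mean())) / denom
    if slope <= 0:
        raise ValueError(f"pixel scale must be positive, got {slope}")
    return slope


def to_polar(points, origin: VirtualOrigin) -> np.ndarray:
    """Convert ``(x, y)`` pixel points to ``(theta, rho)`` about the origin.

    ``theta = atan2(y - origin.y, x - origin.x)`` in image coordinates
    (y down), hence negative above the origin; ``rho`` is the Euclidean
    pixel distance.  A point coinciding with the origin is an error.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = pts - origin.as_array()
    rho = np.hypot(d[:, 0], d[:, 1])
    if np.any(rho == 0):
        raise ValueError("point coincides with the virtual origin")
    theta = np.arctan2(d[:, 1], d[:, 0])
    return np.column_stack([theta, rho])


def to_cartesian(polar_points, origin: VirtualOrigin) -> np.ndarray:
    """Inverse of :func:`to_polar` (image coordinates, y down)."""
    pts = np.atleast_2d(np.asarray(polar_points, dtype=float))
    theta, rho = pts[:, 0], pts[:, 1]
    x = origin.x + rho * np.cos(theta)
    y = origin.y + rho * np.sin(theta)
    return np.column_stack([x, y])


def _anchor(polar_contour: np.ndarray) -> tuple[float, float]:
    """Maximum-rho point; ties broken toward the largest theta (anterior)."""
    pts = np.atleast_2d(np.asarray(polar_contour, dtype=float))
    if pts.size == 0:
        raise ValueError("empty contour")
    rho = pts[:, 1]
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite contour point")
    rmax = rho.max()
    cand = np.nonzero(rho == rmax)[0]
    idx = cand[np.argmax(pts[cand, 0])]
    return float(pts[idx, 0]), float(pts[idx, 1])


def compute_alignment(
    subject_ref_contour,
    target_ref_contour,
    reference_id: str = "",
) -> AlignmentTransform:
    """Rotation/scaling mapping a subject's reference contour onto the target's.

    Both inputs are mean contours of the designated alignment category
    (normally the high front vowel; callers may substitute another
    category for individual subjects).  The anchor is the point furthest
    from the virtual origin; the transform rotates the subject anchor
    onto the target anchor's angle and scales its radius to match.
    """
    th_s, rho_s = _anchor(subject_ref_contour)
    th_t, rho_t = _anchor(target_ref_contour)
    dtheta = th_t - th_s
    # canonicalize to (-pi, pi]
    dtheta = float(np.arctan2(np.sin(dtheta), np.cos(dtheta)))
    if dtheta == -np.pi:
        dtheta = np.pi
    if rho_s <= 0:
        raise ValueError("subject anchor radius must be positive")
    return AlignmentTransform(dtheta, rho_t / rho_s, reference_id)


def apply_alignment(polar_contour, transform: AlignmentTransform) -> np.ndarray:
    """Apply ``theta' = theta + dtheta``, ``rho' = rho * scale``.

    Shape-preserving: pairwise theta differences and rho ratios within
    the contour are unchanged.
    """
    pts = np.atleast_2d(np.asarray(polar_contour, dtype=float)).copy()
    pts[:, 0] += transform.dtheta
    pts[:, 1] *= transform.scale
    return pts
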