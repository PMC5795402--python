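"""Breast point-cloud geometry: quadrant planes, quadrant assignment and the
excision cylinder.

The package works in a single right-handed patient frame shared with the
synthetic generator:

* ``x`` — medial→lateral axis of a right breast (mirrored for left breasts),
* ``y`` — posterior→anterior (the chest wall lies near ``y = 0`` and the
  breast protrudes towards ``+y``),
* ``z`` — inferior→superior.

All coordinates are in millimetres.  The pectoral (chest-wall) plane is
estimated from three annotated corner points of the pectoral muscle; the
superior–inferior boundary is the plane parallel to the ``xy``-plane through
the nipple; the lateral–medial boundary is perpendicular to the pectoral
plane, passes through the nipple and contains the superior–inferior normal
direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

logger = logging.getLogger(__name__)

Laterality = Literal["R", "L"]
QuadrantName = Literal["UOQ", "UIQ", "LOQ", "LIQ"]

#: Quadrant labels in canonical (one-hot) order.
QUADRANTS: tuple[str, ...] = ("UOQ", "UIQ", "LOQ", "LIQ")

#: Upper bound on the excised fraction of breast volume for BCS eligibility.
MAX_EXCISION_FRACTION = 0.20


class DegenerateGeometryError(ValueError):
    """Raised when input geometry cannot define the required planes/cylinder."""


@dataclass
class BreastPCL:
    """Ordered breast point cloud (surface points first, then interior).

    Parameters
    ----------
    points
        ``(n, 3)`` float array, mm.  The first ``n_surface`` rows are skin
        surface points, the remaining ``n_interior`` rows interior points.
        Row order is the per-point correspondence used throughout.
    laterality
        ``"R"`` or ``"L"``.
    nipple
        Nipple position, mm.
    pectoral_corners
        ``(3, 3)`` array: two superior corner points of the pectoral muscle
        followed by one inferior corner point.
    breast_volume
        Total breast volume in mm^3.
    """

    points: np.ndarray
    n_surface: int
    n_interior: int
    laterality: str
    nipple: np.ndarray
    pectoral_corners: np.ndarray
    breast_volume: float
    patient_id: str = "P0"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.nipple = np.asarray(self.nipple, dtype=float)
        self.pectoral_corners = np.asarray(self.pectoral_corners, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if self.n_surface + self.n_interior != len(self.points):
            raise ValueError("n_surface + n_interior must equal len(points)")
        if self.laterality not in ("R", "L"):
            raise ValueError(f"laterality must be 'R' or 'L', got {self.laterality!r}")
        if self.breast_volume <= 0:
            raise ValueError("breast_volume must be positive")
        c = self.pectoral_corners
        if np.linalg.norm(np.cross(c[1] - c[0], c[2] - c[0])) < 1e-9:
            raise DegenerateGeometryError("pectoral corner points are collinear")

    @property
    def surface_points(self) -> np.ndarray:
        return self.points[: self.n_surface]

    @property
    def interior_points(self) -> np.ndarray:
        return self.points[self.n_surface :]

    def with_points(self, points: np.ndarray) -> "BreastPCL":
        """Copy of this cloud with replaced coordinates (same correspondence)."""
        return BreastPCL(
            points=np.asarray(points, dtype=float),
            n_surface=self.n_surface,
            n_interior=self.n_interior,
            laterality=self.laterality,
            nipple=self.nipple.copy(),
            pectoral_corners=self.pectoral_corners.copy(),
            breast_volume=self.breast_volume,
            patient_id=self.patient_id,
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class Plane:
    """Plane in Hessian normal form: ``dot(normal, p) = offset``."""

    normal: np.ndarray
    offset: float

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points @ self.normal - self.offset


@dataclass(frozen=True)
class QuadrantPlanes:
    pectoral_plane: Plane
    superior_inferior_plane: Plane
    lateral_medial_plane: Plane


@dataclass
class ExcisionCylinder:
    """Cylindrical excision volume, axis perpendicular to the chest wall.

    ``base_point`` sits on the pectoral plane; the cylinder extends ``height``
    mm along the unit ``axis`` (towards the skin) with the given ``radius``,
    so that pi * radius^2 * height = volume_fraction * breast volume.
    """

    base_point: np.ndarray
    axis: np.ndarray
    height: float
    radius: float
    volume_fraction: float
    tumor_center: np.ndarray

    def __post_init__(self) -> None:
        self.base_point = np.asarray(self.base_point, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.tumor_center = np.asarray(self.tumor_center, dtype=float)
        if not np.isclose(np.linalg.norm(self.axis), 1.0):
            raise ValueError("axis must be a unit vector")

    @property
    def volume(self) -> float:
        return float(np.pi * self.radius**2 * self.height)

    def cylindrical_coords(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Axial coordinate along the axis and radial distance to the axis."""
        rel = np.atleast_2d(points) - self.base_point
        axial = rel @ self.axis
        radial = np.linalg.norm(rel - np.outer(axial, self.axis), axis=1)
        return axial, radial

    def distance_to_solid(self, points: np.ndarray) -> np.ndarray:
        """Euclidean distance to the solid cylinder (zero for inside points)."""
        axial, radial = self.cylindrical_coords(points)
        axial_excess = np.maximum(np.maximum(-axial, axial - self.height), 0.0)
        radial_excess = np.maximum(radial - self.radius, 0.0)
        return np.hypot(axial_excess, radial_excess)

    def nearest_axis_point(self, points: np.ndarray) -> np.ndarray:
        """Closest point of the axis *segment* for every input point."""
        axial, _ = self.cylindrical_coords(points)
        t = np.clip(axial, 0.0, self.height)
        return self.base_point + np.outer(t, self.axis)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError("zero-length vector cannot be normalised")
    return v / n


def build_quadrant_planes(pcl: BreastPCL) -> QuadrantPlanes:
    """Construct the three quadrant-defining planes from a breast cloud.

    The pectoral plane normal is the (normalised) cross product of the two
    vectors spanned by the three pectoral corner points, oriented towards the
    nipple.  The superior–inferior plane is parallel to the ``xy``-plane and
    crosses the nipple; the lateral–medial plane is perpendicular to the
    pectoral plane, crosses the nipple and contains the superior–inferior
    normal direction.
    """
    c = pcl.pectoral_corners
    raw = np.cross(c[1] - c[0], c[2] - c[0])
    if np.linalg.norm(raw) < 1e-9:
        raise DegenerateGeometryError("pectoral corner points are collinear")
    normal = _unit(raw)
    # orient towards the breast (nipple side of the chest wall)
    if float(normal @ (pcl.nipple - c[0])) < 0:
        normal = -normal
    pectoral = Plane(normal, float(normal @ c[0]))

    si_normal = np.array([0.0, 0.0, 1.0])
    superior_inferior = Plane(si_normal, float(si_normal @ pcl.nipple))

    lm_raw = np.cross(pectoral.normal, si_normal)
    if np.linalg.norm(lm_raw) < 1e-9:
        raise DegenerateGeometryError(
            "pectoral normal is parallel to the superior-inferior normal"
        )
    lm_normal = _unit(lm_raw)
    lateral_medial = Plane(lm_normal, float(lm_normal @ pcl.nipple))
    return QuadrantPlanes(pectoral, superior_inferior, lateral_medial)


def assign_quadrant(
    points: np.ndarray, planes: QuadrantPlanes, laterality: str
) -> np.ndarray:
    """Assign each point to UOQ / UIQ / LOQ / LIQ.

    The superior–inferior plane separates upper from lower; the
    lateral–medial plane separates outer (lateral) from inner (medial), with
    the lateral sense mirrored for left breasts.  Points exactly on a plane
    go to the superior / lateral side.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    upper = planes.superior_inferior_plane.signed_distance(pts) >= 0
    lm = planes.lateral_medial_plane.signed_distance(pts)
    if laterality == "L":
        lm = -lm
    elif laterality != "R":
        raise ValueError(f"unknown laterality {laterality!r}")
    outer = lm >= 0
    labels = np.where(
        upper,
        np.where(outer, "UOQ", "UIQ"),
        np.where(outer, "LOQ", "LIQ"),
    )
    return labels if np.asarray(points).ndim == 2 else labels[0]


def make_excision_cylinder(
    pcl: BreastPCL,
    tumor_center: np.ndarray,
    volume_fraction: float,
    planes: QuadrantPlanes | None = None,
) -> ExcisionCylinder:
    """Define the excision cylinder for a tumor position and excised fraction.

    The cylinder axis runs from the orthogonal projection of the tumor
    center onto the pectoral plane towards the tumor (i.e. perpendicular to
    the chest wall); its height is the skin-to-muscle extent along that axis
    (largest axial projection over the surface points) and its radius is set
    so the cylinder volume equals ``volume_fraction`` of the breast volume.
    """
    if not 0 < volume_fraction <= MAX_EXCISION_FRACTION:
        raise ValueError(
            f"volume_fraction must be in (0, {MAX_EXCISION_FRACTION}], got {volume_fraction}"
        )
    if planes is None:
        planes = build_quadrant_planes(pcl)
    tumor_center = np.asarray(tumor_center, dtype=float)
    pect = planes.pectoral_plane
    gap = float(pect.signed_distance(tumor_center)[0])
    base = tumor_center - gap * pect.normal
    axis = pect.normal if abs(gap) < 1e-9 else _unit(tumor_center - base)

    height = float(np.max((pcl.surface_points - base) @ axis))
    if height <= 0:
        raise DegenerateGeometryError("cylinder height is non-positive")
    radius = float(np.sqrt(volume_fraction * pcl.breast_volume / (np.pi * height)))

    extent = pcl.surface_points.max(axis=0) - pcl.surface_points.min(axis=0)
    if radius > 0.5 * float(extent.min()):
        logger.warning(
            "excision cylinder radius %.1f mm exceeds half the smallest breast "
            "extent (%.1f mm)",
            radius,
            0.5 * float(extent.min()),
        )
    return ExcisionCylinder(
        base_point=base,
        axis=axis,
        height=height,
        radius=radius,
        volume_fraction=float(volume_fraction),
        tumor_center=tumor_center,
    )


def label_damaged(pcl: BreastPCL, cyl: ExcisionCylinder) -> np.ndarray:
    """Boolean mask of points inside the excision cylinder (damaged tissue).

    A point is damaged iff its axial projection lies in ``[0, height]`` and
    its radial distance to the axis is at most ``radius`` (boundary
    inclusive).
    """
    axial, radial = cyl.cylindrical_coords(pcl.points)
    return (axial >= 0) & (axial <= cyl.height) & (radial <= cyl.radius)


def sample_tumor_center(
    pcl: BreastPCL,
    quadrant: str,
    volume_fraction: float,
    rng: np.random.Generator,
    planes: QuadrantPlanes | None = None,
    max_tries: int = 2000,
) -> np.ndarray:
    """Sample a tumor center uniformly inside the requested breast quadrant.

    Candidates are drawn uniformly in the bounding box of the interior
    points, accepted when they fall in the target quadrant, lie strictly
    anterior of the pectoral plane, and the resulting excision cylinder
    fits within the breast's lateral extent (rejection sampling).
    """
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    if planes is None:
        planes = build_quadrant_planes(pcl)
    interior = pcl.interior_points
    lo, hi = interior.min(axis=0), interior.max(axis=0)
    half_extent = 0.5 * float(
        np.min((pcl.surface_points.max(axis=0) - pcl.surface_points.min(axis=0)))
    )
    last = None
    for _ in range(max_tries):
        cand = rng.uniform(lo, hi)
        if assign_quadrant(cand[None, :], planes, pcl.laterality)[0] != quadrant:
            continue
        if float(planes.pectoral_plane.signed_distance(cand)[0]) <= 1e-6:
            continue
        # must be inside the breast: near at least one interior point
        d2 = np.sum((interior - cand) ** 2, axis=1)
        if float(d2.min()) > (0.15 * half_extent) ** 2 + 25.0:
            continue
        cyl = make_excision_cylinder(pcl, cand, volume_fraction, planes)
        last = cand
        if cyl.radius <= half_extent:
            return cand
    if last is not None:  # fall back to the last in-quadrant candidate
        logger.warning("tumor sampler exhausted retries; using last candidate")
        return last
    raise DegenerateGeometryError(
        f"could not place a tumor inside quadrant {quadrant}"
    )
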