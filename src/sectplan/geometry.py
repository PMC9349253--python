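"""Block coordinate frame and cutting-plane geometry.

The block coordinate frame follows the fiducial convention used at the
cryostat: the border of a positioning plate inset in the embedding block is
the X-axis, the perpendicular through one plate end (the origin) is the
Y-axis, and the cutting-forward (specimen feed) direction is the Z-axis.
Coordinates are stored as positive magnitudes in micrometres; ``z`` is the
depth of a point below the block bottom face (the face cut first).

Planes are oriented: the unit normal always has a positive Z component, i.e.
it points against the cutting-forward direction, out of the block face.

Advance convention
------------------
A blade plane is moved only by translation along +Z (the specimen feed axis).
The *advance* ``t`` of a blade relative to a reference plane ``P0`` means the
blade plane is ``P0`` translated by ``t`` micrometres along +Z.  All
cutting-forward distances produced by this module are advances in that sense,
measured from the virtual-plane start position unless stated otherwise.

Key construction: for targets with depths ``z_i`` and maximal depth
``Z_b = max(z_i)``, a needle of height ``2*Z_b - z_i`` erected at each
target's footprint realizes the *virtual sectioning plane* — the expected
plane (through the target centers) translated ``2*Z_b`` against the feed
direction.  Aligning the blade to the needle tips and advancing by the
cutting-forward distance brings the blade exactly through the target centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ConfigError, DegenerateGeometryError, GeometryError

#: absolute tolerance for point/plane coincidence, in µm
ABS_TOL = 1e-6
#: tolerance on unit-normal length
NORMAL_TOL = 1e-9
#: angular tolerance (radians) for plane parallelism checks
PARALLEL_TOL = 1e-6

_Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class BlockFrame:
    """Geometry of an embedding block and its positioning-plate reference.

    Parameters
    ----------
    footprint_x, footprint_y : float
        Bottom-face extent along X and Y, µm.
    height : float
        Block height (maximum target depth), µm.
    plate_edge : pair of 2D points, optional
        Endpoints of the positioning-plate border segment that defines the
        X-axis.  Defaults to the segment from the origin along X.
    origin : 2D point, optional
        The plate end serving as the coordinate origin ("original point").
    """

    footprint_x: float
    footprint_y: float
    height: float
    plate_edge: tuple[tuple[float, float], tuple[float, float]] | None = None
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.footprint_x > 0 and self.footprint_y > 0 and self.height > 0):
            raise ConfigError("block footprint and height must be strictly positive")
        if self.plate_edge is None:
            object.__setattr__(
                self, "plate_edge",
                ((self.origin[0], self.origin[1]),
                 (self.origin[0] + self.footprint_x, self.origin[1])),
            )
        (ax, ay), (bx, by) = self.plate_edge
        if math.hypot(bx - ax, by - ay) <= ABS_TOL:
            raise ConfigError("plate_edge endpoints must be distinct")
        for (px, py) in self.plate_edge:
            if not (self._within_x(px) and self._within_y(py)):
                raise ConfigError("plate_edge endpoints must lie within the footprint")

    def _within_x(self, x: float, tol: float = ABS_TOL) -> bool:
        ox = self.origin[0]
        return ox - self.footprint_x - tol <= x <= ox + self.footprint_x + tol

    def _within_y(self, y: float, tol: float = ABS_TOL) -> bool:
        oy = self.origin[1]
        return oy - tol <= y <= oy + self.footprint_y + tol

    def contains_bottom_point(self, x: float, y: float, tol: float = ABS_TOL) -> bool:
        """True if (x, y) lies on the bottom face (mirrored side allowed)."""
        return self._within_x(x, tol) and self._within_y(y, tol)

    def to_dict(self) -> dict:
        return {
            "footprint_x_um": self.footprint_x,
            "footprint_y_um": self.footprint_y,
            "height_um": self.height,
            "plate_edge_um": [list(p) for p in self.plate_edge],
            "origin_um": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockFrame":
        return cls(
            footprint_x=float(d["footprint_x_um"]),
            footprint_y=float(d["footprint_y_um"]),
            height=float(d["height_um"]),
            plate_edge=tuple(tuple(map(float, p)) for p in d["plate_edge_um"]),
            origin=tuple(map(float, d["origin_um"])),
        )


@dataclass(frozen=True)
class TargetCenter:
    """A named target center in block coordinates (positive magnitudes, µm).

    ``z`` is the depth along the cutting-forward direction.  At the bench the
    axes are read off against the plate in the negative sense, so a target
    recorded as (−2000, −1000, −4000) is stored here as (2000, 1000, 4000);
    the sign convention lives in the frame, not in the stored value.
    """

    name: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.z < 0:
            raise ConfigError(
                f"target {self.name!r}: coordinates are stored as positive "
                f"magnitudes, got ({self.x}, {self.y}, {self.z})"
            )

    @property
    def point(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def footprint(self) -> tuple[float, float]:
        """(x, y) of the target projected onto the block bottom face."""
        return (self.x, self.y)


@dataclass(frozen=True)
class CuttingPlane:
    """An oriented blade plane: unit normal (positive Z component) + a point."""

    normal: np.ndarray
    point: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        p = np.asarray(self.point, dtype=float)
        norm = float(np.linalg.norm(n))
        if norm < NORMAL_TOL:
            raise DegenerateGeometryError("plane normal has zero length")
        n = n / norm
        if abs(n[2]) < NORMAL_TOL:
            raise DegenerateGeometryError(
                "plane is perpendicular to the block bottom (normal has no Z "
                "component); such a plane cannot be realized by the blade"
            )
        if n[2] < 0:
            n = -n
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "point", p)

    def signed_distance(self, points: np.ndarray) -> np.ndarray | float:
        """Signed perpendicular distance(s); positive on the +normal side."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.point) @ self.normal

    def contains(self, point: np.ndarray, tol: float = ABS_TOL) -> bool:
        return abs(float(self.signed_distance(point))) < tol

    def translated(self, advance: float) -> "CuttingPlane":
        """The plane translated ``advance`` µm along +Z (the feed axis)."""
        return CuttingPlane(self.normal, self.point + advance * _Z)

    def is_parallel(self, other: "CuttingPlane", tol: float = PARALLEL_TOL) -> bool:
        dot = float(np.clip(abs(self.normal @ other.normal), -1.0, 1.0))
        return math.acos(dot) <= tol

    def z_at(self, x: float, y: float) -> float:
        """Depth z of the plane point vertically above/below (x, y)."""
        nx, ny, nz = self.normal
        return float((self.normal @ self.point - nx * x - ny * y) / nz)

    def to_dict(self) -> dict:
        return {"normal": [float(v) for v in self.normal],
                "point": [float(v) for v in self.point]}

    @classmethod
    def from_dict(cls, d: dict) -> "CuttingPlane":
        return cls(np.asarray(d["normal"], float), np.asarray(d["point"], float))


@dataclass(frozen=True)
class Needle:
    """One needle of a sectioning-guided model."""

    name: str
    base: tuple[float, float]  # (x, y) on the block face, µm
    tip_height: float          # protrusion toward the blade, µm


@dataclass(frozen=True)
class GuideModel:
    """Needle realization of the virtual sectioning plane.

    Needles stand on the cut face of a dummy block identical in footprint to
    the specimen; their tips (protruding ``tip_height`` µm toward the blade)
    span the virtual sectioning plane used to align the blade angle.
    """

    needles: tuple[Needle, ...]

    def __post_init__(self) -> None:
        if len(self.needles) < 3:
            raise ConfigError("a guide model needs at least 3 needles")
        for nd in self.needles:
            if nd.tip_height < 0:
                raise ConfigError(f"needle {nd.name!r} has negative tip height")

    @property
    def tip_points(self) -> np.ndarray:
        """Tips in block coordinates: depth −tip_height (in front of the face)."""
        return np.array(
            [[nd.base[0], nd.base[1], -nd.tip_height] for nd in self.needles]
        )

    def tip_height(self, name: str) -> float:
        for nd in self.needles:
            if nd.name == name:
                return nd.tip_height
        raise KeyError(name)


# ---------------------------------------------------------------------------
# plane construction

def plane_through_targets(
    t1: TargetCenter, t2: TargetCenter, t3: TargetCenter
) -> CuttingPlane:
    """Expected sectioning plane: the unique plane through three target centers.

    Raises
    ------
    DegenerateGeometryError
        If the centers are coincident or collinear (no unique plane), or if
        the plane would stand perpendicular to the block bottom.
    """
    p1, p2, p3 = t1.point, t2.point, t3.point
    v1, v2 = p2 - p1, p3 - p1
    n = np.cross(v1, v2)
    scale = max(np.linalg.norm(v1), np.linalg.norm(v2), 1.0)
    if np.linalg.norm(n) <= ABS_TOL * scale:
        raise DegenerateGeometryError(
            f"targets {t1.name!r}, {t2.name!r}, {t3.name!r} are collinear or "
            "coincident; they do not define a unique plane"
        )
    return CuttingPlane(n, p1)


def fit_plane(targets: Sequence[TargetCenter]) -> CuttingPlane:
    """Orthogonal least-squares plane through ``n >= 3`` target centers.

    For exactly three targets this reduces to :func:`plane_through_targets`.
    The fit minimizes the sum of squared perpendicular distances (total least
    squares via SVD of the centered coordinates).
    """
    if len(targets) < 3:
        raise ConfigError("plane fitting needs at least 3 targets")
    if len(targets) == 3:
        return plane_through_targets(*targets)
    pts = np.array([t.point for t in targets])
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear cloud: only one significant singular value
    if s[1] <= ABS_TOL * max(s[0], 1.0):
        raise DegenerateGeometryError(
            "targets are collinear; they do not define a unique plane"
        )
    return CuttingPlane(vt[2], centroid)


def virtual_plane(
    targets: Sequence[TargetCenter],
) -> tuple[CuttingPlane, GuideModel]:
    """Virtual sectioning plane and its needle-guide realization.

    With ``Z_b`` the maximal target depth, each target receives a needle of
    tip height ``2*Z_b - z_i`` at its footprint.  The plane through the tips
    is the expected plane translated ``2*Z_b`` against the feed direction, so
    the expected (a-b-c), suppositional (a'-b'-c') and virtual (a''-b''-c'')
    planes are parallel with equal spacing ``Z_b``.

    When several targets tie for the maximal depth the first in input order
    is taken as the deepest; the heights depend only on the ``Z_b`` value, so
    the result is identical under either choice.
    """
    expected = fit_plane(targets)
    z_b = max(t.z for t in targets)
    needles = []
    for t in targets:
        h = 2.0 * z_b - t.z
        # z_b is the maximum depth, so heights are >= z_b >= 0 by construction
        assert h >= 0.0, "internal consistency: negative needle height"
        needles.append(Needle(t.name, t.footprint, h))
    guide = GuideModel(tuple(needles))
    virt = expected.translated(-2.0 * z_b)
    return virt, guide


# ---------------------------------------------------------------------------
# angles and feasibility

def tilt_angle(plane: CuttingPlane) -> float:
    """Tilt of a plane against the block bottom, in degrees within [0, 90).

    This is the cutting angle set between the blade edge surface and the
    cutting face of the specimen block.
    """
    c = float(np.clip(abs(plane.normal @ _Z), 0.0, 1.0))
    return math.degrees(math.acos(c))


@dataclass(frozen=True)
class FeasibilityVerdict:
    """Whether a plane tilt is within the cryostat's angle capacity."""

    feasible: bool
    tilt_deg: float
    capacity_deg: float
    wedge_deg: float  # suggested pre-trim inclined-face angle if infeasible

    def to_dict(self) -> dict:
        return {
            "feasible": self.feasible,
            "tilt_deg": self.tilt_deg,
            "capacity_deg": self.capacity_deg,
            "wedge_deg": self.wedge_deg,
        }


def check_feasibility(
    plane: CuttingPlane, capacity_deg: float = 20.0
) -> FeasibilityVerdict:
    """Check a plane against the cryostat angle capacity (boundary inclusive).

    If the tilt exceeds the capacity the verdict suggests the wedge angle
    (``tilt - capacity``) by which the block face must be pre-trimmed at an
    incline so the residual alignment falls within capacity — e.g. a plane
    at 81° to the block bottom is prepared with a 9° inclined trim.
    """
    if not (0.0 < capacity_deg < 90.0):
        raise ConfigError(f"angle capacity must be in (0, 90)°, got {capacity_deg}")
    tilt = tilt_angle(plane)
    feasible = tilt <= capacity_deg
    wedge = 0.0 if feasible else tilt - capacity_deg
    return FeasibilityVerdict(feasible, tilt, capacity_deg, wedge)


# ---------------------------------------------------------------------------
# mirror transform

def mirror_x(obj, frame: BlockFrame):
    """Reflect across the Y-Z plane through the frame origin (X re-referenced).

    The bottom face of the block is cut first, so section images are viewed
    mirror-reversed relative to the block-bottom layout; this transform maps
    between the two.  It negates X about the origin's X, preserves Y and Z
    (hence all pairwise distances), and is an involution.

    Accepts a 2D/3D point (array-like) or a :class:`CuttingPlane` and returns
    the mirrored counterpart of the same kind.
    """
    ox = frame.origin[0]
    if isinstance(obj, CuttingPlane):
        n = obj.normal.copy()
        p = obj.point.copy()
        n[0] = -n[0]
        p[0] = 2.0 * ox - p[0]
        return CuttingPlane(n, p)
    pt = np.asarray(obj, dtype=float).copy()
    pt[0] = 2.0 * ox - pt[0]
    return pt


# ---------------------------------------------------------------------------
# cutting-forward distance

def cutting_forward_distance(
    plane: CuttingPlane,
    mark: tuple[float, float],
    frame: BlockFrame,
    start: CuttingPlane,
) -> float:
    """Specimen-feed advance from ``start`` until the blade reaches ``plane``
    at the marked bottom position.

    ``mark`` is a 2D (x, y) position labelled on the block bottom face (the
    initial cutting face); the advance is measured to the point of the target
    ``plane`` vertically above that mark.  When the mark is the footprint of
    a target, the returned advance puts the blade plane exactly through that
    target center — and, since the targets are coplanar by construction,
    through all of them.

    The advance is measured along the feed axis (Z), not along the plane
    normal: it equals the signed perpendicular point-to-start-plane distance
    divided by ``cos(tilt)``.

    Raises
    ------
    GeometryError
        If ``start`` and ``plane`` are not parallel, the mark lies outside
        the block bottom face, or the marked position lies behind the start
        plane (negative advance).
    """
    if not start.is_parallel(plane):
        raise GeometryError(
            "start plane and target plane are not parallel; the blade can "
            "only be advanced, not re-tilted, between them"
        )
    mx, my = float(mark[0]), float(mark[1])
    if not frame.contains_bottom_point(mx, my):
        raise GeometryError(f"mark ({mx}, {my}) lies outside the block bottom face")
    target_point = np.array([mx, my, plane.z_at(mx, my)])
    s = float(start.signed_distance(target_point))
    cos_tilt = float(start.normal @ _Z)
    advance = s / cos_tilt
    if advance < -ABS_TOL:
        raise GeometryError(
            f"marked position lies {-advance:.3f} µm behind the start plane"
        )
    return max(advance, 0.0)
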