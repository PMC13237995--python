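"""Mesh, plane, rigid-pose and planar-polygon primitives shared by all planners.

Coordinate convention (right-handed, millimetres):

* ``+x`` — medial–lateral axis, **medial positive**,
* ``+y`` — anterior–posterior axis, anterior positive,
* ``+z`` — distal–proximal axis, proximal positive.

A :class:`RigidPose` decomposes a rigid transform into the six clinical
degrees of freedom (AP/PD/ML translations, FE/AA/IE rotations).  Rotations
are applied flexion first about the fixed medial–lateral axis, then
abduction–adduction (varus positive: the medial compartment closes) about
the fixed anterior–posterior axis, then internal–external rotation about
the fixed distal–proximal axis — a Grood–Suntay-like ordering, i.e.
``R = Rz(IE) @ Ry(AA) @ Rx(FE)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import shapely
import shapely.affinity
import trimesh
from scipy.spatial.transform import Rotation
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

__all__ = [
    "RigidPose",
    "Plane",
    "PlanarContour",
    "pose_to_matrix",
    "matrix_to_pose",
    "cut_mesh_by_plane",
    "polygon_areas",
    "max_overhang_distance",
    "point_plane_distance",
    "load_mesh",
    "save_mesh",
]


@dataclass(frozen=True)
class RigidPose:
    """Six-DOF rigid transform in clinical coordinates (mm / degrees)."""

    AP_mm: float = 0.0
    PD_mm: float = 0.0
    ML_mm: float = 0.0
    FE_deg: float = 0.0
    AA_deg: float = 0.0
    IE_deg: float = 0.0

    def matrix(self) -> np.ndarray:
        return pose_to_matrix(self)

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Pose equivalent to applying ``other`` first, then ``self``."""
        return matrix_to_pose(self.matrix() @ other.matrix())

    def inverse(self) -> "RigidPose":
        return matrix_to_pose(np.linalg.inv(self.matrix()))

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.AP_mm, self.PD_mm, self.ML_mm, self.FE_deg, self.AA_deg, self.IE_deg]
        )

    @staticmethod
    def from_array(a: Iterable[float]) -> "RigidPose":
        ap, pd, ml, fe, aa, ie = (float(v) for v in a)
        return RigidPose(ap, pd, ml, fe, aa, ie)


def pose_to_matrix(pose: RigidPose) -> np.ndarray:
    """4x4 homogeneous transform for a :class:`RigidPose`.

    FE is applied first (about fixed ``x``/ML), then AA (fixed ``y``/AP),
    then IE (fixed ``z``/PD): ``R = Rz(IE) Ry(AA) Rx(FE)``.  Translation
    maps (ML, AP, PD) onto (x, y, z).
    """
    rot = Rotation.from_euler(
        "ZYX", [pose.IE_deg, pose.AA_deg, pose.FE_deg], degrees=True
    )
    m = np.eye(4)
    m[:3, :3] = rot.as_matrix()
    m[:3, 3] = [pose.ML_mm, pose.AP_mm, pose.PD_mm]
    return m


def matrix_to_pose(matrix: np.ndarray) -> RigidPose:
    """Inverse of :func:`pose_to_matrix` (gimbal lock at AA = ±90° aside)."""
    matrix = np.asarray(matrix, dtype=float)
    ie, aa, fe = Rotation.from_matrix(matrix[:3, :3]).as_euler("ZYX", degrees=True)
    ml, ap, pd = matrix[:3, 3]
    return RigidPose(AP_mm=ap, PD_mm=pd, ML_mm=ml, FE_deg=fe, AA_deg=aa, IE_deg=ie)


def transform_points(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    points = np.atleast_2d(points)
    return points @ matrix[:3, :3].T + matrix[:3, 3]


@dataclass(frozen=True)
class Plane:
    """Oriented plane given by a point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", n / nn)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance, positive on the normal side."""
        return (np.atleast_2d(points) - self.point) @ self.normal

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic in-plane orthonormal basis (u, v).

        ``u`` is the projection of the global ML axis (or AP axis when the
        normal is nearly parallel to ML), ``v = normal × u``.
        """
        ref = np.array([1.0, 0.0, 0.0])
        if abs(self.normal @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = ref - (ref @ self.normal) * self.normal
        u /= np.linalg.norm(u)
        v = np.cross(self.normal, u)
        return u, v

    def to_plane_coords(self, points: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        rel = np.atleast_2d(points) - self.point
        return np.column_stack([rel @ u, rel @ v])

    def to_world_coords(self, coords2d: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        coords2d = np.atleast_2d(coords2d)
        return self.point + np.outer(coords2d[:, 0], u) + np.outer(coords2d[:, 1], v)

    def transformed(self, matrix: np.ndarray) -> "Plane":
        p = transform_points(matrix, self.point[None, :])[0]
        n = matrix[:3, :3] @ self.normal
        return Plane(p, n)

    def to_dict(self) -> dict:
        return {"point": self.point.tolist(), "normal": self.normal.tolist()}

    @staticmethod
    def from_dict(d: dict) -> "Plane":
        return Plane(np.asarray(d["point"]), np.asarray(d["normal"]))


def _is_coplanar(a: Plane, b: Plane, tol: float = 1e-6) -> bool:
    if abs(abs(a.normal @ b.normal) - 1.0) > tol:
        return False
    return abs(a.signed_distance(b.point[None, :])[0]) < 1e-4


@dataclass
class PlanarContour:
    """Cross-section polygon(s) living on a plane.

    ``geometry`` is a shapely (Multi)Polygon expressed in the plane's
    deterministic in-plane basis (see :meth:`Plane.basis`).
    """

    plane: Plane
    geometry: Polygon | MultiPolygon = field(default_factory=Polygon)

    @property
    def is_empty(self) -> bool:
        return self.geometry.is_empty

    @property
    def area(self) -> float:
        return float(self.geometry.area)

    def geometry_in_basis_of(self, other: "PlanarContour") -> Polygon | MultiPolygon:
        """Re-express this contour's polygon in ``other``'s plane basis."""
        if not _is_coplanar(self.plane, other.plane):
            raise ValueError("contours are not coplanar")
        su, sv = self.plane.basis()
        ou, ov = other.plane.basis()
        # affine map: world = p0 + x*su + y*sv ; coords in other basis
        d = self.plane.point - other.plane.point
        a, b = su @ ou, sv @ ou
        d_, e_ = su @ ov, sv @ ov
        xoff, yoff = d @ ou, d @ ov
        return shapely.affinity.affine_transform(
            self.geometry, [a, b, d_, e_, xoff, yoff]
        )

    def boundary_points_3d(self, spacing_mm: float = 1.0) -> np.ndarray:
        dense = shapely.segmentize(self.geometry.boundary, spacing_mm)
        pts2d = np.asarray(shapely.get_coordinates(dense))
        return self.plane.to_world_coords(pts2d)

    def to_dict(self) -> dict:
        return {"plane": self.plane.to_dict(), "wkt": self.geometry.wkt}

    @staticmethod
    def from_dict(d: dict) -> "PlanarContour":
        return PlanarContour(Plane.from_dict(d["plane"]), shapely.from_wkt(d["wkt"]))


def _loops_to_geometry(loops: list[np.ndarray]) -> Polygon | MultiPolygon:
    """Assemble closed 2D loops into a valid (Multi)Polygon.

    Loops are sorted by |area|; each loop nested inside an already placed
    outer loop becomes a hole, otherwise it starts a new outer polygon
    (one nesting level, which covers solid cross-sections).
    """
    polys = []
    for loop in loops:
        if len(loop) >= 3:
            p = Polygon(loop)
            if p.area > 1e-12:
                polys.append(shapely.make_valid(p))
    if not polys:
        return Polygon()
    polys.sort(key=lambda p: p.area, reverse=True)
    outers: list[Polygon] = []
    holes: dict[int, list] = {}
    for p in polys:
        rp = p.representative_point()
        placed = False
        for i, o in enumerate(outers):
            if o.contains(rp):
                holes.setdefault(i, []).append(p.exterior.coords)
                placed = True
                break
        if not placed:
            outers.append(p)
            holes[len(outers) - 1] = []
    assembled = [Polygon(o.exterior.coords, holes[i]) for i, o in enumerate(outers)]
    geom = unary_union([shapely.make_valid(p) for p in assembled])
    if isinstance(geom, (Polygon, MultiPolygon)):
        return geom
    # drop any stray lower-dimensional pieces
    parts = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    return unary_union(parts) if parts else Polygon()


def cut_mesh_by_plane(mesh: trimesh.Trimesh, plane: Plane) -> PlanarContour:
    """Cross-section contour of a closed mesh at a plane.

    Returns an empty :class:`PlanarContour` when the plane misses the mesh.
    """
    section = mesh.section(plane_origin=plane.point, plane_normal=plane.normal)
    if section is None:
        return PlanarContour(plane, Polygon())
    loops = [plane.to_plane_coords(np.asarray(d)) for d in section.discrete]
    return PlanarContour(plane, _loops_to_geometry(loops))


def polygon_areas(a: PlanarContour, b: PlanarContour) -> dict[str, float]:
    """Overlap and set-difference areas (mm²) of two coplanar contours."""
    gb = b.geometry_in_basis_of(a)
    ga = a.geometry
    inter = ga.intersection(gb).area
    return {
        "overlap_mm2": float(inter),
        "a_minus_b_mm2": float(ga.difference(gb).area),
        "b_minus_a_mm2": float(gb.difference(ga).area),
    }


def max_overhang_distance(
    implant: PlanarContour,
    resection: PlanarContour,
    sample_spacing_mm: float = 0.1,
) -> float:
    """Maximum distance an implant boundary point overhangs the resection.

    Zero when the implant footprint is contained in the resection surface;
    otherwise the largest distance from any implant-boundary point lying
    outside the resection to the resection region (boundary sampled at
    ``sample_spacing_mm``).
    """
    gi = implant.geometry_in_basis_of(resection)
    gr = resection.geometry
    if gr.covers(gi):
        return 0.0
    dense = shapely.segmentize(gi.boundary, sample_spacing_mm)
    pts = shapely.points(shapely.get_coordinates(dense))
    outside = ~shapely.covers(gr, pts)
    if not outside.any():
        return 0.0
    return float(shapely.distance(pts[outside], gr).max())


def point_plane_distance(point: np.ndarray, plane: Plane) -> float:
    """Signed point-to-plane distance, positive on the normal side."""
    return float(plane.signed_distance(np.asarray(point, dtype=float)[None, :])[0])


def load_mesh(path) -> trimesh.Trimesh:
    mesh = trimesh.load_mesh(path)
    if not isinstance(mesh, trimesh.Trimesh):  # pragma: no cover - scene files
        mesh = trimesh.util.concatenate(tuple(mesh.geometry.values()))
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path) -> None:
    mesh.export(path)
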