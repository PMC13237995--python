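"""Tibial component placement by penalized-coverage maximization.

The tibial cut matches the native posterior slope at a resection depth of
8 mm below the lateral plateau.  The baseplate is then slid and rotated on
the cut (rotation constrained to ±5° about the Insall line, overhang to
2 mm) by a simulated-annealing search that maximizes the penalized
coverage index

    PCI = (area(A_I ∩ A_T) − area(A_I \\ A_T)) / area(A_T) × 100%

where ``A_I`` is the implant undersurface footprint and ``A_T`` the
resection cross-section: coverage credit minus an overhang-area penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
import shapely.affinity
import trimesh
from shapely.geometry import MultiPolygon, Polygon

from .geometry import Plane, PlanarContour, cut_mesh_by_plane
from .kinematics import StandingAlignment

__all__ = [
    "TibialConstraints",
    "SAConfig",
    "TibialPlanResult",
    "build_resection_plane",
    "compute_pci",
    "optimize_tibial_placement",
    "insall_rotation_of",
    "insall_direction_2d",
]


@dataclass(frozen=True)
class TibialConstraints:
    rotation_limit_deg: float = 5.0
    overhang_limit_mm: float = 2.0
    resection_depth_mm: float = 8.0
    match_native_slope: bool = True

    def __post_init__(self) -> None:
        if min(self.rotation_limit_deg, self.overhang_limit_mm,
               self.resection_depth_mm) < 0:
            raise ValueError("constraint limits must be nonnegative")


@dataclass(frozen=True)
class SAConfig:
    max_iterations: int = 200
    initial_temperature: float = 5.0
    cooling_rate: float = 0.97
    proposal_sd_translation_mm: float = 1.0
    proposal_sd_rotation_deg: float = 1.0
    size_change_probability: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0 < self.cooling_rate < 1):
            raise ValueError("cooling_rate must lie in (0, 1)")


@dataclass
class TibialPlanResult:
    x_mm: float
    y_mm: float
    rotation_deg: float  # relative to the Insall line
    chosen_size_id: str
    pci_percent: float
    overhang_mm: float
    resection_plane: Plane
    feasible: bool = True
    implant_contour: PlanarContour | None = None
    resection_contour: PlanarContour | None = None

    def to_dict(self) -> dict:
        return {
            "x_mm": self.x_mm,
            "y_mm": self.y_mm,
            "rotation_deg": self.rotation_deg,
            "chosen_size_id": self.chosen_size_id,
            "pci_percent": self.pci_percent,
            "overhang_mm": self.overhang_mm,
            "resection_plane": self.resection_plane.to_dict(),
            "feasible": self.feasible,
        }


def build_resection_plane(
    tibia: trimesh.Trimesh,
    landmarks: dict[str, np.ndarray],
    alignment: StandingAlignment,
    constraints: TibialConstraints = TibialConstraints(),
) -> Plane:
    """Tibial cut plane: ``resection_depth_mm`` below the lateral plateau
    along the tibial axis, tilted posteriorly by the native slope about the
    medial–lateral axis, with no coronal tilt."""
    if "lateral_plateau" not in landmarks:
        raise ValueError("landmark 'lateral_plateau' is required")
    slope = np.deg2rad(
        alignment.posterior_slope_deg if constraints.match_native_slope else 0.0
    )
    # posterior slope: the cut surface drops posteriorly (z falls as y
    # does), i.e. the surface z - tan(slope)*y = const, normal (0,-sin,cos)
    normal = np.array([0.0, -np.sin(slope), np.cos(slope)])
    point = np.asarray(landmarks["lateral_plateau"], dtype=float) - np.array(
        [0.0, 0.0, constraints.resection_depth_mm]
    )
    return Plane(point, normal)


def _pci_from_polygons(implant, resection) -> float:
    at = resection.area
    if at <= 0:
        raise ValueError("zero-area resection surface")
    overlap = implant.intersection(resection).area
    overhang_area = implant.difference(resection).area
    return float((overlap - overhang_area) / at * 100.0)


def compute_pci(implant_contour: PlanarContour, resection_contour: PlanarContour) -> float:
    """Penalized coverage index in percent; at most 100, negative for
    gross malposition (overhang area exceeding coverage)."""
    gi = implant_contour.geometry_in_basis_of(resection_contour)
    return _pci_from_polygons(gi, resection_contour.geometry)


def _overhang_2d(implant, resection, spacing: float = 0.1) -> float:
    if resection.covers(implant):
        return 0.0
    dense = shapely.segmentize(implant.boundary, spacing)
    pts = shapely.points(shapely.get_coordinates(dense))
    outside = ~shapely.covers(resection, pts)
    if not outside.any():
        return 0.0
    return float(shapely.distance(pts[outside], resection).max())


def implant_footprint(implant: trimesh.Trimesh) -> Polygon | MultiPolygon:
    """Undersurface footprint: cross-section just above the implant's
    lowest surface, in the implant's own (x, y) frame."""
    z0 = implant.bounds[0][2]
    plane = Plane(np.array([0.0, 0.0, z0 + 0.1]), np.array([0.0, 0.0, 1.0]))
    contour = cut_mesh_by_plane(implant, plane)
    if contour.is_empty:
        raise ValueError("implant mesh has no undersurface cross-section")
    # re-express the section in the implant's own (x, y) coordinates
    geom = contour.geometry
    polys = geom.geoms if isinstance(geom, MultiPolygon) else [geom]
    out = []
    for p in polys:
        ext = contour.plane.to_world_coords(np.asarray(p.exterior.coords))[:, :2]
        ints = [contour.plane.to_world_coords(np.asarray(r.coords))[:, :2]
                for r in p.interiors]
        out.append(Polygon(ext, ints))
    return out[0] if len(out) == 1 else MultiPolygon(out)


def insall_direction_2d(landmarks: dict[str, np.ndarray], plane: Plane) -> np.ndarray:
    """Unit 2D direction of the Insall line projected into the plane basis."""
    try:
        ant = np.asarray(landmarks["insall_anterior"], dtype=float)
        post = np.asarray(landmarks["insall_posterior"], dtype=float)
    except KeyError as e:
        raise ValueError(f"missing Insall landmark: {e}")
    d2 = plane.to_plane_coords(ant[None, :])[0] - plane.to_plane_coords(post[None, :])[0]
    norm = np.linalg.norm(d2)
    if norm < 1e-9:
        raise ValueError("degenerate (zero-length) Insall line")
    return d2 / norm


def insall_rotation_of(
    pose_or_axis, landmarks: dict[str, np.ndarray], plane: Plane
) -> float:
    """Signed in-plane angle (deg) between a component AP axis and the
    projected Insall line.

    Accepts either a :class:`~tkaplan.geometry.RigidPose` (whose rotated
    +y axis is projected into the plane) or a 2D AP axis already expressed
    in the plane basis.
    """
    from .geometry import RigidPose  # local import avoids a cycle at module load

    ins = insall_direction_2d(landmarks, plane)
    if isinstance(pose_or_axis, RigidPose):
        ap3 = pose_or_axis.matrix()[:3, :3] @ np.array([0.0, 1.0, 0.0])
        u, v = plane.basis()
        ap = np.array([ap3 @ u, ap3 @ v])
    else:
        ap = np.asarray(pose_or_axis, dtype=float)
    norm = np.linalg.norm(ap)
    if norm < 1e-9:
        raise ValueError("degenerate component AP axis")
    ap = ap / norm
    cross = ins[0] * ap[1] - ins[1] * ap[0]
    return float(np.degrees(np.arctan2(cross, ins @ ap)))


def _place(footprint, x: float, y: float, rot_deg: float):
    g = shapely.affinity.rotate(footprint, rot_deg, origin=(0, 0))
    return shapely.affinity.translate(g, xoff=x, yoff=y)


def optimize_tibial_placement(
    tibia: trimesh.Trimesh,
    implant_catalog: list[trimesh.Trimesh],
    landmarks: dict[str, np.ndarray],
    alignment: StandingAlignment,
    constraints: TibialConstraints = TibialConstraints(),
    sa: SAConfig = SAConfig(),
) -> TibialPlanResult:
    """Simulated-annealing search over in-plane pose and catalog size.

    State is (x, y, rotation-from-Insall, size index); rotation proposals
    are clamped to the ±rotation limit and candidates whose overhang
    distance exceeds the limit score −inf.  The returned placement never
    scores below the centered, Insall-aligned start (elitism).
    """
    if not implant_catalog:
        raise ValueError("implant catalog is empty")
    plane = build_resection_plane(tibia, landmarks, alignment, constraints)
    resection = cut_mesh_by_plane(tibia, plane)
    if resection.is_empty:
        raise ValueError("resection plane does not intersect the tibia")
    res_poly = resection.geometry

    # footprint polygons in the plane basis, Insall line mapped onto +y
    ins = insall_direction_2d(landmarks, plane)
    base_rot = np.degrees(np.arctan2(ins[0], ins[1]))  # rotate footprint AP onto Insall
    footprints = []
    for m in implant_catalog:
        fp = implant_footprint(m)
        fp = shapely.affinity.translate(fp, -fp.centroid.x, -fp.centroid.y)
        footprints.append(shapely.affinity.rotate(fp, -base_rot, origin=(0, 0)))

    cx, cy = res_poly.centroid.x, res_poly.centroid.y
    rot_lim = constraints.rotation_limit_deg

    def objective(x, y, rot, k):
        g = _place(footprints[k], x, y, rot)
        if _overhang_2d(g, res_poly) > constraints.overhang_limit_mm:
            return -np.inf, g
        return _pci_from_polygons(g, res_poly), g

    rng = np.random.default_rng(sa.seed)
    state = [cx, cy, 0.0, len(implant_catalog) // 2]
    cur, _ = objective(*state[:3], state[3])
    # fall back to the smallest size if the centered start overhangs
    if not np.isfinite(cur):
        for k in range(len(implant_catalog)):
            cur, _ = objective(cx, cy, 0.0, k)
            if np.isfinite(cur):
                state[3] = k
                break
    best = list(state)
    best_val = cur
    temp = sa.initial_temperature

    for _ in range(sa.max_iterations):
        cand = list(state)
        if rng.random() < sa.size_change_probability and len(implant_catalog) > 1:
            cand[3] = int(rng.integers(len(implant_catalog)))
        cand[0] += rng.normal(0, sa.proposal_sd_translation_mm)
        cand[1] += rng.normal(0, sa.proposal_sd_translation_mm)
        cand[2] = float(np.clip(cand[2] + rng.normal(0, sa.proposal_sd_rotation_deg),
                                -rot_lim, rot_lim))
        val, _ = objective(*cand[:3], cand[3])
        delta = val - cur
        if delta > 0 or (np.isfinite(val) and rng.random() < np.exp(delta / max(temp, 1e-12))):
            state, cur = cand, val
            if cur > best_val:
                best, best_val = list(state), cur
        temp *= sa.cooling_rate

    if not np.isfinite(best_val):
        return TibialPlanResult(
            x_mm=cx, y_mm=cy, rotation_deg=0.0, chosen_size_id="size_0",
            pci_percent=float("nan"), overhang_mm=float("inf"),
            resection_plane=plane, feasible=False,
            resection_contour=resection,
        )

    g = _place(footprints[best[3]], best[0], best[1], best[2])
    overhang = _overhang_2d(g, res_poly)
    return TibialPlanResult(
        x_mm=float(best[0]),
        y_mm=float(best[1]),
        rotation_deg=float(best[2]),
        chosen_size_id=f"size_{best[3]}",
        pci_percent=float(best_val),
        overhang_mm=float(overhang),
        resection_plane=plane,
        feasible=True,
        implant_contour=PlanarContour(plane, g),
        resection_contour=resection,
    )
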