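"""Collateral ligament wrapping lengths, strains, forces and rig tensions.

Three bundles are modeled: the anterior and posterior bundles of the
superficial medial collateral ligament (aMCL, pMCL) and the intermediate
bundle of the lateral collateral ligament (iLCL).  Each bundle's length at
a flexion angle is the shortest three-dimensional path from its femoral to
its tibial attachment that avoids the bone (and, post-implantation,
implant) surfaces; the length at 0° flexion is the reference length.

Force follows a piecewise nonlinear spring with toe region:

    f(ε) = 0.25 k ε² / ε₁     for 0 ≤ ε ≤ 2ε₁
    f(ε) = k (ε − ε₁)          for ε > 2ε₁
    f(ε) = 0                   for ε < 0

with strain constant ε₁ = 0.03 and stiffnesses k = 2500 N (aMCL),
3000 N (pMCL) and 2000 N (iLCL).  The in-vitro tension protocol applies
baseline tensions of 130 N medially and 100 N laterally plus the computed
bundle force at each test angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .kinematics import FlexionPoseSeries
from .meshquery import closest_points_on_mesh, points_in_mesh

__all__ = [
    "LigamentBundle",
    "LigamentSweep",
    "TensionProtocol",
    "wrapping_path_length",
    "wrapping_path",
    "sweep_lengths",
    "ligament_force",
    "build_tension_protocol",
    "DEFAULT_STIFFNESS_N",
    "BASELINE_TENSION_N",
]

DEFAULT_STIFFNESS_N = {"aMCL": 2500.0, "pMCL": 3000.0, "iLCL": 2000.0}
BASELINE_TENSION_N = {"aMCL": 130.0, "pMCL": 130.0, "iLCL": 100.0}
DEFAULT_EPS1 = 0.03
TEST_ANGLE_GRID = tuple(float(a) for a in range(0, 101, 10))


@dataclass
class LigamentBundle:
    name: str
    femoral_attachment: np.ndarray
    tibial_attachment: np.ndarray
    stiffness_k_N: float
    strain_constant_eps1: float = DEFAULT_EPS1
    reference_length_mm: float | None = None

    def __post_init__(self) -> None:
        if self.name not in DEFAULT_STIFFNESS_N:
            raise ValueError(f"unknown bundle {self.name!r}")
        if self.stiffness_k_N <= 0:
            raise ValueError("stiffness must be positive")
        if self.strain_constant_eps1 <= 0:
            raise ValueError("strain constant must be positive")
        self.femoral_attachment = np.asarray(self.femoral_attachment, float)
        self.tibial_attachment = np.asarray(self.tibial_attachment, float)

    @staticmethod
    def from_landmarks(name: str, landmarks: dict[str, np.ndarray]) -> "LigamentBundle":
        return LigamentBundle(
            name=name,
            femoral_attachment=landmarks[f"{name}_origin"],
            tibial_attachment=landmarks[f"{name}_insertion"],
            stiffness_k_N=DEFAULT_STIFFNESS_N[name],
        )


@dataclass
class LigamentSweep:
    bundle_name: str
    records: list[tuple[float, float, float, float]]  # (flexion, length, strain, force)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records,
                          columns=["flexion_deg", "length_mm", "strain", "force_N"])
        df["bundle"] = self.bundle_name
        return df

    def lengths(self) -> np.ndarray:
        return np.array([r[1] for r in self.records])


@dataclass
class TensionProtocol:
    """Per-angle, per-bundle applied tensions for the loading rig."""

    table: pd.DataFrame  # columns: flexion_deg, bundle, force_N, baseline_N, applied_N

    def applied(self, bundle: str, flexion_deg: float) -> float:
        t = self.table
        row = t[(t.bundle == bundle) & (np.isclose(t.flexion_deg, flexion_deg))]
        if row.empty:
            raise KeyError(f"no protocol entry for {bundle} at {flexion_deg} deg")
        return float(row.applied_N.iloc[0])


def ligament_force(strain: float, k: float, eps1: float = DEFAULT_EPS1) -> float:
    """Piecewise nonlinear bundle force (N); slack below zero strain,
    quadratic toe up to 2·eps1, linear beyond (continuous and C¹ at the
    knot, where f = k·eps1 and f' = k)."""
    if eps1 <= 0:
        raise ValueError("eps1 must be positive")
    if strain < 0:
        return 0.0
    if strain <= 2 * eps1:
        return 0.25 * k * strain**2 / eps1
    return k * (strain - eps1)


# ---------------------------------------------------------------------------
# wrapping path computation
# ---------------------------------------------------------------------------


def _contains(obs, points: np.ndarray) -> np.ndarray:
    """Mesh containment with an axis-aligned bounding-box prefilter."""
    lo, hi = obs.bounds
    cand = np.all((points >= lo) & (points <= hi), axis=1)
    out = np.zeros(len(points), dtype=bool)
    if cand.any():
        out[cand] = points_in_mesh(obs, points[cand])
    return out


def _inside_any(points: np.ndarray, obstacles) -> np.ndarray:
    inside = np.zeros(len(points), dtype=bool)
    for obs in obstacles:
        inside |= _contains(obs, points)
    return inside


def _segments_free(p0s: np.ndarray, p1s: np.ndarray, obstacles,
                   n_samples: int = 12) -> np.ndarray:
    """Batched clearance check: each segment sampled at interior points."""
    t = np.linspace(0.0, 1.0, n_samples + 2)[1:-1]
    pts = (p0s[:, None, :] * (1 - t)[None, :, None]
           + p1s[:, None, :] * t[None, :, None]).reshape(-1, 3)
    blocked = _inside_any(pts, obstacles).reshape(len(p0s), n_samples)
    return ~blocked.any(axis=1)


def _project_out(points: np.ndarray, obstacles, clearance: float) -> np.ndarray:
    """Push any point lying inside an obstacle to the nearest surface
    point plus a small outward clearance."""
    out = points.copy()
    for obs in obstacles:
        inside = _contains(obs, out)
        if not inside.any():
            continue
        closest, _, tid = closest_points_on_mesh(obs, out[inside])
        dirs = closest - out[inside]
        norms = np.linalg.norm(dirs, axis=1, keepdims=True)
        normals = obs.face_normals[tid]
        dirs = np.where(norms > 1e-9, dirs / np.maximum(norms, 1e-12), normals)
        out[inside] = closest + clearance * dirs
    return out


def _coarse_visibility_path(p0, p1, obstacles, seed_offset_frac: float = 0.04):
    """Shortest path on a visibility graph over offset obstacle-surface
    samples, used only to seed the taut-path refinement."""
    nodes = [p0, p1]
    for obs in obstacles:
        scale = float(np.linalg.norm(obs.extents)) / 2
        verts = obs.vertices
        step = max(1, len(verts) // 160)
        sub = np.arange(0, len(verts), step)
        offs = verts[sub] + seed_offset_frac * scale * obs.vertex_normals[sub]
        nodes.extend(offs)
    nodes = np.asarray(nodes)
    n = len(nodes)
    # candidate edges: endpoints to everything, surface samples to near neighbours
    d = np.linalg.norm(nodes[:, None, :] - nodes[None, :, :], axis=2)
    near = d < np.percentile(d[d > 0], 12.0) if n > 2 else d > 0
    near[0, :] = near[:, 0] = True
    near[1, :] = near[:, 1] = True
    ii, jj = np.nonzero(np.triu(near, k=1))
    free = _segments_free(nodes[ii], nodes[jj], obstacles, n_samples=8)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for a, b in zip(ii[free], jj[free]):
        g.add_edge(int(a), int(b), weight=float(d[a, b]))
    try:
        idx = nx.shortest_path(g, 0, 1, weight="weight")
    except nx.NetworkXNoPath:
        raise RuntimeError("wrapping path: visibility graph is disconnected")
    return nodes[idx]


def _resample_polyline(path: np.ndarray, n_points: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] < 1e-12:
        return np.repeat(path[:1], n_points, axis=0)
    si = np.linspace(0, s[-1], n_points)
    out = np.empty((n_points, 3))
    for k in range(3):
        out[:, k] = np.interp(si, s, path[:, k])
    return out


def _shortcut(path: np.ndarray, obstacles) -> np.ndarray:
    """Greedy farthest-visible shortcutting of a polyline."""
    keep = [0]
    i = 0
    n = len(path)
    while i < n - 1:
        lo, hi = i + 1, n - 1
        # exponential then binary search for the farthest visible j
        best = i + 1
        span = 1
        while i + span <= n - 1:
            j = i + span
            if _segments_free(path[i][None], path[j][None], obstacles)[0]:
                best = j
                span *= 2
            else:
                break
        lo, hi = best, min(i + span, n - 1)
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if _segments_free(path[i][None], path[mid][None], obstacles)[0]:
                lo = mid
            else:
                hi = mid - 1
        keep.append(lo)
        i = lo
    return path[keep]


def _polyline_length(path: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())


def wrapping_path(
    origin,
    insertion,
    obstacles,
    clearance_mm: float = 1e-3,
    n_points: int = 100,
    max_iter: int = 30,
    tol: float = 3e-6,
) -> np.ndarray:
    """Shortest obstacle-avoiding polyline from origin to insertion.

    A visibility-graph path seeds an iterative taut-string refinement:
    midpoint smoothing pulls the polyline straight, points falling inside
    an obstacle are projected back to its surface (+``clearance_mm``), and
    greedy shortcutting removes slack in free space, until the length
    stabilizes.
    """
    p0 = np.asarray(origin, dtype=float)
    p1 = np.asarray(insertion, dtype=float)
    obstacles = list(obstacles)
    if _inside_any(np.vstack([p0, p1]), obstacles).any():
        raise ValueError("ligament attachment lies inside an obstacle volume")
    if not obstacles or _segments_free(p0[None], p1[None], obstacles, n_samples=24)[0]:
        return np.vstack([p0, p1])

    path = _resample_polyline(_coarse_visibility_path(p0, p1, obstacles), n_points)
    length = _polyline_length(path)
    for _ in range(max_iter):
        for _ in range(10):  # smoothing sweeps
            path[1:-1] = 0.5 * (path[:-2] + path[2:])
            path[1:-1] = _project_out(path[1:-1], obstacles, clearance_mm)
        path = _shortcut(path, obstacles)
        path = _resample_polyline(path, n_points)
        path[1:-1] = _project_out(path[1:-1], obstacles, clearance_mm)
        new_length = _polyline_length(path)
        if abs(length - new_length) < tol * max(length, 1.0):
            length = new_length
            break
        length = new_length
    return path


def wrapping_path_length(origin, insertion, obstacles, **kwargs) -> float:
    """Length (mm) of the shortest wrapping path; equals the Euclidean
    endpoint distance when the straight segment is unobstructed."""
    return _polyline_length(wrapping_path(origin, insertion, obstacles, **kwargs))


# ---------------------------------------------------------------------------
# flexion sweeps and the tension protocol
# ---------------------------------------------------------------------------


def sweep_lengths(
    bundle: LigamentBundle,
    knee,
    kinematics: FlexionPoseSeries,
    implanted: bool = False,
    femoral_component_matrix: np.ndarray | None = None,
    tibial_component_matrix: np.ndarray | None = None,
) -> LigamentSweep:
    """Bundle length/strain/force at every kinematic frame.

    The femoral attachment and the femur obstacle ride the frame pose; the
    tibia is static.  ``implanted`` adds the component meshes (optionally
    transformed) to the obstacle set.  The 0° frame defines the reference
    length, so strain and force at 0° are zero by construction.
    """
    angles = kinematics.angles()
    if not np.isclose(angles, 0.0).any():
        raise ValueError("kinematics must include a 0 degree frame "
                         "(reference length undefined)")
    static_obs = [knee.tibia_mesh]
    if implanted and knee.tibial_component_mesh is not None:
        tc = knee.tibial_component_mesh.copy()
        if tibial_component_matrix is not None:
            tc.apply_transform(tibial_component_matrix)
        static_obs.append(tc)

    records = []
    lengths = {}
    for flex, pose in kinematics.frames:
        m = pose.matrix()
        femur = knee.femur_mesh.copy()
        femur.apply_transform(m)
        obstacles = [femur] + static_obs
        if implanted and knee.femoral_component_mesh is not None:
            fc = knee.femoral_component_mesh.copy()
            cm = m if femoral_component_matrix is None else m @ femoral_component_matrix
            fc.apply_transform(cm)
            obstacles.append(fc)
        origin_w = m[:3, :3] @ bundle.femoral_attachment + m[:3, 3]
        L = wrapping_path_length(origin_w, bundle.tibial_attachment, obstacles)
        lengths[flex] = L

    L0 = lengths[min(lengths, key=lambda a: abs(a))]
    bundle.reference_length_mm = L0
    for flex in angles:
        L = lengths[float(flex)]
        eps = (L - L0) / L0
        f = ligament_force(eps, bundle.stiffness_k_N, bundle.strain_constant_eps1)
        records.append((float(flex), float(L), float(eps), float(f)))
    return LigamentSweep(bundle_name=bundle.name, records=records)


def build_tension_protocol(
    sweeps: list[LigamentSweep], angles=TEST_ANGLE_GRID
) -> TensionProtocol:
    """Rig protocol: per test angle, applied tension = side baseline
    (130 N medial for aMCL/pMCL, 100 N lateral for iLCL) + computed bundle
    force, linearly interpolated onto the test grid."""
    rows = []
    for sweep in sweeps:
        base = BASELINE_TENSION_N[sweep.bundle_name]
        src_a = np.array([r[0] for r in sweep.records])
        src_f = np.array([r[3] for r in sweep.records])
        for a in angles:
            if a < src_a.min() - 1e-9 or a > src_a.max() + 1e-9:
                continue
            f = float(np.interp(a, src_a, src_f))
            rows.append({"flexion_deg": float(a), "bundle": sweep.bundle_name,
                         "force_N": f, "baseline_N": base, "applied_N": base + f})
    return TensionProtocol(table=pd.DataFrame(rows))
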