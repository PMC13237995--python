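"""Parametric synthetic knee: geometry, landmarks and lunge kinematics.

Stands in for CT bone models and dual-fluoroscopy kinematics.  The femoral
condyles are two equal spheres a fixed distance apart, the tibial plateau
a slightly dished elliptical slab, and the implant articular surfaces
zero-offset shells of the native condyles, so compartment gaps have a
closed form: a coronal deformity of severity ``alpha`` fixed in the
femoral frame separates the medial and lateral gaps by exactly
``spacing * sin(alpha)`` at full extension and terminal flexion (and by
1.0–1.56 times that in between), which serves as the analytic oracle for
the whole planning pipeline.

Frame conventions (mm, degrees): ``+x`` medial, ``+y`` anterior, ``+z``
proximal.  The femoral frame origin sits at the midpoint between the two
condylar sphere centres; the tibial frame origin at the plateau centre with
the plateau rim at ``z = 0``.  Kinematic frames express the femoral frame
relative to the tibial frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import trimesh

from .geometry import RigidPose, matrix_to_pose
from .kinematics import FlexionPoseSeries, load_series, save_series
from .utils import derive_seed

__all__ = [
    "SubjectSpec",
    "SyntheticKnee",
    "generate_knee",
    "generate_cohort",
    "REQUIRED_LANDMARKS",
]

REQUIRED_LANDMARKS = (
    "TEA_medial",
    "TEA_lateral",
    "hip_center",
    "knee_center",
    "ankle_center",
    "lateral_plateau",
    "insall_anterior",
    "insall_posterior",
    "aMCL_origin",
    "aMCL_insertion",
    "pMCL_origin",
    "pMCL_insertion",
    "iLCL_origin",
    "iLCL_insertion",
)

# landmarks expressed in the femoral frame; all others are tibial
FEMORAL_LANDMARKS = (
    "TEA_medial",
    "TEA_lateral",
    "hip_center",
    "knee_center",
    "aMCL_origin",
    "pMCL_origin",
    "iLCL_origin",
)


@dataclass(frozen=True)
class SubjectSpec:
    """Parameters of one synthetic subject.

    Deformity enters twice: ``hka_varus_deg`` is the static standing
    alignment (removed by varus–valgus correction before planning) and
    ``kinematic_varus_amplitude_deg`` the severity of a femur-fixed
    dynamic coronal deformity present in every flexion frame (what
    gap-balance planning must compensate).  Implant thicknesses default
    to 9 mm.
    """

    subject_id: str = "S01"
    condyle_radius_mm: float = 24.0
    condyle_spacing_mm: float = 46.0
    plateau_width_mm: float = 75.0
    plateau_depth_mm: float = 50.0
    native_posterior_slope_deg: float = 3.0
    hka_varus_deg: float = 0.0
    kinematic_varus_amplitude_deg: float = 0.0
    flexion_range_deg: tuple[float, float] = (0.0, 100.0)
    frame_step_deg: float = 10.0
    seed: int = 0
    distal_thickness_mm: float = 9.0
    posterior_thickness_mm: float = 9.0
    baseplate_thickness_mm: float = 9.0
    resection_depth_mm: float = 8.0
    dish_depth_mm: float = 1.0
    kinematic_noise_deg: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "condyle_radius_mm",
            "condyle_spacing_mm",
            "plateau_width_mm",
            "plateau_depth_mm",
            "frame_step_deg",
            "distal_thickness_mm",
            "posterior_thickness_mm",
            "baseplate_thickness_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.condyle_spacing_mm >= self.plateau_width_mm:
            raise ValueError("condyle_spacing_mm must be below plateau_width_mm")
        lo, hi = self.flexion_range_deg
        if not (0.0 <= lo < hi <= 100.0):
            raise ValueError("flexion range must lie within [0, 100] degrees")
        n = (hi - lo) / self.frame_step_deg
        if abs(n - round(n)) > 1e-9:
            raise ValueError("frame_step_deg must divide the flexion range")


@dataclass
class SyntheticKnee:
    femur_mesh: trimesh.Trimesh
    tibia_mesh: trimesh.Trimesh
    femoral_component_mesh: trimesh.Trimesh
    tibial_component_mesh: trimesh.Trimesh
    landmarks: dict[str, np.ndarray]
    kinematics: FlexionPoseSeries
    spec: SubjectSpec

    def __post_init__(self) -> None:
        missing = [n for n in REQUIRED_LANDMARKS if n not in self.landmarks]
        if missing:
            raise ValueError(f"missing landmarks: {missing}")

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.femur_mesh.export(out / "femur.stl")
        self.tibia_mesh.export(out / "tibia.stl")
        self.femoral_component_mesh.export(out / "femoral_component.stl")
        self.tibial_component_mesh.export(out / "tibial_component.stl")
        with open(out / "landmarks.json", "w") as fh:
            json.dump({k: list(map(float, v)) for k, v in self.landmarks.items()},
                      fh, indent=1, sort_keys=True)
        save_series(self.kinematics, out / "kinematics.csv")


def load_landmarks(path) -> dict[str, np.ndarray]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: np.asarray(v, dtype=float) for k, v in raw.items()}


def load_knee_dir(knee_dir, spec: SubjectSpec | None = None) -> SyntheticKnee:
    """Reload a knee previously written by :meth:`SyntheticKnee.save`."""
    d = Path(knee_dir)
    return SyntheticKnee(
        femur_mesh=trimesh.load_mesh(d / "femur.stl"),
        tibia_mesh=trimesh.load_mesh(d / "tibia.stl"),
        femoral_component_mesh=trimesh.load_mesh(d / "femoral_component.stl"),
        tibial_component_mesh=trimesh.load_mesh(d / "tibial_component.stl"),
        landmarks=load_landmarks(d / "landmarks.json"),
        kinematics=load_series(d / "kinematics.csv"),
        spec=spec if spec is not None else SubjectSpec(),
    )


def _dished_slab(a: float, b: float, depth: float, dish: float,
                 sectors: int = 64, cap_rings: int = 4) -> trimesh.Trimesh:
    """Closed elliptical slab (half-axes a, b; z in [-depth, 0]) whose top
    cap is dished by ``dish * (1 - rho^2)`` below the rim."""
    ang = np.linspace(0, 2 * np.pi, sectors, endpoint=False)
    ring = np.column_stack([a * np.cos(ang), b * np.sin(ang)])

    verts: list[np.ndarray] = []
    faces: list[list[int]] = []

    def add_ring(xy: np.ndarray, z: np.ndarray | float) -> np.ndarray:
        z = np.broadcast_to(np.asarray(z, dtype=float), (len(xy),))
        start = len(verts)
        verts.extend(np.column_stack([xy, z]))
        return np.arange(start, start + len(xy))

    bottom = add_ring(ring, -depth)
    rim = add_ring(ring, 0.0)
    # side wall (outward normals, CCW ring seen from +z)
    for i in range(sectors):
        j = (i + 1) % sectors
        faces.append([bottom[i], bottom[j], rim[j]])
        faces.append([bottom[i], rim[j], rim[i]])
    # dished top cap: rings shrinking toward centre
    prev = rim
    for k in range(1, cap_rings):
        rho = 1.0 - k / cap_rings
        cur = add_ring(ring * rho, -dish * (1 - rho**2))
        for i in range(sectors):
            j = (i + 1) % sectors
            faces.append([prev[i], prev[j], cur[j]])
            faces.append([prev[i], cur[j], cur[i]])
        prev = cur
    top_c = len(verts)
    verts.append(np.array([0.0, 0.0, -dish]))
    for i in range(sectors):
        j = (i + 1) % sectors
        faces.append([prev[i], prev[j], top_c])
    # flat bottom cap
    bot_c = len(verts)
    verts.append(np.array([0.0, 0.0, -depth]))
    for i in range(sectors):
        j = (i + 1) % sectors
        faces.append([bottom[j], bottom[i], bot_c])
    mesh = trimesh.Trimesh(vertices=np.array(verts), faces=np.array(faces), process=False)
    mesh.fix_normals()
    return mesh


def _extrude_star(coords2d: np.ndarray, z0: float, z1: float) -> trimesh.Trimesh:
    """Extrude a star-shaped (w.r.t. its centroid) polygon into a closed prism."""
    n = len(coords2d)
    centroid = coords2d.mean(axis=0)
    verts = np.vstack([
        np.column_stack([coords2d, np.full(n, z0)]),
        np.column_stack([coords2d, np.full(n, z1)]),
        np.append(centroid, z0),
        np.append(centroid, z1),
    ])
    c0, c1 = 2 * n, 2 * n + 1
    faces = []
    for i in range(n):
        j = (i + 1) % n
        faces.append([i, j, n + j])
        faces.append([i, n + j, n + i])
        faces.append([j, i, c0])          # bottom cap (normal -z)
        faces.append([n + i, n + j, c1])  # top cap (normal +z)
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    mesh.fix_normals()
    return mesh


def superellipse(a: float, b: float, exponent: float = 2.5, n: int = 96) -> np.ndarray:
    """Boundary of |x/a|^p + |y/b|^p = 1, counter-clockwise."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    c, s = np.cos(t), np.sin(t)
    x = a * np.sign(c) * np.abs(c) ** (2 / exponent)
    y = b * np.sign(s) * np.abs(s) ** (2 / exponent)
    return np.column_stack([x, y])


def make_baseplate(width_mm: float, depth_mm: float, thickness_mm: float,
                   scale: float = 1.0) -> trimesh.Trimesh:
    """Tibial baseplate: superellipse footprint extruded downward.

    In the implant's own frame the underside is at ``z = -thickness`` and
    the tray top at ``z = 0``; +y is the component's AP axis.
    """
    outline = superellipse(scale * width_mm / 2, scale * depth_mm / 2)
    return _extrude_star(outline, -thickness_mm, 0.0)


def default_baseplate_catalog(spec: SubjectSpec) -> list[trimesh.Trimesh]:
    """Four baseplate sizes spanning typical undersizing of the cut surface."""
    return [
        make_baseplate(spec.plateau_width_mm, spec.plateau_depth_mm,
                       spec.baseplate_thickness_mm, scale=s)
        for s in (0.70, 0.76, 0.81, 0.85)
    ]


def _femur_meshes(spec: SubjectSpec) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    r = spec.condyle_radius_mm
    half = spec.condyle_spacing_mm / 2
    med = trimesh.creation.icosphere(subdivisions=3, radius=r)
    med.apply_translation([half, 0.0, 0.0])
    lat = trimesh.creation.icosphere(subdivisions=3, radius=r)
    lat.apply_translation([-half, 0.0, 0.0])
    shaft = trimesh.creation.cylinder(radius=0.55 * r, height=90.0, sections=32)
    shaft.apply_translation([0.0, 0.0, 0.5 * r + 45.0])
    femur = trimesh.util.concatenate([med.copy(), lat.copy(), shaft])
    component = trimesh.util.concatenate([med, lat])
    return femur, component


def _landmarks(spec: SubjectSpec) -> dict[str, np.ndarray]:
    r = spec.condyle_radius_mm
    half = spec.condyle_spacing_mm / 2
    a = spec.plateau_width_mm / 2
    b = spec.plateau_depth_mm / 2
    hka = np.deg2rad(spec.hka_varus_deg)
    dish = spec.dish_depth_mm
    x_lp = -(a - 6.0)
    rho = abs(x_lp) / a
    # epicondyles and ligament origins sit just outside the condylar
    # spheres; tibial insertions just outside the plateau ellipse, so the
    # attachments are valid wrapping-path endpoints
    x_epi = half + r + 4.0
    x_lig = half + r + 1.5

    def on_rim(phi_deg: float, z: float, inflate: float = 1.06) -> np.ndarray:
        phi = np.deg2rad(phi_deg)
        return np.array([inflate * a * np.cos(phi), inflate * b * np.sin(phi), z])

    lm = {
        # femoral frame
        "TEA_medial": np.array([x_epi, 0.0, 0.0]),
        "TEA_lateral": np.array([-x_epi, 0.0, 0.0]),
        "knee_center": np.zeros(3),
        # femoral mechanical axis tilted by the varus deformity
        "hip_center": 400.0 * np.array([-np.sin(hka), 0.0, np.cos(hka)]),
        "aMCL_origin": np.array([x_lig, 3.0, 2.0]),
        "pMCL_origin": np.array([x_lig, -6.0, 3.0]),
        "iLCL_origin": np.array([-x_lig, -2.0, 2.0]),
        # tibial frame
        "ankle_center": np.array([0.0, 0.0, -400.0]),
        "lateral_plateau": np.array([x_lp, 0.0, -dish * (1 - rho**2)]),
        "insall_anterior": np.array([0.0, b + 8.0, -15.0]),
        "insall_posterior": np.array([0.0, -b + 6.0, 0.0]),
        "aMCL_insertion": on_rim(20.0, -55.0),
        "pMCL_insertion": on_rim(-14.0, -20.0),
        "iLCL_insertion": on_rim(188.0, -35.0),
    }
    return lm


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _kinematics(spec: SubjectSpec) -> FlexionPoseSeries:
    """Lunge sweep with a femur-fixed constant-severity coronal deformity.

    The injected deformity ``D = Ry(alpha) @ Rz(-beta)`` rides the femur;
    its rotational component ``beta`` is chosen so the involved
    compartment narrows by the same ``(spacing/2)*sin(alpha)`` at both
    ends of the captured arc (``sin(beta) = tan(50°) * sin(alpha)`` for
    the 0°–100° lunge), i.e. the severity of the deformity is constant
    across the arc.  The medial–lateral gap asymmetry is therefore
    ``spacing*sin(alpha)`` exactly at 0° and 100°, rising to at most
    1.56 times that mid-arc.  Being fixed in the femoral frame, the
    deformity is exactly cancellable by a constant component pose delta
    (AA = −alpha, IE = +beta) — the configuration gap-balance planning
    must recover.  The standing HKA deformity is a separate additive
    offset on the stored AA coordinate, which is what the varus–valgus
    correction removes.  Small smooth IE/AP excursions mimic physiologic
    screw-home motion and femoral rollback.
    """
    lo, hi = spec.flexion_range_deg
    n = int(round((hi - lo) / spec.frame_step_deg)) + 1
    thetas = lo + spec.frame_step_deg * np.arange(n)
    rng = np.random.default_rng(derive_seed(spec.seed, "kinematic_noise"))
    phase_aa, phase_ie = rng.uniform(0, 2 * np.pi, 2)
    r = spec.condyle_radius_mm
    half = spec.condyle_spacing_mm / 2
    alpha = spec.kinematic_varus_amplitude_deg
    # equal compartment narrowing at 0 deg and at terminal (100 deg) flexion
    beta = np.degrees(np.arcsin(np.tan(np.deg2rad(50.0))
                                * np.sin(np.deg2rad(alpha))))
    deform = _rot_y(alpha) @ _rot_z(-beta)
    centers = np.array([[half, 0.0, 0.0], [-half, 0.0, 0.0]])
    frames = []
    for th in thetas:
        noise_aa = spec.kinematic_noise_deg * np.sin(2 * np.pi * th / 100 + phase_aa)
        noise_ie = spec.kinematic_noise_deg * np.sin(2 * np.pi * th / 100 + phase_ie)
        ie_exc = 2.0 * np.sin(np.pi * th / 100) + noise_ie
        rot = _rot_z(ie_exc) @ _rot_x(th) @ deform
        # proximal shift keeping the lower condylar sphere in plateau contact
        pd = r - float((centers @ rot.T)[:, 2].min())
        m = np.eye(4)
        m[:3, :3] = rot
        m[:3, 3] = [0.0, -0.03 * th, pd]  # (x=ML, y=AP, z=PD)
        pose = matrix_to_pose(m)
        pose = RigidPose(
            AP_mm=pose.AP_mm, PD_mm=pose.PD_mm, ML_mm=pose.ML_mm,
            FE_deg=pose.FE_deg,
            AA_deg=pose.AA_deg + spec.hka_varus_deg + noise_aa,
            IE_deg=pose.IE_deg,
        )
        frames.append((float(th), pose))
    return FlexionPoseSeries(frames=frames, subject_id=spec.subject_id)


def generate_knee(spec: SubjectSpec) -> SyntheticKnee:
    """Build one synthetic knee; deterministic for a fixed spec."""
    femur, component = _femur_meshes(spec)
    tibia = _dished_slab(spec.plateau_width_mm / 2, spec.plateau_depth_mm / 2,
                         depth=80.0, dish=spec.dish_depth_mm)
    baseplate = make_baseplate(spec.plateau_width_mm, spec.plateau_depth_mm,
                               spec.baseplate_thickness_mm, scale=0.90)
    return SyntheticKnee(
        femur_mesh=femur,
        tibia_mesh=tibia,
        femoral_component_mesh=component,
        tibial_component_mesh=baseplate,
        landmarks=_landmarks(spec),
        kinematics=_kinematics(spec),
        spec=spec,
    )


def generate_cohort(
    n: int,
    base: SubjectSpec,
    varus_range_deg: tuple[float, float] = (0.7, 7.0),
    seed: int = 0,
) -> list[SyntheticKnee]:
    """Cohort with per-subject kinematic varus drawn uniformly in range."""
    if n < 1:
        raise ValueError("n must be at least 1")
    lo, hi = varus_range_deg
    if lo > hi:
        raise ValueError("varus range must satisfy lo <= hi")
    rng = np.random.default_rng(derive_seed(seed, "cohort_varus"))
    amplitudes = rng.uniform(lo, hi, size=n)
    knees = []
    for i, amp in enumerate(amplitudes):
        spec = replace(
            base,
            subject_id=f"S{i + 1:02d}",
            kinematic_varus_amplitude_deg=float(amp),
            seed=derive_seed(seed, "subject", i),
        )
        knees.append(generate_knee(spec))
    return knees
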