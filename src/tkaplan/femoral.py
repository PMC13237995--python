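"""Femoral component planning: morphology-based reference and gap balancing.

The morphology-based (MB) plan is a measured-resection reference: distal
and posterior cuts remove exactly the component thickness, the posterior
cut is parallel to the transepicondylar axis, and the distal cut is
perpendicular to the varus–valgus-corrected femoral mechanical axis, so
the component restores the native articular surface without any gap
feedback.

Gap-balance (GB) planning then perturbs the component pose in six degrees
of freedom to minimize the mean absolute medial–lateral gap difference

    loss = (1/n) Σ_i | |d_l| − |d_m| |_i

over a chosen set of flexion frames (full series, 0° only, or {0°, 90°}),
using CMA-ES started from the MB pose within anatomically bounded pose
deltas.  Gaps are the shortest signed distances from the medial and
lateral condylar surfaces of the component to the tibial resection plane;
negative values mean penetration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cmaes import cma_es_minimize
from .geometry import Plane, RigidPose, matrix_to_pose
from .kinematics import FlexionPoseSeries, StandingAlignment, resample

__all__ = [
    "FemoralMBPlan",
    "GapProfile",
    "GBConfig",
    "GBPlanResult",
    "build_mb_plan",
    "compute_gaps",
    "gap_loss",
    "optimize_gb",
    "recommend_insert",
    "compare_strategies",
    "STRATEGIES",
]

STRATEGIES = ("MB", "GB_full", "GB_standing", "GB_standing_90")

DEFAULT_INSERT_CATALOG_MM = (6.0, 8.0, 9.0, 10.0, 11.0, 12.0, 14.0)

# per-DOF search half-widths around the MB pose (AP, PD, ML mm; FE, AA, IE deg);
# the AA bound covers the 0.7°-7.0° varus adjustment range with margin
DEFAULT_SEARCH_BOUNDS = {
    "AP_mm": 3.0, "PD_mm": 3.0, "ML_mm": 3.0,
    "FE_deg": 3.0, "AA_deg": 8.0, "IE_deg": 8.0,
}
_DOF_ORDER = ("AP_mm", "PD_mm", "ML_mm", "FE_deg", "AA_deg", "IE_deg")


@dataclass
class FemoralMBPlan:
    component_pose: RigidPose
    distal_plane: Plane
    posterior_plane: Plane
    distal_thickness_mm: float
    posterior_thickness_mm: float


@dataclass
class GapProfile:
    """Per-frame medial/lateral gaps for one subject under one strategy."""

    records: list[tuple[float, float, float]]  # (flexion_deg, d_m_mm, d_l_mm)
    strategy_label: str = "MB"

    def __post_init__(self) -> None:
        if self.strategy_label not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy_label!r}")
        if any(not np.isfinite([m, l]).all() for _, m, l in self.records):
            raise ValueError("gap profile contains non-finite gaps")

    def angles(self) -> np.ndarray:
        return np.array([a for a, _, _ in self.records])

    def differences(self) -> np.ndarray:
        """Per-frame | |d_l| − |d_m| | in mm."""
        return np.array([abs(abs(l) - abs(m)) for _, m, l in self.records])

    def min_gap(self) -> float:
        return float(min(min(m, l) for _, m, l in self.records))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records, columns=["flexion_deg", "d_m_mm", "d_l_mm"])
        df["strategy"] = self.strategy_label
        return df


@dataclass(frozen=True)
class GBConfig:
    strategy: str = "GB_full"
    search_bounds: dict = field(default_factory=lambda: dict(DEFAULT_SEARCH_BOUNDS))
    population_size: int | None = None
    sigma0: float = 1.0
    max_evals: int = 1500
    seed: int = 0
    insert_catalog_mm: tuple[float, ...] = DEFAULT_INSERT_CATALOG_MM

    def __post_init__(self) -> None:
        if self.strategy not in ("GB_full", "GB_standing", "GB_standing_90"):
            raise ValueError(f"unknown GB strategy {self.strategy!r}")
        if any(v <= 0 for v in self.search_bounds.values()):
            raise ValueError("search bounds must be positive")
        if list(self.insert_catalog_mm) != sorted(self.insert_catalog_mm):
            raise ValueError("insert catalog must be sorted ascending")


@dataclass
class GBPlanResult:
    optimized_pose: RigidPose
    delta_from_mb: RigidPose
    loss_mm: float
    gap_profile: GapProfile
    recommended_insert_mm: float
    insert_warning: bool
    distal_plane: Plane

    def to_dict(self) -> dict:
        return {
            "optimized_pose": self.optimized_pose.as_array().tolist(),
            "delta_from_mb": self.delta_from_mb.as_array().tolist(),
            "loss_mm": self.loss_mm,
            "recommended_insert_mm": self.recommended_insert_mm,
            "insert_warning": self.insert_warning,
            "gaps": self.gap_profile.to_dataframe().to_dict(orient="list"),
            "distal_plane": self.distal_plane.to_dict(),
        }


def _condyle_masks(component: trimesh.Trimesh, tol: float = 1e-6):
    """Medial (+x) / lateral (−x) vertex masks in the component frame;
    midline vertices belong to neither condyle."""
    x = component.vertices[:, 0]
    medial = x > tol
    lateral = x < -tol
    if not medial.any() or not lateral.any():
        raise ValueError("component cannot be partitioned into medial/lateral condyles")
    return medial, lateral


def build_mb_plan(
    femur: trimesh.Trimesh,
    landmarks: dict[str, np.ndarray],
    alignment: StandingAlignment,
    component: trimesh.Trimesh,
    distal_thickness_mm: float = 9.0,
    posterior_thickness_mm: float = 9.0,
) -> FemoralMBPlan:
    """Morphology-based reference plan in the femoral frame.

    The distal resection plane lies ``distal_thickness_mm`` above the most
    distal condylar point, perpendicular to the corrected mechanical axis;
    the posterior plane lies ``posterior_thickness_mm`` anterior to the
    most posterior condylar point, parallel to the TEA.  The component is
    posed so its articular surface restores the resected condyles: its
    own distal/posterior extremes coincide with the native ones, its ML
    axis is aligned with the TEA and its proximal axis with the corrected
    mechanical axis.
    """
    for name in ("TEA_medial", "TEA_lateral", "hip_center", "knee_center"):
        if name not in landmarks:
            raise ValueError(f"landmark {name!r} is required for MB planning")

    tea = np.asarray(landmarks["TEA_medial"], float) - np.asarray(
        landmarks["TEA_lateral"], float
    )
    tea /= np.linalg.norm(tea)
    mech = np.asarray(landmarks["hip_center"], float) - np.asarray(
        landmarks["knee_center"], float
    )
    mech /= np.linalg.norm(mech)
    # varus-valgus correction: rotate the raw mechanical axis back into
    # neutral about the AP axis by the standing HKA angle
    hka = np.deg2rad(alignment.hka_deg)
    c, s = np.cos(hka), np.sin(hka)
    rot_y = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    mech = rot_y @ mech

    # orthonormal component axes: z along corrected axis, x along TEA
    z_ax = mech
    x_ax = tea - (tea @ z_ax) * z_ax
    x_ax /= np.linalg.norm(x_ax)
    y_ax = np.cross(z_ax, x_ax)
    rot = np.column_stack([x_ax, y_ax, z_ax])

    # native condylar extremes along the plan axes
    fv = femur.vertices
    distal_native = fv @ z_ax
    posterior_native = fv @ y_ax
    z_low = float(distal_native.min())
    y_low = float(posterior_native.min())

    distal_plane = Plane((z_low + distal_thickness_mm) * z_ax, z_ax)
    posterior_plane = Plane((y_low + posterior_thickness_mm) * y_ax, y_ax)

    # seat the component: its own extremes (in its frame) land on the
    # native extremes; centre it on the TEA midpoint along x
    cv = component.vertices
    comp_z_low = float(cv[:, 2].min())
    comp_y_low = float(cv[:, 1].min())
    mid = 0.5 * (
        np.asarray(landmarks["TEA_medial"], float)
        + np.asarray(landmarks["TEA_lateral"], float)
    )
    t = (
        (mid @ x_ax - float(cv[:, 0].mean())) * x_ax
        + (y_low - comp_y_low) * y_ax
        + (z_low - comp_z_low) * z_ax
    )
    m = np.eye(4)
    m[:3, :3] = rot
    m[:3, 3] = t
    pose = matrix_to_pose(m)
    return FemoralMBPlan(
        component_pose=pose,
        distal_plane=distal_plane,
        posterior_plane=posterior_plane,
        distal_thickness_mm=distal_thickness_mm,
        posterior_thickness_mm=posterior_thickness_mm,
    )


def compute_gaps(
    component: trimesh.Trimesh,
    pose: RigidPose,
    frame: tuple[float, RigidPose],
    tibial_plane: Plane,
) -> tuple[float, float]:
    """Medial and lateral gaps (mm) at one kinematic frame.

    Each gap is the minimum signed distance from that condyle's vertices
    (component pose composed with the frame's femur-in-tibia pose) to the
    tibial resection plane; negative values indicate penetration.
    """
    medial, lateral = _condyle_masks(component)
    _, frame_pose = frame
    m = frame_pose.matrix() @ pose.matrix()
    n = tibial_plane.normal
    # signed distance of transformed vertices: (R v + t) . n - p0 . n
    proj = component.vertices @ (m[:3, :3].T @ n) + m[:3, 3] @ n - tibial_plane.point @ n
    return float(proj[medial].min()), float(proj[lateral].min())


def gap_loss(profile: GapProfile) -> float:
    """Mean per-frame absolute medial–lateral gap difference (mm)."""
    if not profile.records:
        raise ValueError("empty gap profile")
    return float(profile.differences().mean())


def _profile_for_pose(
    component, pose, series: FlexionPoseSeries, plane: Plane, label: str
) -> GapProfile:
    recs = []
    for fr in series.frames:
        d_m, d_l = compute_gaps(component, pose, fr, plane)
        recs.append((fr[0], d_m, d_l))
    return GapProfile(records=recs, strategy_label=label)


def _strategy_frames(kinematics: FlexionPoseSeries, strategy: str) -> FlexionPoseSeries:
    if strategy == "GB_full":
        return kinematics
    if strategy == "GB_standing":
        return resample(kinematics, [0.0])
    if strategy == "GB_standing_90":
        return resample(kinematics, [0.0, 90.0])
    raise ValueError(f"unknown strategy {strategy!r}")


def recommend_insert(
    profile: GapProfile, catalog=DEFAULT_INSERT_CATALOG_MM
) -> tuple[float, bool]:
    """Largest catalog thickness not exceeding the smallest gap over all
    frames; if even the thinnest insert overstuffs, returns it with a
    warning flag."""
    if not len(catalog):
        raise ValueError("insert catalog is empty")
    catalog = sorted(catalog)
    min_gap = profile.min_gap()
    fitting = [t for t in catalog if t <= min_gap + 1e-9]
    if fitting:
        return float(fitting[-1]), False
    return float(catalog[0]), True


def optimize_gb(
    mb: FemoralMBPlan,
    kinematics: FlexionPoseSeries,
    tibial_plane: Plane,
    component: trimesh.Trimesh,
    config: GBConfig = GBConfig(),
) -> GBPlanResult:
    """CMA-ES pose refinement from the MB pose.

    Kinematics must already be varus–valgus corrected.  Pose deltas are
    expressed in the component's six DOFs and composed with the MB pose;
    candidates outside the search bounds are penalized to infeasibility.
    The returned loss never exceeds the MB-pose loss (elitism).
    """
    opt_series = _strategy_frames(kinematics, config.strategy)
    bounds = np.array([config.search_bounds[k] for k in _DOF_ORDER])
    mb_matrix = mb.component_pose.matrix()

    def pose_of(delta: np.ndarray) -> RigidPose:
        return matrix_to_pose(mb_matrix @ RigidPose.from_array(delta).matrix())

    def loss_of(delta: np.ndarray) -> float:
        pose = pose_of(delta)
        total = 0.0
        for fr in opt_series.frames:
            d_m, d_l = compute_gaps(component, pose, fr, tibial_plane)
            total += abs(abs(d_l) - abs(d_m))
        return total / len(opt_series)

    def objective(delta: np.ndarray) -> float:
        excess = np.abs(delta) - bounds
        if (excess > 0).any():
            return 1e3 + float(excess[excess > 0].sum())
        return loss_of(delta)

    res = cma_es_minimize(
        objective,
        x0=np.zeros(6),
        sigma0=config.sigma0,
        popsize=config.population_size,
        max_evals=config.max_evals,
        seed=config.seed,
    )
    if not np.isfinite(res.f_best) or res.f_best >= 1e3:
        raise RuntimeError("gap-balance search found no feasible candidate")

    # elitism: never worse than the MB start
    delta = res.x_best if res.f_best <= objective(np.zeros(6)) else np.zeros(6)
    pose = pose_of(delta)
    profile = _profile_for_pose(component, pose, kinematics, tibial_plane,
                                label=config.strategy)
    opt_profile = _profile_for_pose(component, pose, opt_series, tibial_plane,
                                    label=config.strategy)
    insert, warn = recommend_insert(profile, config.insert_catalog_mm)
    return GBPlanResult(
        optimized_pose=pose,
        delta_from_mb=RigidPose.from_array(delta),
        loss_mm=gap_loss(opt_profile),
        gap_profile=profile,
        recommended_insert_mm=insert,
        insert_warning=warn,
        distal_plane=mb.distal_plane,
    )


def mb_gap_profile(
    mb: FemoralMBPlan,
    kinematics: FlexionPoseSeries,
    tibial_plane: Plane,
    component: trimesh.Trimesh,
) -> GapProfile:
    """Gap profile of the unoptimized MB plan over the full series."""
    return _profile_for_pose(component, mb.component_pose, kinematics,
                             tibial_plane, label="MB")


def _paired_cohens_d(diff: np.ndarray) -> float:
    if len(diff) < 2:
        return 0.0
    sd = diff.std(ddof=1)
    return float(diff.mean() / sd) if sd > 0 else float("inf") if diff.mean() else 0.0


def compare_strategies(
    profiles_a: list[GapProfile], profiles_b: list[GapProfile]
) -> pd.DataFrame:
    """Per-angle paired comparison of two strategies across subjects.

    At each flexion angle the per-subject gap differences of strategy A
    and B are compared with the two-sided paired Wilcoxon signed-rank test
    (exact distribution when sample size permits and differences are
    untied); p-values are Holm-adjusted across angles.  Effect size is
    Cohen's d of the paired differences.
    """
    if len(profiles_a) != len(profiles_b) or not profiles_a:
        raise ValueError("strategy comparison requires equal, nonempty cohorts")
    angles = profiles_a[0].angles()
    for p in profiles_a + profiles_b:
        if not np.array_equal(p.angles(), angles):
            raise ValueError("gap profiles are not on a common flexion-angle grid")
    a = np.array([p.differences() for p in profiles_a])  # (subjects, angles)
    b = np.array([p.differences() for p in profiles_b])

    rows = []
    for j, ang in enumerate(angles):
        diff = a[:, j] - b[:, j]
        if np.allclose(diff, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(a[:, j], b[:, j], alternative="two-sided",
                                     method="auto")
        rows.append({"flexion_deg": float(ang), "statistic": float(stat),
                     "p_value": float(p), "effect_size_d": _paired_cohens_d(diff)})
    table = pd.DataFrame(rows)
    _, p_holm, _, _ = multipletests(table["p_value"], method="holm")
    table["p_holm"] = p_holm
    table["significant"] = table["p_holm"] < 0.05
    return table


def holm_adjust(p_values) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p-values."""
    _, adj, _, _ = multipletests(np.asarray(p_values, dtype=float), method="holm")
    return adj
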