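import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from tkaplan.femoral import (
    GapProfile,
    GBConfig,
    build_mb_plan,
    compare_strategies,
    compute_gaps,
    gap_loss,
    holm_adjust,
    mb_gap_profile,
    optimize_gb,
    recommend_insert,
)
from tkaplan.geometry import Plane, RigidPose
from tkaplan.kinematics import StandingAlignment, correct_varus_valgus
from tkaplan.synthetic import SubjectSpec, generate_knee
from tkaplan.tibial import build_resection_plane


def _planning_context(knee):
    spec = knee.spec
    al = StandingAlignment(spec.hka_varus_deg, spec.native_posterior_slope_deg)
    plane = build_resection_plane(knee.tibia_mesh, knee.landmarks, al)
    corrected = correct_varus_valgus(knee.kinematics, al)
    mb = build_mb_plan(knee.femur_mesh, knee.landmarks, al, knee.femoral_component_mesh)
    return al, plane, corrected, mb


class TestMBPlan:
    def test_planes_match_component_thickness(self, symmetric_knee):
        knee = symmetric_knee
        al = StandingAlignment(0.0, knee.spec.native_posterior_slope_deg)
        mb = build_mb_plan(knee.femur_mesh, knee.landmarks, al,
                           knee.femoral_component_mesh, 9.0, 9.0)
        z_low = knee.femur_mesh.vertices[:, 2].min()
        # distal plane 9 mm above the most distal condylar point, normal +z
        assert np.allclose(mb.distal_plane.normal, [0, 0, 1], atol=1e-9)
        assert mb.distal_plane.point @ mb.distal_plane.normal == pytest.approx(
            z_low + 9.0
        )
        # posterior plane parallel to the TEA (x axis)
        assert abs(mb.posterior_plane.normal @ np.array([1.0, 0, 0])) < 1e-9
        # component pose restores the native articular surface
        assert np.abs(mb.component_pose.as_array()).max() < 1e-6

    def test_posterior_plane_follows_rotated_tea(self, symmetric_knee):
        knee = symmetric_knee
        lm = {k: v.copy() for k, v in knee.landmarks.items()}
        rot = np.deg2rad(3.0)
        m = np.array([[np.cos(rot), -np.sin(rot), 0],
                      [np.sin(rot), np.cos(rot), 0], [0, 0, 1.0]])
        lm["TEA_medial"] = m @ lm["TEA_medial"]
        lm["TEA_lateral"] = m @ lm["TEA_lateral"]
        mb = build_mb_plan(knee.femur_mesh, lm, StandingAlignment(),
                           knee.femoral_component_mesh)
        tea = lm["TEA_medial"] - lm["TEA_lateral"]
        assert abs(mb.posterior_plane.normal @ tea) < 1e-9

    def test_zero_thickness_planes_tangent_to_condyles(self, symmetric_knee):
        knee = symmetric_knee
        mb = build_mb_plan(knee.femur_mesh, knee.landmarks, StandingAlignment(),
                           knee.femoral_component_mesh, 0.0, 0.0)
        z_low = knee.femur_mesh.vertices[:, 2].min()
        assert mb.distal_plane.point @ mb.distal_plane.normal == pytest.approx(z_low)

    def test_missing_landmarks_rejected(self, symmetric_knee):
        with pytest.raises(ValueError, match="TEA"):
            build_mb_plan(symmetric_knee.femur_mesh, {}, StandingAlignment(),
                          symmetric_knee.femoral_component_mesh)


class TestComputeGaps:
    plane = Plane([0, 0, -8], [0, 0, 1])

    def _component(self):
        med = trimesh.creation.icosphere(subdivisions=3, radius=24)
        med.apply_translation([23, 0, 0])
        lat = trimesh.creation.icosphere(subdivisions=3, radius=24)
        lat.apply_translation([-23, 0, 0])
        return trimesh.util.concatenate([med, lat])

    def test_symmetric_frame_gives_equal_gaps(self):
        comp = self._component()
        frame = (0.0, RigidPose(PD_mm=24.0))
        d_m, d_l = compute_gaps(comp, RigidPose(), frame, self.plane)
        assert d_m == pytest.approx(d_l, abs=1e-9)

    def test_varus_frame_matches_small_angle_oracle(self):
        comp = self._component()
        frame = (0.0, RigidPose(PD_mm=24.0, AA_deg=3.0))
        d_m, d_l = compute_gaps(comp, RigidPose(), frame, self.plane)
        assert abs(d_l - d_m) == pytest.approx(46 * np.sin(np.deg2rad(3)), abs=0.2)

    def test_plane_normal_translation_shifts_both_gaps(self):
        comp = self._component()
        base = compute_gaps(comp, RigidPose(),
                            (0.0, RigidPose(PD_mm=24.0, AA_deg=2.0)), self.plane)
        up = compute_gaps(comp, RigidPose(),
                          (0.0, RigidPose(PD_mm=26.0, AA_deg=2.0)), self.plane)
        assert up[0] - base[0] == pytest.approx(2.0, abs=1e-9)
        assert up[1] - base[1] == pytest.approx(2.0, abs=1e-9)

    def test_unpartitionable_component_rejected(self):
        comp = trimesh.creation.icosphere(subdivisions=2, radius=5)
        comp.apply_translation([10, 0, 0])  # all vertices medial
        with pytest.raises(ValueError, match="partition"):
            compute_gaps(comp, RigidPose(), (0.0, RigidPose()), self.plane)


class TestGapLoss:
    def test_balanced_profile_is_zero(self):
        profile = GapProfile([(a, 2.0, 2.0) for a in range(0, 101, 10)], "MB")
        assert gap_loss(profile) == 0.0

    def test_direct_evaluation(self):
        profile = GapProfile([(0.0, 3.0, 1.0), (10.0, 2.0, 4.0)], "MB")
        assert gap_loss(profile) == pytest.approx(2.0)

    def test_uses_absolute_gap_values(self):
        profile = GapProfile([(0.0, -3.0, 1.0)], "MB")
        assert gap_loss(profile) == pytest.approx(2.0)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            gap_loss(GapProfile([], "MB"))

    @settings(max_examples=60, deadline=None)
    @given(gaps=st.lists(st.tuples(st.floats(0, 20), st.floats(0, 20)),
                         min_size=1, max_size=12),
           offset=st.floats(0, 5))
    def test_relabeling_and_common_offset_invariance(self, gaps, offset):
        base = GapProfile([(i * 10.0, m, l) for i, (m, l) in enumerate(gaps)], "MB")
        swapped = GapProfile([(i * 10.0, l, m) for i, (m, l) in enumerate(gaps)], "MB")
        shifted = GapProfile(
            [(i * 10.0, m + offset, l + offset) for i, (m, l) in enumerate(gaps)], "MB"
        )
        assert gap_loss(base) == pytest.approx(gap_loss(swapped))
        assert gap_loss(base) == pytest.approx(gap_loss(shifted))


class TestRecommendInsert:
    def test_largest_fitting_thickness(self):
        profile = GapProfile([(0.0, 10.4, 11.0)], "GB_full")
        assert recommend_insert(profile, [9, 10, 11, 12]) == (10.0, False)

    def test_overstuffed_falls_back_with_warning(self):
        profile = GapProfile([(0.0, 8.0, 9.5)], "GB_full")
        assert recommend_insert(profile, [9, 10, 11]) == (9.0, True)

    def test_exact_fit(self):
        profile = GapProfile([(0.0, 11.0, 11.0)], "GB_full")
        assert recommend_insert(profile, [9, 10, 11, 12]) == (11.0, False)

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            recommend_insert(GapProfile([(0.0, 9.0, 9.0)], "GB_full"), [])


class TestOptimizeGB:
    def test_symmetric_knee_stays_at_mb(self, symmetric_knee):
        _, plane, corrected, mb = _planning_context(symmetric_knee)
        res = optimize_gb(mb, corrected, plane, symmetric_knee.femoral_component_mesh,
                          GBConfig(seed=1))
        assert res.loss_mm < 0.1
        assert np.abs(res.delta_from_mb.as_array()[3:]).max() < 1.0

    def test_recovers_injected_varus(self, varus3_knee):
        _, plane, corrected, mb = _planning_context(varus3_knee)
        res = optimize_gb(mb, corrected, plane, varus3_knee.femoral_component_mesh,
                          GBConfig(seed=2))
        assert res.loss_mm < 0.2
        assert res.delta_from_mb.AA_deg == pytest.approx(-3.0, abs=0.5)

    def test_standing_only_balances_extension_but_not_flexion(self, varus3_knee):
        _, plane, corrected, mb = _planning_context(varus3_knee)
        full = optimize_gb(mb, corrected, plane, varus3_knee.femoral_component_mesh,
                           GBConfig(strategy="GB_full", seed=3))
        standing = optimize_gb(mb, corrected, plane,
                               varus3_knee.femoral_component_mesh,
                               GBConfig(strategy="GB_standing", seed=3))
        assert standing.loss_mm < 0.1  # balanced at the 0 deg target
        assert standing.gap_profile.differences().mean() > 3 * full.gap_profile.differences().mean()

    def test_elitism_never_worse_than_mb(self, varus3_knee):
        _, plane, corrected, mb = _planning_context(varus3_knee)
        mb_loss = gap_loss(mb_gap_profile(mb, corrected, plane,
                                          varus3_knee.femoral_component_mesh))
        res = optimize_gb(mb, corrected, plane, varus3_knee.femoral_component_mesh,
                          GBConfig(seed=4, max_evals=60))
        assert gap_loss(res.gap_profile) <= mb_loss + 1e-9

    def test_seeded_reproducibility(self, varus3_knee):
        _, plane, corrected, mb = _planning_context(varus3_knee)
        a = optimize_gb(mb, corrected, plane, varus3_knee.femoral_component_mesh,
                        GBConfig(seed=5, max_evals=300))
        b = optimize_gb(mb, corrected, plane, varus3_knee.femoral_component_mesh,
                        GBConfig(seed=5, max_evals=300))
        assert np.array_equal(a.delta_from_mb.as_array(), b.delta_from_mb.as_array())


def _profiles(values_by_subject, label="MB"):
    return [
        GapProfile([(10.0 * i, 5.0, 5.0 + v) for i, v in enumerate(vals)], label)
        for vals in values_by_subject
    ]


class TestCompareStrategies:
    def test_identical_profiles_not_significant(self):
        vals = [[1.0, 2.0, 3.0]] * 8
        table = compare_strategies(_profiles(vals), _profiles(vals, "GB_full"))
        assert (table["p_holm"] == 1.0).all()
        assert not table["significant"].any()

    def test_uniform_direction_floor_p_value(self):
        """Eight paired differences of the same sign reach the exact
        two-sided signed-rank floor p = 2/2^8 = 0.0078125."""
        rng = np.random.default_rng(0)
        a = [[2.0 + 0.01 * rng.standard_normal()] for _ in range(8)]
        b = [[0.0] for _ in range(8)]
        table = compare_strategies(_profiles(a), _profiles(b, "GB_full"))
        assert table["p_value"].iloc[0] == pytest.approx(0.0078125, abs=1e-10)

    def test_holm_textbook_vector(self):
        adj = holm_adjust([0.001, 0.04, 0.2])
        assert np.allclose(adj, [0.003, 0.08, 0.2])

    def test_unpaired_input_rejected(self):
        with pytest.raises(ValueError):
            compare_strategies(_profiles([[1.0]] * 3), _profiles([[1.0]] * 4, "GB_full"))
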