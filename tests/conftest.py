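import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from tkaplan.femoral import GBConfig, build_mb_plan, mb_gap_profile, optimize_gb
from tkaplan.kinematics import StandingAlignment, correct_varus_valgus
from tkaplan.synthetic import SubjectSpec, default_baseplate_catalog, generate_cohort, generate_knee
from tkaplan.tibial import SAConfig, build_resection_plane, optimize_tibial_placement
from tkaplan.utils import derive_seed


@pytest.fixture(scope="session")
def varus3_knee():
    """One knee with a 3-degree dynamic coronal deformity."""
    return generate_knee(SubjectSpec(kinematic_varus_amplitude_deg=3.0, seed=11))


@pytest.fixture(scope="session")
def symmetric_knee():
    return generate_knee(SubjectSpec(seed=12))


def plan_knee(knee, seed=0, strategies=("GB_full",), sa_iterations=200, max_evals=1500):
    """Tibial + femoral planning for one knee; shared across tests."""
    spec = knee.spec
    alignment = StandingAlignment(spec.hka_varus_deg, spec.native_posterior_slope_deg)
    tibial = optimize_tibial_placement(
        knee.tibia_mesh, default_baseplate_catalog(spec), knee.landmarks, alignment,
        sa=SAConfig(max_iterations=sa_iterations,
                    seed=derive_seed(seed, spec.subject_id, "sa")),
    )
    corrected = correct_varus_valgus(knee.kinematics, alignment)
    mb = build_mb_plan(knee.femur_mesh, knee.landmarks, alignment,
                       knee.femoral_component_mesh,
                       spec.distal_thickness_mm, spec.posterior_thickness_mm)
    profiles = {"MB": mb_gap_profile(mb, corrected, tibial.resection_plane,
                                     knee.femoral_component_mesh)}
    gb = {}
    for strategy in strategies:
        res = optimize_gb(
            mb, corrected, tibial.resection_plane, knee.femoral_component_mesh,
            GBConfig(strategy=strategy, max_evals=max_evals,
                     seed=derive_seed(seed, spec.subject_id, "gb", strategy)),
        )
        gb[strategy] = res
        profiles[strategy] = res.gap_profile
    return {"tibial": tibial, "mb": mb, "gb": gb, "profiles": profiles,
            "corrected": corrected, "knee": knee}


@pytest.fixture(scope="session")
def cohort8():
    """The 8-knee study cohort: spacing 46 mm, plateau 75 mm, injected
    dynamic varus uniform in [0.7, 7.0] degrees."""
    return generate_cohort(8, SubjectSpec(), (0.7, 7.0), seed=1)


@pytest.fixture(scope="session")
def cohort8_plans(cohort8):
    return [plan_knee(k, seed=1) for k in cohort8]
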