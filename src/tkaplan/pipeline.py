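"""End-to-end planning pipeline on synthetic cohorts.

Generates a cohort, runs tibial placement, builds the MB reference and
the three gap-balance variants per subject, optionally sweeps ligament
lengths, and writes plan JSONs, gap-difference curves, strategy comparison
tables and a run manifest.  Every stochastic stage draws its seed from the
global seed and the (subject, stage) pair, so single subjects are
independently reproducible.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .femoral import (
    GBConfig,
    build_mb_plan,
    compare_strategies,
    gap_loss,
    mb_gap_profile,
    optimize_gb,
)
from .kinematics import StandingAlignment, correct_varus_valgus
from .ligament import LigamentBundle, build_tension_protocol, sweep_lengths
from .synthetic import SubjectSpec, SyntheticKnee, default_baseplate_catalog, generate_cohort
from .tibial import SAConfig, TibialConstraints, optimize_tibial_placement
from .utils import derive_seed

__all__ = ["PipelineConfig", "run_pipeline", "summarize_cohort"]

GB_STRATEGIES = ("GB_full", "GB_standing", "GB_standing_90")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortBlock(_Strict):
    n: int = 8
    varus_range_deg: tuple[float, float] = (0.7, 7.0)
    subject_overrides: dict = {}


class TibialBlock(_Strict):
    rotation_limit_deg: float = 5.0
    overhang_limit_mm: float = 2.0
    resection_depth_mm: float = 8.0
    match_native_slope: bool = True
    sa_max_iterations: int = 200
    sa_initial_temperature: float = 5.0
    sa_cooling_rate: float = 0.97


class GBBlock(_Strict):
    max_evals: int = 1500
    population_size: Optional[int] = None
    sigma0: float = 1.0
    strategies: tuple[str, ...] = GB_STRATEGIES


class ReportBlock(_Strict):
    figures: bool = True
    ligaments: bool = False
    ligament_implanted: bool = False


class PipelineConfig(_Strict):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    seed: int = 1
    cohort: CohortBlock = CohortBlock()
    tibial: TibialBlock = TibialBlock()
    gb: GBBlock = GBBlock()
    report: ReportBlock = ReportBlock()


def _stage(name: str, subject: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(
                    f"pipeline stage '{name}' failed for subject {subject}: {exc}"
                ) from exc
            return False

    return _Ctx()


def _plan_subject(knee: SyntheticKnee, cfg: PipelineConfig) -> dict:
    spec = knee.spec
    sid = spec.subject_id
    alignment = StandingAlignment(
        hka_deg=spec.hka_varus_deg,
        posterior_slope_deg=spec.native_posterior_slope_deg,
    )
    constraints = TibialConstraints(
        rotation_limit_deg=cfg.tibial.rotation_limit_deg,
        overhang_limit_mm=cfg.tibial.overhang_limit_mm,
        resection_depth_mm=cfg.tibial.resection_depth_mm,
        match_native_slope=cfg.tibial.match_native_slope,
    )

    with _stage("tibial_planning", sid):
        tibial = optimize_tibial_placement(
            knee.tibia_mesh,
            default_baseplate_catalog(spec),
            knee.landmarks,
            alignment,
            constraints,
            SAConfig(
                max_iterations=cfg.tibial.sa_max_iterations,
                initial_temperature=cfg.tibial.sa_initial_temperature,
                cooling_rate=cfg.tibial.sa_cooling_rate,
                seed=derive_seed(cfg.seed, sid, "tibial_sa"),
            ),
        )

    with _stage("kinematic_correction", sid):
        corrected = correct_varus_valgus(knee.kinematics, alignment)

    with _stage("mb_planning", sid):
        mb = build_mb_plan(
            knee.femur_mesh, knee.landmarks, alignment,
            knee.femoral_component_mesh,
            distal_thickness_mm=spec.distal_thickness_mm,
            posterior_thickness_mm=spec.posterior_thickness_mm,
        )
        profiles = {
            "MB": mb_gap_profile(mb, corrected, tibial.resection_plane,
                                 knee.femoral_component_mesh)
        }

    gb_results = {}
    for strategy in cfg.gb.strategies:
        with _stage(f"gb_planning[{strategy}]", sid):
            res = optimize_gb(
                mb, corrected, tibial.resection_plane, knee.femoral_component_mesh,
                GBConfig(
                    strategy=strategy,
                    max_evals=cfg.gb.max_evals,
                    population_size=cfg.gb.population_size,
                    sigma0=cfg.gb.sigma0,
                    seed=derive_seed(cfg.seed, sid, "gb", strategy),
                ),
            )
            gb_results[strategy] = res
            profiles[strategy] = res.gap_profile

    subject = {
        "subject_id": sid,
        "injected_varus_deg": spec.kinematic_varus_amplitude_deg,
        "tibial": tibial,
        "mb": mb,
        "gb": gb_results,
        "profiles": profiles,
    }

    if cfg.report.ligaments:
        with _stage("ligament_sweep", sid):
            sweeps = [
                sweep_lengths(
                    LigamentBundle.from_landmarks(name, knee.landmarks),
                    knee, corrected, implanted=cfg.report.ligament_implanted,
                )
                for name in ("aMCL", "pMCL", "iLCL")
            ]
            subject["ligament_sweeps"] = sweeps
            subject["tension_protocol"] = build_tension_protocol(sweeps)
    return subject


def summarize_cohort(subjects: list[dict]) -> pd.DataFrame:
    """Mean ± sd summary of PCI, Insall deviation, GB pose deltas and mean
    gap difference per strategy (sd is 0 for a single subject)."""
    if not subjects:
        raise ValueError("no subjects to summarize")
    rows = {}

    def add(name: str, values) -> None:
        v = np.asarray(values, dtype=float)
        rows[name] = {"mean": float(v.mean()),
                      "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                      "n": len(v)}

    add("pci_percent", [s["tibial"].pci_percent for s in subjects])
    add("insall_deviation_deg", [abs(s["tibial"].rotation_deg) for s in subjects])
    strategies = sorted({k for s in subjects for k in s["profiles"]})
    for strat in strategies:
        add(f"mean_gap_diff_mm[{strat}]",
            [s["profiles"][strat].differences().mean() for s in subjects])
    gb_keys = sorted({k for s in subjects for k in s.get("gb", {})})
    for strat in gb_keys:
        deltas = np.array([s["gb"][strat].delta_from_mb.as_array() for s in subjects])
        for j, dof in enumerate(("AP_mm", "PD_mm", "ML_mm", "FE_deg", "AA_deg", "IE_deg")):
            add(f"gb_delta[{strat}][{dof}]", deltas[:, j])
    out = pd.DataFrame(rows).T
    out.index.name = "quantity"
    return out


def _write_figures(subjects, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strategies = list(subjects[0]["profiles"])
    fig, ax = plt.subplots(figsize=(6, 4))
    for strat in strategies:
        angles = subjects[0]["profiles"][strat].angles()
        diffs = np.array([s["profiles"][strat].differences() for s in subjects])
        ax.plot(angles, diffs.mean(axis=0), marker="o", label=strat)
    ax.set_xlabel("flexion (deg)")
    ax.set_ylabel("| |d_l| - |d_m| | (mm)")
    ax.legend()
    ax.set_title("Cohort-mean medial-lateral gap difference")
    fig.tight_layout()
    fig.savefig(out / "gap_differences.png", dpi=120)
    plt.close(fig)

    if "ligament_sweeps" in subjects[0]:
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
        for k, name in enumerate(("aMCL", "pMCL", "iLCL")):
            for s in subjects:
                sweep = next(w for w in s["ligament_sweeps"] if w.bundle_name == name)
                df = sweep.to_dataframe()
                axes[k].plot(df.flexion_deg, df.length_mm, alpha=0.6)
            axes[k].set_title(name)
            axes[k].set_xlabel("flexion (deg)")
        axes[0].set_ylabel("length (mm)")
        fig.tight_layout()
        fig.savefig(out / "ligament_lengths.png", dpi=120)
        plt.close(fig)


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the full planning workflow on a synthetic cohort.

    Returns the report bundle (subjects, summary table, per-angle strategy
    comparisons); when ``out_dir`` is given, also writes plan JSONs, CSV
    tables, figures and a manifest.  Byte-identical on re-run for a fixed
    config.
    """
    base = SubjectSpec(**config.cohort.subject_overrides)
    knees = generate_cohort(
        config.cohort.n, base, config.cohort.varus_range_deg, seed=config.seed
    )
    subjects = [_plan_subject(k, config) for k in knees]
    summary = summarize_cohort(subjects)

    comparisons = {}
    for strat in config.gb.strategies:
        comparisons[f"{strat}_vs_MB"] = compare_strategies(
            [s["profiles"][strat] for s in subjects],
            [s["profiles"]["MB"] for s in subjects],
        )

    bundle = {"subjects": subjects, "summary": summary, "comparisons": comparisons}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in subjects:
            doc = {
                "subject_id": s["subject_id"],
                "injected_varus_deg": s["injected_varus_deg"],
                "tibial_plan": s["tibial"].to_dict(),
                "mb_pose": s["mb"].component_pose.as_array().tolist(),
                "gb_plans": {k: v.to_dict() for k, v in s["gb"].items()},
                "mb_gaps": s["profiles"]["MB"].to_dataframe().to_dict(orient="list"),
            }
            with open(out / f"plan_{s['subject_id']}.json", "w") as fh:
                json.dump(doc, fh, indent=1, sort_keys=True)
            if "tension_protocol" in s:
                s["tension_protocol"].table.to_csv(
                    out / f"tension_protocol_{s['subject_id']}.csv", index=False
                )
        summary.to_csv(out / "summary.csv")
        for name, table in comparisons.items():
            table.to_csv(out / f"comparison_{name}.csv", index=False)
        manifest = {
            "tkaplan_version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "config": config.model_dump(),
            "subjects": [s["subject_id"] for s in subjects],
            "subject_specs": [asdict(k.spec) for k in knees],
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        if config.report.figures:
            _write_figures(subjects, out)
    return bundle
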