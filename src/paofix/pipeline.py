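"""Cohort-scale orchestration: gait -> MSK -> FE -> failure -> statistics.

Mirrors the study protocol at desk scale: generate repeated walking trials
per subject, keep the typical trials by clustering, run inverse dynamics and
muscle recruitment, pick representative subjects from their hip-reaction
curves, couple the phase-averaged hip and muscle forces onto the synthetic
pelvis-fragment-screw FE model for all eight gait phases and the requested
fixation layouts, and summarize peak stresses, weighted mean stress and
yield loads, ending with the between-layout comparison of the high-stress
phase statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import failure_analysis as fa
from . import fe_solver as fe
from . import gait_processing as gp
from . import io as pio
from . import msk_model as mm
from . import synthetic_data as sd

G_ACCEL = 9.81

#: phases 2-4 carry the largest loads during stance ("high-stress phases")
HIGH_STRESS_PHASES = (1, 2, 3)       # 0-based indices of phases 2..4


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Configuration of a full cohort run (all seeds derive from ``seed``)."""

    groups: tuple = ("healthy", "postop")
    n_subjects: int = 3
    n_trials: int = 5                # walking repeats per subject
    k_typical: int = 3               # typical trials kept by clustering
    k_subjects: int = 2              # representative subjects for FE
    fixations: tuple = ("IS", "TS")
    edge_size_mm: float = 5.0
    callus_margin_mm: float = fe.DEFAULT_CALLUS_MARGIN_MM
    callus_degradation: float = fe.DEFAULT_CALLUS_DEGRADATION
    tensile_limit: float = fa.DEFAULT_TENSILE_LIMIT
    compressive_limit: float = fa.DEFAULT_COMPRESSIVE_LIMIT
    increment_N: float = fa.DEFAULT_LOAD_INCREMENT_N
    fail_fraction: float = fa.DEFAULT_FAIL_FRACTION
    delete_failed: bool = True
    noise_sd: float = 0.02
    phase_boundaries: tuple | None = None
    out_dir: str | None = None
    seed: int = 0
    write_meshes: bool = False

    def phase_set(self) -> gp.PhaseSet:
        return gp.PhaseSet(self.phase_boundaries) if self.phase_boundaries else gp.PhaseSet()


def _subject_seed(global_seed: int, group_idx: int, subject: int, trial: int) -> int:
    return (global_seed * 1_000_003 + group_idx * 10_007 + subject * 101 + trial) % (2**31 - 1)


# ---------------------------------------------------------------------------
# MSK stage
# ---------------------------------------------------------------------------

def run_subject(profile: sd.CohortProfile, n_trials: int, k_typical: int,
                phase_set: gp.PhaseSet, seed: int, group_idx: int, subject: int) -> dict:
    """Generate trials, keep typical ones, run IDA; return subject summary."""
    trials, curves = [], []
    for j in range(n_trials):
        p = sd.profile_for_group(
            profile.group, seed=_subject_seed(seed, group_idx, subject, j),
            body_mass_kg=profile.body_mass_kg, noise_sd=profile.noise_sd,
        )
        t = sd.generate_gait_trial(p)
        trials.append(t)
        curves.append(gp.normalize_to_cycle(t))
    typical = gp.select_typical_trials(curves, k=k_typical, seed=seed)
    idas = [mm.run_ida(curves[i], phase_set=phase_set) for i in typical]

    hrf_curves = np.array([r.hrf_magnitude_bw for r in idas])
    mean_hrf = hrf_curves.mean(axis=0)
    roms = [gp.extract_rom(curves[i]) for i in typical]
    agg = _average_aggregates([r.phase_aggregates for r in idas])
    return {
        "group": profile.group,
        "subject": subject,
        "typical_trials": [int(i) for i in typical],
        "mean_hrf_bw": mean_hrf,
        "hrf_peaks": gp.extract_hrf_peaks(mean_hrf),
        "rom_deg": {k: float(np.mean([r[k] for r in roms])) for k in roms[0]},
        "phase_aggregates": agg,
        "body_mass_kg": profile.body_mass_kg,
    }


def _average_aggregates(aggs: list[dict]) -> dict:
    out = {
        "phase_names": aggs[0]["phase_names"],
        "hrf_vector_bw": np.mean([a["hrf_vector_bw"] for a in aggs], axis=0).tolist(),
        "hrf_magnitude_bw": np.mean([a["hrf_magnitude_bw"] for a in aggs], axis=0).tolist(),
        "group_force_vectors_bw": {},
    }
    for g in aggs[0]["group_force_vectors_bw"]:
        out["group_force_vectors_bw"][g] = np.mean(
            [a["group_force_vectors_bw"][g] for a in aggs], axis=0
        ).tolist()
    return out


# ---------------------------------------------------------------------------
# FE stage
# ---------------------------------------------------------------------------

def phase_load_cases(mesh: fe.TetMesh, aggregates: dict, body_mass_kg: float) -> list[fe.LoadCase]:
    """Eight phase load cases from IDA aggregates coupled onto the mesh.

    The joint patch carries the hip contact force on the pelvis (negative of
    the force on the femur); each muscle-group region carries the reaction
    of its resultant pull.
    """
    bw = body_mass_kg * G_ACCEL
    cases = []
    hrf = np.asarray(aggregates["hrf_vector_bw"])
    gvec = aggregates["group_force_vectors_bw"]
    for k in range(len(aggregates["phase_names"])):
        region_forces = {"joint_contact": -hrf[k] * bw}
        for g, vecs in gvec.items():
            region_forces[f"region_{g}"] = -np.asarray(vecs[k]) * bw
        cases.append(fe.build_load_case(mesh, phase_id=k + 1, region_forces=region_forces))
    return cases


def run_fixation_fe(
    config: RunConfig,
    fixation: str,
    aggregates: dict,
    body_mass_kg: float,
    edge_size_mm: float | None = None,
) -> dict:
    """Solve all 8 phases for one fixation layout and run the yield protocol
    at the maximum-load phase; returns stress summary + yield result."""
    spec = sd.SyntheticGeometrySpec(
        fixation=fixation,
        target_edge_size_mm=edge_size_mm or config.edge_size_mm,
        seed=config.seed,
    )
    mesh = sd.generate_pelvis_mesh(spec)
    hu = sd.generate_density_field(mesh, noise_sd=25.0, seed=config.seed)
    materials = fe.assign_materials(
        mesh, hu,
        callus_margin_mm=config.callus_margin_mm,
        degradation=config.callus_degradation,
    )
    model = fe.FEModel(mesh, materials)
    cases = phase_load_cases(mesh, aggregates, body_mass_kg)
    fields = [model.solve(c) for c in cases]
    summary = fa.summarize_phases([f.von_mises for f in fields],
                                  aggregates["phase_names"])

    hrf_mag = np.asarray(aggregates["hrf_magnitude_bw"])
    max_phase = int(np.argmax(hrf_mag))
    # the incremented "gait load" is the hip contact force of the max phase
    joint_N = float(np.linalg.norm(aggregates["hrf_vector_bw"][max_phase])) * body_mass_kg * G_ACCEL
    yres = fa.compute_yield_load(
        mesh, materials, cases[max_phase], body_mass_kg,
        reference_load_N=joint_N,
        tensile_limit=config.tensile_limit,
        compressive_limit=config.compressive_limit,
        increment_N=config.increment_N,
        fail_fraction=config.fail_fraction,
        delete_failed=config.delete_failed,
    )
    return {
        "fixation": fixation,
        "mesh": mesh,
        "stress_summary": summary,
        "max_load_phase": max_phase + 1,
        "yield": yres,
        "n_load_cases": len(cases),
    }


def compare_fixation_yields(
    config: RunConfig,
    aggregates: dict,
    body_mass_kg: float,
    fixations: tuple = ("IS", "TS", "2S-a", "2S-b", "2S-c", "2S-d", "2S-e"),
) -> dict:
    """Yield loads for all requested layouts on the same synthetic geometry.

    Returns {fixation: yield_load_bw} plus the parent three-screw layout for
    each two-screw variant, for side-by-side stability comparison.
    """
    yields = {}
    for fx in fixations:
        run = run_fixation_fe(config, fx, aggregates, body_mass_kg)
        yields[fx] = run["yield"].yield_load_bw
    return {
        "yield_load_bw": yields,
        "parents": {fx: sd.PARENT_LAYOUT.get(fx) for fx in fixations},
    }


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    diff_of_means_MPa: float
    se_MPa: float
    ci95_MPa: tuple
    F: float
    p: float

    def to_json_dict(self) -> dict:
        return {
            "groups": [self.label_a, self.label_b],
            "n": [self.n_a, self.n_b],
            "diff_of_means_MPa": self.diff_of_means_MPa,
            "se_MPa": self.se_MPa,
            "ci95_MPa": list(self.ci95_MPa),
            "F": self.F,
            "p": self.p,
        }


def compare_fixations(samples_a, samples_b, label_a="A", label_b="B") -> ComparisonResult:
    """Difference of means with SE/CI and a one-way F test between two
    groups of p100 samples (pooled over the high-stress phases)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise PipelineError("compare", "need at least 2 samples per group")
    diff = float(a.mean() - b.mean())
    se = float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size))
    dof = a.size + b.size - 2
    tcrit = stats.t.ppf(0.975, dof)
    if se > 0:
        ci = (diff - tcrit * se, diff + tcrit * se)
    else:
        ci = (diff, diff)
    F, p = stats.f_oneway(a, b)
    if not np.isfinite(F):
        F, p = 0.0, 1.0
    return ComparisonResult(
        label_a=label_a, label_b=label_b, n_a=int(a.size), n_b=int(b.size),
        diff_of_means_MPa=diff, se_MPa=se, ci95_MPa=ci, F=float(F), p=float(p),
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_cohort_pipeline(config: RunConfig) -> dict:
    """Execute generate -> process -> MSK -> FE -> statistics -> reports.

    Returns a manifest of all artifacts and summary statistics; fully
    reproducible for a fixed ``config.seed``.  Groups without surgery
    (healthy) contribute MSK summaries only; FE/failure stages run for the
    operated groups across the configured fixation layouts.
    """
    phase_set = config.phase_set()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_seed": config.seed, "stages": [], "artifacts": [],
                      "groups": {}, "fe_runs": [], "comparisons": {}}

    try:
        subject_summaries: dict[str, list] = {}
        for gi, group in enumerate(config.groups):
            profile = sd.profile_for_group(group, noise_sd=config.noise_sd)
            subs = []
            for s in range(config.n_subjects):
                subs.append(run_subject(profile, config.n_trials, config.k_typical,
                                        phase_set, config.seed, gi, s))
            subject_summaries[group] = subs
            manifest["groups"][group] = {
                "n_subjects": len(subs),
                "rom_deg": {k: float(np.mean([x["rom_deg"][k] for x in subs]))
                            for k in subs[0]["rom_deg"]},
                "hrf_peak1_bw_mean": float(np.mean(
                    [x["hrf_peaks"]["peak1_bw"] for x in subs])),
            }
        manifest["stages"].append("msk")
    except Exception as exc:
        raise PipelineError("msk", str(exc)) from exc

    operated = [g for g in config.groups if g != "healthy"]
    if operated:
        try:
            group = operated[0]
            subs = subject_summaries[group]
            hrf_list = [s["mean_hrf_bw"] for s in subs]
            k = min(config.k_subjects, len(hrf_list))
            reps = gp.cluster_subjects_by_hrf(hrf_list, k=k, seed=config.seed)
            manifest["representative_subjects"] = [int(i) for i in reps]
            manifest["stages"].append("clustering")
        except Exception as exc:
            raise PipelineError("clustering", str(exc)) from exc

        try:
            p100_samples: dict[str, list] = {fx: [] for fx in config.fixations}
            for rep in reps:
                subj = subs[rep]
                for fx in config.fixations:
                    run = run_fixation_fe(config, fx, subj["phase_aggregates"],
                                          subj["body_mass_kg"])
                    summary = run["stress_summary"]
                    entry = {
                        "group": group,
                        "subject": int(rep),
                        "fixation": fx,
                        "n_load_cases": run["n_load_cases"],
                        "p100_MPa": [float(x) for x in summary.p100_MPa],
                        "WMV_s100_MPa": summary.wmv_s100_MPa,
                        "max_load_phase": run["max_load_phase"],
                        "yield_load_N": run["yield"].yield_load_N,
                        "yield_load_bw": run["yield"].yield_load_bw,
                        "yield_capped": run["yield"].capped,
                    }
                    manifest["fe_runs"].append(entry)
                    p100_samples[fx].extend(summary.p100_MPa[list(HIGH_STRESS_PHASES)])
                    if out_dir and config.write_meshes:
                        inp = out_dir / f"mesh_{fx}_subject{rep}.inp"
                        pio.write_inp(run["mesh"], inp)
                        manifest["artifacts"].append(inp.name)
            manifest["stages"].append("fe")

            fx_names = list(config.fixations)
            if len(fx_names) >= 2:
                cmp_res = compare_fixations(
                    p100_samples[fx_names[0]], p100_samples[fx_names[1]],
                    label_a=fx_names[0], label_b=fx_names[1],
                )
                manifest["comparisons"][f"{fx_names[0]}_vs_{fx_names[1]}"] = cmp_res.to_json_dict()
            manifest["stages"].append("statistics")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("fe", str(exc)) from exc

    if out_dir:
        summary_path = out_dir / "summary.json"
        pio.write_json(manifest, summary_path)
        manifest["artifacts"].append(summary_path.name)
    return manifest
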