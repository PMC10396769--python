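"""Peak-stress statistics, mesh-convergence protocol and yield-load analysis.

Three evaluation tools for solved pelvis-fixation FE models:

* ``p100_mean`` — mean of the 100 largest integration-point von Mises
  stresses, a robust "mean peak stress" summary per gait phase.
* ``wmv_s100`` — the weighted mean value of stress across the eight gait
  phases, WMV = sum_i p100_i * (p_i / S_p), where p_i is the peak stress of
  phase i and S_p = sum_i p_i: phases that load the construct harder weigh
  more.
* mesh convergence — start at a coarse edge size and refine in fixed steps
  until the maximum von Mises stress changes by less than a tolerance
  (variation rate measured against the previous, coarser mesh).
* yield load — starting from a gait-phase load case, grow the load in fixed
  (10 N) increments; a bone element fails by the maximum principal strain
  criterion (tensile or compressive limit), and the yield load is the load
  at which failed bone volume reaches a set fraction (1%) of total bone
  volume.  Failed elements can be deleted (stiffness knocked down) with
  re-solution between increments, or the linear-scaling shortcut can be
  used when deletion is off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fe_solver import FEModel, LoadCase, MaterialField, TetMesh

#: default bone yield strains (dimensionless): tensile and compressive
DEFAULT_TENSILE_LIMIT = 0.0073
DEFAULT_COMPRESSIVE_LIMIT = 0.0104

DEFAULT_LOAD_INCREMENT_N = 10.0
DEFAULT_FAIL_FRACTION = 0.01


class InputError(ValueError):
    pass


class DegenerateWeightsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Peak-stress statistics
# ---------------------------------------------------------------------------

def p100_mean(von_mises: np.ndarray, k: int = 100) -> dict:
    """Mean of the ``k`` largest von Mises values (all values if fewer).

    Returns the mean plus metadata flagging short inputs.
    """
    v = np.asarray(von_mises, dtype=float).ravel()
    if v.size == 0:
        raise InputError("empty stress field")
    used = min(k, v.size)
    top = np.partition(v, v.size - used)[v.size - used:]
    return {
        "p100_MPa": float(top.mean()),
        "n_used": int(used),
        "truncated": used < k,
    }


def wmv_s100(p100_per_phase: np.ndarray, peaks_per_phase: np.ndarray) -> float:
    """Phase-peak-weighted mean of the per-phase p100 statistics.

    WMV = sum_i p100_i * p_i / S_p with S_p = sum_i p_i; a convex
    combination of the p100 values, so min(p100) <= WMV <= max(p100).
    """
    p100 = np.asarray(p100_per_phase, dtype=float)
    peaks = np.asarray(peaks_per_phase, dtype=float)
    if p100.shape != peaks.shape:
        raise InputError("p100 and peak vectors must have matching length")
    if np.any(peaks < 0):
        raise InputError("phase peak stresses must be non-negative")
    s_p = peaks.sum()
    if s_p <= 0:
        raise DegenerateWeightsError("sum of phase peaks is zero; weights undefined")
    return float(np.sum(p100 * peaks) / s_p)


@dataclass
class StressSummary:
    """Per-phase peak-stress statistics for one fixation model."""

    p100_MPa: np.ndarray             # (8,)
    peak_MPa: np.ndarray             # (8,) single max per phase
    phase_names: list[str] = field(default_factory=list)

    @property
    def s_p(self) -> float:
        return float(self.peak_MPa.sum())

    @property
    def wmv_s100_MPa(self) -> float:
        return wmv_s100(self.p100_MPa, self.peak_MPa)

    def to_json_dict(self) -> dict:
        return {
            "p100_MPa": [float(x) for x in self.p100_MPa],
            "peak_MPa": [float(x) for x in self.peak_MPa],
            "S_p_MPa": self.s_p,
            "WMV_s100_MPa": self.wmv_s100_MPa,
            "phase_names": list(self.phase_names),
        }


def summarize_phases(von_mises_per_phase: list[np.ndarray], phase_names=None) -> StressSummary:
    """StressSummary from raw per-phase integration-point stress fields."""
    p100 = np.array([p100_mean(v)["p100_MPa"] for v in von_mises_per_phase])
    peaks = np.array([float(np.max(v)) for v in von_mises_per_phase])
    return StressSummary(p100_MPa=p100, peak_MPa=peaks,
                         phase_names=list(phase_names or []))


# ---------------------------------------------------------------------------
# Mesh convergence
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    sizes_mm: list
    max_von_mises_MPa: list
    element_counts: list
    variation_rates_percent: list    # None for the first entry
    selected_size_mm: float | None
    converged: bool

    def to_json_dict(self) -> dict:
        return {
            "sizes_mm": self.sizes_mm,
            "max_von_mises_MPa": self.max_von_mises_MPa,
            "element_counts": self.element_counts,
            "variation_rates_percent": self.variation_rates_percent,
            "selected_size_mm": self.selected_size_mm,
            "converged": self.converged,
        }


def run_mesh_convergence(
    case_factory,
    start_mm: float = 4.0,
    step_mm: float = 0.5,
    tol_percent: float = 1.0,
    size_floor_mm: float = 0.5,
) -> ConvergenceReport:
    """Refine the mesh in fixed steps until max von Mises stabilises.

    ``case_factory(size_mm)`` returns the solved maximum von Mises stress
    (MPa) at that edge size, or a ``(stress, element_count)`` pair.  The
    variation rate at each refinement is ``100*|s_prev - s_cur|/s_prev``
    (previous = coarser mesh); the first size whose rate drops below
    ``tol_percent`` is selected, and one confirmation step is recorded when
    the floor allows.
    """
    if not start_mm > step_mm > 0:
        raise InputError("need start > step > 0")
    sizes, stresses, counts, rates = [], [], [], []
    selected = None
    size = start_mm
    while size >= size_floor_mm - 1e-9:
        out = case_factory(size)
        stress, count = out if isinstance(out, tuple) else (out, None)
        sizes.append(float(size))
        stresses.append(float(stress))
        counts.append(count)
        if len(stresses) == 1:
            rates.append(None)
        else:
            prev = stresses[-2]
            rate = 100.0 * abs(prev - stresses[-1]) / prev if prev != 0 else 0.0
            rates.append(float(rate))
            if selected is None and rate < tol_percent:
                selected = float(size)
            elif selected is not None:
                break                     # confirmation step recorded
        size = round(size - step_mm, 12)
    return ConvergenceReport(
        sizes_mm=sizes,
        max_von_mises_MPa=stresses,
        element_counts=counts,
        variation_rates_percent=rates,
        selected_size_mm=selected,
        converged=selected is not None,
    )


# ---------------------------------------------------------------------------
# Incremental yield-load simulation
# ---------------------------------------------------------------------------

@dataclass
class YieldResult:
    yield_load_N: float | None
    yield_load_bw: float | None
    iterations: list                 # (load_N, failed_volume_fraction)
    failed_elements: np.ndarray
    capped: bool
    strain_limits: tuple
    meta: dict = field(default_factory=dict)


def _failure_mask(principal: np.ndarray, tensile: float, compressive: float) -> np.ndarray:
    """Maximum principal strain criterion: tensile or compressive exceedance."""
    return (principal[:, 0] > tensile) | (principal[:, 2] < -compressive)


def _criticality(principal: np.ndarray, tensile: float, compressive: float) -> np.ndarray:
    """Per-element strain-to-limit ratio: in a linear model the element
    fails once the load scale grows by 1/criticality."""
    c = np.maximum(principal[:, 0] / tensile, -principal[:, 2] / compressive)
    return np.maximum(c, 0.0)


def compute_yield_load(
    mesh: TetMesh,
    materials: MaterialField,
    loadcase: LoadCase,
    body_mass_kg: float,
    tensile_limit: float = DEFAULT_TENSILE_LIMIT,
    compressive_limit: float = DEFAULT_COMPRESSIVE_LIMIT,
    increment_N: float = DEFAULT_LOAD_INCREMENT_N,
    fail_fraction: float = DEFAULT_FAIL_FRACTION,
    delete_failed: bool = True,
    load_cap_bw: float = 20.0,
    reference_load_N: float | None = None,
) -> YieldResult:
    """Incremental yield-load prediction for a fixation load case.

    The base case is the given gait-phase load; its reference magnitude
    (default: resultant applied force) grows in ``increment_N`` steps.
    Bone elements failing the principal-strain criterion accumulate volume;
    yield is declared when failed bone volume reaches ``fail_fraction`` of
    total bone volume.  With ``delete_failed`` the failed elements lose
    their stiffness (knocked down to a vanishing modulus) and the model is
    re-solved, letting damage redistribute load; increments where the
    linear model predicts no new failure are skipped in one jump, which
    leaves the reported yield identical to stepping one increment at a
    time.  Loads are reported in N and in body-weight multiples.
    """
    if tensile_limit <= 0 or compressive_limit <= 0 or increment_N <= 0:
        raise InputError("strain limits and increment must be positive")
    vols = mesh.element_volumes()
    bone = ~materials.screw_mask
    total_bone_vol = vols[bone].sum()

    if reference_load_N is None:
        reference_load_N = float(np.linalg.norm(loadcase.nodal_forces.sum(axis=0)))
    if reference_load_N <= 0:
        raise InputError("load case has zero resultant; no reference load to scale")

    bw = body_mass_kg * 9.81
    cap_N = load_cap_bw * bw
    base_N = float(reference_load_N)

    E_work = materials.E.copy()
    failed = np.zeros(mesh.n_elements, dtype=bool)
    iterations: list[tuple[float, float]] = []
    load = base_N

    def failed_fraction() -> float:
        return float(vols[failed].sum() / total_bone_vol)

    while load <= cap_N + 1e-9:
        work_mat = MaterialField(
            E=E_work, nu=materials.nu, rho=materials.rho,
            screw_mask=materials.screw_mask, callus_mask=materials.callus_mask,
        )
        model = FEModel(mesh, work_mat)
        result = model.solve(loadcase.scaled(load / base_N))
        crit = _criticality(result.principal_strains, tensile_limit, compressive_limit)
        crit[failed | ~bone] = 0.0

        newly = _failure_mask(result.principal_strains, tensile_limit, compressive_limit)
        newly &= bone & ~failed
        if newly.any():
            failed |= newly
            iterations.append((float(load), failed_fraction()))
            if failed_fraction() >= fail_fraction:
                return YieldResult(
                    yield_load_N=float(load),
                    yield_load_bw=float(load / bw),
                    iterations=iterations,
                    failed_elements=np.where(failed)[0],
                    capped=False,
                    strain_limits=(tensile_limit, compressive_limit),
                    meta={"delete_failed": delete_failed, "base_load_N": base_N},
                )
            if delete_failed:
                E_work = np.where(failed, 1e-6, E_work)
                continue   # re-solve at the same load with degraded stiffness
        # no (further) failures at this load: jump to the first increment at
        # which the current linear response fails a new element
        cmax = crit.max()
        if cmax <= 0:
            break
        next_scale = (load / base_N) / cmax
        next_load = np.ceil(max(next_scale * base_N, load + increment_N) / increment_N) * increment_N
        iterations.append((float(load), failed_fraction()))
        load = float(next_load)

    return YieldResult(
        yield_load_N=None,
        yield_load_bw=None,
        iterations=iterations,
        failed_elements=np.where(failed)[0],
        capped=True,
        strain_limits=(tensile_limit, compressive_limit),
        meta={"delete_failed": delete_failed, "base_load_N": base_N,
              "load_cap_N": float(cap_N)},
    )


def yield_load_linear_shortcut(
    mesh: TetMesh,
    materials: MaterialField,
    loadcase: LoadCase,
    body_mass_kg: float,
    tensile_limit: float = DEFAULT_TENSILE_LIMIT,
    compressive_limit: float = DEFAULT_COMPRESSIVE_LIMIT,
    increment_N: float = DEFAULT_LOAD_INCREMENT_N,
    fail_fraction: float = DEFAULT_FAIL_FRACTION,
    reference_load_N: float | None = None,
) -> YieldResult:
    """No-deletion yield load from one linear solve.

    With deletion off, strains scale linearly with load, so the yield load
    is the smallest increment multiple at which the volume of elements with
    criticality >= base/load reaches the failure fraction.
    """
    vols = mesh.element_volumes()
    bone = ~materials.screw_mask
    total_bone_vol = vols[bone].sum()
    if reference_load_N is None:
        reference_load_N = float(np.linalg.norm(loadcase.nodal_forces.sum(axis=0)))
    model = FEModel(mesh, materials)
    result = model.solve(loadcase)
    crit = _criticality(result.principal_strains, tensile_limit, compressive_limit)

    # order bone elements by the load scale at which each fails
    c_bone = crit[bone]
    v_bone = vols[bone]
    order = np.argsort(-c_bone)
    cum_vol = np.cumsum(v_bone[order])
    reach = int(np.searchsorted(cum_vol, fail_fraction * total_bone_vol))
    if reach >= c_bone.size or c_bone[order][reach] <= 0:
        return YieldResult(
            yield_load_N=None, yield_load_bw=None, iterations=[],
            failed_elements=np.array([], dtype=int), capped=True,
            strain_limits=(tensile_limit, compressive_limit),
            meta={"delete_failed": False},
        )
    scale = 1.0 / c_bone[order][reach]
    load = float(np.ceil(scale * reference_load_N / increment_N) * increment_N)
    bw = body_mass_kg * 9.81
    bone_ids = np.where(bone)[0]
    failed = bone_ids[crit[bone] * (load / reference_load_N) >= 1.0]
    return YieldResult(
        yield_load_N=load,
        yield_load_bw=float(load / bw),
        iterations=[(load, float(vols[failed].sum() / total_bone_vol))],
        failed_elements=failed,
        capped=False,
        strain_limits=(tensile_limit, compressive_limit),
        meta={"delete_failed": False, "base_load_N": float(reference_load_N)},
    )
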