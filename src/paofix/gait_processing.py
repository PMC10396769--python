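"""Gait-cycle processing: normalization, phase segmentation, curve clustering.

A gait trial is a time series of hip angles (three anatomical planes) and
ground reactions recorded over at least one full gait cycle.  All downstream
analysis works on curves resampled to 101 points spanning 0-100% of the
cycle (heel strike to ipsilateral heel strike).  The cycle is further divided
into the eight functional phases of the Rancho Los Amigos (RLA)
classification, which drive phase-wise load averaging in the finite-element
stage.

Two clustering selections are supported, both k-medoids on z-scored,
concatenated curves: picking "typical" trials out of repeated walking trials
of one subject, and picking representative subjects from their hip-reaction
force curves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

N_CYCLE_SAMPLES = 101

#: Default RLA phase boundaries in percent of gait cycle.  The eight
#: functional phases are standard Rancho Los Amigos values; they are
#: configurable because clinical conventions vary by a few percent.
DEFAULT_RLA_BOUNDARIES: tuple[float, ...] = (0.0, 2.0, 12.0, 31.0, 50.0, 62.0, 75.0, 87.0, 100.0)

RLA_PHASE_NAMES: tuple[str, ...] = (
    "initial_contact",
    "loading_response",
    "midstance",
    "terminal_stance",
    "pre_swing",
    "initial_swing",
    "midswing",
    "terminal_swing",
)


class GaitEventError(ValueError):
    """Raised when a trial lacks the gait events an operation needs."""


class ParameterError(ValueError):
    """Raised for out-of-range analysis parameters (e.g. k > n trials)."""


@dataclass
class GaitTrial:
    """Raw gait time series for one walking trial.

    Angles are in degrees, ordered (sagittal, frontal, transverse); ground
    reaction force in N and moment in N*m with components (x anterior,
    y vertical, z lateral) in the pelvis-aligned lab frame.  ``events``
    holds heel-strike and toe-off times in seconds.
    """

    time: np.ndarray                 # (n,) s, strictly increasing
    angles_deg: np.ndarray           # (n, 3)
    grf_N: np.ndarray                # (n, 3)
    grm_Nm: np.ndarray               # (n, 3)
    body_mass_kg: float
    events: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.grf_N = np.asarray(self.grf_N, dtype=float)
        self.grm_Nm = np.asarray(self.grm_Nm, dtype=float)
        if self.time.ndim != 1 or np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be 1-D and strictly increasing")
        if self.body_mass_kg <= 0:
            raise ValueError("body mass must be positive")
        for name in ("angles_deg", "grf_N", "grm_Nm"):
            arr = getattr(self, name)
            if arr.shape != (self.time.size, 3):
                raise ValueError(f"{name} must have shape (n, 3)")
        for key, times in self.events.items():
            t = np.asarray(times, dtype=float)
            if t.size and (t.min() < self.time[0] - 1e-9 or t.max() > self.time[-1] + 1e-9):
                raise GaitEventError(f"event '{key}' outside trial time range")


@dataclass
class GaitCycleCurves:
    """Signals resampled to 101 uniform samples over 0-100% gait cycle."""

    percent: np.ndarray              # (101,) 0..100
    angles_deg: np.ndarray           # (101, 3)
    grf_N: np.ndarray                # (101, 3)
    grm_Nm: np.ndarray               # (101, 3)
    body_mass_kg: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.percent.shape != (N_CYCLE_SAMPLES,):
            raise ValueError("cycle curves must have exactly 101 samples")

    def stack(self) -> np.ndarray:
        """All signals as one (101, 9) array (angles, GRF, GRM)."""
        return np.hstack([self.angles_deg, self.grf_N, self.grm_Nm])


@dataclass
class PhaseSet:
    """Eight labeled half-open percent intervals partitioning [0, 100].

    Interval i is [boundaries[i], boundaries[i+1]); the final interval is
    closed at 100 so that the union is exactly [0, 100].
    """

    boundaries: tuple[float, ...] = DEFAULT_RLA_BOUNDARIES
    names: tuple[str, ...] = RLA_PHASE_NAMES

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.size != len(self.names) + 1:
            raise ValueError("need one more boundary than phases")
        if b[0] != 0.0 or b[-1] != 100.0 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must increase strictly from 0 to 100")

    @property
    def n_phases(self) -> int:
        return len(self.names)

    def intervals(self) -> list[tuple[float, float]]:
        b = self.boundaries
        return [(b[i], b[i + 1]) for i in range(self.n_phases)]

    def phase_of(self, percent: float) -> int:
        """0-based phase index containing a cycle percent."""
        if not 0.0 <= percent <= 100.0:
            raise ValueError("percent must lie in [0, 100]")
        idx = int(np.searchsorted(self.boundaries, percent, side="right") - 1)
        return min(idx, self.n_phases - 1)

    def masks(self, percent: np.ndarray) -> np.ndarray:
        """Boolean (n_phases, len(percent)) membership masks."""
        idx = np.minimum(
            np.searchsorted(self.boundaries, percent, side="right") - 1,
            self.n_phases - 1,
        )
        return idx[None, :] == np.arange(self.n_phases)[:, None]

    def to_json_dict(self) -> dict:
        return {
            "names": list(self.names),
            "boundaries_percent": list(self.boundaries),
        }


def normalize_to_cycle(trial: GaitTrial) -> GaitCycleCurves:
    """Resample a trial onto 101 uniform points over one gait cycle.

    The cycle spans the first two heel strikes in ``trial.events``; each
    signal is linearly interpolated onto the uniform grid.
    """
    strikes = np.asarray(trial.events.get("heel_strikes", ()), dtype=float)
    if strikes.size < 2:
        raise GaitEventError("need two successive heel strikes to define a cycle")
    t0, t1 = strikes[0], strikes[1]
    if t1 <= t0:
        raise GaitEventError("heel strikes must be increasing in time")
    t_grid = np.linspace(t0, t1, N_CYCLE_SAMPLES)

    def interp(sig: np.ndarray) -> np.ndarray:
        return np.column_stack([np.interp(t_grid, trial.time, sig[:, j]) for j in range(3)])

    return GaitCycleCurves(
        percent=np.linspace(0.0, 100.0, N_CYCLE_SAMPLES),
        angles_deg=interp(trial.angles_deg),
        grf_N=interp(trial.grf_N),
        grm_Nm=interp(trial.grm_Nm),
        body_mass_kg=trial.body_mass_kg,
        meta={
            "cycle_bounds_s": (float(t0), float(t1)),
            "source_rate_hz": float(1.0 / np.median(np.diff(trial.time))),
            "toe_off_percent": _toe_off_percent(trial, t0, t1),
        },
    )


def _toe_off_percent(trial: GaitTrial, t0: float, t1: float) -> float | None:
    toe_offs = np.asarray(trial.events.get("toe_offs", ()), dtype=float)
    inside = toe_offs[(toe_offs > t0) & (toe_offs < t1)]
    if inside.size == 0:
        return None
    return float(100.0 * (inside[0] - t0) / (t1 - t0))


def segment_rla_phases(
    curves: GaitCycleCurves | None = None,
    boundaries: tuple[float, ...] | None = None,
) -> PhaseSet:
    """Return the eight-phase RLA segmentation of the gait cycle.

    The RLA phases are defined on cycle percent, so the curves themselves
    only validate context; ``boundaries`` overrides the standard values.
    """
    return PhaseSet(boundaries=tuple(boundaries) if boundaries is not None else DEFAULT_RLA_BOUNDARIES)


# ---------------------------------------------------------------------------
# k-medoids clustering of curves
# ---------------------------------------------------------------------------

def _zscore_concat(curve_matrix: np.ndarray) -> np.ndarray:
    """Z-score each column so no signal dominates the distance by units."""
    mu = curve_matrix.mean(axis=0)
    sd = curve_matrix.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (curve_matrix - mu) / sd


def _curve_matrix(curves: list) -> np.ndarray:
    rows = []
    for c in curves:
        arr = c.stack() if isinstance(c, GaitCycleCurves) else np.asarray(c, dtype=float)
        rows.append(arr.ravel())
    mat = np.asarray(rows)
    return _zscore_concat(mat)


def _kmedoids(dist: np.ndarray, k: int, rng: np.random.Generator, n_restarts: int = 50) -> list[int]:
    """Plain alternating k-medoids (PAM-style) with random restarts.

    Exhaustive over all medoid subsets when the problem is small enough,
    which makes the result exactly optimal there.
    """
    n = dist.shape[0]
    if k > n:
        raise ParameterError(f"k={k} exceeds number of curves n={n}")
    if k == n:
        return list(range(n))
    # small problems: exact search
    if _n_subsets(n, k) <= 20000:
        best, best_cost = None, np.inf
        for subset in itertools.combinations(range(n), k):
            cost = dist[:, subset].min(axis=1).sum()
            if cost < best_cost - 1e-12:
                best, best_cost = subset, cost
        return sorted(best)

    best, best_cost = None, np.inf
    for _ in range(n_restarts):
        medoids = list(rng.choice(n, size=k, replace=False))
        for _ in range(100):
            assign = np.argmin(dist[:, medoids], axis=1)
            new_medoids = []
            for ci in range(k):
                members = np.where(assign == ci)[0]
                if members.size == 0:
                    new_medoids.append(medoids[ci])
                    continue
                within = dist[np.ix_(members, members)].sum(axis=0)
                new_medoids.append(int(members[np.argmin(within)]))
            if new_medoids == medoids:
                break
            medoids = new_medoids
        cost = dist[:, medoids].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best, best_cost = list(medoids), cost
    return sorted(best)


def _n_subsets(n: int, k: int) -> float:
    from math import comb

    return comb(n, k)


def select_typical_trials(trials: list, k: int = 3, seed: int = 0) -> list[int]:
    """Pick ``k`` representative trials by k-medoids on concatenated curves.

    Mirrors the protocol of collecting five walking trials per subject and
    keeping three "typical" ones.  Returns sorted medoid indices.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if len(trials) < k:
        raise ParameterError(f"need at least k={k} trials, got {len(trials)}")
    mat = _curve_matrix(trials)
    dist = np.linalg.norm(mat[:, None, :] - mat[None, :, :], axis=2)
    return _kmedoids(dist, k, np.random.default_rng(seed))


def cluster_subjects_by_hrf(hrf_curves: list, k: int = 2, seed: int = 0) -> list[int]:
    """Pick representative subjects by k-medoids on their HRF cycle curves."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if len(hrf_curves) < k:
        raise ParameterError(f"need at least k={k} curves, got {len(hrf_curves)}")
    mat = _curve_matrix(hrf_curves)
    dist = np.linalg.norm(mat[:, None, :] - mat[None, :, :], axis=2)
    return _kmedoids(dist, k, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Range-of-motion and HRF peak summaries
# ---------------------------------------------------------------------------

def extract_rom(curves: GaitCycleCurves) -> dict[str, float]:
    """Per-plane range of motion (max - min) in degrees."""
    rom = curves.angles_deg.max(axis=0) - curves.angles_deg.min(axis=0)
    return {
        "sagittal_deg": float(rom[0]),
        "frontal_deg": float(rom[1]),
        "transverse_deg": float(rom[2]),
    }


def extract_hrf_peaks(
    hrf_bw: np.ndarray,
    percent: np.ndarray | None = None,
    stance_end_percent: float = 62.0,
    second_peak_after_percent: float = 35.0,
    prominence_bw: float = 0.02,
) -> dict:
    """First and second stance peaks of an HRF magnitude curve (in BW).

    A healthy curve is M-shaped: two stance local maxima with a valley
    between.  The second peak is reported only if a stance maximum after
    ``second_peak_after_percent`` exceeds the inter-peak minimum by at least
    ``prominence_bw`` body weights; otherwise the curve is flagged flat
    (second peaks can flatten out or disappear after surgery).
    """
    hrf_bw = np.asarray(hrf_bw, dtype=float)
    if percent is None:
        percent = np.linspace(0.0, 100.0, hrf_bw.size)
    stance = percent <= stance_end_percent
    x = hrf_bw[stance]
    pc = percent[stance]

    maxima = _local_maxima(x)
    result: dict = {"peak1_bw": None, "peak1_percent": None,
                    "peak2_bw": None, "peak2_percent": None, "second_peak_flat": True}
    if maxima.size == 0:
        # monotone stance curve: peak1 = max value
        i = int(np.argmax(x))
        result["peak1_bw"], result["peak1_percent"] = float(x[i]), float(pc[i])
        return result

    early = maxima[pc[maxima] < second_peak_after_percent]
    late = maxima[pc[maxima] >= second_peak_after_percent]
    if early.size:
        i1 = early[np.argmax(x[early])]
    else:
        i1 = maxima[np.argmax(x[maxima])]
    result["peak1_bw"], result["peak1_percent"] = float(x[i1]), float(pc[i1])

    late = late[late > i1]
    if late.size:
        i2 = late[np.argmax(x[late])]
        valley = float(x[i1:i2 + 1].min())
        if x[i2] - valley >= prominence_bw:
            result["peak2_bw"], result["peak2_percent"] = float(x[i2]), float(pc[i2])
            result["second_peak_flat"] = False
    return result


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima (plateaus take the first index)."""
    from scipy.signal import argrelextrema

    idx = argrelextrema(x, np.greater_equal, order=1)[0]
    # drop endpoints and plateau repeats
    idx = idx[(idx > 0) & (idx < x.size - 1)]
    keep = [i for i in idx if x[i] > x[i - 1] or x[i] > x[i + 1]]
    out, prev = [], -10
    for i in keep:
        if i > prev + 1 or (out and x[i] != x[out[-1]]):
            out.append(i)
        prev = i
    return np.asarray(out, dtype=int)


def extract_rom_and_peaks(curves: GaitCycleCurves, hrf_bw: np.ndarray | None = None) -> dict:
    """Combined per-plane RoM and, when an HRF curve is given, stance peaks."""
    summary = {"rom": extract_rom(curves)}
    if hrf_bw is not None:
        summary["hrf_peaks"] = extract_hrf_peaks(hrf_bw, curves.percent)
    return summary
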