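# Methods

This note documents the models implemented in `paofix`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data do and do not establish about real subjects.

## Musculoskeletal stage

**Reduced model.**  The full marker-driven lower-extremity multibody model
is out of scope; `paofix` works at the joint-angle level with a single hip
joint and one rigid stance-limb segment (mass 16.1% of body mass, length
0.9 m × height ratio, COM at 45% of segment length, radius of gyration 35%
— standard anthropometric values).  Ground reactions are applied at the
point below the hip; centre-of-pressure excursion is carried by the
ground-reaction-moment channel.  All the governing equations under test
(strength scaling, recruitment, HRF balance) act at this level, so nothing
in the verification depends on the omitted segments.

**Coordinates.**  Pelvis-aligned frame: x anterior, y vertical up,
z lateral; origin at the hip centre for the muscle model.  FE load cases
record the pelvis reference frame (origin at the posterior-superior iliac
spine midpoint, XY vertical through the pubic symphysis, XZ horizontal) as
metadata.

**Strength scaling.**  `F = F₀ (k_m/k_L)(R_muscle,subj/R_muscle,gen)` with
`R_muscle = 0.5 − R_fat`.  The generic-model denominator makes the formula
the identity for a subject identical to the generic model, which is the
only dimensionally and semantically consistent reading of the
mass/height/fat scaling intent.

**Muscle set.**  Twelve muscle elements in four functional groups
(abductors, flexors, extensors, adductors, with rotator accents) and
representative attachment coordinates.  Adductor origins sit medially
(negative z) as on the pubis/ischium; this matters because it gives them
physiological frontal-plane moment arms (~2–6 cm).  The set positively
spans all three hip moment axes (asserted by test), so every bounded
moment demand is recruitable.  The iliopsoas wraps a 2-cm cylinder at the
pubis–acetabulum; the wrap path is the exact tangent–arc–tangent
construction obtained by developing the cylinder plus tangent planes into
a plane (`L = sqrt(L_xy² + Δz²)`), verified against a penalized numeric
shortest-path search.

**Inverse dynamics.**  Newton–Euler balance per cycle sample; angular
accelerations by central finite differences (one-sided at the ends) of the
three hip angles treated per-axis with a single scalar segment inertia.
Angle curves are Gaussian low-pass filtered at 6 Hz (the gait-laboratory
convention, periodic boundary) before differentiation inside `run_ida`;
the raw `inverse_dynamics` operator is unfiltered so it can be checked
against an independent oracle to 1e-8.  Without the filter, measurement
noise of a few percent injects tens of N·m of spurious inertial moment at
heel strike — the classic double-differentiation artifact.

**Recruitment.**  `min Σ(fᵢ/Nᵢ)ᵖ, Cf = r, f ≥ 0`, default `p = 3`.  The
primary solver is a dual Newton/root solve on the KKT stationarity
`fᵢ = Nᵢ^{p/(p−1)} (max((Cᵀλ)ᵢ, 0)/p)^{1/(p−1)}`, which reduces the
problem to `len(r)` unknowns; feasibility is pre-checked with non-negative
least squares and an SLSQP solve on the primal is the fallback.
Constraint residual tolerance 1e-6 (relative), objective effectively at
stationarity.  The dual form also exposes the closed-form family used in
tests: with equal moment arms, `fᵢ ∝ Nᵢ^{3/2}` for `p = 3`.

## Synthetic gait generator

Signals are parameterized sums of Gaussian bumps.  The vertical GRF is two
humps (16% and 46% of cycle) plus a valley filler, with coefficients
solved so the anchor values are exact; braking/propulsion shear is centred
on the humps and scales with them; stance occupies 62% of the cycle with
smooth 6%-ramps and exactly zero swing loads.  Angle curves are sinusoids
with amplitudes set by the per-group range-of-motion targets
(sagittal/frontal/transverse: healthy 45/16/15°, preoperative
37.6/11.5/8.4°, postoperative 35.5/14.3/13.6°).

**Calibration to HRF targets.**  Profiles state their conditions as
downstream HRF stance peaks in BW (healthy 2.80/2.75, preoperative
2.45/2.11, postoperative 3.12/1.90; the postoperative first peak and
preoperative second peak carry the published SDs 1.41 and 1.03).  The
generator inverts the gait→HRF map by a cached finite-difference Newton
solve through the actual pipeline, then refines each trial so that the
*measured* downstream peaks (the same extraction the analysis uses) equal
the drawn targets.  Closing the loop on the measured value matters with
noise: the extracted peak is a maximum over a noisy curve and would
otherwise be biased upward.  Per-trial targets are truncated at 1.2 BW
(walking below that peak load is not physiological).  Noise is smoothed
white noise at 2% of each signal's amplitude by default, windowed to
stance for the ground reactions.  All generators are pure functions of
(profile, seed).

The postoperative "sharper initial peak" is realized by a narrower first
GRF hump (width 0.055 vs 0.080 cycle fraction); a curvature comparison at
matched amplitude is asserted in the tests.

**What the generator does not emulate:** marker trajectories and
soft-tissue artifacts, inter-leg asymmetry, double-support force sharing,
spontaneous cadence variability, and any anatomical realism of the
waveform details beyond peak statistics, RoM and gross shape.  Passing
tests therefore demonstrate the correctness and calibration of the
*pipeline*, not clinical validity on real gait data.

## Geometry and FE stage

**Parametric construct.**  The hemipelvis is a gently curved
80 × 60 × 20 mm plate (shear-type bend, so no element inversion) cut by an
oblique osteotomy plane into a retained ilium (fixed at the medial face)
and an acetabular fragment (loaded at a joint-contact patch).  Screws are
smooth cylinders without thread geometry, bonded by sharing nodes;
elements are assigned to the nearest screw axis within the capture radius
(max of screw radius and 0.75× edge size, so coarse meshes keep connected
screw bodies).  Layouts: IS = three oblique screws, TS = two oblique + one
transverse, 2S-a…e = the five two-screw subsets.  The mesh is a structured
Kuhn (6-tets-per-hex) tetrahedralization — conforming, watertight and
strictly positive-volume by construction.

**Materials.**  HU → density: `ρ = (HU + 1.4246)·0.001/1.058` above the
HU = −1 cutoff, zero at or below (the only algebraically sensible
parenthesization of the calibration; the cutoff branch is exact).
Density → modulus: `E = max(a ρᵇ, 1 MPa)` with a = 2017.3 MPa, b = 2.46 (a
literature pelvic/femoral mapping; the source protocol does not state
one), ν = 0.3 for bone.  Screws: titanium alloy, E = 110 GPa, ν = 0.3.
Callus: elements whose centroid lies within 10 mm of the osteotomy surface
(exact point-triangle distances) have E multiplied by 0.3.

The synthetic density defaults (cortical shell 1800 HU on surface-adjacent
elements, trabecular interior 900 HU) and the 0.3 callus factor were
chosen once so the construct operates in the regime the clinical analysis
reports: essentially no failed volume at 1× gait load and yield loads in
the 3–6 BW band across layouts.  They are generator-level conditions, not
fitted quantities; per-element HU values for real studies come from CT.

**Elements and solver.**  Tet4 constant-strain elements with a single
integration point at the centroid; sparse assembly and a cached sparse LU
factorization reused across the eight phase load cases and yield
iterations.  Loads are coupled to named surface regions with exact static
equivalence (equal sharing for the force; a minimum-norm couple
distribution when a moment is requested).  Verification: patch test to
machine precision, uniaxial bar stress/displacement within 2%, global
force balance to 1e-8 relative, exact load linearity.

## Failure analysis

`p̄100` is the mean of the 100 largest element von Mises values (all
values, flagged, when fewer exist).  `WMV_s−100 = Σ p̄100ᵢ pᵢ / S_p` uses
the single per-phase maximum as the weight `pᵢ` (the alternative reading —
weighting by `p̄100` itself — is configurable at the call site by passing
those values as weights).

**Mesh convergence** starts at a coarse edge size and refines in fixed
steps; the variation rate is `100·|σ_prev − σ_cur|/σ_prev` with the
*coarser* mesh in the denominator, which reproduces the worked example's
printed rates (2.1%, 1.6%) from its stress sequence; the first size under
the 1% tolerance is selected and one confirmation step recorded.

**Yield protocol.**  The maximum-load gait phase (largest phase-mean HRF)
is scaled up in 10 N increments of the hip contact force.  A bone element
fails when its maximum principal strain exceeds 0.73% in tension or 1.04%
in compression (standard bone yield strains; the criterion's limits are
not stated by the source protocol and are configurable).  Yield is the
load at which failed bone volume (element-volume weighted, screws
excluded) reaches 1% of total bone volume.  With deletion on (default),
failed elements drop to a vanishing modulus and the system is re-solved;
increments at which the current linear response cannot fail any new
element are skipped in one jump, which leaves the result identical to
stepping one increment at a time.  With deletion off, a single linear
solve gives the same answer via the strain-quantile scaling shortcut
(cross-checked in tests).  A configurable cap (20 BW) returns a flagged
capped result instead of iterating forever.

## Cohort pipeline and statistics

The cohort run mirrors the study protocol: five walking trials per
subject, three "typical" trials kept by k-medoids clustering (Euclidean
distance on z-scored concatenated curves, exact exhaustive search for
small cohorts, 50 restarts otherwise), inverse dynamics on the typical
trials, representative subjects selected by k-medoids on their HRF curves
(k = 2), then FE and failure analysis per fixation layout across the eight
Rancho Los Amigos phases (default boundaries 0/2/12/31/50/62/75/87/100%
of cycle, configurable).  "High-stress phases" are phases 2–4; the
between-layout comparison reports the difference of mean `p̄100` over
those phases with SE, 95% t-CI and a one-way F test (the source protocol
does not name its test; ANOVA is the natural choice for a two-group mean
comparison and degenerates to it).  Identical groups return F = 0, p = 1.

Every stage derives its randomness from the global seed; the summary JSON
of two runs with the same configuration is byte-identical.

## Problem sizes and numerical choices

Default FE meshes use a 5 mm edge (~4.6 k tetrahedra), which the package's
own convergence protocol can refine; the cohort defaults (3 subjects, 5
trials, 2 representative subjects, IS + TS) run in minutes on one core.
Degenerate inputs are rejected with typed errors: empty coupling regions,
screws that miss the fragment, coplanar morphing landmarks, infeasible
recruitment demands (with the residual in the message), unconstrained FE
systems.  Ties in k-medoids resolve to the lexicographically smallest
index set via strict-improvement comparisons.

## Known limitations

* The hemipelvis is a parametric plate, not patient anatomy; absolute
  stress and yield magnitudes are not comparable to patient-specific
  models, only orderings and protocol behaviour are meaningful.
* Tet4 elements are stiff in bending; the convergence protocol exists
  precisely to pick an adequate mesh, but quadratic elements are out of
  scope.
* Recruitment is quasi-static (no activation dynamics or Hill-type
  force-length/velocity properties).
* Screw-bone interfaces are fully bonded; no contact, friction, or thread
  mechanics.
* One stance limb: double support is not modelled, so phase aggregates
  near the stance/swing transitions underestimate contralateral effects.
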