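# Methods

`adaptrt` simulates, end to end, a comparison of two treatment strategies in
intensity-modulated proton therapy (IMPT) for high-risk prostate cancer:

* **NART** (non-adaptive): one robust plan, optimized on the planning
  anatomy, is delivered on every treatment day;
* **DART** (daily-adaptive): the plan is re-optimized on each day's anatomy
  with identical goals and robustness settings.

Both strategies are evaluated on the same stream of synthetic daily
anatomies, per-fraction (with the single-day dose extrapolated x21 to the
whole course) and as a deformably accumulated total dose on the planning
anatomy.  Everything below is a deliberate simplification chosen so that the
whole 23-patient x 21-fraction experiment runs on a desktop CPU in minutes
while preserving the mechanisms that drive the NART/DART contrast.

## Synthetic pelvic anatomy

The planning phantom is an analytic assembly in world millimetres (LPS):
an ellipsoidal prostate (~30 ml) at the isocenter, two posterior-superior
seminal-vesicle (SV) lobes (~6 ml total), a tubular rectum (superellipsoid,
p = 6; ~110 ml) whose tube deliberately overlaps the posterior prostate/SV
surface — the priority rule carves the target out of it, leaving the
anatomically concave anterior rectal wall wrapped around the target — an
ellipsoidal bladder (~135 ml) anterior-superior, a pelvic bone ring with
femoral heads, and a water-equivalent elliptic body.  HU are class-constant
per tissue (soft tissue 0, bone 700, air -1000); the CTV is the union of
prostate and the entire SV.  Masks are evaluated analytically at voxel
centers with a fixed priority order, so the four organs are pairwise
disjoint by construction and `CTV = prostate u SV` exactly.  Per-patient
variability jitters organ sizes and positions within bounds that keep every
deformation support clear of the rigid bone.

The planning bladder is deliberately moderate: the cohort statistics the
generator reproduces have daily bladders on average ~34% larger than at
planning, so the planning state sits near the low end of the filling range.

### Daily variation model

Per-organ percent volume differences are drawn from **shifted lognormal**
distributions moment-matched to the cohort statistics

| organ    | mean (%) | SD (%) | P(larger than planning) |
|----------|---------:|-------:|------------------------:|
| prostate |   -2.13  | 12.88  |  (not calibrated)       |
| SV       |   12.18  | 28.88  |  (not calibrated)       |
| rectum   |   14.54  | 24.54  | 0.71                    |
| bladder  |   34.10  | 46.22  | 0.82                    |

The lognormal shift is the free parameter: where an exceedance fraction is
reported it is solved for; a plain normal cannot honour both the moments and
the bladder's 82%.  For the rectum the requested 0.71 lies marginally below
the family's symmetric limit (~0.723), so the fit returns the closest
attainable member — the discrepancy is under one Monte-Carlo standard error
at n = 483.  Draws are truncated to [-80%, +250%]: the lower bound keeps
volumes physical, the upper bound keeps the deformation invertible; the
truncation biases the bladder mean by well under one standard error.

Volume change is realized geometrically by **radial scaling warps**: inside
the organ the map is a uniform scaling about the organ center (volume factor
s^3), blending smoothly to the identity at 1.8x the organ's normalized
radius (2.4x for the small SV lobes).  Monotonicity of the radial profile is
exactly the invertibility condition and is checked at construction.  Because
neighbouring warps overlap, each organ's realized volume is its own scale
times the Jacobian of the other warps; two fixed-point passes correct each
scale so that the *mean Jacobian determinant of the full chain over the
organ* — which is exactly the realized volume ratio — matches the drawn
percentage.  A filling bladder additionally translates its content
cranially (the base is anchored), which is what keeps large fills from
unphysically crushing the SV between bladder and rectum; a filling rectum,
anchored posteriorly by the sacrum, likewise shifts its content anteriorly,
advancing the anterior wall toward the target.

SV displacement is coupled to the neighbours along the anterior-posterior
axis: `shift = -0.05 mm/% x d_rectum + 0.03 mm/% x d_bladder` (full rectum
pushes the SV forward, posterior bladder expansion pushes it back),
implemented as a smoothly localized translation warp and clipped at +-6 mm.
The coefficients are calibration knobs, not measured quantities.

A rigid set-up error (zero-mean Gaussian, SD 2 mm per axis translation,
1 degree per axis rotation, truncated at 3 SD) completes the daily instance.
These magnitudes are stand-ins — chosen so the 3 mm robustness setting is
exercised near its design point — since the emulated cohort does not report
them.  Daily volume draws are exchangeable across fractions by default; a
per-patient systematic offset (variance split) is available but off, since
the emulated statistics are cohort-marginal.

Because every daily anatomy is generated *by* an exactly invertible
parametric deformation, the ground-truth correspondence replaces the
deformable image registration of a clinical workflow, for both contour
propagation and dose mapping.  What the generator does **not** emulate: CT
noise and artifacts, intra-fraction motion, contouring variability (a
boundary-jitter option exists in principle via the variation parameters but
segmentation is otherwise perfect), bladder field-of-view truncation, and
day-to-day correlation of filling.  Passing tests therefore demonstrate the
*strategy* contrast under controlled anatomical variation, not performance
on real images.

## Dose engine

A deliberately simple spot-scanning pencil-beam model: two opposed lateral
parallel (non-divergent) fields; water-equivalent path length (WEPL) from a
cumulative midpoint sum of relative stopping power along the beam axis
(exact Siddon-style tracing is available for arbitrary rays and is the
oracle in tests); an analytic Bragg curve (entrance plateau 30% of peak with
a linear rise, Gaussian-smeared peak at the nominal range, Gaussian distal
falloff 80->20% over 4 mm, hard zero 10 mm beyond the range); a normalized
lateral Gaussian whose sigma grows linearly with depth (5 mm + 0.025/mm;
6 mm in the cohort profile).  Dose = 1.1 x physical dose (fixed RBE).
HU -> stopping power is a piecewise-linear monotone curve anchored at air
and water.  No nuclear halo, no Monte Carlo, no variable RBE.

Robustness scenarios enter the engine as (i) a rigid isocenter shift (dose
sampled at shifted positions) and (ii) a multiplicative stopping-power
scale.  `Scenario.range_scale` is the RSP multiplier: a value above 1 gives
a *shorter* range in the patient.  Scaling HU voxel-by-voxel (the error-
scenario evaluation) and scaling RSP are equivalent here to within the
piecewise linearity of the calibration curve.

## Robust optimization

Spot lattice: energy layers every 5 mm of water range (6 mm in the cohort
profile) spanning the CTV WEPL envelope +-10 mm; lateral positions on a
1.5-sigma grid covering the CTV silhouette, widened by a configurable
envelope margin (4 mm in trials) so the same lattice can be re-weighted on
any daily anatomy.

The objective is evaluated on worst-case composite doses over 9 scenarios
(nominal, six +-3 mm axis shifts, +-3.5% range — shifts and range errors
are not cross-producted): voxel-wise scenario minimum inside the CTV,
maximum elsewhere.  Terms: one-sided quadratic under-dose below the 63
Gy(RBE) prescription (weight 300) and over-dose above 110% (weight 80) on
CTV voxels; rectum V50 < 20%, V30 < 50% and bladder V30 < 30% as
DVH-point penalties (weight 2) — one-sided quadratics on the voxels that
currently violate each volume constraint, re-selected every outer
iteration — and a normal-tissue shell capped at the Dmax goal (weight 1).
Target terms dominate OAR terms (target priority).  Minimization is
L-BFGS-B on non-negative weights inside the outer re-linearization loop
(up to 6 outer x 40 inner iterations from a uniform scale-correct start;
daily re-optimizations warm-start from the original plan with 3 x 20).
Finally the plan is renormalized so the nominal CTV D99 equals 100.5% of
prescription — the usual clinical prescription normalization, giving plans
the slight overshoot real plans show against their D99 goal; the internal
Dmax budget is divided by the same factor so the normalized plan still
respects the printed 110% goal.  A weak always-on penalty (weight 0.15) above each OAR threshold implements the protocol's
"as low as possible" clause.

The daily re-optimization re-weights a fixed per-patient lattice rather
than placing new spots; with the variation-envelope margin this is a
standard online-adaptation compromise that keeps each daily plan inside a
second of CPU.

## Alignment and accumulation

Each daily anatomy is aligned the clinical way: 6-DOF bone matching, then a
translation taking the daily prostate centroid to the planning isocenter.
Bone matching minimizes the mean squared mismatch between the reference
bone's signed-distance field at the transformed points and the daily
signed-distance values (for a rigid bone these fields must agree; plain
overlap of a thick shell is degenerate), by Powell search from the centroid
offset.  On the 2 mm phantom grid this recovers a known set-up error to
better than 0.2 mm / 0.1 degree; on the 5 mm cohort grid to well under half
a voxel.  The couch correction is folded into the anatomy's analytic
deformation chain, so aligned masks and HU are re-evaluated exactly, with
no resampling blur.  No residual rotation about the prostate is applied
after bone matching.

Fraction doses are computed at the nominal scenario only (the set-up error
is already realized in the anatomy; robustness scenarios exist only inside
the optimizer and the error-scenario evaluation).  Accumulation pulls each
fraction dose back to planning coordinates through the exact deformation
(trilinear interpolation, zeros outside the daily grid) and sums the 21
fractions; no energy/mass correction is applied, matching commercial
DIR-based dose accumulation, and the deformations are near-volume-
preserving.

## Evaluation

Cumulative DVHs use 0.05 Gy bins; D-indices interpolate linearly inside a
bin, V-indices are reported relative (%) or absolute (ml, bladder V63).
Clinical goals: D99 of CTV/prostate/SV above 95% of prescription (59.85
Gy(RBE)), rectum Dmax < 66 Gy(RBE), rectum V30/V50 and bladder V30 as in
planning, bladder V63 < 10 ml.  Gamma analysis is global (dose difference
normalized to the reference maximum), 10% low-dose cutoff, searched over a
sphere of radius DTA at half-DTA sub-voxel steps with trilinear
interpolation; all three knobs are exposed.  Paired t-tests (scipy) compare
DVH indices; McNemar's test (statsmodels) compares goal achievement, exact
binomial below 25 discordant pairs, chi-square above.

## Problem sizes and numerical choices

Cohort runs use a 5 mm isotropic grid (the package default phantom grid is
2 mm), the 6 mm-sigma beam profile, ~1100-1300 spots per patient, and
evaluate the optimizer on all CTV voxels plus seeded 400-voxel samples of
each OAR and of an 8 mm shell; per-fraction dose is computed on an
index-aligned sub-grid covering all structures plus 16 mm, and fraction
doses are accumulated on the same sub-box of the planning grid (the
accumulated DVHs only need structure voxels).  These sizes are
the package's desk-scale operating point; all of them are configuration,
not code.  Ties in the worst-case composite resolve to the first scenario;
degenerate statistics (zero-variance differences, zero discordant pairs)
are reported as p = 1 or p = 0 with a warning rather than raised.

## Known limitations

* The dose engine is a toy: no beam divergence, nuclear buildup, or
  measured beam data; its absolute OAR numbers (planning rectum V50 around
  13%, V60 around 5%, Dmax around 67 Gy(RBE)) are in a plausible range but
  are not commissioning-grade.
* Mid-dose rectum sparing under adaptation comes out *slightly worse* than
  under the static plan in this model (mean fractional rectum V50 higher by
  under one point for DART), because each daily re-optimized plan delivers a
  full mid-dose shell conformal to that day's anatomy while the static
  plan's shell is geometrically diluted by organ motion.  Clinical cohorts
  report the opposite for the rectum; reproducing that requires rectal-shape
  dynamics (localized distension into a near-constraint-limit dose
  distribution) beyond the radial volume-scaling family used here.  The
  high-dose rectal indices (Dmax, V60) do adapt in the expected
  direction.
* The anatomy model scales organs about fixed centers; it cannot produce
  topology changes (gas pockets), local wall deformations, or realistic
  bladder-neck anchoring beyond the cranial-shift approximation.
* Strategy contrasts are driven by SV displacement of a few millimetres
  against a 3 mm robustness margin; cohorts with much larger motion would
  need the set-up/coupling parameters re-estimated from data.
* The zero-variation limit reproduces NART = DART only up to the optimizer's
  convergence tolerance, since daily re-optimization may continue to
  improve an already-feasible OAR index slightly.
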