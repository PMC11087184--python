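# Methods

## Motion model and displacement statistics

The analysis is strictly in-plane and two-dimensional: each cine slice
is treated independently in its own mm coordinate frame, one slice at a
time. The 3D patient (LPS) embedding is carried through the data model
so that margin directions can be reported in the radiotherapy frame,
but no through-plane motion is measured — LV twist produces
through-plane motion in long-axis slices that this method cannot see,
and that is a known limitation, not a bug.

For a tracked contour point with per-phase positions x_p (P = 25 or 30
phases), the reported quantities are maxima over all unordered phase
pairs, computed by exact O(P²) enumeration (435 pairs at P = 30;
exactness was preferred over any convex-hull or range shortcut for the
overall distance, and the projected maxima use the same enumeration so
the three quantities are computed identically):

- overall: max ‖x_q − x_p‖
- tangential: max |(x_q − x_p) · t̂|
- normal: max |(x_q − x_p) · n̂|

**Frame convention.** t̂ and n̂ are evaluated at the *reference
(end-diastolic) position* of each point and held fixed across phases.
The projections of a phase-pair difference are only well defined once a
single frame is chosen; the ED frame is the natural choice because
contours are traced at ED and every trajectory starts there. With an
orthonormal frame this gives the per-pair identity
(Δ·t̂)² + (Δ·n̂)² = ‖Δ‖², which the test suite asserts to 1e-9 on every
phantom point. Because the three reported values take their maxima over
possibly different phase pairs, only max(tangential, normal) ≤ overall ≤
√(tangential² + normal²) holds per point after maximisation.

Normals point *outward* (away from the cavity) on both borders. The sign
affects only the motion traces (inward motion is negative); reported
maxima are absolute values.

## Resampling and point correspondence

Contours are resampled to equal arc-length spacing on cubic splines —
500 points per long-axis border, 120 per short-axis border — with
periodic closure for closed (short-axis) contours and natural end
conditions for open (long-axis) contours; open contours keep their
first and last input points exactly. Equal spacing is found by dense
sampling (≥ 50× the output count), a cumulative chord-length table and
inverse interpolation, and is uniform to well within 0.1% of the mean
spacing.

A consequential design choice: the equal-arc parameters are computed
**once, on the reference phase**, and every other phase's spline —
built over the *reference* chord-length knots, so that input-point
index keeps its material meaning — is evaluated at those same
parameters. Resampling every phase independently to equal spacing would
re-distribute points along the deformed contour and silently destroy
point correspondence wherever motion has a tangential component,
biasing tangential displacements towards zero. With the chosen scheme a
rigidly translating contour yields exactly the translation at every
resampled point (asserted in tests).

## LV long axis and AHA segmentation

The long axis of a long-axis slice is defined automatically from the
reference-phase epicardial contour: the base point is the midpoint of
the open contour's endpoints; the principal direction is the covariance
eigenvector best aligned with the base→centroid direction (the raw
leading eigenvector can be the wall-to-wall direction on short, wide
ventricles); the apex is the contour point with maximal projection onto
that direction. Axial position a ∈ [0, L] splits points into half-open
thirds — basal [0, L/3), mid [L/3, 2L/3), apical [2L/3, L] — and the
sign of the cross product with the axis selects the wall. Epicardial
points with a beyond the maximal axial coordinate of the endocardial
reference contour form the apical cap (segment 17), which therefore
never contains endocardial points.

The wall-to-segment mapping per view is configurable, with documented
defaults: 2-chamber anterior {1, 7, 13} / inferior {4, 10, 15};
3-chamber anteroseptal {2, 8, →13} / inferolateral {5, 11, →16};
4-chamber (infero)septal {3, 9, 14} / (antero)lateral {6, 12, 16}.
Which geometric side is which wall is set by a per-slice
`side_polarity` flag (synthetic phantoms have no anatomy to detect it
from). Short-axis slices are divided into six 60° sectors about the
endocardial centroid, starting at a per-slice reference angle (default
90° counterclockwise from the image +u axis — no RV-insertion detection
is attempted); exact boundary angles belong to the lower-numbered
sector, with a 1e-9-degree snap to absorb floating-point rounding at
the edges. Segment labels are assigned once at the reference phase and
held fixed, so per-point maxima aggregate within a stable segment.

Per-patient values for a segment seen in several slices are combined by
n_points-weighted averaging, separately per plane (long-axis and
short-axis displacement components are different physical quantities
and are never mixed).

## Cohort statistics

Group tables report mean ± sample SD (ddof = 1) per segment cell, a
classical one-way fixed-effects ANOVA p-value (explicit sum-of-squares
decomposition, F upper tail), and Holm-Bonferroni-adjusted pairwise
p-values for all six group pairs at α = 0.05. The pairwise test family
behind the published tables' footnotes is not specified anywhere
authoritative; Welch t-tests were chosen as the default for
unequal-variance robustness, with a pooled-variance option. Cells where
any group has fewer than two patients are flagged, not fatal. Body
surface area uses the Mosteller formula
BSA = √(height_cm · weight_kg / 3600); coverage statements use the
normal CDF (fraction below a threshold) and the mean ± SD one-sigma
interval.

## ITV margins

*Whole-LV match*: the end-diastolic LV is aligned to the blurred
average image, so the epicardial border already sits at the outer edge
of the motion envelope; the full endocardial radial mean is applied
inward, full longitudinal means apically, no outer or basal margin.
This encodes the observed predominantly inward-and-apexward motion from
end-diastole and is applied uniformly to all segments (a config switch
can disable the zero-outer/zero-basal assumption).
*Target-centered*: the target is matched to the centre of the blurred
wall; half of each mean displacement is applied in both radial and both
longitudinal directions, kept at two-decimal precision (6.1 mm →
3.05 mm).

Two rounding behaviours are pinned deliberately: the halved ITV
components keep exact two decimals, while the combined
cardiac + respiratory margin rounds each half-component to 0.1 mm
*before* summing (2.5 + 3.4 = 5.9 from a 6.7 mm respiratory extent).
The inconsistency between the two conventions is inherited from the
published worked examples and both are regression-tested.

## Synthetic phantom

The phantom exists to give the pipeline data with analytically known
answers, not to be anatomically realistic.

- **Activation**: raised cosine s(t) = (1 − cos 2πt)/2 sampled at
  t = p/(P−1). s spans [0, 1] with the peak attained exactly for odd P
  (default 25), so a prescribed amplitude *is* the expected maximum
  pairwise displacement. Even phase counts undersample the peak by
  < 0.2%.
- **Short-axis**: concentric circles, radii R(t) = R_ED − A·s(t),
  optional rotation Φ·s(t) (twist) and in-plane translation. A
  rotation-only phantom has the closed form overall = 2R sin(Φ/2),
  tangential = 2R sin(Φ/2)cos(Φ/2), normal = 2R sin²(Φ/2) in the ED
  frame, which the pipeline reproduces within 1%.
- **Long-axis**: open capsule (U) contours — two walls plus an apex
  semicircle — for each border, the epicardial capsule extending one
  wall-thickness beyond the endocardial apex so segment 17 is
  populated. Wall points move towards the central axis by the border's
  radial amplitude and towards the apex by a longitudinal amplitude
  that is **constant over the basal third and tapers linearly to zero
  at the apex**. The plateau-then-taper profile makes the basal-segment
  mean equal the prescribed base amplitude (a strictly linear taper
  from the base would make it 5/6 of it) while still vanishing at the
  apex. The generator exposes the exact per-point displacement field
  and frames, so per-segment expected means are available analytically;
  the end-to-end recovery budget is 5% + 0.05 mm, covering resampling
  and segment-boundary discretisation.
- **Cohort**: four groups × n subjects, amplitudes scaled per group
  (control 1.0, HFpEF 0.8, HFmrEF 0.75, HFrEF 0.6) with lognormal
  inter-patient variability (σ = 0.2, mean-centred). LVEF comes from a
  prolate-ellipsoid volume proxy of the endocardial cavity,
  EF = 1 − (L_ES/L_ED)(R_ES/R_ED)², monotone in the radial amplitude;
  group geometry is chosen so the proxy can satisfy the clinical
  cutoffs (HFpEF gets a smaller, hypertrophic cavity — preserved EF
  with reduced displacement; HFrEF a dilated thin-walled one). Each
  subject is rejection-sampled (≤ 200 draws) until the rounded LVEF
  falls inside the group's range; failure raises with a diagnostic.
  All randomness flows from one recipe seed through spawned per-subject
  seed sequences, so identical seeds give byte-identical datasets.

**What the phantom does not emulate** — and therefore what passing
tests do *not* establish about real data: anatomical LV shape
(papillary muscles, outflow tract, wall-thickness variation), regional
wall-motion abnormalities and scar, respiratory motion and drift,
tracking noise in the contour points, through-plane motion, and any
realistic relationship between demographics and motion. The phantom's
rotational symmetry also makes all segments within a level identical,
which real tables are not. Pipeline correctness on the phantom shows
the machinery recovers known motion; clinical displacement magnitudes
should come from measured data, e.g. the bundled published group table.

## Problem sizes and numerical choices

The default test-suite cohorts use 3–10 subjects per group; the cohort
ordering check runs the full four-group, 50-per-group configuration
(200 subjects × 5 slices) in well under two minutes on one CPU.
Degenerate inputs are rejected early: fewer than four distinct contour
points, zero-length spline derivatives, non-orthonormal slice frames,
single-phase series, non-positive pixel spacing or BSA. Consecutive
duplicate contour points collapse to one before spline fitting.
Boundary conventions (half-open level thirds, lower-sector angle ties,
points exactly on the long axis assigned to the first wall) are each
pinned by a dedicated test.
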