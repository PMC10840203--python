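# Methods

## Data model

The unit of geometry is a binary mask volume: a 3D boolean grid with
per-axis voxel spacing in mm and an `axis_map` that assigns each grid
axis to a signed patient direction (LR toward patient left, AP toward
posterior, CC toward cranial). Coordinates are voxel-center based and
0-indexed: voxel `(i, j, k)` sits at `(i·s0, j·s1, k·s2)` mm along the
grid axes, signed per the axis map. This affine-free convention is
unambiguous at desk scale; NIfTI input derives the axis map and spacing
from the affine (an identity affine falls back to a configurable
default, axis 0 = CC, 1 = AP, 2 = LR), and all metrics are invariant to
jointly permuting grid axes and axis map, which is tested.

A phase series is the ordered per-phase masks of one (subject, state,
structure) over the cardiac cycle — canonically 20 phases, 0–95% in 5%
steps, with 0% as the reference phase. Series invariants (reference
phase present, strictly increasing percents, identical grids, no empty
phase) are enforced at assembly, so downstream code never sees a
degenerate series.

## Motion summaries

Per phase the pipeline computes the unweighted centroid of foreground
voxel centers (mm, patient axes), the volume (voxel count × voxel
volume, reported in mL), and — against the 0% phase only — the Dice
coefficient on voxel counts and the Hausdorff distance. Reference-phase
pairing (rather than all phase pairs) follows the reference-based
definition of the shape comparison; it is also what keeps the cost
linear in phase count.

Per-subject summaries:

- displacement per axis = max − min of the centroid component over the
  cycle (peak-to-peak), unsigned. This is the standard
  motion-management amplitude; a `mean_from_reference` alternative
  (mean per-phase unsigned offset from the reference centroid) is
  available behind a switch but is not the default.
- volume max/min/mean over all phases, variation
  `100·(V_max − V_min)/V_min`.
- DSC max/min/mean over the 19 reference comparisons, variation with
  the same (max−min)/min form. When the minimum DSC is exactly 0 (the
  structure leaves its reference-phase footprint entirely — small,
  fast-moving structures can do this) the variation is undefined; it is
  flagged NaN, logged with its identifiers, and excluded from cohort
  averaging rather than imputed.
- HD max and mean over the reference comparisons.

## Hausdorff distance

Both masks are reduced to their 6-connectivity boundary voxels (a
foreground voxel with a background face-neighbor; the grid border
counts as background). For solid voxelized shapes the Hausdorff
distance of the boundary sets equals that of the full sets, and the
reduction keeps the exhaustive reference implementation tractable. The
production implementation evaluates exact Euclidean distance transforms
(anisotropic spacing respected) of each surface set on the joint
bounding box and takes the larger directed maximum; it agrees with the
exhaustive pairwise reference to ≤ 1e-9 mm on randomized mask pairs
(tested on 200 pairs up to 16³). Only the classic maximum form is
provided — no HD95 or average-surface-distance variants.

Empty-vs-empty Dice (0/0) and any metric on an empty mask raise an
error rather than adopting a convention; series invariants make these
cases unreachable in the pipeline, so a silent default would only mask
upstream bugs.

## Cohort statistics

Cohort cells are mean ± SD (ddof 1) across subjects per (structure,
state, metric). Comparisons are two-sided at α = 0.05 with a normality
gate: Shapiro–Wilk on the paired differences (α = 0.05); if normality
is not rejected, a paired t test; otherwise a Mann–Whitney U test on
the two samples. Mann–Whitney is an *unpaired* rank test and pairing it
with a paired design loses power (with large between-subject spread it
can fail to reject even for a consistent within-subject effect); it is
kept as the default for fidelity to common practice in this study
design, a recommendation for the Wilcoxon signed-rank test is logged
whenever that branch is taken, and `nonnormal_test="wilcoxon"` switches
to it. Constant differences (including x = y) short-circuit to a
flagged degenerate result with p = 1. No multiple-testing correction is
applied. Percent changes between states default to the change of means
(`100·(mean(y) − mean(x))/mean(x)`); the mean of per-subject ratios is
available as a mode.

Type-I error of the gated test under a simulated null (both samples
from one normal, n = 23 pairs, 1000 replicates) is verified to lie in
[0.03, 0.07] at the 0.05 level, and power against a d = 1 shift at
n = 23 exceeds 0.9.

## The phantom

The synthetic cohort generator emulates the acquisition geometry and
effect structure of a breath-hold cine-MR motion study; it makes no
attempt at anatomical or MR-intensity realism.

**Grid.** 36 × 70 × 70 voxels at 5 × 2 × 2 mm: 5 mm slices along CC
(typical cine slice thickness) and 2 mm in-plane (the in-plane
resolution of such scans is not standardized; 2 mm is a realistic
choice given a 50 cm field of view).

**Structures.** Ten primitives with closed-form volume and centroid:
solid ellipsoids (heart, pericardium, LV, RV, VS, AS), concentric
ellipsoid shells (LVM, RVM), and capsules — tubes with hemispherical
caps — for the coronary branches (pmLAD, pLCX). The capsule caps and a
slight oblique tilt of the coronary axes avoid the severe slice
quantization a flat-capped, exactly slice-aligned cylinder suffers at
5 mm spacing. Sizes and motion amplitudes are illustrative magnitudes
for a healthy adult heart (whole heart ≈ 550 mL moving ~2–3 mm; RVM
with the largest LR excursion; coronaries with the largest CC
excursion; chambers with large volume excursions). The smallest
structures (atrial septum, coronary radii) are rendered larger than
their anatomical size and the strongest shell contractions moderated so
that every structure stays resolved (≥ roughly two voxels across) at
peak contraction on the fixed grid; with anatomical dimensions the
5 mm slices cannot support quantitative volume recovery. These defaults
are illustrative only and are never asserted against published cohort
values.

**Motion.** Per structure, an affine scale
`s(t) = 1 − a·(1 − cos(2πt/n))/2` on all linear dimensions about the
structure center (so `a` is the linear contraction amplitude and the
per-cycle volume ratio is `(1 − a)⁻³`) and a translation
`τ(t) = A·(1 − cos(2πt/n))/2` per patient axis, so `A` is exactly the
peak-to-peak centroid excursion for even phase counts. The raised
cosine is smooth, periodic, and has its extrema exactly at phases 0 and
n/2, which makes max/min-based truth values closed-form.

**States.** Each breath-hold state applies a global volume scale
(cube root on linear dimensions) and a CC offset: EIBH is the neutral
reference, EEBH scales volumes by 1.02 with a +2 mm (cranial) shift,
DIBH scales by 0.88 with a −10 mm (caudal) shift — the direction and
order of magnitude of deep-inspiration cardiac compression.

**Subjects.** Per subject and structure, multiplicative lognormal
jitter on the translation and contraction amplitudes (σ = 0.15, clipped
to [0.5, 1.6]) and on linear size (σ = 0.08, clipped to [0.85, 1.18],
i.e. ~24% volume SD — the order of inter-subject cardiac volume spread
and large enough that per-subject voxelization errors decorrelate
rather than repeating one shared grid alignment). Jitter is drawn from
a generator seeded by (phantom seed, subject index) only, so a
subject's realized motion is identical across states — a paired design.
Contraction is capped at 0.6 after jitter.

**Voxelization.** A voxel is foreground iff its center lies inside the
analytic primitive; truth is computed from the realized post-jitter
parameters in closed form. A structure whose analytic extent would
leave the grid at any phase raises an error naming structure and phase.
At the default resolution the voxelized volume of every default
structure is within 5% of its analytic volume at base geometry, and on
a 10-subject cohort the cohort-mean recovered peak-to-peak displacement
is within 2 voxel lengths per axis (in practice ≲ 0.3 mm) and the
cohort-mean volume variation within 3 percentage points of truth;
both are tested.

## Pipeline and reports

The pipeline writes a per-subject CSV (one row per subject, state, and
structure) plus four cohort tables — displacement (LR/AP/CC mean ± SD),
volume (max/min/mean/variation with the within-state max-vs-min
p-value), DSC (same shape), HD (max/mean) — and a between-state
comparison table, all with a fixed float format so identical
configurations reproduce byte-identical reports. Cohort cells with
fewer than two subjects are reported and skipped, never imputed; every
degenerate or undefined exclusion is logged with its identifiers. A
validation pass lists missing phases (relative to the union of phase
percents observed for that structure/state across subjects — a phase
missing from *all* subjects is therefore not detectable), missing
reference phases, unreadable files, empty masks, and grid mismatches
without computing any metric.

## Problem sizes

Tests and the acceptance script run the phantom at the default grid
with 10-subject cohorts for recovery and effect-direction checks, a
4-subject two-state cohort for the full Dice/Hausdorff table path, 200
random pairs up to 16³ for oracle equivalence, and 1000 replicates for
statistical calibration; the full suite completes in well under a
minute on one CPU. Larger cohorts (e.g. 23 subjects × 3 states × 10
structures × 20 phases) generate in minutes at desk scale.

## Known limitations

- Rigid-plus-uniform-scaling motion only: no deformation, strain,
  regional wall motion, or phase lag between structures; structures
  move independently and may overlap.
- No MR intensity simulation, noise, artifacts, intra-phase blur, or
  irregular rhythm; contouring variability is not modeled.
- Volume quantization at 5 mm slices limits per-subject volume-
  variation recovery for small structures; quantitative statements
  about sub-voxel-scale structures require the cohort averaging the
  tests use.
- Breath-hold states alter only global volume and CC position, so
  between-state displacement differences are null by construction;
  state comparisons of displacement exercise the statistical machinery,
  not a programmed effect.
- The Mann–Whitney branch of the normality-gated test is unpaired; see
  the statistics section for the logged caveat and the Wilcoxon option.
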