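# Methods

## Scope and data model

`tagstrain` analyses short-axis grid-tagged cine MRI of the left
ventricle: one sequence per slice level (basal, midventricular, apical),
frame 0 = end-diastole (ED), last frame = end-systole (ES), plus a
binary ED myocardium mask per slice (segmentation itself is an input,
not something this package does). All images are normalized to
zero-mean, unit-variance intensity per frame on load. Coordinates are
0-based, pixel-centred, `(x = column, y = row)`; polar angles are
counterclockwise from +x in the displayed (y-up) orientation.

## Phantom (synthetic data generator)

The phantom emulates the acquisition the method targets: a tagged
annular LV cross-section, 6 mm tag spacing, 1.5 mm isotropic pixels
(the clinical range is 1.32–1.75 mm), 8 frames ED→ES.

**Motion.** An incompressible ring contracts: a material point at ED
polar coordinates (r, θ) maps at frame t to
r′ = √(r² − c(θ)·Δ(t)), θ′ = θ + twist·t/(T−1), where Δ(t) ramps
linearly from 0 to r_endo,ED² − r_endo,ES². Contractility c(θ) ∈ [0,1]
is 1 in healthy tissue and reduced inside configured "infarct" sectors,
blended across a 10° cosine ramp so regional infarcts do not create
strain singularities. The inverse map is also closed-form, so frames
are rendered by evaluating the analytic tag texture (product of two
raised cosines at the tag period, amplitude decaying by a per-frame
fading factor to mimic tag fading) at the exact ED preimage of every
pixel — subpixel-exact, with no interpolation error. The blood pool and
background are static; Gaussian noise is optional; identical configs
(including seed) give bit-identical stacks.

**Ground truth.** The circumferential stretch of an ED arc element is
λ_c = √((∂r′/∂θ)² + r′²)/r (the tangential-gradient term is nonzero
only inside sector blending ramps; ∂c/∂θ is evaluated by a tiny central
difference, accurate to ~1e-9 since the ramp is C¹), and the
circumferential Green–Lagrange strain is E_cc = ½(λ_c² − 1). Rigid
twist contributes nothing, and c = 1 everywhere with Δ = 0 gives
E_cc ≡ 0.

**Default study conditions.** ED endocardial/epicardial radii
25/35 mm; ES endocardial radius 16 mm, i.e. ~20% midwall
circumferential shortening — the average healthy value the strain
literature reports — so healthy phantom segments sit clearly on the
healthy side of the benchmark table while remaining trackable. The
synthetic population used for evaluation gives each LV one contiguous
territory of two adjacent akinetic (c = 0.2) segments per slice:
infarcts occupy contiguous coronary territories, so scattered
single-segment lesions are deliberately not emulated (see Limitations).
A segment's ground-truth label is infarcted when its mean contractility
over its angular span is below 0.5.

**What the phantom does not emulate:** MR physics (k-space, SPAMM pulse
trains), through-plane motion, papillary muscles, breathing or motion
artifacts beyond global noise/fading, and anatomical variability.
Passing phantom tests therefore demonstrates correctness of the
numerics and logic under ideal imaging, not clinical performance.

## Tracking

Matching uses normalized cross-correlation. `ncc_match` computes the
full NCC surface of a template inside a search window (direct
sliding-window evaluation), picks the peak of |NCC| (sign reported, so
anticorrelated matches are detectable), breaks exact ties toward the
smaller displacement, and refines by independent quadratic fits through
the 3×3 neighbourhood (clamped to ±0.5 px). A perfect correlation
(≥ 1 − 1e−9) skips refinement, so identical frames yield an identically
zero field. Zero-variance templates raise a degenerate-texture error
and the caller falls back to the parent estimate.

`hierarchical_match` runs a four-level coarse-to-fine cascade —
template sizes 49/25/13/7 px with search radii 10/6/4/2 px, grid
strides 12/6/3/2 px — chosen so the coarsest template spans ≥ 2 tag
periods at 6 mm tags / 1.5 mm pixels. Each level is seeded by the
previous level's field, smoothed per component with a σ = 1 (grid
units) Gaussian, and interpolated bilinearly to dense form. Border or
degenerate points keep the parent estimate and are reported in a
structured warning.

`track_sequence` registers every frame to ED directly rather than
chaining frame-to-frame displacements: composition accumulates the
small per-pair bias (worst at the endocardial edge, where templates
straddle fast-moving wall and static cavity) into ~0.6 px at ES,
whereas ED-referenced matching is drift-free (~0.2–0.4 px ES RMS).
Because cumulative motion approaches the 4 px tag period by ES, a
full coarse cascade against ED becomes ambiguous (picket-fence lobes);
the tracker therefore runs the full cascade only for frame 1 and then,
for each later frame, re-matches only the finest level seeded by the
previous frame's field. Every search thus stays within half a tag
period, which is the condition that defeats wrong-lobe locking. The
difference vector V = P_ED − P_current is available on the result.

## Strain

Displacement gradients are computed on the regular ED lattice by
central differences, one-sided at mask boundaries; points with no
lattice neighbour along an axis are invalid and excluded from segment
statistics. The default tensor is E = ½(FᵀF − I) with F = I + ∇u
referenced to ED, which yields the expected negative ES circumferential
strain; a `literal` convention switch builds D = (I − ∇V)⁻¹ and
E = ½(DᵀD − I) instead for comparison (the two are not equivalent —
D is the inverse deformation). No additional smoothing is applied to E;
regularization already happened in tracking.

Local directions use the mask centroid: e_r radial, e_c its +90°
counterclockwise rotation. CS = e_cᵀ E e_c is a quadratic form, so the
stored y-down orientation affects only e_c's sign, never CS.

The AHA partition assigns equal-angle sectors (60° for 6-segment
slices, 90° for apical) by polar angle about the mask centroid,
anchored at the anterior RV-insertion angle (a required input; the
phantom's default anchor is 60° clockwise from image "up", i.e. polar
30°). Ids follow the standard numbering: 1–6 basal, 7–12 mid, 13–16
apical.

## Detection

`ES_calculated = Med(CS_ES)` per segment (median for outlier
robustness) is compared with a packaged benchmark table of healthy ES
circumferential strain means (SDs included) per slice and wall sector;
the apical slice's 4 segments take the mean of the paired
septal/lateral columns (lossless — the paired columns are equal). A
segment is flagged "potentially infarcted" when its shortening
magnitude is *strictly* below the benchmark mean magnitude; an optional
k·SD margin is exposed (default 0) since the table publishes SDs but
the rule as stated uses only means. "Less than the benchmark" is
implemented in magnitude terms — the only reading consistent with
reduced contraction, given both values are negative.

The H-spread of a segment is the interquartile range of its per-frame
median CS values S_f1…S_fES, using linear interpolation of the order
statistics (so IQR(1,2,3,4) = 3.25 − 1.75 = 1.5); a constant series
gives exactly 0. A flagged segment is infarcted when
100·(H_ref − H_seg)/H_ref ≥ α for its slice, where H_ref is the mean
H-spread of the *unflagged* segments of the same slice
(H_healthy_basal/mid/apical); when a slice has no unflagged segment the
mean over all unflagged segments of the LV is used (H_healthy_all), and
when no segment anywhere is unflagged all flagged segments are
classified infarcted with a structured warning. If H_ref = 0 (all
reference series constant) the reduction is undefined: the segment is
reported with NaN reduction, classified not-infarcted, and a warning is
emitted. Unflagged segments always carry reduction 0. Slice thresholds
default to α = 30 (basal), 30 (mid), 20 (apical) — the calibrated
values; the apical threshold is lower because partial-thickness
involvement dilutes apical segment statistics.

## Evaluation

Segments are the unit of analysis: each record carries the ground-truth
label and the H-spread-reduction score (0 for unflagged segments). ROC
curves sweep all distinct score thresholds (predict infarcted when
score ≥ threshold; scikit-learn's `roc_curve` with no intermediate
dropping), AUC is trapezoidal, and the 95% CI is a stratified bootstrap
(1,000 resamples by default, seeded). α selection evaluates the hard
decision rule at each grid value (default 10, 20, …, 100), scores it by
the AUC of the binary prediction (= balanced accuracy), and breaks ties
toward the smaller, more sensitive α. Repeated k-fold (default k = 5,
10 repeats, per slice level) selects α on training folds and scores
held-out folds; folds whose test part lacks a class contribute their
selected α but no AUC; a `test_fraction` option reproduces the
random-5%-test variant, and `by_participant` folds by patient to
prevent within-patient leakage (the default pools segments, matching
the published protocol). All randomness flows from one seed; identical
seeds give identical outputs.

Confusion rates follow TPR = TP/(TP+FN) and FPR = FP/(TN+FP), reported
as NaN when the denominator is 0 (e.g. healthy participants have no
positives, so sensitivity is undefined while FPR is not).

## Numerical choices and degenerate inputs

- NCC is evaluated in float64 directly (no FFT), surfaces clipped to
  [−1, 1]; windows with near-zero variance score 0.
- Subpixel refinement is the standard 3-point parabola per axis,
  clamped to half a pixel.
- Field smoothing σ = 1 grid unit per level; unvisited grid nodes are
  filled from the nearest valid node before smoothing.
- Quantiles: linear interpolation of order statistics throughout.
- Degenerate cases (empty masks, single-frame stacks, centroid points,
  single-class ROC inputs, k < 2) raise explicit `ValueError`s;
  recoverable issues (border templates, degenerate texture, all-flagged
  slices) emit structured warnings and are recorded in run manifests.

## Problem sizes

Default test and acceptance runs use 128×128 px slices, 8 frames,
~820 myocardial points per slice, and a 20-LV synthetic population
(960 labeled segments); these sizes give stable statistics for every
check while keeping a full run in the order of a minute.

## Known limitations

- Strain is 2D in-plane; radial/longitudinal strain, transmural
  layering, and the 17-segment apex cap are out of scope.
- The tracker assumes inter-frame motion well under the tag period;
  very low frame rates or extreme contraction (endocardial stretch
  below ~0.6) degrade accuracy.
- A healthy segment sandwiched between two separate akinetic sectors
  inherits reduced strain from the blending ramps and field smoothing
  and can be misclassified; contiguous territories do not show this.
- Benchmark flagging depends on literature values for healthy adults;
  cohorts with globally altered strain (e.g. cardiomyopathy) would need
  a recalibrated table.
- The evaluation harness quantifies separation on synthetic cohorts;
  clinical AUC requires clinical data.
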