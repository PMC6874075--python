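# Methods

This note documents the models, parameter choices and numerical decisions
behind `tibiamct`, in the spirit of a methods appendix: what each stage
assumes, what the synthetic data do and do not emulate, and where the
design was genuinely open.

## Conventions and units

Images are `(z, y, x)` arrays with isotropic spacing in μm; Z is the
longitudinal axis and slice 0 is proximal. Calibrated images carry tissue
mineral density (TMD) in mg HA/cc; BMC is reported in mg (voxel volume in
cm³ for unit coherence with mg/cc). Mechanics use mm, MPa (N/mm²), N and
microstrain (με). Left limbs are horizontally flipped into the right-limb
frame before analysis so that paired comparisons and quadrant labels line
up anatomically.

## Preprocessing

* **Calibration.** TMD = intercept + slope·grey, least-squares fitted to
  the mean grey values of hydroxyapatite inserts of known density
  (800/400/200/100/0 mg HA/cc in the quality-control phantom generator).
  Negative calibrated densities are clamped to zero: density is physically
  non-negative and the background insert defines zero.
* **Gaussian filter.** Discrete kernel: normalised tabulation of
  exp(−r²/2σ²), σ = 0.65 voxel, support truncated to 3×3×3 (the truncation
  radius is set to exactly one voxel). Boundary: reflection.
* **Threshold.** 256-bin histogram over the VOI, 5-bin moving-average
  smoothing, the two most prominent local maxima taken as background and
  bone peaks (a second mode must reach 5% of the tallest peak's
  prominence, otherwise the histogram is declared unimodal and a manual
  threshold is required); the threshold is the midpoint of the two peak
  grey levels. The boundary rule is inclusive: voxel ≥ threshold ⇒ bone,
  so the threshold value itself is in the bone phase.
* **Despeckle.** 26-connected 3-D components smaller than 10 voxels are
  removed; "smaller than" is strict, a 10-voxel component survives. The
  despeckle connectivity (26, as in CTAn-style "3-D volumes") is a
  separate parameter from the FE mesh connectivity (6).
* **Closing.** Cortical pores are closed per slice with a Euclidean disk
  of radius 10 px. Dilation/erosion are computed via per-slice distance
  transforms, which is exactly equivalent to the explicit
  structuring-element operations (verified against them in the tests) and
  much faster on stacks.
* **Alignment.** Phantoms are generated pre-aligned, so image-to-image
  registration is replaced by principal-axis alignment (first principal
  axis of the bone voxel cloud mapped to Z; nearest-neighbour resampling
  for masks, trilinear for greyscale; an isotropy guard raises when no
  dominant axis exists). This is a deliberate substitution: mutual-
  information registration adds an operator-free dependency on a fixed
  reference scan that synthetic studies do not need.
* **Length.** Slab convention: (last − first occupied slice + 1) × spacing,
  so a single-slice object is one spacing long.

## Morphometry

* **Local thickness** follows the model-independent maximal-sphere
  definition: the thickness at a voxel is the diameter of the largest
  inscribed ball containing it. A digital ball centred at c with EDT value
  d(c) covers the voxels strictly closer than d(c) (the nearest background
  voxel sits exactly at d(c)); its diameter in voxels is 2·d(c) − 1. The
  map is computed as a sequence of openings — for every distinct EDT value,
  descending, the set {d ≥ r} dilated by r — which is exactly the union of
  all inscribed balls without enumerating centres. Everything outside the
  supplied grid counts as background, so thickness is bounded by the VOI
  extent. Known bias: for structures a few voxels thick the strict
  inscribed-ball rule underestimates the nominal diameter by roughly one
  voxel (rim voxels are not covered by the central ball); at the study's
  resolution (50 μm rods at 10.4 μm spacing) this propagates into Tb.Th
  and hence inflates the Tb.N ratio by tens of percent. The tests
  therefore check exact agreement with an exhaustive sphere oracle, the
  sphere/plate analytic cases, and ground-truth recovery with tolerances
  that reflect this digitisation bias.
* **Trabecular VOI.** Slices [ref + 0.2 mm, ref + 1.2 mm] below the
  reference slice (the growth-plate merge point — an input parameter;
  phantoms carry it in their ground truth). The manual contouring of the
  original workflow is operator-dependent and is replaced by an automatic
  endosteal contour: per slice, the cortical shell is the largest 2-D
  component of the raw bone mask (trabecular struts are smaller, separate
  components), pore-closed, filled, and eroded one pixel past its own
  maximal depth; the remaining interior is the trabecular region. Slices
  whose bone encloses no cavity (no cortex) keep the full slice.
* **Tb.N** uses the plate-model ratio (BV/TV)/Tb.Th. The mid-axis-spacing
  variant used by some scanner softwares is noted as an alternative but
  not implemented.
* **Cortical VOI.** 1 mm centred at the midshaft, defined as 50% of the
  computed tibia length. Tt.Ar = filled periosteal area, Ct.Ar = closed
  bone area (slice means); Ct.Th is the 3-D direct (maximal-sphere)
  thickness of the closed cortical phase — the 3-D choice was open and is
  flagged. Non-annular sections are flagged but still measured.

## Densitometry

The densitometric VOI starts at the first slice distal to the growth plate
and spans 80% of the tibia length. Fibula exclusion is a per-slice
component-tracking rule: the principal tibial component is seeded as the
largest component on the first slice and followed by maximal overlap with
the previous filled periosteal envelope; components inside the envelope
(trabecular struts) are kept, components outside (the fibula) are dropped.
Ten equal longitudinal sections (remainder slices to the most distal
section) × four quadrants make 40 partitions. Quadrant boundaries are the
two vertical planes through the per-section bone centroid at ±45° to the
image X axis; the anatomical mapping (lateral = +X, anterior = +Y,
medial = −X, posterior = −Y) is an orientation convention and
configurable, since the source method does not state the plane equations.
Sector membership uses exact integer sign tests on count-scaled centroid
offsets, so a 90° grid rotation permutes partitions exactly (the voxel
exactly on the centroid, possible only for symmetric masks, is assigned to
the lateral sector by convention). Partitions cover the full cross-section
of the slice range, so BMD divides by the section×quadrant block volume.
Conservation (Σ partition BMC = whole-VOI BMC) holds to machine precision
by construction and is asserted in the tests.

## Micro-FE

Each bone voxel of the largest 6-connected component becomes an 8-node
hexahedral element with homogeneous isotropic linear elasticity
(E = 14.8 GPa, ν = 0.3; heterogeneous, density-mapped properties are out
of scope). The element matrix uses 2×2×2 Gauss quadrature (exact for the
trilinear integrand) and is computed once per model since all elements are
identical cubes. Assembly is double precision throughout.

* **Stiffness case.** Proximal-surface nodes fixed in all DOFs; distal
  nodes carry a prescribed axial displacement directed proximally, with
  transverse DOFs left free — the literal reading of an axial-displacement
  boundary condition, which also makes the ν = 0 closed form E·A/L exact
  (at ν = 0 a uniform uniaxial state satisfies the discrete equations
  identically). Whether the original solver also pinned transverse DOFs is
  unknown; free was chosen and flagged.
* **Strength case.** Proximal fixed; a unit probe load equally distributed
  over the distal nodes. Element centroid strains come from the
  Gauss-point-averaged strain-displacement matrix; nodal strains are the
  volume average of adjacent element strains ("nodes" in the 2% criterion
  is read as mesh nodes). Principal strains per node; nodes within 10% of
  the total mesh length of either end are excluded from the criterion
  (not from the solve). Per node λ = min(10300/|ε₃|, 8000/ε₁) over the
  applicable modes (με); strength = probe load × λ₍ₖ₎ with
  k = ceil(0.02·N), ascending order, ties sharing rank deterministically.
  Equal nodal loads are exactly consistent with a uniform stress state
  only when every distal node has equal tributary area, hence the analytic
  strength benchmark uses a single-element cross-section; general meshes
  are validated against a brute-force incremental load-scaling oracle.
* **Solver.** Constrained DOFs are eliminated; the reduced SPD system is
  solved directly (sparse LU) up to 40 000 free DOFs and by
  Jacobi-preconditioned conjugate gradients (relative residual ≤ 1e-8,
  cap 10·N_dof iterations) above. The direct path exists because the
  analytic benchmarks demand 1e-6 relative accuracy, which a Krylov
  tolerance of 1e-8 does not always guarantee through the reaction sum;
  whole-bone models use CG. Whole-bone meshes may optionally be coarsened
  by an integer factor (majority rule) before meshing to keep study runs
  tractable; the element edge scales accordingly.

## Statistics

Per parameter, a linear mixed-effects ANOVA on the pooled records: fixed
effects Strain, Intervention, Side and all two-way interactions, random
intercept per mouse, REML (delegated to statsmodels' `MixedLM`; the
bespoke content is the gating/splitting/pruning/contrast pipeline and the
reporting convention). All factors are two-level and sum-coded (±1), so
each term is one coefficient and, in the balanced design, coefficient
tests equal ANOVA term tests.

* **Degrees of freedom.** Containment (split-plot) rule: between-mouse
  terms against n_mice − p_between, within-mouse (Side-involving) terms
  against n_obs − n_mice − p_within — exact for the balanced paired design
  (a Satterthwaite approximation is not available for `MixedLM`; the
  choice is logged here).
* **Gating.** Shapiro–Wilk on the marginal residuals; Levene (Brown–
  Forsythe) across interventions and across strains, applied to per-mouse
  averages — the two limbs of a mouse are strongly correlated and treating
  them as independent inflates the false-flag rate of the variance test
  several-fold. Heteroskedasticity (p < 0.05) triggers subgroup
  splitting; the split factor defaults to the parameter's conventional
  choice (intervention for cortical/size/BMC-type parameters, strain for
  volume-fraction-type) and otherwise to the factor with the smaller
  Levene p.
* **Pruning.** Non-significant two-way interactions removed iteratively,
  largest p first (the original pruning order is unstated; largest-first
  is deterministic), refitting after each removal; main effects always
  retained.
* **Contrast.** Left/right estimated marginal means are model predictions
  averaged over the remaining factor grid; the difference carries a
  t-based CI on the within-mouse df. Percent difference = 100·diff/left
  marginal mean, with the CI endpoints scaled the same way and rounded to
  one decimal in reports. The SD column reports the SD of the raw
  per-mouse paired differences.
* **Calibration.** The full procedure (gating + splitting + pruning +
  contrast) has a slightly inflated type-I error — splitting doubles the
  number of Side tests when spuriously triggered, and pruning is a
  selection step. On 100 null cohorts of 20 mice the measured rejection
  rate is ~7% at nominal 5%, and CI coverage of an injected −14.2% effect
  is 97–99%; both are asserted in the acceptance tests and recomputed by
  the acceptance script.

## Synthetic phantoms

The phantom emulates the measurement situation, not anatomy: a cortical
shell whose periosteal radius and cortical thickness hold a metaphyseal
value over the trabecular region (wide canal, thin cortex) and taper
linearly to a distal value (narrow shaft, thick cortex); a lattice of
axis-aligned rods on a jittered grid in the medullary canal; uniform
tissue density (720 mg HA/cc by default); grey = (TMD − intercept)/slope
plus Gaussian detector noise in grey units (default curve: slope
0.7 mg HA/cc per grey, intercept −50, i.e. bone ≈ 1100 grey,
background ≈ 70; noise SD 30 grey in studies for a contrast-to-noise ratio
of ~30). Default geometry: 380×104×104 voxels at 10.4 μm (a ~4 mm
bone — a scaled-down tibia, so lengths and stiffnesses are not those of an
18 mm tibia), periosteal radius 500→300 μm, cortex 110→250 μm, rods of
50 μm at 170 μm pitch in a 1.2 mm proximal region, giving Tb.Th ≈ 50 μm,
Tb.N ≈ 1–1.5 /mm and Tb.BV/TV in the mouse range — matching the scale of
the measured trabecular parameters (left-limb Tb.N ≈ 1.4 /mm). The rod
lattice is not a physiological network; its virtue is analytic ground
truth (rod count, diameter, areas, per-voxel density) recomputable from
the noiseless label field by direct counting.

Left/right pairing: the right image is the mirrored left (reflection
across the sagittal plane) with the configured effect applied — rod count
scaled (selection seeded), rod diameter scaled, periosteal radius scaled
by √(1+δ/100) so the area changes by δ — and an independent noise draw.
Zero effect and zero noise give a voxel-for-voxel mirrored pair;
identical spec and seed give bit-identical output. The fibula is not part
of the default phantom; a small off-axis rod can be added to exercise the
exclusion rule. No scanner physics (beam hardening, ring artefacts,
partial-volume blur beyond the reconstruction filter) is emulated;
phantoms represent already-corrected reconstructions. Passing tests on
phantoms therefore demonstrate correctness of the measurement chain and
statistical recovery under known truth, not robustness to scanner
artefacts or anatomical variability.

Study cohorts add per-mouse biological variation (multiplicative
perturbations of radius, cortical thickness, rod diameter and tissue
density, CV 3% by default, shared by both limbs of a mouse) so that the
mixed model sees realistic between-mouse variance. The record-level
simulator (`stats.simulate_study_records`) mirrors the measured
trabecular-number structure directly: strain×intervention cell means
1.39/1.06/1.66/1.51 per mm, between-mouse SD 0.2, residual SD 0.131
(giving a paired-difference SD ≈ 0.185), 5 mice per cell, with the
right-side effect applied multiplicatively.

## Problem sizes

Test and acceptance runs use reduced problem sizes chosen to exercise
every code path at full fidelity: phantom studies of 4 mice on
220×88×88 grids with 0.5 mm trabecular VOIs, whole-bone FE coarsened to a
6-voxel element edge (~4–15 k elements), analytic FE benchmarks at
10×10×100 voxels, thickness oracles at ≤32³, and statistical calibration
over 100 cohorts of 20 mice. All quantities reported by the acceptance
script are computed at run time under these sizes.

## Known limitations

* Thickness-based metrics inherit the one-voxel digitisation bias for
  structures a few voxels thick (see above); comparisons between limbs are
  unaffected because both sides share the bias.
* The Tb.N plate-model ratio deviates from rods-per-unit-length for
  rod-like architectures.
* Registration is principal-axis only; intensity-based registration of
  real longitudinal scans is out of scope.
* Micro-FE assumes homogeneous linear elasticity and voxel meshes;
  geometric/material nonlinearity and experimental validation are out of
  scope.
* The mixed-model pipeline assumes two-level factors throughout.
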