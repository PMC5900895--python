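# Methods

## Model and procedure

The package treats static B0 shimming as masked linear least squares. Shim
coils produce fields shaped as real solid harmonics; on a voxel grid with
world coordinates in mm (isocenter at the origin, x left-right, +y
anterior, +z superior, B0 along z) the basis is evaluated in unnormalized
Cartesian polynomial form — 1; x; y; z; z²−(x²+y²)/2; xz; yz; x²−y²; xy;
and so on through fourth order, (N+1)² terms in total. This convention
matches shim-coil naming (Z2, XZ, ...); coefficients carry units of
Hz·mm⁻ⁿ for an order-n term, so the choice of polynomial scaling is
absorbed by the coefficients and never affects residuals. Every polynomial
satisfies Laplace's equation, which the test suite verifies with a
27-point isotropic finite-difference Laplacian (its leading error term is
proportional to the biharmonic and therefore vanishes on harmonic
polynomials through fourth order).

A shim setting s for a field f over a brain mask minimizes ‖f + Bs‖ on
masked voxels — the shim field *adds* to the subject's field, so the
optimal coefficients are the negated projection. The DC term is always in
the design; the optimal residual is then mean-free, and minimizing RMS is
identical to minimizing the standard deviation, which is the reported
metric (population convention, divisor N — immaterial at brain-mask voxel
counts but fixed for reproducibility). The least-squares solve is a
column-scaled SVD; rank deficiency raises an error naming the
unresolvable terms rather than silently truncating, since a silently
truncated fit would corrupt strategy comparisons.

Template-based prediction works in a standard space. Each database field
map is unwrapped, cleared of the scanner's baseline shim field
(synthesized from recorded settings through the harmonic basis or a coil
calibration), QC'd for ≥ 90% brain coverage, and warped to standard space
with an affine transform; the template is the voxelwise mean over subjects
valid at each voxel, with the voxelwise standard deviation and
contribution count retained. For a new subject, a structural localizer is
registered to the standard-space anatomy (12 dof), the inverse transform
pulls the template mean into subject space, and the shim is computed from
that predicted field.

Instead of an external brain atlas, the standard space is the cohort
generator's own mean anatomy on a 2-mm grid, so the repository ships no
third-party volumes; any NIfTI anatomy with a brain mask is a drop-in
replacement, and externally computed plain-text 4×4 transforms can be
injected in place of the built-in registration.

## Synthetic cohort: what it emulates, and what it does not

`b0shim.synthetic` generates the study conditions. Each subject is a
shared parametric head (ellipsoidal head and brain, frontal-sinus and
ear-canal air cavities, a neck stub) warped by a random affine — rotations
N(0, 5°) per axis, scales N(1, 5%), translations N(0, 3 mm), emulating
uninstructed head positioning — with cavity radii jittered by 20%. The
susceptibility contrast between tissue and air is 0.36 ppm (configurable);
the induced field follows from the k-space dipole kernel
D(k) = 1/3 − kz²/|k|² with the Lorentz-sphere convention, under which the
interior of a uniform sphere shifts by exactly zero — stated explicitly
because conventions differing by Δχ/3 circulate. D(0) is set to 0: the
mean field is a convention, and shimming is blind to the DC term. The
volume is zero-padded by a factor of 2 (after subtracting the
volume-face background value, so the object is effectively embedded in
infinite background medium) to suppress circular-convolution wrap-around;
against the uniform-sphere closed form this setup is accurate to ~1% at
exterior points and ~0.02% of scale inside.

On top of the dipole field, every subject receives the same scanner-frame
gradients (2 Hz/mm inferior-superior, 1 Hz/mm anterior-posterior),
emulating the body-induced field; subject-specific Gaussian field
perturbations (σ = 10 mm) at the cavity locations with amplitudes drawn
from N(0, 30 Hz) at the sinus and N(0, 20 Hz) at the ears; 1 Hz voxel
noise; and a random baseline shim (uniform per term, ±0.5 Hz/mm first
order, ±0.01 Hz/mm² second order) standing in for unknown scanner state.
The default grid is 64³ at 2 mm isotropic, matching typical field-map
resolution. The amplitudes are free parameters chosen to give a plausible
desk-scale 7 T brain field (unshimmed standard deviation ≈ 40 Hz,
localized cavity structure of tens of Hz); they are not claims about any
human population, and absolute residuals in Hz are therefore not
comparable to values measured in people — only the *orderings* and
*invariants* across strategies are meaningful, which is what the tests
assert. Real-data features deliberately absent: realistic tissue classes,
chemical shift, R2* decay, flow and motion, and the full ~10 ppm air-tissue
susceptibility contrast.

One physical feature the generator does reproduce: scanner-frame field
components do not co-rotate with anatomy, so template prediction degrades
for strongly rotated heads. Passing tests consequently bound the
prediction error pooled over a cohort, not per subject.

## Evaluation design

The leave-one-out evaluation holds out one subject; the template, the
individual fixed shims, their average, and the per-term random-shim
ranges are all derived from the remaining subjects only (no leakage; the
per-subject precomputations depend on that subject alone, so fold
training sets are leak-free by construction, and an explicit guard aborts
if a held-out subject appears in its own training set). All strategies for
a subject are scored with the same basis and brain mask, making the
measured-field shim an exact lower bound — asserted, not assumed. The
tune-up shim is represented by the all-zero setting: no phantom
calibration exists for synthetic data, whereas a real scanner's tune-up is
a nonzero phantom-optimized setting; only its role (no subject
information) is preserved. Random-shim ranges are recomputed within each
fold rather than once globally — the leakage-free choice where either
reading is defensible. Residual std is computed over the same mask used
for fitting.

The Wilcoxon signed-rank test drops zero differences, assigns mid-ranks to
ties, enumerates the exact null over all 2ⁿ sign patterns for n ≤ 12
retained pairs (valid under ties), and uses a tie-corrected normal
approximation above; all differences zero returns p = 1 by definition.

## Numerical choices

- Wrap convention (−π, π], half-open at −π.
- Unwrapping: quality-guided region growing (quality = inverse local
  wrapped-gradient variance, optionally magnitude-weighted), correct
  modulo one 2π constant per connected component when neighbouring true
  phase differences stay below π; each component's constant is fixed by
  bringing its median into (−π, π]. Volumes are unwrapped as 3D even for
  2D-acquired slices. Wrap ambiguity beyond ±1/(2ΔTE) (±490 Hz at
  ΔTE = 1.02 ms) is not resolved — severely aliased voxels stay aliased.
- Registration: SimpleITK, normalized cross-correlation on all voxels (no
  random sampling, hence deterministic), geometric center initialization,
  regular-step gradient descent over a 3-level pyramid whose finest level
  is half resolution — sufficient for the smooth structural images used
  here (recovery of known affines to ≲0.3°, ≲0.1 mm, ≲0.6% scale).
  Field maps are interpolated trilinearly, masks nearest-neighbour;
  resampling is pull-based and marks out-of-footprint voxels invalid.
- Field-map-to-structural alignment is rigid (6 dof); structural-to-
  standard is 12 dof.
- Template mean/std use a one-pass accumulator; the std of identical
  inputs is zero only to ~√ε relative accuracy.
- Degenerate inputs raise typed errors: empty masks, rank-deficient
  designs (naming terms), constant images in registration, identical
  calibration settings, mismatched term sets, broken transform chains.

## Problem sizes

The shipped evaluation uses a 20-subject cohort at 64³ × 2 mm with 100
random shims per fold, and 10 training + 10 held-out subjects for the
prediction experiment — sizes chosen so the full test suite and the
acceptance script each complete in minutes on a single CPU while leaving
every statistical comparison well resolved. Larger cohorts sharpen the
strategy means (the template error itself shrinks as 1/√n, which is
verified explicitly) but do not change any asserted ordering.

## Known limitations

- The vendor's iterative routine shim is not emulated; hardware current
  limits are not enforced (no clamping), and coil winding geometry and
  eddy currents are out of scope — coil impurities enter only through the
  calibration matrix.
- Registration is affine only; no nonlinear refinement.
- Because synthetic cavity perturbations are partly unpredictable by
  construction, the template's advantage over the averaged fixed shim seen
  in real populations is not reproduced at desk scale: with modest
  positional variation the fixed-shim strategies perform relatively
  better here, consistent with the observation that fixed shims approach
  template performance when head positioning is tightly constrained.
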