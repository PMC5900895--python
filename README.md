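# b0shim

Template-based B0 field-map prediction and spherical-harmonic shimming for
brain MRI.

## The problem

Static B0 shimming homogenizes the scanner's main field over the brain by
driving room-temperature shim coils whose fields are shaped as real solid
harmonics (X, Y, Z, Z2, XZ, ...). The usual workflow first acquires a
dual-echo B0 field map — a minute or more of scan time — and then solves a
masked linear least-squares problem for the shim currents. This package
implements and evaluates an alternative that needs **no field map**: the
field in a new subject's brain is *predicted* from a template built out of
a database of field maps from other people, using only a quick structural
localizer to map the template into the subject's head.

The approach rests on an empirical observation: across subjects, the
low-order part of the brain's susceptibility-induced field (dominant
inferior-superior and anterior-posterior gradients) is highly consistent,
while the intersubject variability concentrates near the frontal sinuses
and ear canals — spatial structure too high-order for shim coils to
correct anyway. A template therefore retains exactly the part of the field
a shim can act on.

## What the package does

- **`b0shim.harmonics`** — real solid-harmonic bases through 4th order
  ((N+1)² terms), least-squares field decomposition, and shim-coil
  calibration from fields measured at stepped hardware settings.
- **`b0shim.processing`** — field maps from dual-echo phase
  (`field = wrap(Δφ)/(2π ΔTE)`), quality-guided region-growing 3D phase
  unwrapping, baseline-shim removal from recorded settings, and the 90%
  brain-coverage QC rule for database inclusion.
- **`b0shim.spatial`** — affine transform algebra with space-label
  checking, pull-based resampling, intensity-based registration (rigid and
  12-dof), template construction (voxelwise mean/std of registered field
  maps), and inverse-warp field prediction.
- **`b0shim.synthetic`** — a seeded cohort generator: parametric head
  susceptibility models with air cavities, the k-space dipole forward
  model D(k) = 1/3 − kz²/|k|², per-subject affine variation, baseline
  shims and dual-echo phase simulation.
- **`b0shim.evaluation`** — static shim computation (minimize the residual
  field's standard deviation over the brain mask), the seven comparison
  strategies (measured / individual & averaged registered / individual &
  averaged fixed / random / tune-up), leave-one-out cross-validation with
  strict fold separation, and an exact-enumeration Wilcoxon signed-rank
  test.

The shim for a field f is the setting s minimizing ‖f + Bs‖ over masked
voxels, where B holds the harmonic basis fields (DC term included, so
minimizing the RMS equals minimizing the standard deviation); the optimal
coefficients are the negated least-squares projection of f onto B.

## Worked example

```
b0shim simulate-cohort --n 10 --seed 7 --out cohort/
b0shim build-template --cohort cohort/ --out template/
b0shim predict --template template/ --localizer cohort/sub-000_structural.nii.gz \
       --out predicted.nii.gz
b0shim shim --field predicted.nii.gz --mask predicted_mask.nii.gz \
       --order 2 --out shim.json
b0shim evaluate --cohort cohort/ --out eval/
```

The same pipeline from Python, on a 20-subject synthetic cohort:

```python
from b0shim import CohortConfig, EvalConfig, loocv_evaluate, sample_cohort, template_anatomy

cfg = CohortConfig(n_subjects=20, seed=1)
cohort = sample_cohort(cfg)
ev = loocv_evaluate(cohort, EvalConfig(seed=2), anatomy=template_anatomy(cfg))
print(ev.strategy_means().round(2))
```

prints the mean residual-field standard deviation (Hz) per strategy:

```
strategy
measured                  2.90
tuneup                   41.43
averaged_registered       6.24
individual_registered     8.10
individual_fixed          4.80
averaged_fixed            3.91
random                    6.02
```

Reading: with no subject-specific shim (`tuneup`, an all-zero setting on
synthetic data) the brain field has a 41 Hz standard deviation. Shimming
from the subject's own measured field map (the lower bound by
construction) leaves 2.9 Hz. The template prediction
(`averaged_registered`) reaches 6.2 Hz using no field measurement at all —
most of the way to the optimum — and even strategies using only the
database's shim statistics (`random`, `averaged_fixed`) far outperform the
no-information baseline, because the dominant field structure is shared
across subjects.

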