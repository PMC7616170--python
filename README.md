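# scarshape

Quantitative characterization of myocardial scar from late gadolinium
enhancement cardiac MR (LGE-CMR), for researchers studying the
arrhythmogenic substrate of ventricular tachycardia and the effect of
post-processing threshold choices on scar metrics.

Ablation workup routinely maps the left ventricle as a color-coded
pixel-signal-intensity (PSI) volume — each voxel's signal expressed as
a percentage of the maximal myocardial signal (the full-width-at-half-
maximum, FWHM, normalization) — and splits it into three tissue
classes under a threshold band *(t_low, t_high)*:

- **healthy** myocardium: PSI < t_low
- **border zone (BZ)**: t_low ≤ PSI ≤ t_high
- **scar core**: PSI > t_high

The conventional band is 40–60%; this package implements that scheme
for arbitrary bands (the four clinically studied configurations
45–55, 40–60, 35–65 and 30–70 are built in) and quantifies, per band:

- tissue **masses** in grams (voxel count × voxel volume × 1.05 g/mL),
  with the exact partition *total enhancement = BZ + core*;
- **conducting corridors** (channels/isthmuses): connected BZ regions
  surrounded by scar core, with per-corridor mass;
- a labeled **tetrahedral volume mesh** and the two **interface
  surface areas** — healthy ↔ hyperenhancement (BZ + core) and
  BZ ↔ core — in cm²;
- **outcome statistics** relating per-patient metrics to arrhythmia
  recurrence: Pearson r, empirical ROC with the rank (Mann–Whitney)
  AUC, Youden-J optimal cutoffs (J = sensitivity + specificity − 1),
  and paired mean differences with t-based CIs.

Because clinical LGE stacks cannot be redistributed, the package
includes a synthetic **phantom generator** — an ellipsoidal-shell LV
at 1.3 × 1.3 × 5 mm resolution with configurable infarct patches, BZ
rims, corridors, transmural enhancement falloff and noise — plus a
**cohort generator** with a stated logistic recurrence model, so every
stage has an analytic or ground-truth oracle.

## Worked example

```python
import scarshape as ss

# a transmural infarct phantom with one conducting channel and a
# partial-volume blur so tissue fractions genuinely depend on the band
patch = ss.ScarPatchSpec(channels=(ss.ChannelSpec(width_mm=5.0),))
spec = ss.PhantomSpec(scar_patches=(patch,), psf_fwhm_mm=3.0, seed=7)
stack = ss.generate_phantom(spec)
print(ss.characterize_stack(stack).to_string(index=False))
```

```
config  healthy_g  bz_mass_g  core_mass_g  total_enhancement_g  corridor_count  corridor_mass_g  surface_healthy_he_cm2  surface_bz_core_cm2
 45-55  94.092863   5.119433    17.833725            22.953158               1         4.489485                 21.3369              19.3271
 40-60  93.569385   6.122025    17.354610            23.476635               1         4.702425                 19.5143              21.6632
 35-65  93.214485   6.947168    16.884368            23.831535               1         4.835513                 19.1984              22.0467
 30-70  92.841840   7.719075    16.485105            24.204180               1         6.343838                 19.8263              22.1169
```

Each row is one threshold configuration. Widening the PSI band moves
the graded boundary voxels from core into border zone: BZ mass grows,
core mass shrinks, and total enhancement equals BZ + core exactly in
every row. The single inserted channel is recovered at all four bands
while its mass grows with the band width; corridor count staying flat
as corridor mass grows is exactly the threshold-sensitivity pattern
this kind of analysis studies. The interface areas are the summed
facet areas of the labeled tetrahedral mesh.

The statistics layer works the same way on a synthetic cohort:

```python
cohort = ss.generate_cohort(n=27, seed=1)
report = ss.roc_summary_report(cohort)     # AUC per metric x band; Youden
                                      # cutoff/sens/spec/J where AUC > 0.7
```

A command-line interface mirrors the library
(`scarshape phantom|cohort|psi|classify|corridors|interface|stats`);
volumes are NIfTI, meshes and shell layers legacy ASCII VTK, cohorts
CSV.

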