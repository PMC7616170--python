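# Methods

## PSI normalization (FWHM)

Every in-mask voxel's signal intensity is expressed as a percentage of
a reference maximum taken over the whole LV myocardium mask:
`psi = 100 · SI / SI_ref`, clipped to [0, 100]. Two reference modes:

- `global_max` — the maximal in-mask SI. Exact on noise-free
  phantoms; used wherever a test needs exact PSI levels.
- `robust_percentile` (default, 98th percentile) — guards against hot
  pixels; values above the reference clip to 100.

Normalization is global per ventricle, not per slice and not per
layer: a single reference keeps the PSI field continuous across
slices. By construction, PSI 50 is the "half maximum" of the FWHM
scheme, and PSI is invariant to rescaling all intensities by a
positive constant.

## Tissue classification and masses

A threshold band `(t_low, t_high)` in PSI percent assigns
healthy (< t_low), border zone (closed interval [t_low, t_high]) and
core (> t_high). Voxels exactly at a threshold are border zone; the
closed interval is stated explicitly because floating-point
comparisons at the boundary are otherwise ambiguous. The four standard
bands are 45–55, 40–60, 35–65, 30–70 (narrowest first; widening the
band can only grow the BZ set and shrink the core set, which is the
mechanism behind the monotone mass trends across bands).

Masses are computed on the voxel grid — count × voxel volume ×
density — with myocardial density 1.05 g/mL. Voxel-grid masses are
exact and independent of any mesh or layer count; the partition
identities (BZ + core = total enhancement; healthy + enhancement =
total myocardial mass) hold to machine precision and are
property-tested.

## Corridor detection

Corridors (conducting channels/isthmuses) are operationalized as
26-connected components of BZ voxels whose within-myocardium boundary
is predominantly scar core. For each component, face-adjacent (6-
connectivity) non-BZ neighbours inside the myocardium are counted as
core or healthy contacts; a component is a corridor iff
`core / (core + healthy) ≥ core_fraction_min` (default 2/3) and it has
at least `min_voxels` voxels (default 5, suppressing single-voxel
noise). Permissive 26-connectivity groups the component; conservative
face adjacency counts its contacts. Contacts against the mask exterior
(blood pool, epicardial fat) are not counted on either side. The
contact-fraction rule deliberately admits both fully core-enclosed
channels and true isthmuses that open into healthy tissue at their
ends; both knobs are exposed on the CLI. Components are ordered by
minimum linear voxel index, making detection a pure, order-independent
function of the label field. On phantoms with non-touching inserted
channels (width ≥ 2 voxels, core rims ≥ 2 voxels), recovery is exact.

## Labeled mesh and interface areas

Each in-mask voxel is split into five tetrahedra (one central, four
corner tets), with the two mirror-image decompositions assigned by
voxel checkerboard parity so that shared cube faces of neighbouring
voxels are cut along the same diagonal — the mesh is conforming and
element volumes sum exactly to voxel volume. Elements inherit the
voxel's tissue label. A second path meshes the space between
consecutive shell layers (hexahedral cells split the same way) and
labels elements by classifying PSI interpolated at element centroids;
centroid labeling is chosen over per-vertex voting for determinism.
Inverted cells (crossing layer surfaces) raise an error naming the
layer pair; zero-volume cells are tolerated because the endocardial
radius legitimately collapses at the apical caps.

Interface areas sum interior facets shared by exactly two elements
whose labels fall on opposite sides of the requested pair
(healthy vs BZ∪core, or BZ vs core). Two estimators:

- `correction="none"` (default): the raw facet sum. This measures the
  staircase boundary exactly — conservation holds to machine
  precision, axis-aligned interfaces (cuboid oracles) are exact — but
  it overestimates the area of a *curved* interface, approaching 3/2 ×
  for a sphere on an isotropic grid, because voxel facets can only be
  axis-aligned.
- `correction="normal"`: each facet is weighted by |cos| of the angle
  between its normal and a local estimate of the true interface
  normal (gradient of the class indicator smoothed with a 2 mm
  Gaussian). Since the staircase area element of orientation *i*
  carries weight |n_i| relative to the true element, this weighting is
  a consistent estimator of the geometric area; measured errors on a
  10 mm spherical core are 0.1% at isotropic 1.3 mm and ≈3% at
  1.3 × 1.3 × 5 mm. It requires the voxel-built mesh (the indicator
  volume travels with it).

Reported units are cm² (mm²/100). Curved-anatomy area estimates
should use the normal-corrected mode; the uncorrected mode is the
unambiguous conserved quantity and the right target for exact oracles.
Smoothed (marching-cubes style) surfaces are deliberately not used:
they would change areas systematically and break facet conservation.

## Layered shell model

Rays are cast from the per-slice mask centroid at `n_rays` uniformly
spaced angles; the first and last mask crossings give the endocardial
and epicardial radii, and layer k of n sits at relative wall depth
(k−1)/(n−1) (so n = 2 returns the endo and epi surfaces themselves).
Default 9 layers ≈ 0.7 mm spacing at a 6 mm wall — below in-plane
resolution. Rays that cross no myocardium on an occupied slice raise
an error naming the slice rather than patching the gap. Per-vertex
PSI is trilinear-interpolated after nearest-neighbour fill outside the
mask (so edge vertices never mix background zeros).

## Outcome statistics

AUC uses the rank (Mann–Whitney) formulation with ties contributing ½,
which equals the exhaustive pairwise probability P(pos > neg) + ½
P(tie) (tested exhaustively for n ≤ 20, and cross-checked against an
independent library implementation). Candidate cutoffs are midpoints
between consecutive distinct values plus ±∞. The Youden-optimal
operating point maximizes J = sensitivity + specificity − 1; ties in J
break toward the highest sensitivity, then the lower cutoff — the
most sensitive of the equally informative cutoffs. The summary report
gives cutoff/sensitivity/specificity/J only where AUC strictly exceeds
0.7, mirroring the convention of restricting cutoff selection to
usefully discriminative metrics; the gate is strict (> not ≥).
Direction defaults to "higher predicts recurrence" (all scar metrics
trend that way), with an explicit flag to invert. Pearson correlation
and paired mean differences (t-based 95% CI, optional Bonferroni
scaling for m contrasts) use standard formulas; AUC p values are
two-sided asymptotic Mann–Whitney. A cumulative-J convenience sums J
over chosen metrics per band as a coarse ranking aid.

## Synthetic phantom

Geometry: an ellipsoidal myocardial shell (default endocardial
semi-axes 20/20/35 mm, epicardial 30/30/45 mm — wall 10 mm, total mass
≈ 120 g), long axis along the slice normal, on a 1.3 × 1.3 × 5 mm
short-axis grid. Scar patches are wedges in (angle, apicobasal
fraction, transmural depth) coordinates, where transmural depth is
measured along the ray from the LV centre between the directional
endo- and epicardial radii. Each patch grows a BZ rim (all in-mask
tissue within `bz_rim_thickness`, default 3 mm, of the core via an
anisotropic distance transform). Channels are BZ bands carved through
the core at a fixed apicobasal position, inset 3 mm from the core's
lateral edges so they are fully core-enclosed — the ground truth for
corridor recovery.

Signal: piecewise-constant per class (healthy 20, BZ 50, core 100
arbitrary units — placing healthy and core safely outside all four
bands and BZ mid-band after FWHM normalization) plus additive Gaussian
noise (default σ = 2, i.e. SNR ≈ 10 against healthy tissue), clipped
at zero. Additive Gaussian is used rather than Rician: the object
under test is thresholding, not MR magnitude statistics. Two optional
realism features:

- `psf_fwhm_mm` — Gaussian partial-volume blur of the noise-free SI,
  applied after nearest-tissue fill outside the mask so the blur mixes
  tissue classes rather than darkening the wall from the background;
- `transmural_si_decay_mm` — linear falloff of core SI with transmural
  depth (classic subendocardial enhancement pattern).
  `realistic_infarct_spec()` packages a large 150° transmural wedge
  with 14 mm falloff across a 14 mm wall; this continuum of PSI values
  is what makes tissue fractions genuinely threshold-dependent, and
  under it the interface-area orderings across bands reproduce the
  directions seen clinically (healthy–HE area largest at 30–70;
  BZ–core area smallest at 30–70).

Noise-free three-level phantoms keep exactly three distinct in-mask
intensities — the exact-oracle configuration used by the recovery
tests. Deterministic per seed via `numpy.random.default_rng`.

What the phantom does *not* emulate: inversion-recovery contrast
physics, Rician magnitude noise, coil inhomogeneity, motion, papillary
muscles, trabeculation, or irregular scar shapes. Passing tests
therefore demonstrate correctness of the computational pipeline on
known geometry, not clinical accuracy on patient scans.

## Synthetic cohorts

Per-patient metrics (7 metrics × 4 bands) are log-normal with means
and SDs at the scale of published ischemic-VT cohorts (recorded in the
output metadata, never hard-coded into tests); corridor counts are
rounded to integers. A shared per-patient latent factor (loading 0.7)
induces the cross-band correlation real scar metrics exhibit.
Recurrence is Bernoulli with
`p = expit(beta0 + beta1 · (x − mean)/sd)` on one driving metric
(default: healthy–HE interface area at 45–55, beta0 = 0.25 for ≈ 56%
prevalence, beta1 = 1.5 per SD). The model-implied AUC of the driving
metric — `∫ f₁(x) F₀(x) dx` over the log-normal metric density split
by outcome — is computed by trapezoidal quadrature on a dense grid,
independent of the empirical ROC path, and the empirical AUC recovers
it within 0.01 (50 cohorts × n = 2000).

## Problem sizes and numerical choices

Tests and the acceptance script run phantoms at 96 × 96 × 32 (default
anatomy) and 64 × 64 × 56 isotropic (spherical analytic oracles);
batches of 20 phantoms for monotonicity and 50 × 2000 cohorts for AUC
recovery — sizes at which every analytic tolerance in the suite is
met with margin. Degenerate voxel tetrahedra abort meshing
(tolerance 1e-9 mm³); facet matching uses exact integer vertex keys,
so interface sums are order-independent bit-for-bit. The −1 label
marks out-of-mask voxels everywhere.

## Known limitations

- Absolute interface areas of clinical meshes produced by smoothing
  pipelines are not comparable to staircase or normal-corrected voxel
  areas; only orderings and arithmetic relations are.
- Corridor detection operationalizes "surrounded by core" with a
  contact-fraction rule; vendor channel algorithms are proprietary and
  may disagree on borderline components.
- The layered shell model assumes a star-shaped myocardium per slice
  about the slice centroid; strongly non-convex masks would need a
  different parameterization.
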