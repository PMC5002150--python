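# Methods

This note documents the models, conventions and design choices behind
`petiq`, in the spirit of the methods documentation of simulation
packages: what is modeled, what is deliberately simplified, and what
passing tests therefore do and do not demonstrate.

## Synthetic cohort and phantom

The phantom module emulates a small thoracic FDG-PET cohort so the whole
pipeline runs without external data.  Each subject is a voxel grid
(default 48×48×32 at 4 mm isotropic) with three compartments: an
elliptical-cylinder body filled with lung tissue, a liver sphere
(radius 24 mm) in the lower-posterior body, and one or two spherical
lung lesions.  Cohort parameters and their sources:

| parameter | distribution | default rationale |
|---|---|---|
| weight | uniform 45–79 kg | printed cohort range |
| liver SUV | normal(1.57, 0.40), truncated > 0 | printed mean ± SD |
| lesion SUV | normal(1.92, 0.95), truncated ≥ 0.5 | printed mean ± SD; floor keeps lesions above lung background |
| lesion volume | uniform 1.2–17.58 ml | printed range |
| net true counts | normal(1.32·10⁸, 3.91·10⁷) × scale, truncated > 0 | printed mean ± SD; `scale` shrinks desk-scale runs |
| injected dose | normal(168.6, 50.0) MBq, truncated to 118–260.5 | printed cohort |
| lung background SUV | 0.5 (configurable) | typical aerated-lung uptake; no value is stated for the source cohort |
| attenuation factor | a(m) = exp(0.02·m), m in kg | any monotone increasing form suffices, since the per-subject sensitivity K_i is estimated empirically downstream; 0.02/kg gives a ~2× attenuation spread across the weight range |

Lesion spheres are rasterized by taking the `round(V / v_voxel)` voxel
centers nearest the sphere center (ties broken by voxel index), which
keeps the discrete volume within half a voxel volume of the request at
any radius.  Note that the alternative "centers within r" rule does not
control volume error: a 30 mm sphere on 4 mm voxels rasterizes to 251
voxels (16.06 ml) versus the analytic 14.14 ml, a lattice-count effect
that vanishes as voxels shrink.

Event generation is **fixed-total multinomial**: exactly N true events
are distributed over voxels with probability proportional to the SUV
map.  This makes "counts in the scan" — the x-axis of every
count-response analysis — exact, while per-voxel counts remain
asymptotically Poisson.  Randoms (off by default) are uniform over the
body with n_random = round(rf·N/(1−rf)); they carry no spatial
structure and are excluded by reconstruction (ideal randoms
subtraction).

Not modeled: anatomy beyond three compartments, respiratory motion,
scatter, dead time, time-of-flight.  Consequently, passing tests show
that the *statistical* machinery behaves correctly under Poisson-like
counting noise; they do not show robustness to anatomical texture,
which in real data adds a count-independent floor to VOI variability.

## Dose reduction

`thin_stream` retains each event independently with probability f
(true and random events alike), so retained counts are Binomial(n, f);
`bootstrap_stream` draws round(f·n) events with replacement.  Both are
exposed because thinned realizations of one parent stream are *not*
fully independent: two realizations at fraction f share the parent's
noise with correlation ≈ f.  On the mean image across R realizations
this inflates the voxel variance by (1 + (R−1)f), so SNR² ∝ N holds
cleanly only for f ≪ 1/R.  All quantitative scaling tests therefore use
small fractions (the regime the fraction schedule's lower half
occupies); this is a property of the resampling design itself, not an
artifact of the implementation.

Sub-seeds are derived as `SeedSequence([master_seed, fraction_index,
realization_index])`, so any single realization is reproducible in
isolation.

## Reconstruction backends

**Binning backend.** Voxel value = true-event count × calibration.
With multinomial event placement, E[count_v] = N·suv_v/Σsuv, so the
calibration Σsuv/N reproduces each compartment's SUV in expectation —
in particular the full-statistics liver mean equals the phantom liver
SUV.  Thinned realizations are calibrated with the expected retained
counts f·N, mirroring how SUV normalizes by injected dose rather than
by realized counts.  The backend is exactly linear in the stream, which
is what makes it the oracle for SNR² ∝ N and COV ∝ N^(−1/2).

**OSEM surrogate.** A single-slice parallel-beam system with an
explicit sparse pixel-driven projector: each pixel center is projected
onto the detector axis per view and split linearly between the two
nearest radial bins (bin width = pixel size, 63 views over 180°).  The
adjoint is the exact matrix transpose (verified to machine precision),
so the multiplicative OSEM updates (3 iterations, 21 interleaved-angle
subsets, uniform positive initialization) are well posed.  An optional
Gaussian PSF is applied symmetrically in projector and adjoint; the
5 mm Gaussian post-filter (σ = FWHM/2.3548, applied in the image domain
after the final iteration) completes the protocol.  Image-domain event
streams are mapped to sinogram counts stochastically: an event in pixel
j is assigned one detector bin with probability proportional to column
j of the projector — the discrete analogue of detection along a random
line of response.  Because the projector is not norm-preserving, the
surrogate's SUV scale is pinned empirically: the full-statistics
reference reconstruction is rescaled so its liver mean equals the
phantom liver SUV, and the same factor (with the 1/f dose scaling)
applies to every realization.

The surrogate reproduces *regime* properties of clinical iterative
reconstruction — positivity-induced upward bias in cold regions,
downward bias in hot regions at low counts, loss of SNR²–counts
proportionality below a few thousand counts per slice — and makes no
attempt to match any scanner's 3D geometry, corrections or absolute
quantification.  A separate consequence of the small 2D system is that
liver SNR saturates at high counts (projector discretization becomes
the dominant spatial variation), which is why quantitative SNR² fits
are run on the binning backend only.

## VOIs

Lesions are segmented on the full-statistics image: the seed voxel is
hill-climbed to the lesion maximum, the mask is all voxels ≥ pct % of
that maximum restricted to the connected component (26-connectivity)
containing it.  The component restriction is the automatable surrogate
for a reader excluding neighboring nodes.  Masks are delineated once
and copied to all reduced-count images.  The CNR background is the
morphological shell dilation(lesion, r) − lesion with a Euclidean ball
of radius 2 voxels (a Chebyshev cube is available by flag, and the
radius is configurable, covering the "two iterated unit dilations"
reading).  Background spheres are 3 cm in diameter; in the liver the
sphere sits at the liver centroid, in the lung at the point deepest
inside lung tissue (clipped to fit the grid).  In the
threshold-sensitivity analysis (20/40/60/80 % of SUVmax) the shell
derived from the 20 % mask is shared by all four thresholds.

Lesion inclusion uses volume ≤ 20 ml and full-statistics CNR ≥ 2, both
inclusive; the size subgroups split at 5 ml with the 5 ml boundary
assigned to the large group (the small group's empirical maximum is
below 5 ml).

## Metric conventions

- Spatial SD inside a VOI uses the population divisor N_VOI.
- SDs across the realization ensemble (SD image, STE) use the sample
  divisor R−1, since R = 10 is small.
- SNR, CNR and bias are computed on the ensemble mean image, not as
  averages of per-realization values.
- COV is SD/mean (in percent).  The printed form of the ensemble-noise
  equation in the source inverts this ratio, contradicting its own
  description as a coefficient of variation; SD/mean is the universal
  definition and matches the printed magnitudes.  A strict-as-printed
  mode is available via `as_printed=True`.
- The SUVmax COV variant reads the SD image at the location of the
  mean-image maximum.
- Degenerate VOIs (zero spatial SD) are flagged and their SNR reported
  as +inf rather than raising.

## Count-response models

All fits express counts in units of 10⁶: the published saturation curve
1/(1 + 2.41·x^(−0.8)) evaluates to 0.60 at x = 5 only in those units,
consistent with "60 % at 5·10⁶ counts".

K_i is the through-origin OLS slope of liver SNR² on counts, fitted by
default over the 1–20·10⁶ mid-count regime (desk-scale runs pass their
own range).  The pooled corrected fit uses a free intercept, matching
the published nonzero intercept.  R² is 1 − SS_res/SS_tot (SS_tot about
the mean) for every model form, linear or not.

The normalized-CNR curve is fitted by Levenberg–Marquardt on
log-parameters (enforcing a, b > 0) from a 3×3 multi-start grid
(a ∈ {0.5, 2.41, 10}, b ∈ {0.3, 0.8, 1.5}); the lowest-SSE start wins.
Constant data are rejected as degenerate.  The curve is heuristic — no
interpretative model is attached — and its closed-form inverse
x = (a/(1/y − 1))^(1/b) answers "how many counts for a target fraction
of full CNR".  The descriptive power-law fitter used for K_i-versus-
covariate summaries is log-log OLS.

## Minimum-counts analysis

"Passing a threshold" means the metric magnitude ≤ the allowed percent
level.  Per case, N\* is the smallest count level that passes *and*
whose every higher available level also passes — the suffix guard
protects against non-monotone noise in individual series and makes N\*
invariant to adding passing levels above it.  N\* values are pooled
into histograms on bins centered at integer multiples of 10⁶ counts;
the curve summaries are the frequency-weighted mean of bin centers
(histogram mean), the median ("half of the cases") and the maximum.
Cases that never pass are censored from the summaries and reported as a
separate count, since the procedure's source is silent on censoring.
Required counts are non-increasing in the allowed level by
construction.

## Pipeline and problem sizes

`run_pipeline` executes the stages under one master seed and writes
tidy CSV/JSON artifacts plus a manifest with per-subject seeds and
SHA-256 hashes; a rerun with the same config is bit-identical.  The
default configuration (4 subjects, count scale 0.02, six smallest
schedule fractions, R = 10, binning backend) finishes in well under a
minute on one CPU.  The cohort-level acceptance analysis uses 16
subjects at count scale 0.15 (≈2·10⁷ true counts per subject) with the
four smallest schedule fractions — chosen, per the thinning-correlation
argument above, so that realizations are effectively independent and
the SNR² ∝ N regime is actually in force.  The OSEM directional checks
use a 48×48 single-slice phantom with 4·10⁵ parent counts.

## Known limitations

- The three-compartment phantom has no intra-organ texture, so organ
  VOI variability is purely statistical; real livers and lungs add a
  count-independent variance floor, which is precisely why
  patient-derived minimum-count thresholds cannot be reproduced from
  synthetic data and are not targeted.
- The OSEM surrogate is 2D and uncorrected; only directions, not
  magnitudes, of its low-count effects are asserted.
- Randoms are generated for accounting but not propagated through a
  randoms-correction model.
- `sample_cohort` draws lesion count (1–2) per subject heuristically;
  the cohort's lesions-per-subject distribution is not a calibrated
  quantity.
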