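# Methods

## The measurement model

Visible light below ~600 nm is strongly absorbed by hemoglobin while the
surrounding tissue autofluoresces under laser excitation, so in a wide-field
intravital image a blood vessel appears as a dark structure on a bright
background. For an excitation/emission channel the light that reports a
vessel must cross it twice — into the tissue at the excitation wavelength and
back out at the collection wavelength — so the intensity over a vessel of
blood path d is

    I = I_bg · exp(−μ_eff · d),       μ_eff = μa(ex) + μa(em)

with μ_eff = 2·μa(ex) when no emission filter is used (only backscattered
excitation light is collected). The predicted vessel/tissue contrast of a
channel is C = 100·(1 − exp(−μ_eff·d)) percent, evaluated at a nominal
vessel diameter d. The same attenuation law drives phantom rendering, so
predicted and phantom-measured contrast agree exactly on centerline pixels —
a deliberate cross-module consistency check, not a coincidence.

The whole-blood absorption table (`spectral_model.WHOLE_BLOOD`, per mm at
{450, 488, 530, 550, 590, 635, 700} nm = {35, 14, 22, 28, 4.2, 0.33, 0.09})
is a coarse transcription of standard oxyhemoglobin extinction tabulations at
~150 g/L hemoglobin. It is deliberately coarse: every conclusion drawn from
it in this package is an ordering or a bound (488/550 maximal, 635 nm in the
few-percent regime), never an exact value. Lookups interpolate linearly at
the band center; band widths are ignored, and querying outside the tabulated
range is a hard error rather than an extrapolation.

Contrast is measured, not just predicted, as the signed relative intensity
deficit C = 100·(mean_tissue − mean_vessel)/mean_tissue over disjoint
vessel/tissue ROIs. It is invariant under global intensity rescaling, and a
channel in which vessels come out brighter than tissue reports a negative
value instead of being clamped.

## Phantom generator

The generator replaces the camera. It emulates wide-field imaging of a
mammary fat pad and produces co-registered channel images together with the
exact ground truth the pipeline is asked to recover.

Geometry is two-dimensional with an analytic thickness map: the method only
probes superficial tissue, so depth is collapsed into the per-pixel blood
path 2·√(r² − s²) through a cylindrical vessel of radius r at lateral
distance s from its centerline. Vessels are straight-segment capsule chains
grown by a biased random walk with stochastic branching (child radius =
parent radius × decay). Two properties of the growth model matter:

- **Bounded tree footprint.** Each tip lives at most `max_tip_steps` (8)
  steps, so a single tree covers ≲0.5% of the field. A denser vasculature is
  reached by sprouting more trees — the neoangiogenesis picture — rather
  than by letting one tree percolate.
- **Rejection placement with clearance.** A proposed tree is committed only
  if, after a 2 px dilation, it touches no previously placed vessel.
  Distinct vessels therefore never merge in the rasterized mask. Without
  this, the mask percolates into a single connected component at tumor-level
  area fractions and any object-count statistic loses its relation to vessel
  density.

When `vessel_area_target` is set, trees are added until the rasterized
vessel fraction first reaches the target (granularity: one tree, ≲0.4% of
the field). Rasterization uses an exact pixel-center capsule test with no
anti-aliasing, which keeps the exhaustive per-pixel oracle in the test suite
exact. Rendering is I_bg·exp(−μ_eff·thickness) plus additive Gaussian noise
on the normalized 0–1 scale, clipped to [0, 1].

The microvessel-density (MVD) analog mirrors histological counting: in each
of 5 randomly placed square subfields (half the field side), every
8-connected vessel object visible inside the window counts as one vessel —
two branches whose junction lies outside the window count twice, exactly as
profiles on a section do — and the count is the rounded mean over windows.

Cohorts follow the validation design: 3 control + 13 tumor subjects, tumor
area target = 3× control, per-subject multiplicative lognormal jitter
(SD 0.15 on the log scale) standing in for between-animal variability, and
per-subject seeds derived from the cohort seed via `numpy.random.SeedSequence`
so cohorts are reproducible without global RNG state.

### Default parameters

| parameter | default | why |
|---|---|---|
| field | 384 × 384 px at 7.5 µm/px (2.88 mm) | wide-field macro view of a fat pad region |
| initial vessel radius | 25 µm (floor 15 µm) | arteriole/venule calibre resolvable at this pitch |
| step / tip lifetime / branch prob. | 60 µm / 8 steps / 0.08 | short, gently curved vessels with occasional branches |
| control area fraction | 0.06 | a few percent of tissue is vessel in a healthy pad |
| tumor multiplier | 3 | clearly separated groups, same order as real neoangiogenesis |
| noise SD | 0.02 | mild sensor noise on a 0–1 scale |
| tissue optics | autofluorescence 0.8, reflectance 0.9, vessel diameter 0.05 mm | bright but unsaturated background; 50 µm nominal vessel |

What the phantom does **not** emulate: uneven illumination and vignetting,
structured (non-Gaussian, non-white) background texture, scattering blur,
motion, specular reflections, 3-D vessel crossings, and flow. Passing tests
therefore demonstrate correctness of the algorithms under the stated image
model, not performance on arbitrary real acquisitions — on real data the
flat-background assumption inside the edge refinement is the first thing to
revisit.

## Segmentation pipeline

`combine → threshold → refine → measure`, deterministic end to end.

1. **Combine**: normalized weighted mean of the selected channels (default:
   weight 1 on ex488/em550, the maximal-contrast pair). A weighted mean is
   the most literal reading of "vary the contribution of each channel" and
   keeps the composite in [0, 1].
2. **Threshold**: vessels are pixels *below* the threshold (dark-vessel
   polarity is the default; `invert` exists for other contrast mechanisms).
   The automatic threshold is Otsu's criterion on a 256-bin histogram of the
   in-ROI pixels — an interactive threshold would reintroduce the
   user-dependence the method is meant to remove. A constant composite
   raises `DegenerateImageError` rather than guessing.
3. **Refine**: hysteresis linking, the edge-growing step of the Canny
   detector. The background level and a robust noise SD (1.4826 × MAD) are
   estimated from tissue beyond a 3·edge_sigma halo around the seeds; every
   pixel more than `growth_nsigma` (2.5) noise SDs darker than the
   background is a candidate, and candidate components touching a seed are
   kept. Rationale: a vessel's rim intensity approaches the background
   smoothly (the chord length → 0 at the lumen edge), so a global threshold
   systematically misses rim pixels, and a gradient-ridge snap carries a
   sub-pixel inward bias that is material on vessels 5–7 px wide. Growing to
   the noise floor is unbiased under the additive-noise model. Components
   smaller than `min_object_px` (5) are removed; the result is clipped to
   the tissue ROI.
4. **Measure**: vessel area = pixel count × pitch², reported absolutely
   (mm²) and as a fraction of the tissue-ROI area (per mm² of tissue), since
   either normalization may be wanted.

Numerical notes: ties in channel ranking break by ascending excitation then
emission wavelength (no-filter before filtered at the same laser);
`linear_fit` defines R² = 0 for a constant response (SS_tot = 0); the t-test
is the two-sided equal-variance Student form, degenerate variances are hard
errors; significance is judged at p < 0.05 with no multiple-testing
correction, matching the study design being emulated.

## Validation experiment

`recovery_experiment` generates a cohort, quantifies every subject with the
default configuration, and reports: per-subject records, tumor-vs-control
Student's t on measured areas, OLS of measured area against the MVD analog
(the in-vivo-vs-histology regression), and OLS against the true phantom area
(pure recovery quality). On noise-free phantoms area recovery is essentially
exact (the hysteresis step recovers every rim pixel with sub-LSB deficits
excepted), so the area-vs-MVD R² is limited by the MVD analog's own sampling
noise — which is the realistic regime: the reference method, not the imaging
method, is the noisier one.

Problem sizes used by the shipped experiments — 16 subjects per cohort at
384² px, 5 cohorts for the headline number, 20 single phantoms for the
accuracy sweep — were chosen so a full run completes in a couple of minutes
on one CPU while leaving every statistic comfortably estimable.

## Known limitations

- The absorption table is a 7-knot caricature; do not use it for
  oximetry-grade work (oxy/deoxy unmixing is explicitly out of scope).
- The refinement step assumes an approximately uniform background within
  the ROI; a shading correction should precede it on real images.
- The MVD analog reproduces the *statistical structure* of histological
  counting, not staining biology; its absolute counts are not calibrated to
  real CD31 counts.
- 2-D geometry cannot represent vessel crossings at different depths; such
  crossings would merge objects and bias both area and counts.
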