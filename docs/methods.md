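# Methods

## Pipeline model

A torso scan is an unordered point cloud in mm, z vertical, the
participant facing −x. Shape is analysed per participant in an anatomical
frame so that location, orientation and scale never enter the descriptor:

* **Segment definition.** The torso segment runs from the buttock
  (hip-girth) landmark to the xiphoid process. Buttock and neck heights
  are inputs (ground truth from the generator, or a landmark file for real
  scans); the xiphoid height is placed at 60% of the buttock-to-neck
  distance.
* **Surface landmarks.** In the 2 mm band at xiphoid height, the
  posterior (L1) and anterior (L2) landmarks are located on the
  anterior–posterior axis. The AP direction is first estimated from a
  thick slab (±12% of the buttock-to-neck distance around the xiphoid) as
  the first circular moment of radius deviations about the slab centroid —
  torso sections are anteriorly fuller, so this vector points anterior.
  One 2 mm band alone is too small for a stable estimate on noisy scans,
  and the raw directional third moment carries a three-fold harmonic whose
  maxima are ambiguous; the slab-pooled first harmonic has neither
  problem. If the normalised asymmetry falls below 0.04 (a symmetric
  outline; noisy symmetric test shapes measure ≤ ~0.011, torso slabs
  ~0.2), the scanner's canonical facing is assumed instead. The landmark
  itself is the outline's crossing of the AP axis, from a local quadratic
  fit of radius vs angle over ±0.25 rad. An extremum-based landmark
  (max/min x) is ill-conditioned here: the posterior aspect of a torso
  section is nearly flat (curvature radius of metres), so the extremum
  location slides laterally by centimetres under mm-level noise, while
  the axis crossing moves only with the estimated direction (≈ 0.5° at
  1 mm noise). Both the extreme-window-centroid rule and the raw extremum
  remain available (`method="mean"`, `n_extreme`).
* **Frame.** Origin = midpoint of L1L2; X = unit L1→L2; w = X rotated
  +15° about the global vertical; Z = unit X×w (upward); Y = X×Z. The
  frame removes yaw, translation and — combined with the size step —
  scale; it deliberately does not superimpose participants onto each
  other (no Procrustes across subjects).
* **Slices.** The cropped segment yields 25 bands of 2 mm height, centres
  uniformly spanning the segment inclusive of half-band margins; each
  band's points are flattened to the band-centre height and ordered
  counter-clockwise about the slice centroid.
* **Size.** One scalar rescales all outlines (and their heights) so the
  joint centroid size of the pooled configuration — each slice centred at
  its own centroid, planar deviations only — equals 1. The joint size is
  measured on the 70-point resampled outlines rather than the raw band
  points: centroid size is a statistic of a fixed-size landmark
  configuration, and raw scanner bands have density-dependent point
  counts, which would make the computed size scale with the square root
  of point count rather than with geometry (a 2 mm band over a uniformly
  rescaled body contains ∝ 1/scale points, so raw-point centroid size
  grows only as √scale). `centroid_size` itself implements the standard
  formula exactly; `scale_slices(cs_source="raw")` gives the raw-point
  variant.
* **Descriptor.** Each outline is converted to polar radii about the
  slice stack's common axis (x = y = 0 in the frame), fitted with a
  periodic cubic smoothing spline, and resampled at 70 uniform angles.
  The polar centre is the frame axis, not the per-slice centroid: a
  per-slice-centroid parameterisation is invariant to per-slice
  translation and would erase lateral postural lean — a mode the shape
  model must retain — from the descriptor entirely. A real FFT yields 35
  non-DC harmonics; harmonic *m*'s coefficient is the amplitude 2|c_m|/70,
  which discards phase and is therefore invariant to the outline's start
  angle (and to reflections); harmonics above 10 are treated as sensor
  noise and dropped. 25 slices × 10 harmonics = 250 values per torso.
* **Shape model.** Centred PCA over the 250-vectors (no per-column
  standardisation — all entries share units); retained PCs are the
  leading components with ≥ 1% explained variance each.
* **Statistics.** Torso measures are divided by stature, then z-scored
  (sample SD). Pearson correlations use two-sided t-based p-values with
  α = 0.001; sex differences use Welch t-tests. Each shape PC gets a
  PLS1/NIPALS model on the 34 measures; the component count minimises the
  10-fold cross-validated MSPE under the one-standard-error rule
  (per-model selection; a global forced count is available via
  `force_n_components`). VIP_j = √(p·Σ_a SSY_a w²_aj / Σ_a SSY_a) with
  mean-square 1 by construction; VIP ≥ 0.8 flags contributing measures.
  Pooled-model residuals regressed on the ±1 sex code decide whether
  unexplained PC variation is sexually dimorphic. Per-sex analyses
  re-centre PC scores as within-sex z-scores. The waist sweep predicts
  every PC across the sample's waist range with stature fixed at
  180 cm (male) / 160 cm (female) and the other 32 measures at their
  conditional expectation given waist (OLS slopes within sex; grand-mean
  imputation available).

## Synthetic cohort

The generator emulates the study conditions end to end. One torso is a
star-shaped radius function

    r(θ, z) = [B(z) + taper·G_T·g₃(u)]·(1 − ε·cos 2θ)
              − [α·B(z) + ap·G_A·g₁(u) + bulge·G_B·g₂(u)]·cos θ

with u the normalised segment height, B(z) a hip–waist–chest base-radius
profile, ε = 0.15 a fixed ellipticity (torsos are wider than deep) and
α = 0.10 a fixed population-level anterior fullness. Latent modes and
defaults:

| mode | distribution (default) | geometric effect |
|---|---|---|
| ap_weighting | N(1.0, 0.45) | mid-torso anterior mass shift, 9 mm/unit |
| taper | N(±1.0·sex, 0.55) | upper-vs-lower radius gradient, 7 mm/unit |
| roundness | N(0, 0.085) | multiplicative girth inflation |
| lean | N(0, 1) | lateral shear, 0.035 rad-equivalent/unit (~2°) |
| bulge | N(1.0, 0.50) | low-anterior protrusion, 7 mm/unit |

The taper sex offset is the sole sex effect on shape, per the observed
wider-above/wider-below contrast between male and female torsos. The
anterior modes carry positive means (adult torsos are anteriorly full on
average), which also keeps the amplitude-only descriptor approximately
linear in the latents around the population mean. Lean is drawn
independently of physique and of every measure — it is the analogue of
the posture-driven shape component that body measures cannot explain.
Because amplitudes discard sign, the lean-linked PC tracks |lean|; it is
identified as the retained PC whose scores correlate most strongly with
|lean| (`pipeline.lean_pc_analysis`).

Stature follows the study population (male 176.1 ± 7.3 cm, female
164.0 ± 7.0 cm); base radius ~ N(150, 11) mm male / N(144, 12) mm female.
Clouds are sampled as horizontal rings (~1.5 mm pitch, finer than the
2 mm analysis bands, 110 points per ring on one shared angular grid),
occluded over a contiguous arc (8% of circumference) on two random bands,
perturbed by 1.0 mm isotropic noise (laser-scanner class accuracy), and
posed by a random yaw (±15°), translation (±50 mm) and uniform scale
(0.97–1.03). The 34 measures (12 girths, 8 widths, 8 depths, 6 lengths)
are evaluated on the analytic noise-free surface — girths by spectral
quadrature of the outline arc length — then re-expressed in posed units;
the reported table adds 0.3 cm measurement noise. Weight is a volume
proxy (tissue density × torso volume / torso mass share), a documented
stand-in for a measured weight.

What the generator does **not** emulate: non-star-shaped anatomy (arms,
breast overhang), soft-tissue articulation, pose bending (the lean is a
shear, not a spinal curve), scanner-specific raster artefacts, or
realistic measure-correlation structure beyond what the shared size and
taper factors induce (synthetic girth–girth correlations are ~0.99 vs
~0.9 in real cohorts). Passing tests therefore show the *machinery* is
correct and its invariances hold; they do not certify accuracy on real
scans.

## Numerical choices

* Spline smoothing: FITPACK's residual budget s = n·σ̂², with σ̂²
  estimated from second differences of the ordered radii. This targets
  the same quantity as per-profile generalised cross-validation at a
  fraction of its cost over the ~50k profile fits of a cohort run.
* Angularly coincident samples (two raster rings flattened into one band)
  are merged to their median radius before the spline fit; outlines
  multi-valued beyond 5% of the median radius additionally warn
  (non-star-shaped input).
* Band point sets use closed z-intervals; slice extraction requires ≥ 10
  points per band and fails loudly on excessive occlusion.
* PCA loadings take a deterministic sign (largest-magnitude entry
  positive); CV folds are seeded and, for pooled models, stratified by
  sex; every random draw in the pipeline descends from the single config
  seed, making rerun outputs byte-identical.
* The perimeter oracle for girths uses a spectral derivative, giving
  near-machine accuracy for smooth outlines (an a = 150, b = 100 mm
  ellipse evaluates to 793.272 mm, matching 4aE(e²) to <0.1%).

## Scale choices

Cohort sizes are the package's own study conditions: n = 400 for the
numbered analysis scripts, n = 600 for the acceptance recomputation and
the lean-PC characterisation, n = 2000 (measures only, no clouds) for
moment checks and the PLS recovery experiments. The descriptor-invariance
suite uses 25 random transforms with full-circle yaw, ±200 mm
translations and ±5% scale on a noise-free torso; the worst observed
relative change of the 250-vector is ~4×10⁻⁴ against a 10⁻³ bound.

## Known limitations

* The lateral position of the posterior landmark is intrinsically soft
  (flat back); with 1 mm point noise it scatters by a few mm, which feeds
  the frame origin and adds first-harmonic noise to the descriptor.
* Amplitude-only descriptors lose phase: reflected or locally re-phased
  shapes can collide, and signed latents are only recoverable as
  magnitudes.
* The joint-size step assumes slice outlines sample the surface with
  comparable density across participants, as scanner rasters do.
* PLS R² values are in-sample (component count is what cross-validation
  controls), so they carry the usual mild optimism at p = 34, n ≥ 300.
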