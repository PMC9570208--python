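# Methods

## The measurement model

Laurdan partitions into the RBC plasma membrane and its emission spectrum
shifts with lipid packing: ordered (gel / liquid-crystalline, LC) phases
emit toward the blue channel, disordered fluid phases toward the green.
The generalized polarization

GP = (I_blue − G·I_green) / (I_blue + G·I_green)

condenses the two channel intensities into a bounded index (−1 ≤ GP ≤ 1;
higher = more ordered). `G` corrects for unequal channel sensitivity; it
defaults to 1 and can be calibrated from a reference of known GP via
`calibrate_g`, which solves GP(ref) = gp_ref for G over a stated mask.
Pixels whose denominator I_blue + G·I_green does not exceed `denom_floor`
(default 1 detector unit) are left *undefined* and excluded from every
statistic and mask downstream — a ratio of near-zero counts is shot noise,
not a fluidity estimate.

Analysis proceeds in four stages, each behind its own module:

1. **Segmentation** (`segmentation`): foreground by Otsu's threshold on
   the summed channels, hole filling, 8-connected labelling, then
   per-object filters — projected area inside a window (defaults
   20–120 µm², bracketing the ~50 µm² projected area of a real RBC) and
   solidity ≥ 0.85 — to reject debris and aggregates. Rejections are
   logged per object. An opt-in supervised mode replaces the Otsu step
   with a random-forest pixel classifier over multi-scale Gaussian
   intensity and gradient-magnitude features (σ = 1, 2, 4 px), trained on
   sparse cell/background/debris labels. Touching cells are not split;
   the synthetic scenes place cells with clearance, and a watershed would
   add a failure mode the analysis does not need.
2. **GP mapping** (`gp`): the formula above, pixelwise; per-subject
   aggregation pools all defined pixels inside cell masks across the
   subject's images. Whether a per-patient index should pool pixels or
   average per-cell means is a genuine degree of freedom, so both are
   reported (`mean_gp`, `mean_gp_cellwise`); pooling is the default
   analysis value.
3. **LC domains** (`domains`): a reference stack of 20 cells is drawn
   (seed-deterministically, without replacement) from the reference group
   — DM by default — and its pooled defined-GP values define the global
   threshold GP\* at the 75th percentile (linear interpolation between
   order statistics). The threshold is strict (GP > GP\*) and the *same*
   GP\* is applied to every group, including CTRL. Connected components
   (8-connectivity, matching common particle-analysis practice) of
   suprathreshold pixels inside cells are domains; components under
   `min_px` = 2 pixels are discarded as indistinguishable from shot
   noise. Per-cell thresholding and 4-connectivity exist behind flags.
4. **Group statistics** (`stats`): one-way ANOVA per feature, then Welch
   pairwise t-tests with Holm step-down adjustment (default) or Tukey's
   HSD — both are provided because the two conventions coexist in this
   literature, and the choice is surfaced in `adjust_method` rather than
   hidden. χ² (Pearson, no continuity correction, expected-count < 5
   flagged) for categorical covariates; normal Q-Q tables for visual
   normality checks. The subject is the statistical unit for GP
   (n = subjects); the cell is the unit for morphometrics (a fixed
   seed-drawn sample, default 20 cells per group).

## Morphometry on pixel-corner geometry

Per domain we report area (pixel count × pixel area), maximum Feret
diameter, perimeter and circularity. Feret and perimeter are measured on
the convex hull of the domain's *pixel-corner* points (each pixel
contributes its four corners). Consequences, deliberate:

- a single pixel is a unit square: Feret = √2 × pixel size, never 0;
- an axis-aligned n×m rectangle yields its exact polygon values
  (10×10 square: p = 40, Feret = 10√2, circularity = π/4);
- the Feret diameter is computed by rotating calipers over the hull
  vertices, and the test suite verifies it equals the brute-force
  all-pairs maximum on hundreds of random shapes.

Circularity is 4πA/p² evaluated *on the outline polygon itself* (shoelace
area over polygon perimeter), capped at 1. Using the polygon's own area
rather than the pixel count removes the half-pixel circumscription bias of
the corner hull — digitized discs of radius 5→40 px measure 0.977→0.997,
converging monotonically to 1 — while leaving convex shapes' values exact.
For concave domains (rare merges of planted ellipses) the hull overstates
the area and the cap absorbs the overshoot; the package does not attempt
concave perimeter estimation because planted domains are ellipses and
suprathreshold excursions at realistic photon counts are compact.

A weighted boundary-chain estimator (1 per axial step, √2 per diagonal)
was evaluated and rejected: it reproduces neither the exact square values
(gives p = 36, circularity 0.97) nor sub-0.2 circularity for a 1-px-wide
bar, both of which the corner-hull polygon satisfies simultaneously.

## The synthetic generator

The generator (`synthetic`) is the package's ground-truth instrument. It
emulates the study design: per subject, five fields of view; cells as
non-overlapping discs (annular rims optional); per cell a two-phase GP
field — fluid background plus planted elliptical LC domains at
GP_LC = 0.70 — rendered into expected intensities by inverting the GP
formula (blue = I(1+GP)/2, green = I(1−GP)/(2G_true)) and degraded by
independent per-channel Poisson noise. Rendering is exactly invertible:
noise-free images map back to the planted field at machine precision, so
estimator error downstream is attributable, never baked in.

Group presets carry the printed study targets as simulation truth:
per-subject mean GP 0.534/0.519/0.501 (between-subject SD
0.018/0.007/0.026) for CTRL/DM/DM+PAD, domains per cell 20.2/95.4/100.1,
Feret 1.028/0.245/0.183 µm, circularity 0.643/0.846/0.903. Domain
elongations (3.0/2.0/1.7) invert the analytic ellipse circularity against
the circularity targets. Two constructions make the recovery exact rather
than approximate:

- **Exact subject means.** A subject's GP offset is drawn once from
  Normal(0, subject SD). Within each cell the fluid-phase GP is solved
  from the *realized* LC area fraction f so that the noise-free cell mean
  equals target + offset exactly. The offset is expressed in the fluid
  phase (scaled by 1/(1−f)) while GP_LC stays fixed: fluidity varies in
  the disordered phase, the ordered phase keeps its packing-determined
  GP. This also keeps a single global threshold meaningful for outlying
  subjects — an offset applied to the LC phase would carry their domains
  across GP\* and make domain counts depend on the subject draw.
- **Separated placement.** Planted ellipses are rejection-sampled with a
  one-pixel clearance (up to 200 tries, then the domain is dropped with a
  log message); without the clearance, adjacent domains fuse under
  8-connectivity and realized counts could not track the Poisson rate.
  Realized counts match the preset rates within ~2%.

### Geometry choices, with the reasoning

- **Pixel size 0.05 µm/px.** The smallest domain class (0.183 µm Feret)
  must span several pixels to be countable at min_px = 2; 0.05 µm/px is
  ordinary oversampling for a 60×/1.4 NA confocal (lateral resolution
  ≈ 0.16 µm). Configurable everywhere.
- **Cell radii: CTRL 2.80–2.90 µm, DM/DM+PAD 1.60–1.67 µm.** The quartile
  rule can only isolate a two-phase field's ordered phase if the
  reference group's LC area fraction exceeds 25% — otherwise the 75th
  percentile falls inside the fluid mode and thresholding produces noise
  speckles instead of domains. The printed domain count × domain area
  targets therefore pin the DM cell area (LC fraction ≈ 0.26 just above
  the quartile), and CTRL cells are sized so that 20 elongated 1-µm
  domains remain packable without overlap (LC fraction 0.22). These radii
  are smaller than a real RBC's ≈ 3.5–4 µm; the count/size/fraction
  targets are mutually incompatible with real cell areas under a strict
  two-phase model, and the generator resolves the conflict in favour of
  the quantities the pipeline must recover. With these settings the
  DM-stack threshold lands at GP\* ≈ 0.69, between the fluid phase
  (≤ 0.55 for any plausible subject) and GP_LC = 0.70.
- **Photon budget 10,000 photons/pixel** (blue + green, background 5):
  per-pixel GP shot noise ≈ 0.009 SD, small against the 0.25 phase gap,
  so domain detection is noise-robust while GP estimator behaviour under
  Poisson statistics is still exercised. No read noise, no PSF blur by
  default (optional Gaussian blur), no photobleaching.

### What the generator does not emulate

Real Laurdan imaging has continuous GP textures rather than two discrete
phases, optical blur that softens domain boundaries, membrane-only (ring)
staining in equatorial sections, touching and overlapping cells, debris
with dye affinity, and patient-level covariate structure. Passing the
recovery tests therefore demonstrates that the *pipeline's operations are
correct and unbiased under known truth* — not that the clinical group
differences would be recovered from real microscopes; the printed group
values function as simulation inputs, and no clinical claim follows from
recovering them.

## Problem sizes and determinism

Every stochastic step takes a seed (NumPy `default_rng`); identical seeds
give bitwise-identical images, masks, thresholds and tables. The
end-to-end validation cohort uses the study's sample sizes (10/12/15
subjects × 5 images) at 256×256 px with packing-capped cells per image
(≈ 5 DM-sized or 1–2 CTRL-sized cells per field, i.e. 25 vs 5–10 cells
per subject), which preserves every analysis unit count that matters
(subjects per group; 20 cells per group for morphometrics) at a few
minutes of runtime; full-size runs (512×512, ~20 cells per field, ~100
RBC per DM subject) use the same code path via `laurdangp run`. The
detectability check for the DM vs DM+PAD GP contrast runs 100 replicates
at the subject level — drawing per-subject means from the generator's
subject model — because that is the level at which the test operates.

## Known limitations

- The corner-hull perimeter is exact for convex digitized shapes only;
  strongly concave domains would need a minimum-perimeter-polygon
  estimator.
- A global threshold couples domain detection to between-subject GP
  shifts; the per-cell mode decouples them but no longer matches a single
  printed reference threshold. Which the original workflow used is
  ambiguous; the default is global.
- The Otsu default assumes bimodal intensity (bright cells, dark
  background); dim or unevenly illuminated data should use the classifier
  mode.
- Holm-adjusted Welch tests and Tukey HSD can disagree near α; both are
  emitted, the default is Holm.
- `anova_from_summary` trusts the reported SDs' degrees of freedom
  (ddof = 1); summary tables using population SDs would bias F slightly.
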