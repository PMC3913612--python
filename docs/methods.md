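# Methods

This note records the models, numerical choices and study conditions behind
`burnscar`, at the level of detail a user needs to interpret results or
change a default responsibly.

## Difference-image model

The fused difference image combines three change signals computed from a
co-registered bi-temporal pair: the change-vector magnitude (Euclidean norm
of the per-pixel spectral difference over the configured CVA bands), the
NDVI difference and the NBR difference.  Conventions:

* **Difference sign** is pre minus post for both indices, so burned
  vegetation — whose NIR collapses while red and mid-IR rise — is positive
  change in every component.  This matches the standard dNBR convention and
  is what lets the segmentation assume the scar is the bright phase.
* **Normalization order**: each component is min-max normalized to [0, 1]
  first; the fusion weights w_k = σ_k/Σσ are then the standard deviations of
  the *normalized* components over valid pixels, and the weighted sum is
  min-max rescaled again.  A constant component gets weight 0; if all three
  are constant there is no change signal and the fusion raises an error
  rather than returning noise.
* **Nodata** pixels (flagged value or non-finite, in either date) are
  excluded from every minimum, maximum, SD, regression and evaluation
  statistic.
* **NBR band pairing** defaults to the conventional NIR/SWIR2 pair for both
  the TM preset (bands 4 and 7) and the OLI preset (bands 5 and 7); SWIR1
  can be selected through a custom band-role map.  Values may be digital
  numbers or reflectance — every statistic used is invariant to a global
  affine rescaling of a band.

Separability of burn versus unburned pixels on any grid is reported as
D = |μ_b − μ_u|/(σ_b + σ_u), with class histograms on a fixed 64-bin grid
over [0, 1] and their overlap fraction Σ min(p_b, p_u); the bin count is
fixed for reproducibility of reports.

## Automatic initial contour

Date-2 NIR is regressed on date-1 NIR by ordinary least squares *with an
intercept*: the textbook slope formula cov(X¹,X²)/var(X¹) is exactly the
OLS-with-intercept slope, and the intercept absorbs additive illumination
offsets between dates, which is the point of using a regression rather than
a plain difference.  The per-pixel error is the squared residual divided by
the residual variance of the fit (a squared 1-D Mahalanobis distance, mean
1 by construction, invariant to jointly rescaling both bands).

The change/no-change threshold on these errors comes from 2-class K-means.
For scalar data the optimal 2-partition is an interval split of the sorted
values, so the solver scans all splits with prefix sums and returns the
global within-cluster-SSE optimum directly — deterministic, exact, and
cheaper than Lloyd iterations (which the test suite keeps as an independent
cross-check).  The "change" class is the one with the higher center.  The
resulting mask becomes a binary-step surface φ₀ = ±2.

## Chan–Vese solver

Regularized Heaviside H_ε(z) = ½(1 + (2/π) arctan(z/ε)) and Dirac
δ_ε(z) = ε/(π(ε² + z²)); region means are the H_ε-weighted averages.
Curvature div(∇φ/|∇φ|) uses central differences with replicate (Neumann)
borders and η = 1e-8 in the gradient-magnitude denominator.  Evolution is
explicit gradient descent; no reinitialization of φ is performed — the
δ_ε-localized update does not require a signed-distance function, and φ₀ is
internally rescaled to unit maximum magnitude so results are invariant to
the height of a binary-step start.  Pixels with φ = 0 exactly are assigned
outside (deterministic tie-break).

Defaults (all exposed in `CVParams` and the CLI config): λ₁ = λ₂ = 1,
ν = 0, ε = 1, Δt = 0.5, μ = 0.1 for images normalized to [0, 1].  μ = 0.1
is the conventional length-penalty weight for unit-range images; at the
noise level of the study scenes (below) it is the term that removes
speckle and is the practical advantage of the level set over per-pixel
thresholding.  The explicit scheme is stable here since μ·Δt ≪ 1 and the
data term per step is bounded by Δt·δ_ε·max|force| < 1.

**Phase labeling.**  With λ₁ = λ₂ and ν = 0 the energy is invariant under
swapping inside and outside, so which phase ends at φ > 0 depends only on
the start; rectangle starts are observed to converge to either labeling.
The pipeline therefore relabels the final mask so the positive class is the
brighter phase of the difference image — the burn scar, under the sign
convention above.

**Stopping rule.**  The contour is considered converged when the fraction
of pixels whose sign changed over the last `stop_window` = 30 iterations
falls below `tol` = 1e-4.  Two guards make this robust: (i) quiet windows
occur *before* motion starts — a binary step needs a warm-up descent to
reach the zero level, and a rectangle tiling idles near the symmetric
c₁ = c₂ saddle for hundreds of iterations — so the flip rule is only
trusted on its own once a cumulative 2% of pixels (`min_activity`) have
flipped at least once; (ii) runs that never reach that activity stop at a
quiet window after `min_iter` = 2000 iterations.  Iteration counts are
therefore comparable between initializations but, as with any C-V
implementation, depend on the stopping parameters.

**Baseline configurations.**  Otsu maximizes between-class variance on a
256-bin histogram of the grid's own range.  Fuzzy C-means uses m = 2,
tol = 1e-5, max 300 alternating updates, intensity-only features, and
deterministic 10/90-percentile center initialization (random starts can
collapse both centers onto the majority mode when the scar is a small
fraction of the scene).  The traditional C-V baseline (TCV) segments the
CVA-only difference image from a tiled-rectangle start (default spacing 16,
rectangles of half the cell size); it runs with μ = 0.01 because under
μ = 0.1 the seed rectangles vanish by curvature flow during the saddle
phase before the data term can separate them — 0.01 is the strongest
smoothing the rectangle start tolerates, i.e. the baseline's best working
configuration.

## Synthetic study scenes

The generator emulates an *uncorrected* digital-number Landsat-like pair
(TM-style 6-band layout) around a fire event:

* background of vegetation (≈85%) and soil patches from a smoothed Gaussian
  random field, with per-class per-band means and SDs on a DN-like scale;
* a burn region drawn as a thresholded, center-biased smoothed Gaussian
  random field — naturally irregular, possibly concave, one connected
  component by default (a multi-blob option exists for topology tests) —
  targeting a scar fraction of 0.15 within ±50%;
* post-fire spectral shift inside the scar, default
  (−5, −8, +12, −60, +10, +25) DN across (blue, green, red, NIR, SWIR1,
  SWIR2): a strong NIR drop with red/mid-IR rises.  The shift is feathered
  through a Gaussian blur of the truth mask (σ = 2 px) so scar edges are
  gradual mixed pixels while the truth stays binary;
* non-fire temporal change everywhere at date 2: a per-band multiplicative
  illumination gain drawn uniformly from [0.92, 1.08] (sun angle and
  atmosphere differences, which raw DN pairs retain), white per-pixel noise
  with SD 15 DN, and optionally a smooth clutter field with a weak burn-like
  spectral signature (off by default).

The gain and noise levels were chosen so the separability diagnostics of
the generated scenes match the range reported for real Landsat fire scenes
analyzed with the same statistics — CVA-only D ≈ 1.3 and fused D ≈ 1.7 on
average — rather than the near-perfectly separable scenes a noise-free
generator produces.  This calibration matters scientifically: with white
noise only, the multi-band CVA average is the best possible single signal
and a global threshold is nearly Bayes-optimal, so neither the fusion gain
nor the level set's advantage over thresholding can be observed.  What the
generator does **not** emulate: spatially correlated phenology/moisture
clutter (available but off by default), clouds and shadows, registration
error, topographic illumination, and severity gradients within the scar.
Passing results on these scenes therefore demonstrate the machinery and
the method ordering under the stated conditions, not performance on any
particular real fire.

## Study sizes

The shipped comparisons and the acceptance script use ten generator seeds
at 128×128 pixels, chosen so a full four-method comparison completes in
about a minute on one CPU while per-scene medians are stable; the disk
fixture for solver verification is 64×64 with intensities 0.2/0.8 and noise
SD 0.02.

## Known limitations

* Iteration counts are stopping-rule dependent; only orderings between
  initializations are meaningful.
* The TCV baseline is volatile across scenes (its saddle escape is
  noise-driven), which matches its role as the weakest configuration.
* FCM on strongly imbalanced scenes can still place its fuzzy boundary
  poorly; it is a baseline, not a recommended method.
* The solver is the plain explicit two-phase scheme: no narrow band, no
  semi-implicit stepping, no multiphase extension; very large rasters will
  be slow.
* Georeferencing is carried opaquely (raw GeoTIFF tags copied to outputs);
  no reprojection or CRS interpretation is attempted.
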