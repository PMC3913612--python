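# burnscar

Automatic burn-scar extraction from bi-temporal multispectral satellite
imagery, for fire-ecology and forestry applications: given two co-registered
acquisitions of the same area before and after a fire, produce a binary map
of the burned area with no training data and no hand-picked thresholds.

## Method

The pipeline has three stages.

**1. Weighted-fusion difference image.**  Three per-pixel change signals are
computed between the dates: the change-vector magnitude over the reflective
bands

&nbsp;&nbsp;ΔCVA(x) = ‖X²(x) − X¹(x)‖₂ ,

and the pre-minus-post differences of two spectral indices that react
strongly to burning, ΔNDVI with NDVI = (NIR − R)/(NIR + R), and ΔNBR with
NBR = (NIR − MIR)/(NIR + MIR).  Each component is min-max normalized to
[0, 1] and the three are fused with weights proportional to their standard
deviations, w_k = σ_k / Σσ, so the component carrying the strongest change
signal dominates the difference image DI = Σ w_k d_k.  Class separability is
diagnosed with the normalized distance D = |μ_b − μ_u| / (σ_b + σ_u).

**2. Automatic initial contour.**  Unchanged pixels keep a nearly linear
relation between their NIR values at the two dates, so the date-2 NIR band
is regressed on the date-1 band by least squares (slope = cov/var).  The
squared residual scaled by the residual variance — a 1-D Mahalanobis
distance — flags change pixels; a 2-class K-means on these error values
(solved exactly for scalar data) supplies the change/no-change threshold,
and the change mask becomes the starting surface φ₀ of the level set.

**3. Chan–Vese level-set segmentation.**  The difference image is segmented
by minimizing the two-phase piecewise-constant energy

&nbsp;&nbsp;E = μ·Length(φ=0) + ν·Area(φ>0) + λ₁∫|DI − c₁|² H(φ) + λ₂∫|DI − c₂|² (1 − H(φ))

with the regularized Heaviside H_ε(z) = ½(1 + (2/π) arctan(z/ε)) and its
derivative δ_ε, region means c₁, c₂, and explicit gradient descent

&nbsp;&nbsp;φ ← φ + Δt·δ_ε(φ)·[μ·div(∇φ/|∇φ|) − ν − λ₁(DI − c₁)² + λ₂(DI − c₂)²].

Because the contour is the zero level of a surface, it splits and merges
freely, and the region-based energy handles the blurred, concave scar
boundaries that defeat edge-based methods.  Baselines from the same study
design are included: Otsu thresholding and fuzzy C-means on the fused DI,
and the traditional Chan–Vese configuration (TCV: CVA-only difference image,
tiled-rectangle initial contour).  Accuracy is reported as missed / false /
right alarm rates (percent of all pixels; they sum to 100), Cohen's kappa,
and the number of level-set iterations.

Because public burn scenes with reference outlines are not bundled, the
package ships a synthetic-scene generator (`burnscar.synthetic_scenes`)
producing bi-temporal pairs with a known scar: irregular blurred-edge burn
regions, post-fire spectral shifts (NIR down, red and mid-IR up), per-band
illumination gain differences and temporal noise calibrated so the
difference-image separability matches values reported for real Landsat
fire scenes (D ≈ 0.9–1.9).

## Worked example

```
$ burnscar simulate --out demo --seed 7
INFO wrote synthetic pair (128x128, scar 10.2%) to demo

$ burnscar run --pre demo/pre.tif --post demo/post.tif --truth demo/truth.tif \
      --sensor tm --method proposed --out demo/run --seed 7
INFO running method=proposed on (128, 128) pixels
INFO kappa=0.9443 right=98.95% iterations=1290
```

`demo/run/` now holds the extracted mask (`mask.tif`), the fused difference
image, the automatic initial contour, the energy trace, the resolved
configuration and `report.json`:

```json
{
  "missed_pct": 0.177, "false_pct": 0.873, "right_pct": 98.950,
  "kappa": 0.944, "iterations": 1290
}
```

Only 0.18% of pixels are burn missed as unburned and 0.87% are false alarms;
kappa 0.944 is chance-corrected agreement with the true scar.  Comparing all
four methods on the same pair:

```
$ burnscar compare --pre demo/pre.tif --post demo/post.tif --truth demo/truth.tif \
      --out demo/cmp --seed 7
          missed_pct  false_pct  right_pct  kappa  iterations
method
proposed      0.1770     0.8728    98.9502 0.9443   1290.0000
otsu          1.3733     2.3071    96.3196 0.8067         NaN
fcm           0.2563    21.5393    78.2043 0.3816         NaN
tcv           8.0872     0.2319    91.6809 0.3092   1950.0000
```

The regularized level set on the fused difference image beats both global
thresholding methods, and the automatic initial contour reaches convergence
in far fewer iterations than the traditional rectangle start.

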