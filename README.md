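# plaqueindex

Tools for measuring the **abdominal aortic atherosclerotic plaque index
(API)** from contrast-enhanced CT and for analysing its association with
post-operative kidney function.

The API is the volumetric burden of calcified plaque in the abdominal aorta,

```
API = 100 · V_plaque / (V_lumen + V_plaque)   [percent]
```

where both volumes come from a semi-automatic segmentation of the aorta: a
sparse set of per-slice contours is interpolated into a tubular region of
interest, and lumen and calcium are then grown inside it with two disjoint
Hounsfield-unit bands (contrast-enhanced blood vs. calcium), which makes the
two compartments structurally non-overlapping. Because an increasing API
reflects progressive loss of aortic patency, it is a candidate predictor of
chronic kidney disease (CKD, operationalised as eGFR < 60 mL/min/1.73 m²)
after nephron-sparing kidney surgery.

The package is aimed at imaging/outcomes researchers who want a fully
scriptable version of this measurement chain plus the statistics that go
with it. Since no patient imaging ships with the package, every stage is
validated on synthetic data with analytically known ground truth:

- **`plaqueindex.phantoms`** — synthetic contrast-CT aorta phantoms with
  mural annular-arc plaques of known volume (partial-volume blur and noise
  included; a super-sampling occupancy oracle provides exact truth).
- **`plaqueindex.ct_io`** — NIfTI / MetaImage volumes and masks with strict
  spacing metadata, (z, y, x) axis convention, ROI cropping.
- **`plaqueindex.segmentation`** — contour interpolation (centroid-aligned
  signed-distance blending), band-constrained region growing, API
  volumetry.
- **`plaqueindex.cohort`** — synthetic surgical cohorts in which CKD risk
  depends log-linearly on the API category (0 / <10 / ≥10) alongside
  comorbidity burden and baseline eGFR.
- **`plaqueindex.clinical`** — CKD-EPI eGFR, Δ%eGFR, Mann–Whitney U,
  Fisher's exact test, odds ratios, logistic models with Wald CIs.
- **`plaqueindex.rocreg`** — covariate-adjusted **binormal ROC regression**
  by maximum likelihood: the classifier T follows `N(z'γ, σ₀²)` in controls
  and `N(z'γ + α + βx, σ₁²)` in cases, inducing
  `ROC(u; x) = Φ(a(x) + b·Φ⁻¹(u))` with `a(x) = (α + βx)/σ₁`, `b = σ₀/σ₁`
  and `AUC(x) = Φ(a(x)/√(1+b²))`. This quantifies how much extra
  discrimination the plaque index adds to the Δ%eGFR classifier.

## Worked example

Measure the plaque index of a phantom whose true API is 10.0%:

```python
from plaqueindex import (default_phantom_suite, generate_phantom,
                         auto_keyframe_contours, interpolate_contours,
                         segment_aorta_plaque, compute_api)

spec, truth = default_phantom_suite()[3]          # the ~10% phantom
vol, _ = generate_phantom(spec)                   # 1 mm isotropic CT volume
contours = auto_keyframe_contours(vol)            # one contour every 10 slices
tube = interpolate_contours(contours, vol.shape, vol.spacing)
api = compute_api(segment_aorta_plaque(vol, tube))
print(api.to_json())
```

```json
{
  "lumen_mm3": 22956.0,
  "plaque_mm3": 2488.0,
  "total_mm3": 25444.0,
  "api_percent": 9.778336739506367
}
```

The estimate is 9.78% against a ground truth of 10.00% — a 0.22
percentage-point error, dominated by partial-volume blur at the plaque
boundary.

Fit the ROC regression on simulated marker data where the plaque index
truly adds β = 0.13 discrimination per unit:

```python
from plaqueindex.rocreg import RocRegression, simulate_binormal

m, s, Z, x = simulate_binormal(2000, 2000, gamma=(0.2, 0.3, 0.2, 0.4),
                               alpha=0.4, beta=0.13, rng=7)
res = RocRegression(m, s, Z, x,
                    exog_names=["hypertension", "coronary", "diabetes"]).fit()
print(res.summary())
```

```
Binormal ROC regression (maximum likelihood)
  n cases=2000  n controls=2000  loglike=-5601.55  converged=True
  sigma0=0.9831  sigma1=0.9801  ROC slope b=1.0030
  ...
         beta   0.1305  se 0.0038  95% CI [ 0.1230,  0.1381]
  beta (marker scale) 0.1305; standardised beta/sigma1 0.1332; p=3.019e-253
  AUC at case covariate 10: 0.891
  AUC at case covariate 15: 0.955
  AUC at case covariate 20: 0.985
```

The fitted β ≈ 0.130 recovers the generating effect, and the AUC at plaque
indices 10/15/20 shows discrimination increasing with calcification burden.

## Command line

```bash
plaqueindex phantom --outdir runs/phantoms                 # suite + truth JSONs
plaqueindex segment --volume runs/phantoms/api10.nii.gz --outdir runs/seg
plaqueindex cohort  --outdir runs/cohort --n 800 --seed 2
plaqueindex analyze --cohort-csv runs/cohort/cohort.csv --outdir runs/analysis
plaqueindex e2e     --outdir runs/e2e --seed 0             # full demo chain
```

Every run directory contains a `manifest.json` with the configuration hash,
seeds and SHA-256 checksums of all outputs; rerunning with the same seed
reproduces the checksums exactly.

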