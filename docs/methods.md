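# Methods

This note documents the models implemented in `plaqueindex`, the default
parameters and why they were chosen, what the synthetic generators emulate
(and deliberately do not), and the numerical choices that matter for
reproducing results.

## 1. The plaque index and its segmentation

The abdominal aortic atherosclerotic plaque index is defined as

```
API = 100 · V_plaque / (V_lumen + V_plaque)  [percent]
```

The denominator is the *segmented aortic model* — lumen plus calcified
plaque. The aortic wall is not segmented as a separate compartment; the
pipeline recognises exactly two tissues inside the tubular region of
interest, so "total aortic volume" means their union. Volumes are voxel
counts times the voxel volume, which makes the API invariant under a global
rescaling of the voxel spacing (it is a pure ratio).

Segmentation follows a three-phase, semi-automatic design:

1. **ROI.** The user (or a script) crops the volume to the abdominal aorta
   (`ct_io.crop_to_roi`). All arrays are (z, y, x)-ordered with half-open
   0-based indices; spacing/origin live in world (x, y, z) mm. One fixed
   convention, applied by the file readers, removes the most common class
   of volumetric indexing bugs.
2. **Sparse contouring + interpolation.** Closed polygons are drawn (or
   auto-extracted) roughly every 10 slices and interpolated into a tube.
   Interpolation is shape-based: the signed distance transforms (SDTs) of
   the two flanking keyframe polygons are linearly blended and thresholded
   at zero. The SDTs are first re-sampled into a common frame centred on
   the linearly interpolated centroid; without that alignment, plain SDT
   blending cannot bridge keyframes whose cross-sections do not overlap
   (the blend is negative everywhere between two far-apart circles).
   With alignment, a translating circle interpolates as a moving circle —
   which is also the right behaviour for a curved aorta. Each interpolated
   slice keeps its largest connected component, so the tube is a single
   channel per slice.
3. **Dual-band region growing.** Lumen grows in the band
   `[t_lumen_lo, t_lumen_hi)` seeded from every in-band voxel of the tube;
   plaque grows in `[t_plaque_lo, ∞)` constrained to the tube dilated by
   `dilation_margin` voxels (default 2), so mural calcium protruding
   slightly past the drawn contour is still captured. The invariant
   `t_lumen_hi ≤ t_plaque_lo` makes lumen/plaque disjointness a structural
   property rather than a post-hoc correction. Growth is a connected-
   component flood fill (face adjacency by default; 26-connectivity
   available); it is implemented with `scipy.ndimage` labelling and is
   tested for exact equality against an independent brute-force BFS.

**Default thresholds.** Lumen `[140, 475)` HU, plaque `[475, ∞)` HU. These
are full-width-half-maximum cuts: 140 is the midpoint between soft-tissue
background (~30 HU) and contrast-enhanced lumen (~250 HU), 475 the midpoint
between lumen and calcium (~700 HU). Midpoint thresholds make thresholded
volumes first-order insensitive to partial-volume blur — a threshold far
from the midpoint systematically moves the recovered boundary by
`σ·Φ⁻¹(fraction)` and biases plaque volume by that offset times the
interface area. (A plaque cut at 350 HU, for instance, over-extends ~0.8σ
into the blurred lumen shell and inflates the API by 1–2 percentage points
at realistic blur.) All thresholds are configuration-exposed; clinical data
with different contrast protocols will need different values.

**Seeding.** All in-band voxels inside the tube are used as seeds rather
than a single user click. This is deterministic, needs no interaction, and
is a superset of any single-seed result within the same constraint.

## 2. CT phantoms and ground truth

The phantom is a tube along the grid's z axis: centreline `(x(z), y(z))`
given by low-order polynomials (mm), lumen radius `r(z)` constant or
linearly tapered, and plaques modelled as **mural annular arcs** — solids
bounded by `[z₀, z₁]` axially, `[θ₀, θ₁]` on the wall, growing inward from
the wall with a fixed radial thickness. Mural arcs match atherosclerotic
morphology and make lumen/plaque disjointness geometrically meaningful;
free-floating spheres would not. Tissue HU means (background 30, lumen 250,
plaque 700) are generic contrast-CT values chosen to be separable by single
thresholds; Gaussian tissue/pixel noise (default sd 20 HU) is added and the
volume is blurred with a Gaussian point-spread function.

**Partial volume.** The default PSF width is `0.6 × max(spacing)` — an
FWHM of ~1.4 voxel pitches, typical of clinical reconstruction, and scaled
with resolution because a finer acquisition has a proportionally sharper
PSF. This scaling is what makes the API error genuinely converge as voxel
spacing shrinks: with a *fixed* physical PSF the segmentation converges to
the blurred solid's thresholded volume, not to the true pre-blur volume, so
the error would plateau at a nonzero bias. Ground truth always refers to
the continuous pre-blur solids, so accuracy tests face realistic boundary
blur rather than a self-fulfilling target.

**Truth oracle.** `analytic_truth` counts sub-voxel centres (default 8³ per
voxel) inside the continuous solids. For the suite geometries the truth is
also available in closed form (cylinder `πr²L`; annular sector
`(θ₁−θ₀)/2·(r²−(r−t)²)·(z₁−z₀)`), and the oracle agrees with those to
<0.5%. The occupancy-count error decreases as O(1/supersample) but
oscillates inside that envelope with sub-cell lattice alignment, so tests
assert the envelope (error at s=16 ≤ error at s=4, both <0.1%) rather than
step-by-step monotonicity.

**Default suite.** Five named phantoms on a 48×48×80 mm grid at 1 mm
isotropic spacing with a gently bowed centreline and a 10 mm lumen: target
APIs 0, 2, 5, 10 and 20% — the clinically salient range around the 10%
cutpoint used in the outcome models and the 10/15/20 thresholds used in the
ROC regression. Plaque arcs/thicknesses were solved against the
annular-sector closed form, so the targets are hit to <0.01 points.

What the phantoms do **not** emulate: acquisition physics (beam hardening,
streaks, photon noise correlations), non-calcified soft plaque, surrounding
anatomy, patient motion. Passing the recovery tests therefore demonstrates
correctness of the geometry/volumetry chain under noise and blur — not
clinical robustness on real scans.

## 3. Renal function and categorisation

- **eGFR**: 2009 CKD-EPI creatinine equation,
  `141·min(Scr/κ,1)^α·max(Scr/κ,1)^-1.209·0.993^age` with the female
  (κ=0.7, α=−0.329, ×1.018) and male (κ=0.9, α=−0.411) branches; the race
  coefficient (×1.159) is off by default and available by flag.
- **Δ%eGFR**: `100·(eGFR_last − eGFR_pre)/eGFR_pre`; negative = decline.
- **CKD**: `eGFR < 60` (KDIGO stage ≥ 3). The cutoff is config-exposed;
  sites using stage ≥ 3b (45) or albuminuria-based definitions can adjust,
  and the package makes no claim about any particular study's operational
  definition.
- **API categories**: 0, (0, 10), ≥ 10 — zero meaning "no measurable
  imbalance between plaque and lumen", not "no plaque".

## 4. Synthetic cohorts

One latent comorbidity factor `u ~ N(0,1)` per patient couples age, the
Charlson index (Poisson with log-rate 1.25 + 0.35u), hypertension/diabetes/
coronary disease (logistic in u, the Charlson index, and log1p(API)),
baseline eGFR (82 − 8u ± noise), and the plaque index. The API marginal is
a mixture of a point mass at zero (weight 0.35, modulated by u) and a
log-normal tail (μ=0.2, σ=1.3, loading 0.35 on u) — zero inflation is
required by the observed lower-quartile-at-zero pattern, the tail feeds the
≥10 category (~4–5% of patients).

The outcome is one Bernoulli draw per patient from

```
logit P(CKD) = −1.217 + ln(1.27)·CCI + ln(0.98)·eGFR_pre
               + ln(2.96)·1[0<API<10] + ln(25.2)·1[API≥10]
```

The coefficient anchors are odds ratios reported for this kind of cohort;
the intercept −1.217 was calibrated once by large-n simulation so the
marginal CKD prevalence is ≈ 49/183 ≈ 0.268, and the comorbidity-submodel
intercepts were calibrated the same way so the per-arm hypertension and
diabetes prevalences land near 48.5/75.5% and 11.2/36.7%. The positive
API–u coupling is medically realistic (atherosclerosis travels with
comorbidity burden) and keeps the *crude* ≥10-vs-0 odds ratio near the
generating conditional value: confounding through CCI/eGFR pushes the crude
OR up by about as much as odds-ratio non-collapsibility pulls it down.

**Trajectories.** Each patient gets one percentage change drawn around an
API-category mean (−2.5 / −6 / −18% for categories 0 / <10 / ≥10, sd 8)
applied to all follow-up time points plus small per-time noise — pointwise
eGFR is all the downstream analysis uses, so no longitudinal correlation
structure is modelled. The last-follow-up eGFR is then resampled onto the
label-consistent side of the CKD threshold: the category-mean model alone
cannot guarantee that `classify_ckd(eGFR_last)` agrees with the drawn
outcome label for patients near the boundary, and downstream consistency
checks (and any user who recomputes the label from the table) need the two
to agree. The stored Δ% column is recomputed from the stored (rounded)
eGFR columns so the CSV is internally consistent.

Tumour-side/histology/operative fields are noise covariates that exercise
the report layout; no surgical decision process is modelled.

## 5. Statistical methods

- **Mann–Whitney U**: exact two-sided null distribution when the combined
  sample is ≤ 12 without ties (verified against full permutation
  enumeration); otherwise the tie-corrected normal approximation with
  continuity correction, using midranks. The exact branch refuses ties.
- **Fisher's exact test**: two-sided, sum of hypergeometric probabilities
  ≤ that of the observed table; only 2×2 (r×c inputs must be dichotomised
  by the caller). Verified against enumeration over all margin-fixed
  tables.
- **Odds ratios**: cross-product with Woolf logit CIs; a 0.5 continuity
  correction on all cells when any cell is zero, flagged in the result.
- **Logistic regression**: statsmodels Newton ML with Wald ORs/CIs and
  McFadden pseudo-R². An API covariate is auto-expanded to the category
  indicators with 0 as reference. Constant covariates are dropped with a
  flag; separation or failed maximisation returns a flagged
  diagnostic-only fit, never silent NaNs. Wald (not profile) intervals are
  reported deliberately: with sparse high-OR categories they produce the
  characteristic huge asymmetric CIs a reader should see, and coverage
  under the generator is 93–96% at n = 2000.
- **Multiple testing**: none; α = 0.05 two-sided throughout.

## 6. ROC regression

The covariate-adjusted binormal model: controls `T ~ N(z'γ, σ₀²)`, cases
`T ~ N(z'γ + α + β·x, σ₁²)` with shared location coefficients γ (intercept
+ comorbidity indicators) and a case-only discrimination covariate x (the
plaque index). Induced ROC at covariate value x:

```
ROC(u; x) = Φ(a(x) + b·Φ⁻¹(u)),  a(x) = (α + β·x)/σ₁,  b = σ₀/σ₁,
AUC(x) = Φ(a(x)/√(1+b²))
```

Estimation is direct joint maximum likelihood over
`(γ, α, β, log σ₀, log σ₁)` with BFGS; a two-stage least-squares pass
(controls first, case offsets second) supplies starting values and is kept
*only* as an initialiser. Standard errors come from the inverse numerical
Hessian at the optimum; σ estimates are floored at 1e−6. BFGS sometimes
reports "precision loss" at the flat optimum of a large-n likelihood, so a
solution is also accepted when the scaled gradient is negligible
(∞-norm ≤ 1e−4·(1+|nll|)).

Two conventions worth noting. First, the classifier must be oriented so
larger = more disease-like; the CLI negates Δ%eGFR (a *decline* becomes a
positive score) and records that in the output metadata. Second, β is
reported on two scales — the raw marker scale and the ROC-intercept scale
β/σ₁ — because "effect of the covariate on discrimination" is ambiguous
between them; both are in the results object and the summary.

Under correct specification the implementation recovers: the closed-form
covariate-free AUC `Φ(1/√2) ≈ 0.760` for N(0,1) vs N(1,1) to within 0.01
at n = 50 000 per arm; β = 0.13 with |bias| < 1% of the truth over 200
replicates at n = 2000 per arm; and ~95% Wald CI coverage of β = 0 under
the null.

## 7. Reporting pipeline

`analyze`/`e2e` write: per-arm baseline/operative/functional summary tables
(median (IQR) and count (%) with Mann–Whitney / Fisher p-values), two
logistic models (baseline covariates: ASA, CCI, pre-op eGFR, API
categories; perioperative covariates: RENAL score, ischemia time,
complication grade, API categories), the ROC regression, the API-vs-eGFR
scatter data, and empirical ROC points. Plot images are best-effort; the
CSV/JSON data are canonical and are what determinism checks cover. Every
run directory has a manifest with config hash, seeds and SHA-256 checksums.

## 8. Problem sizes and tolerances used in validation

The test-suite and acceptance-script problem sizes are chosen to make each
statistical check decisive at desk scale: phantom work at 1 mm (with one
2/1/0.5 mm convergence sweep on the ~10% phantom), 100 random 20³ volumes
for the flood-fill oracle, full enumeration for exact tests up to n = 12,
200 replicates at n = 2000 for logistic coverage and for ROC-regression β
recovery, and n = 50 000 per arm for the binormal AUC limit. With these
sizes the whole validation runs in a few minutes on one CPU.

## 9. Known limitations

- Single-threshold tissue classification cannot be unbiased at *both*
  plaque interfaces (lumen-facing and background-facing) simultaneously;
  midpoint defaults make the residual bias second-order, but very thin
  (< 1 voxel) plaques remain under-measured at coarse spacing.
- DICOM series are not read; convert to NIfTI/MetaImage first. Direction
  matrices are assumed identity.
- The cohort generator reproduces marginal and conditional association
  structure, not clinical reality: no informative censoring, no
  measurement error in creatinine, no site effects.
- The ROC regression assumes Gaussian classifier distributions within
  groups (the binormal model); heavy-tailed markers would need a
  transformation first.
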