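# Methods

This note documents the models behind `hypervine`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a user extending the package should know about.

## Trait generator

Thirteen per-vine traits are generated: pre-dawn and mid-day leaf water
potential (Ψpd, Ψmd, MPa), total and lateral leaf area (m²/vine), pruning
weight (kg/vine), yield (kg/vine), cluster weight (g), berry weight (g),
total soluble solids (°Brix), titratable acidity (g/L), malate (g/L),
total anthocyanins and phenolics (mg/g). Only marginal summaries (mean,
min, max, CV%) are published for the field cohort, so:

- **Marginals.** Each trait is a Gaussian truncated to its published
  [min, max]. Truncation shrinks variance and pulls the mean toward the
  interval centre, so the parent (μ, σ) are found by least squares on the
  truncated moments; a final affine recalibration x → α + βx pins the
  distribution's mean and SD to the published targets exactly (β ≈ 1 in
  all cases; re-clipped to the bounds). One trait, malate, has a
  published CV (56.8 %) that sits just above what any truncated normal
  on its printed range can attain at its mean (~55.4 %); the affine
  stage closes most of the gap (realized ≈ 56.6 % at n = 10⁴).
  Water potentials are handled on the signed scale (min = −0.73 MPa <
  max = −0.27 MPa for Ψpd), where the published table lists magnitudes.
- **Joint structure.** A Gaussian copula couples the marginals. The
  default correlation matrix is a modelling choice, not a published
  fact: a positively inter-correlated vigor block (leaf areas, pruning
  weight, yield, cluster/berry weight), water potentials more negative
  on high-vigor vines, and malate/anthocyanins/phenolics tracking the
  shaded fruit-zone microclimate while opposing sugar accumulation.
  Entries are in ±0.3–0.6 and the matrix is eigenvalue-clipped to the
  nearest valid correlation. It is fully overridable via `TraitSpec`.
- Sampling is a pure function of (spec, n, seed); every stochastic
  operation in the package takes an explicit seed and no global RNG
  state is used.

## Canopy reflectance forward model

Real canopy spectra are replaced by a minimal parametric model with known
ground truth:

R(λ) = vis + (nir − vis)·logistic((λ − λ_re)/w) + g·exp(−(λ−550)²/(2·15²))

Defaults: visible baseline 0.05, NIR plateau 0.45, green bump 0.04,
red-edge inflection λ_re = 715 nm, logistic width 12 nm. Couplings are
linear in each trait's deviation from its published mean: the NIR plateau
rises with total leaf area (+0.05 per m²) and falls with water stress
(+0.30 per MPa of Ψpd, i.e. stressed vines are darker in the NIR); λ_re
shifts down under stress (+25 nm/MPa); the green bump tracks a
standardized vigor composite (+0.015 per z). Multiplicative lognormal
noise (sd 0.01) is applied per band; outputs are clipped strictly inside
(0, 1). With zero noise each coupled trait is an exact monotone function
of some band's reflectance — the planted signal the retrieval tests
verify. No radiative transfer, atmosphere or BRDF is modelled.

## Scene rendering and radiometry

The block follows the study geometry: north–south rows at 2.4 m spacing,
vines at 1 m within the row, vertical canopies rendered as 0.6 m wide
raised strips (height 1.8 m) on flat ground, with a 0.16 m shaded-leaf
strip along each canopy's east edge (shadow spectrum = canopy × 0.25),
1 m grass strips centred in the inter-rows, bright soil elsewhere, and
the five reference panels (2/9/25/50/88 %) in a southern margin. The
default demo uses a 5 cm ground sampling distance and a 60-vine block
(6 rows × 10 vines), which keeps the 50-band cube around 300 × 300
pixels; the flown campaign's ~2 cm GSD is supported but generates
proportionally larger rasters. Rasters live in a local metric frame
(meters, pixel-centre convention, north-up); no geodetic CRS is attached.

DN formation per band: L = ρ·E(λ) with a smooth solar-like irradiance
curve, DN = round(L/gain + dark + noise) with gain = E(λ)/50000 (so full
reflectance ≈ 50 000 counts), dark current 100 counts, Gaussian DN noise
sd 20 counts. **Noise-free oracle mode** disables the DN noise, the
canopy multiplicative noise *and* the rounding (continuous counts):
rounding alone would floor the reflectance round-trip error at
0.5·gain ≈ 10⁻⁵, so the exactness checks (panel recovery ≤ 10⁻⁸,
full-scene recovery ≤ 10⁻⁶) are defined on the continuous chain. The
calibration inverse subtracts dark in the DN domain by default
(L = gain·(DN − dark)); the post-gain order is available because sensor
documentation states the two inconsistently. Panel radiances are
averaged over polygons eroded by one pixel to avoid boundary mixels.
Negative reflectances are preserved (clipping is an option, not the
default): validity judgements belong to the segmentation filters.

## Segmentation

Ground model: moving-window 5th-percentile surface of the DSM with a
4.8 m window (twice the row spacing, so every window sees inter-row
ground); `scipy.ndimage.percentile_filter`, which takes the rank-floor
("lower") percentile — the brute-force oracle in the tests matches that
convention. CHM = DSM − ground, floored at 0. Canopy mask = (CHM >
0.5 m) AND (reflectance at the band nearest 800 nm > 0.15); the height
rule removes soil and grass, the NIR brightness rule removes shaded
leaves (canopy × 0.25 ≈ 0.11 in the NIR, below the 0.15 threshold). The
thresholds are package defaults — the original workflow publishes none —
and are configurable. ROI membership is pixel-centre containment; a vine
whose ROI retains no masked pixel is excluded with a warning rather than
failing the run.

## Index registry

37 uniquely named indices cover the 38 published formula rows (one row is
printed twice with an identical formula). Formulas are implemented
verbatim as printed, including departures from the literature's canonical
forms (PRI band order, the NDRE pair, the MTCIvar denominator, the NRI
bands at 555/550 nm, the additive red-edge-position expression, and
EVI/EVI2 with the "+1" outside the ratio — which, unlike canonical EVI,
makes them scale-invariant). Two printed rows have unbalanced
parentheses (NDRE, MTVI) and are closed in the only way consistent with
their names. Wavelengths resolve to the nearest band centre within one
FWHM (8 nm); on the default grid every printed wavelength resolves, and
660 and 663 nm land on the same 663.3 nm centre. Derivative-window
indices (Max/Σ [D_a, D_b]) default to all bands within the closed nm
interval ("window" mode; 2–3 bands on the default grid), with a "pair"
mode restricted to the two named bands. Division by zero yields NA with
a warning, never an exception; polygon averages skip NA pixels per
index. Two aggregations are exposed: per-pixel indices averaged within
the polygon (the study protocol, default) and indices on the mean
spectrum; they coincide exactly on homogeneous polygons and differ by at
most the per-pixel index spread otherwise.

## Chemometrics

- **PLS**: single-response NIPALS with deflation on mean-centred data
  (for one response the weight step is a direct covariance projection).
  Verified numerically against scikit-learn's NIPALS implementation and,
  at full rank, against the least-squares solution. If the residual
  covariance is exhausted early (rank-deficient X or constant y), the
  model records the number of extracted components and further LVs
  contribute nothing rather than erroring.
- **Cross-validation**: random, balanced deletion groups (k = 3 default),
  a pure function of (n, k, seed). Mean centring is refit inside every
  training fold by default (no leakage); a "global" switch reproduces
  centre-once workflows. LVs are chosen by minimum RMSECV with ties to
  fewer LVs. R²cv = 1 − PRESS/SS_total (can be negative); a
  squared-correlation alternative is available. `lv_max` defaults to
  min(10, n/3) to keep small folds from overfitting.
- **Forward iPLS**: the band axis is split into contiguous intervals of
  10 or 5 variables (a remainder is absorbed by the last interval, with
  a warning). Selection starts from the single best interval — so even a
  pure-noise response reports one interval — and greedily adds the
  interval that most reduces RMSECV, re-optimising the LV count for
  every candidate set, stopping at the first non-improvement; the
  RMSECV trajectory is therefore strictly decreasing. Ties break
  deterministically (RMSECV, then fewer LVs, then lower interval
  index). Selected wavelength ranges are printed by merging adjacent
  intervals and formatting the resolved band centres rounded to integer
  nm ("start:end").
- **Univariate table**: OLS per (index, trait) pair matched by vine id;
  traits measured on a subset (the water potentials, 30 of 60 vines)
  use only their subset. Two-sided p from the slope F-test; significance
  ladder '****' p<0.0001, '**' p<0.001, '*' p<0.01, else ns. No
  multiple-testing correction is applied (the matrix is reported raw);
  with 481 cells, ~5 would pass p<0.01 by chance under global
  independence.
- **Model report**: per trait, one full-spectrum PLS row and one iPLS
  row per width; the best row minimises RMSECV (ties → higher R²cv,
  then fewer variables).

## What the tests do and do not show

The synthetic scenes exercise the full chain against exact ground truth:
calibration is checked to machine precision on the continuous noise-free
chain, segmentation against the renderer's class masks, extraction
against the generated spectra, and trait retrieval against planted
couplings. They do not emulate atmospheric variability, BRDF and
view-angle effects, band-to-band misregistration of a moving platform,
mixed pixels at sub-GSD scale, or biochemically realistic spectral
signatures — so passing tests demonstrate correctness of the processing
chain, not field-level retrieval accuracy. Trait–index correlations on
the synthetic cohort reflect the planted couplings (traits the forward
model does not drive are recovered only through their copula correlation
with driven traits, visibly weaker in the model report — a useful
negative control).

Two simulation-design notes. The LV-selection consistency check uses a
planted rank-3 signal at n = 120: with 3 deletion groups on 30 samples,
RMSECV differences between adjacent LV counts are dominated by fold
noise even as the response noise vanishes, and selection stabilises only
with more samples. The parameter-recovery check (R²cv ≥ 0.8 under 10 %
response noise) uses collinear, smooth low-rank predictors, as
reflectance spectra are; on independent Gaussian predictors the same
signal-to-noise yields visibly lower cross-validated R², which is a
property of PLS on unstructured designs, not a defect.

## Problem sizes

Defaults were chosen so the full test suite and the demo pipeline run in
well under a minute each on a single core: a 60-vine block at 5 cm GSD
(50 × ~300 × ~300 cube), 10⁴ draws for generator calibration checks,
200 replicates for LV-selection consistency and 100 for iPLS window
recovery. All sizes scale up through configuration without code changes.
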