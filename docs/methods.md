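# Methods

`leafspec` implements a chemometric pipeline for estimating leaf potassium
content (LKC, percent of dry mass) of cotton from visible/near-infrared
hyperspectral leaf images, together with a synthetic scene generator that
supplies seeded data with known ground truth. This note documents the models,
the defaults and why they were chosen, the numerical decisions, and what the
synthetic experiments do and do not demonstrate.

## The measurement model

A benchtop line-scan acquisition is modelled as a rows × cols × 128-band cube
of raw digital numbers (DN). The reference LKC of a leaf comes from a
flame-photometer assay,

    K(%) = ρ · V · t_s · 10⁻⁴ / m,

with ρ the K mass concentration from the standard curve (µg·mL⁻¹), V the
measuring liquid volume (mL), t_s the separation multiple and m the dry mass
(g) (`preprocess.lab_k_percent`).

Processing steps:

1. **Reflectance calibration.** Per band, divide by the mean DN of the gray
   reference panel and multiply by the panel's known reflectance. The ratio
   form makes the result invariant to global illumination gain.
2. **Band trimming.** Keep centers in the closed window 400–950 nm. The
   sensor grid is 128 centers at 376 + 5.2·i nm; this spacing leaves exactly
   106 bands in the window. (A literal 376–1044 nm linspace gives 105; the
   5.2 nm spacing reproduces the documented 106-band window and honours the
   nominal ~5 nm resolution. The last center is then 1036.4 nm.)
3. **Segmentation.** Single-band threshold at the band nearest 800 nm:
   reflectance below 0.25 is the background plate. The published threshold
   interval "0.25–0.3098" is read as a lower cut at 0.25 with 0.3098 being
   the observed leaf maximum, not an upper cut — an upper cut would discard
   the brightest leaf pixels. The largest 4-connected component is kept,
   which drops isolated speckle. Named wavelengths ("800 nm") map to the
   nearest band center, ties toward the lower center.
4. **Whole-leaf spectrum.** Per-band arithmetic mean over the mask — the
   original spectrum R of the leaf.

## Continuous wavelet transform

Each spectrum f(λ) is projected onto dilated/translated copies of the sym2
mother wavelet,

    W_f(a, b) = Σ_λ f(λ) · a^(−1/2) ψ((λ − b)/a),

at the dyadic scales a = 2¹ … 2¹⁰ ("CWT-1" … "CWT-10"), giving a 10 × 106
coefficient matrix per leaf. Numerical choices:

* λ is the band **index** (Δ = 1). On a uniform grid this is equivalent to
  nm up to a relabeling of scale, and coefficients are indexed by band.
* ψ is sampled once by cascade refinement (`pywt.Wavelet("sym2").wavefun`,
  level 12 → 2¹² points over the support), recentred on the midpoint of its
  support so the transform is (discretely) shift-covariant, and linearly
  interpolated at each scale's sample points.
* Boundaries use symmetric (mirror) extension. Zero padding would create
  edge ramps that masquerade as red-edge features.
* The implementation is checked against a literal brute-force evaluation of
  the discretized integral at every scale (1e-8 relative).

The scale-by-wavelength **correlation map** holds |Pearson r| between each
coefficient and LKC across the leaves of a stage; zero-variance coefficient
columns are set to 0 and flagged.

**Coefficient images.** For a characteristic wavelength, the per-pixel CWT
coefficient at the nearest band is min–max scaled over the leaf mask to
0–255 (background 0). Min–max is per image — each leaf uses the full dynamic
range — which also makes the images invariant to global gain. A raw-band
mode (`raw_band=True`) scales the reflectance band itself instead; the
coefficient mode is the default. Note that at small scales (CWT-1/2) the
spectral-axis kernel spans few bands, so per-band sensor noise can dominate
the coefficient field; texture links are better resolved at mid/high scales
or in raw-band mode.

## Variable selection

Both selectors score subsets by RMSECV of a PLS regression with 5-fold
cross-validation. The fold partition is drawn once per selection run
(seeded shuffle) and reused for every candidate subset, so comparisons are
paired. The latent-variable count inside selection is fixed at
min(10, |subset|, n − ⌈n/5⌉ − 1). The inner fits use a small NIPALS PLS1
core; the public modeling API uses scikit-learn's PLSRegression, and the two
are cross-checked in the tests.

**CARS** (50 Monte Carlo runs): per run, fit PLS on a random 80% row subset
(the subsampling fraction is standard practice; the source does not state
it), rank the current variables by |regression coefficient|, apply the
enforced exponentially decreasing retention schedule

    r_i = a e^(−k i),  r_1 = 1,  r_N = 2/p
    ⇒ a = (p/2)^(1/(N−1)),  k = ln(p/2)/(N−1),

keeping the top ⌈r_i·p⌉ variables, then adaptively resample (⌈r_i·p⌉
weighted draws with replacement ∝ |coefficient|, unique survivors). The
subset with the lowest RMSECV across runs wins; run 1 evaluates the full
variable set, so the winner can never be worse than no selection.

**Random frog** (10,000 iterations): a working subset of nominal size Q = 5
walks through subset space; candidate sizes are drawn as round(|N(Q, 0.3Q)|)
clipped to [1, p]; shrinking keeps the top variables of the current subset
by |PLS coefficient|, growing adds uniform draws from the complement, and
with probability 1/2 one member is swapped for an outside variable. A
candidate is accepted when its RMSECV improves, else with probability
0.1 · (current/candidate RMSECV). The selection probability of a variable is
the fraction of iterations whose working subset contains it; variables at or
above a stage threshold (defaults 0.40 / 0.21 / 0.23 for budding / flowering
/ boll) are selected. The walk internals are a reconstruction of the cited
algorithm — the source describes it only qualitatively — and all knobs
(Q, η = 0.1, proposal spread) are configurable.

Selections are capped at 10 variables (by |coefficient| for CARS, by
probability for random frog); exact ties at the cap break toward the lower
variable index, as do all other ties in the package.

## Image features

**Texture.** Gray-level co-occurrence matrices at 256 levels, step 1, angles
0°/45°/90°/135°, counting only pixel pairs with *both* members inside the
leaf mask, symmetrized and normalized. Statistics per angle: energy
ENE = ΣΣP², entropy ENT = −ΣΣP ln P (0·ln 0 := 0), contrast
CON = ΣΣP(i−j)², correlation COR = ΣΣP(i−μᵢ)(j−μⱼ)/√(σᵢ²σⱼ²). Two printed
formulas were normalized to their standard forms: the contrast kernel is
(i−j)² (the only reading for which a constant image has zero contrast), and
the correlation denominator carries the square root so COR ∈ [−1, 1]. With
the mean and population variance of each statistic across the four angles,
each image yields 24 = 4×4 + 8 texture features, named
`641 nm-CON-135°`, `594 nm-MEA (CON)`, etc.

**Color.** First three moments of the masked gray-level distribution (single
channel): mean MEA, spread VAR as the root-mean-square deviation, and
asymmetry SKE as the signed cube root of the third central moment — the
standard color-moment definitions — 3 features per image (`532 nm-VAR`,
…).

**Screening.** Features significantly correlated with LKC (Pearson,
p < 0.05) survive stage 1; CARS picks the final set among survivors. An
empty survivor set degrades fusion to spectra-only and is flagged.

## Modeling

The 2:1 **concentration-gradient split** sorts samples by K and sends the
middle of each consecutive block of three to validation (60 → 40/20); the
global K extremes are forced into calibration, so the calibration range
always covers the validation range. The block rule is our reconstruction of
the cited method, chosen because it reproduces both documented outcomes
(exact 2:1 ratio; calibration spans the data).

PLSR is mean-centered without unit-variance scaling (reflectance,
coefficients and 8-bit image features share comparable ranges; switchable).
The latent count minimizes 5-fold RMSECV, capped at
min(10, p, n − ⌈n/5⌉ − 1). Metrics are the population forms

    R² = 1 − Σ(yᵢ − ŷᵢ)² / Σ(yᵢ − ȳ)²,   RMSE = √(Σ(yᵢ − ŷᵢ)²/n),

computed on the designated set only. The comparison harness fits the raw
spectrum R plus every CWT scale per selector, picks the best row by highest
validation R² (ties: lower validation RMSE, then fewer features), and then
fits the four fusion combinations {spectra, +color, +texture,
+color+texture} on that best feature set. Best scales are recomputed per
dataset, never hard-coded.

## The synthetic scene generator

`simulate` emulates the acquisition: one five-lobed leaf (randomized polar
polygon — non-convex, so masked texture statistics are genuinely exercised)
on a dark plate (reflectance 0.12) with a gray panel (0.60), 128 bands,
DN = reflectance · 3000 + 100 + N(0, 8). The deterministic leaf spectrum has
chlorophyll absorption dips at 450/680 nm, a green peak at 550 nm, a red
edge over 690–760 nm, and an NIR plateau whose height decreases linearly in
K (slope 0.04 reflectance units per % K around a pivot of 1.3%). Three
linear K links carry the signal:

| link | default | meaning |
| --- | --- | --- |
| NIR plateau slope | 0.04 /% | K deficiency raises VIS/NIR reflectance |
| speckle amplitude slope | 0.03 /% (base 0.08) | K deficiency roughens texture |
| brightness slope | 0.02 /% | K deficiency brightens the leaf |

plus per-leaf plateau jitter (sd 0.015) and a smooth within-leaf field
(relative sd 0.04). Per-stage K is drawn from a truncated normal on the
stage's [min, max] whose parent parameters are moment-matched so the
*truncated* distribution has the stage's published mean and sd (naive
truncation of N(mean, sd) would bias both; the boll stage's sd of 0.56 on
[0.40, 2.30] slightly exceeds the truncated-normal supremum ≈ 0.548, so that
stage is matched in least squares). Campaigns default to 3 stages × 60
leaves = 180 samples; scenes default to 192×192 pixels for desk-scale runs
(the full 692×520 frame is available by config). Everything is reproducible
byte-for-byte from (config, seed); scenes are re-rendered on demand from
per-sample seeds rather than held in memory.

The linear-link form is a stand-in, not an inference about cotton
physiology: the true K→reflectance functional form is unknown. The generator
also omits radiative-transfer realism (PROSPECT-class optics), line-spread
functions and illumination geometry. Consequently, passing recovery tests
shows that the *pipeline* recovers signal structured the way the analysis
assumes — it does not validate the biology, and real-data performance may
differ.

## Synthetic experiment design and problem sizes

The statistical test and acceptance experiments use these sizes, chosen to
keep a desk run short while leaving enough samples for stable statistics:

* **Selector recovery:** y = 2x₄₀ + x₇₀ + noise (σ = 10% of signal sd),
  n = 60, p = 106; both selectors must include both planted variables in
  ≥ 90% of 20 seeds.
* **Full-pipeline recovery:** noiseless scenes (every stochastic amplitude
  zero), 60 leaves, 96×96 pixels, CARS, scales {1, 3, 9}; validation
  R² ≥ 0.99 (observed: 1.0 to machine precision).
* **Fusion-effect structure:** 96×96 scenes, 60 leaves, CARS, scales
  {1, 3, 9}. *Texture-driven* campaigns raise the per-leaf plateau jitter to
  0.045 so biological variability dominates the spectral K signal while the
  speckle link stays at its default; "+texture" fusion must beat spectra-only
  validation R² in ≥ 70% of 10 seeds. *Spectra-only* campaigns switch the
  speckle and brightness links off; fusion must not materially improve
  (mean gain < 0.05).

Structural checks (106 bands, 24+3 features, 40/20 split, 180 samples,
≤ 10 characteristic wavelengths) run at the defaults.

## Known limitations

* The published per-stage headline metrics were computed on the field
  dataset, which is not deposited; they are not reproducible here and are
  not targets of the synthetic experiments.
* Random-frog internals and the concentration-gradient block rule are
  reconstructions of algorithms the source cites but does not specify;
  both are documented above and configurable.
* GLCM symmetrization is assumed (standard, configurable in effect through
  the matrix itself); whether the original analysis symmetrized is unstated.
* Small-scale coefficient images are sensor-noise limited (see above);
  image-feature screening will then discard them, which mirrors the
  degraded-fusion path rather than failing.
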