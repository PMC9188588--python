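# Methods

## Camera model

A camera is described per pixel `k` by baseline `BL_k` (ADU), dark current
`DC_k` (electrons/s), read noise `RN_k` (electrons, std dev), gain `g_k`
(ADU/electron) and flatfield `F_k` (relative photon sensitivity, mean ≈ 1).
A frame at exposure time `t` with expected incident photoelectron map `p`
(zero for dark frames) is simulated as

```
ADU_k = clip(round(BL_k + g_k · (Poisson(F_k·p_k + DC_k·t) + Normal(0, RN_k))),
             0, 2^bit_depth − 1)
```

Key modelling commitments:

* **Thermal noise is not a free parameter.** Thermal electron counts are
  Poisson, so the thermal-noise variance per second in electron units *is*
  the dark-current rate (`TN² ≡ DC`). The simulator never carries an
  independent `TN`; the calibration estimates `TN²` from a separate fit
  and the agreement of the two estimates is a self-consistency diagnostic
  (it holds to within ~5% on the standard fixtures, and the test suite
  checks it).
* **Read noise is Gaussian in the simulator** even though the fitting side
  treats it through a Poisson-style variance shift. Keeping the physical
  model and the inference approximation separate lets the tests measure
  what the approximation costs (empirically: nothing measurable at the
  photon counts used here).
* **Quantization and clipping are modelled.** Rounding adds ≈ 1/12 ADU²
  of variance, and below ~5 thermal electrons it genuinely distorts
  per-pixel variances (by up to ~20% at λ ≈ 2 e⁻ with gain ≈ 2); default
  baselines ≥ 100 ADU keep zero-clipping negligible, and saturation only
  matters in deliberately overexposed tests. Because the calibration's
  *predictions* are compared against *measurements* that pass through the
  same quantization, these effects largely cancel in the validation
  experiments.
* **Hot pixels are dark-current defects.** The synthetic camera plants
  `round(fraction · n_pixels)` pixels with dark current ≥ 10× the median
  (uniform multiplier in [10, 30]); an optional flag also triples their
  read noise, but by default defects are dark-current-dominated, which is
  what makes their offset and noise grow strongly with exposure time.

Synthetic-camera defaults (a 64×64 "standard fixture" with 1% hot pixels)
are chosen to look like an uncooled industry-grade sensor: baseline
100 ± 4 ADU varying smoothly over the chip, log-normal dark current with
median 28 e⁻/s (log-σ 0.45), read noise 1.5 ± 0.25 e⁻, gain 2.0 ± 0.05
ADU/e⁻, flatfield within ±2% (smooth field). The fixture generator is
seeded and versioned, so every experiment is reproducible from
(configuration, seed). What the generator does **not** emulate: rolling
shutter timing, temperature drift within or across acquisitions, pixel
crosstalk, and response nonlinearity. Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to those effects on real hardware.

## Photon-free calibration

Per-pixel means and unbiased (n−1) variances are accumulated streaming
(shifted-sum accumulation with the first frame as shift, so only one chunk
of frames is ever resident and the cancellation error stays ~9 orders of
magnitude below the signal). Three closed-form two-parameter OLS fits per
pixel, vectorized over the pixel grid (no iterative solver — the model is
exactly linear):

1. mean vs `t` → baseline (intercept), dark current in ADU/s (slope);
2. variance vs `t` → read noise² in ADU² (intercept), thermal noise² in
   ADU²/s (slope);
3. variance vs mean → gain (slope; the intercept is left free because read
   noise contributes a t-independent variance floor).

Numerical and statistical choices:

* **Negative fitted intercepts are retained** in the calibration result
  (flooring them would bias downstream aggregates) and flagged in the
  diagnostics; they are floored at zero only when materializing the
  variance map.
* **Gain degeneracy.** A pixel whose mean spans less than 5 standard
  errors of the mean across exposure times (e.g. zero dark current) has an
  ill-conditioned gain design; its gain is NaN and excluded from the
  median. The global gain is the median of valid per-pixel gains because
  single-pixel gain estimates in the few-electron regime are noisy.
* **Units.** All fitted maps are stored in the ADU domain; electron-domain
  views divide by the global median gain on demand. Exposure times are
  seconds internally; file interfaces carry explicit "ms"/"s" unit keys.
* **Flatfield.** From one (averaged) bright frame: offset-subtract, divide
  by a Gaussian-smoothed version of itself (σ = short image dimension / 8)
  to absorb the illumination profile, normalize to median 1. The smoothing
  scale is a free choice; edge effects of the smoothing reach ~2% within
  one σ of the border on strong illumination gradients. Without a bright
  frame the flatfield is identity and the photon response is uniform at
  the median gain.
* **Traditional comparison method.** The varying-light-level
  characterization at fixed `t` is implemented as the baseline to compare
  against: offset/variance from the darkness stack (hence including the
  thermal contribution at that `t`), gain from variance-vs-mean across
  light levels.

Derived maps at exposure time `t`: `offset = BL + DC_adu·t`,
`variance = max(0, RN²_adu + TN²_adu·t)`,
`photon_response = median_gain · flatfield`.

## SMLM engine

PSFs are integrated Gaussians (difference of error functions per axis over
unit pixels). The astigmatic 3D model uses
`σ_x,y(z) = σ0·sqrt(1 + u² + A·u³ + B·u⁴)` with `u = (z ∓ γ)/d`; defaults
σ0 = 130 nm, γ = 250 nm, d = 400 nm, A = B = 0 give mirror-symmetric
widths crossing at z = 0 with a usable range of roughly ±400 nm. The
projected pixel width defaults to 98 nm. This parametric form stands in
for bead-derived experimental PSF models, which are out of scope; the
astigmatism physics (z encoded in ellipticity) is preserved. Coordinates:
pixels are unit squares in a 0-based frame, pixel centers at
half-integers; x runs along columns, y along rows; a mirror-symmetry
regression test pins the convention.

Fitting converts ADU to photoelectrons with the maps
(`e_k = (ADU_k − offset_k)/pr_k`, `v_k = variance_k/pr_k²`) and maximizes
the variance-shifted Poisson likelihood `Σ d_k·ln m_k − m_k` with
`d_k = e_k + v_k` and `m_k(θ) = N·E_k(θ) + bg + v_k` over
`θ = (x, y[, z], N, bg)`. Because `offset(t)` contains `DC·t` and
`variance(t)` contains `TN²·t`, the dark current's mean is removed and its
Poisson variance is counted — this is the exposure-time-specific
treatment, and a dedicated experiment shows that maps evaluated at the
wrong exposure time leave residual hot-pixel bias that correct-time maps
remove. The "uncorrected" reference fitter substitutes field-average
scalar offset, variance and photon response for the per-pixel maps.

Optimizer: Levenberg–Marquardt on the Fisher-scoring normal equations with
analytic gradients, vectorized over batches of ROIs (this is what keeps
1,000-repeat-per-position studies at seconds per position). Max 50
iterations; convergence when the accepted step is below 1e-4 px in
position, 1e-2 nm in z, 1e-2 photons in N, 1e-3 in background; damping
λ×8 on rejection, λ/3 on acceptance; λ > 1e9 flags the fit
non-convergent (reported, never raised). Initialization: background from
the 25% intensity quantile, photons from the background-subtracted sum,
position from the centroid, z = 0. Offset-subtracted data may be
negative; the model (not the data) is floored at 1e-6 inside the
logarithm. v is floored at 0.

CRLB: Fisher matrix `I_ij = Σ_k (∂μ_k/∂θ_i)(∂μ_k/∂θ_j)/(μ_k + v_k)` with
the same analytic derivatives (validated against finite differences to
1e-4); position rows are expressed per nm. Near-singularity is detected on
the diagonally-normalized matrix (eigenvalue ratio < 1e-12) so that the
mixed parameter units cannot masquerade as degeneracy, and the degenerate
parameter is named in the error.

Modality presets carry the mean photon counts per emitter and frame
(PALM 3,420 / STORM 9,000 / DNA-PAINT 35,100 for a scientific-grade
camera; 1,900 / 5,000 / 19,500 for an industry-grade one) and single-frame
exposure times 50/50/500 ms. Background levels are not part of the
presets' source parameterization; the defaults here are 10/30/50
photoelectrons/pixel/frame (PALM/STORM/PAINT), exposed as a parameter.
Bias/RMSE experiments place one emitter on the center of each grid pixel,
simulate 1,000 repeats by default (fixed photon count for RMSE studies; a
photon-count sampler can be supplied instead), fit corrected and
uncorrected, and report per-axis bias (mean estimate minus truth), RMSE
and sqrt-CRLB in nm.

## Validation experiments and problem sizes

* **Hold-out map validation** (standard fixture, five calibration times
  1–500 ms × 8,000 frames, held-out 30 and 200 ms × 8,000 frames):
  prediction errors are averaged over pixels within each held-out time,
  then over times (the averaging order is a choice; per-time values are
  also reported). An analytic mode feeds exact model moments through the
  same code path and must give zero error — a self-consistency oracle.
* **Gain comparison**: five light levels (0, 200, 500, 1,000, 2,000
  photoelectrons/pixel) at 10 ms, 5,000 frames per level.
* **Bias/CRLB restoration**: 8×8 grid of emitter positions around a
  planted 100×-median hot pixel on a 36×36 camera, 1,000 repeats per
  position, all three modality presets.
* Frame counts (8,000; light stacks 5,000; 3,000 for unit-level recovery
  checks) and grid sizes are the package's desk-scale choices: large
  enough that estimator noise sits well below the effects being measured,
  small enough to run on one CPU in minutes.

## Known limitations

* Gain scatter between pixels (±2.5%) is absorbed into the photoelectron
  conversion via the global median gain; for cameras with strong gain
  nonuniformity the flatfield map is the intended carrier of that
  variation and a bright frame should be supplied.
* The likelihood treats read+thermal noise by the variance-shift
  approximation; at very low photon counts (≪100) the approximation cost
  grows and has not been characterized here.
* No drift model: real cameras show slow parameter drift over long time
  scales; calibrations should be refreshed accordingly.
* The camera response is assumed linear; nonlinearity is neither modelled
  nor corrected.
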