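# Methods

This note records the models implemented in `ricewave`, the parameter
choices that matter, the numerical decisions taken where the design was
genuinely open, and what the synthetic-data tests do and do not establish.

## Rician bias and its closed-form inverse

Magnitude MR pixels follow a Rice distribution
p(μ | A) = (μ/σ²) e^{−(μ²+A²)/2σ²} I₀(Aμ/σ²). Writing x = A/σ and
z = m/σ for the normalized true amplitude and noisy mean, the mean-ratio
function v links them (see README for the formula). Properties used
throughout:

* v(0) = √(π/2) (the Rayleigh mean over σ); v is strictly increasing with
  v′(0) = 0; v(x) = x + 1/(2x) + O(x⁻³) for large x, so the asymptotic
  slope is exactly 1.
* v′ collapses, via I₀′ = I₁ and I₁′(t) = I₀(t) − I₁(t)/t, to
  v′(x) = √(π/2)·(x/2)·e^{−x²/4}[I₀ + I₁](x²/4). The module also ships the
  equivalent all-positive power series (terms x^{4k+1}/(2·64^k (k!)²) and
  x^{4k+3}/(16(k+1)·64^k (k!)²)), truncated when a term falls below 1e−16
  of the partial sum; the two routes cross-check each other in the tests.
* Products e^{−t} I_k(t) are evaluated with exponentially scaled Bessel
  functions (`scipy.special.ive`) — naive evaluation overflows for
  x ≳ 38. `ive` itself degrades above t ≈ 1e9, so beyond t = 1e8 the
  uniform asymptotic expansion (2πt)^{−1/2}[1 − (4k²−1)/(8t) + …] is used;
  at the switch point its truncation error is far below double precision.

The inverse is approximated by F(z) = √(a z² + b + c e^{d z}) with a > 0
and b, c, d < 0, fitted by Levenberg–Marquardt least squares
(tolerances 1e−15) of x_j against F(v(x_j)) on x_j = 0.1·j, j = 1..500,
from the initial point (1, −1, −2, −1). The fit is convex enough that the
optimum is a fixed point of refitting; the maximum grid residual of the
converged fit is ≈ 9·10⁻⁴, comfortably below the 0.05 round-trip bound
the tests assert. The radicand has a unique positive root z₀ (the radicand
is strictly increasing, negative at 0), located by Brent's method to
|residual| < 1e−10.

Evaluation of the inverse is piecewise:

* z < z₀ → 0. F is imaginary there; a normalized mean below the
  pure-noise mean √(π/2) is best explained by zero amplitude.
* z₀ ≤ z ≤ v(50) → F(z). The fit covers x ≤ 50, i.e. SNR up to
  20 log₁₀ 50 ≈ 34 dB.
* z > v(50) → H⁻¹(z) = √(z² − π/2), the exact inverse of the asymptote
  H(x) = √(x² + v(0)²) with unit slope. The jump at the seam is ≈ 0.02 in
  x-units at x = 50 and irrelevant in practice (coefficients that far into
  the high-SNR regime are barely biased).

## The denoising pipeline

Eight steps (see `wavelet_filter.denoise`); the defaults are

| parameter | default | meaning |
|---|---|---|
| `haar_level` | 3 | Haar stage depth; scaling coefficients are 8×8-block means ×8 |
| `daub_level` | 4 | Daubechies-4-vanishing-moments stage depth |
| `rho_d` | 5 | bilateral spatial scale, in scaling-coefficient pixels |
| `rho_r_factor` | 1.5 | bilateral range scale = 1.5·σ̃, in coefficient units |
| `bilateral_window` | 15 | bilateral neighborhood (15×15) |
| `tau` | 2 | Wiener threshold factor; σ*² = τσ² |
| `wiener_window` | 5 | window for the local second moment E[d²] |
| `background_patch` | 16×16 at (0,0) | pure-background region for σ̃ |

σ̃ is estimated from the background patch as
√(Σ I²/(2 q₁q₂)) — the Rayleigh second moment E[I²] = 2σ² at zero signal.
Because both 2-D transforms are orthonormal, white noise of standard
deviation σ in the image keeps standard deviation σ per coefficient at
every level, so the same σ̃ serves the bias map (through
z = c/(σ̃·2^L)), the bilateral range scale, and the Wiener threshold; no
re-estimation happens after the provisional reconstruction (whether the
original procedure re-estimates is unknowable from its description; one σ̃
keeps the pipeline a single deterministic function of the input).

Open choices resolved here:

* **Boundary policy.** Transforms run in periodization mode so coefficient
  grids halve exactly per level and reconstruction is exact to 1e−10; the
  image is reflect-padded once to a multiple of 2⁴ = 16 and cropped back
  at the end. This also preserves the block-mean identity of Haar scaling
  coefficients on aligned images, which the bias map relies on.
* **E[d²] estimator.** Eq.-level sources leave the second-moment estimate
  of the empirical Wiener weight unspecified; here it is the per-coefficient
  mean square over a 5×5 window within the same subband (reflect borders),
  the usual local-empirical-Wiener choice. The window is a config knob.
* **Negative z.** Scaling coefficients of a nonnegative image are
  nonnegative for Haar, but padding/rounding can produce tiny negatives;
  they are clamped to 0 before the bias map (which sends them to 0 anyway).
* **Output clip.** Magnitude data are nonnegative; the final image is
  clipped at 0.
* **σ̃ = 0 short-circuit.** With an exactly zero background patch the
  bias, bilateral and shrinkage stages are inactive; the pipeline is then
  the identity up to transform round-off, which the tests assert at 1e−6
  RMSE.

The bilateral filter renormalizes its weights over the in-bounds part of
the neighborhood, so borders get genuine convex combinations rather than
zero-padded bleed-in. Its output is bounded by the input range — a
property test.

## Quality metrics

SNR, PSNR, RMSE, MAE are the standard definitions (PSNR's peak is the
reference maximum). SSIM is computed per region with population moments
and stabilizers c₁ = 0.01·255 = 2.55, c₂ = 0.03·255 = 7.65, then averaged
over the partition. The partition itself is a free choice; the default is
non-overlapping 8×8 blocks with partial edge blocks included, and SSIM
values should always be reported together with the scheme. This is a
block-average SSIM, deliberately not the sliding-Gaussian-window variant
common elsewhere; the two are not comparable numerically.

## Phantom and noise simulation

The default phantom is a deterministic 128×128 piecewise-constant image of
nested shapes at gray levels {10, 22, 44, 66, 88} on a zero background —
at least four distinct tissue-like levels spanning the [0, 88] intensity
range — with all-zero corners so a 16×16 background patch is always
available. Rician noise is generated exactly as it arises physically:
J_e = √((J + e₁)² + e₂²) with e₁, e₂ ~ N(0, σ²) i.i.d. per pixel. The
validation experiments use σ ∈ {1, 2, 5, 8, 12} with 10 seeded
realizations per level; all substreams derive from one root seed through
`numpy.random.SeedSequence` spawn keys, so every experiment is
bit-reproducible and parallelizable.

What the phantom does **not** emulate: anatomical texture, partial-volume
gradients, spatially varying coil sensitivity, or correlated noise.
Passing the direction-of-improvement tests (both filter variants improve
all five metrics for σ ≥ 2; the bilateral variant's mean SSIM dominates at
σ ∈ {5, 8, 12}) therefore establishes the ordering of the methods under
piecewise-constant conditions, not the magnitude of the improvement to be
expected on clinical images. At σ = 1 the two variants are nearly
indistinguishable and improvement at that level is not asserted.

## Prony relaxometry

Echo curves y_i = b + Σ C_j e^{−iλ_jΔt} are fitted per pixel with
Δt = 0.044 s and n = 8 echoes (so k ≤ 3 satisfies n ≥ 2k + 1). The
baseline is one more geometric mode whose ratio is *known* to be 1, and
that knowledge is imposed structurally: first-differencing the echoes
divides the characteristic polynomial by (ρ − 1) exactly, after which an
order-k linear-prediction system on the differenced signal yields the
decay ratios as polynomial roots, and b, C_j follow by linear least
squares on [1, ρ_j^i]. The alternative — estimating all k+1 roots and
labelling the one nearest 1 as the baseline — was tried first and
discarded: with b small relative to the amplitudes the ρ = 1 root is
nearly undetermined, noise sends it far from 1, and the labelling rule
then mislabels the genuine decay root as baseline, invalidating pixels
whose decay was in fact recovered well (in a two-region test at σ = 0.5
only ~11 % of pixels survived; the constrained form recovers the large
majority).

A fit is invalid when any root is materially complex
(|Im ρ| > 1e−8·|ρ|), ≤ 0, or > 1 + 1e−9; both tolerances are module
constants. Model selection runs k = 1..3 and keeps the valid fit with the
smallest ℓ₂ echo-domain residual; a larger k wins only by improving the
residual beyond a margin of 1e−9·(1 + ‖y‖), so already-perfect fits
resolve to the simplest order. Pixels with no valid order are flagged
no-fit and excluded from histograms.

The relaxation histogram divides [0, 30] s⁻¹ (the brain-tissue range)
into 100 bins of width 0.3. Each component with C > 0 and λ in range adds
C to its bin (half-open bins, last closed); everything else accumulates in
`discarded_mass`, so retained + discarded equals the total fitted
amplitude mass exactly — a conservation test. Amplitudes enter as-is, not
normalized per pixel: the density is then a tissue-fraction-weighted
distribution, which keeps bright and dark pixels comparable in the units
the decay model defines. The density integrates to 1.

The dispersion benchmark builds a 64×64 two-compartment stack (rates
4 s⁻¹ and 14 s⁻¹, amplitudes 40, baseline 2 inside tissue, zero
background) at σ = 2, and measures the rms spread of the rate histogram
about its mean with and without denoising each echo first, over 20 seeded
replicates. Problem sizes (64×64 stacks, 128×128 single images, 10–20
replicates) were chosen so the entire suite runs in well under a minute
per experiment while keeping the Monte-Carlo margins (3 standard errors)
meaningful.

## Known limitations

* The filter is strictly 2-D and single-image; no volumetric or
  cycle-spinning variants.
* Prony fitting is per pixel with no spatial regularization; at high noise
  many pixels are legitimately flagged no-fit rather than forced into a
  model.
* The bias inverse is an approximation with ≈ 1e−3 worst-case grid
  residual; applications needing exact inversion of v should solve
  v(x) = z numerically instead.
* 16-bit image interchange quantizes intensities to (max−min)/65535;
  exact-value work should use the text formats.
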