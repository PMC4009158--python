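# ricewave

Wavelet-domain bilateral denoising of Rician-noise magnitude MR images,
with the image-quality metrics to validate it and a Prony-type
multi-exponential T2-relaxometry pipeline for tissue classification.

## The problem

The gray value of a magnitude MR image is the modulus of a complex signal
whose real and imaginary parts carry independent Gaussian noise of equal
standard deviation σ. The magnitude therefore follows a **Rice
distribution**: its mean *m* overestimates the true amplitude *A*, most
severely at low signal-to-noise. With x = A/σ and z = m/σ the two are
linked by the mean-ratio function

    v(x) = √(π/2) · [(1 + x²/2) I₀(x²/4) + (x²/2) I₁(x²/4)] · e^(−x²/4),

where I₀, I₁ are modified Bessel functions. Debiasing means inverting v.
`ricewave` evaluates v stably to arbitrary SNR, and fits the closed-form
inverse approximation

    F(z) = √(a z² + b + c e^(d z)),   a > 0,  b, c, d < 0,

by nonlinear least squares on the grid x_j = 0.1·j, j = 1..500. The fitted
constants are a = 1.0000108, b = −1.0122372, c = −2.7102422,
d = −1.2598921; F vanishes at its unique positive root z₀ ≈ 1.2534 (just
above the pure-noise mean √(π/2)) and covers amplitudes up to x = 50
(about 34 dB), beyond which the asymptotic inverse
H⁻¹(z) = √(z² − π/2) takes over.

The **denoising filter** applies this inverse where it does the most good:
to the level-3 Haar scaling coefficients, which for the Haar basis are
exactly scaled block means and hence local estimates of the Rician mean.
An edge-preserving bilateral filter then smooths the debiased scaling
array, the image is rebuilt, and a second pass (Daubechies with four
vanishing moments, level 4) shrinks the detail coefficients with an
empirical Wiener weight α = (E[d²] − 2σ²)₊ / E[d²]. Switching the
bilateral stage off reproduces the plain bias-correction filter for
comparison.

Denoising matters downstream: per-pixel fitting of multi-echo T2 decays

    y_i = b + Σ_j C_j e^(−i λ_j Δt),   i = 1..n,   n ≥ 2k + 1,

by Prony's method (linear prediction → polynomial roots → rates
λ_j = −ln ρ_j / Δt) is notoriously ill-conditioned, and the
amplitude-weighted histogram of fitted relaxation rates over [0, 30] s⁻¹ —
the tissue-classification fingerprint — sharpens visibly when each echo is
filtered first. `ricewave` ships the fitter (model order selected over
k = 1..3 by residual), the histogram, and a seeded phantom/noise/multi-echo
simulator so the whole chain runs without external data.

## Worked example

```python
import ricewave as rw

img   = rw.make_phantom(rw.default_phantom_spec())      # 128×128, values 0..88
noisy = rw.add_rician_noise(img, 5.0, seed=42)
den   = rw.denoise(noisy)                                # full pipeline

for name, im in (("noisy", noisy), ("denoised", den)):
    r = rw.report(img, im)
    print(f"{name:9s} SNR {r.snr_db:6.2f} dB  PSNR {r.psnr_db:6.2f} dB  "
          f"RMSE {r.rmse:5.2f}  MAE {r.mae:5.2f}  SSIM {r.ssim:.4f}")
```

prints

```
noisy     SNR  12.41 dB  PSNR  22.98 dB  RMSE  6.25  MAE  5.25  SSIM 0.3433
denoised  SNR  18.43 dB  PSNR  29.00 dB  RMSE  3.12  MAE  1.97  SSIM 0.7517
```

The filter estimated σ̃ ≈ 5.12 from the phantom's all-zero corner patch
(true σ = 5), roughly halved the RMS error and doubled the structural
similarity. The same pipeline is available from the shell:

```bash
ricewave simulate noise --sigma 5 --seed 42 --out noisy.csv
ricewave denoise --input noisy.csv --output den.csv --patch 0,0,16,16
ricewave evaluate --reference clean.csv --test noisy.csv den.csv
ricewave compare --replicates 10 --out table.csv   # both variants, σ = 1..12
ricewave relaxometry --echoes e1.csv ... e8.csv --dt 0.044 --denoise --out hist.csv
```

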