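"""Reference-based image quality measures: SNR, PSNR, RMSE, MAE and SSIM.

All five compare a test image against a noise-free reference.  SNR and PSNR
are reported in decibels; identical images yield ``inf``.  SSIM is computed
region-wise (population moments within each region, stabilizing constants
c1 = 0.01*255 = 2.55 and c2 = 0.03*255 = 7.65 for 8-bit-range intensities)
and averaged over a partition of the image; the default partition is
non-overlapping 8x8 blocks with partial edge blocks included.  The partition
is a genuine free choice and should be reported alongside SSIM values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricReport", "snr", "psnr", "rmse", "mae", "ssim", "report"]

SSIM_C1 = 0.01 * 255  # 2.55
SSIM_C2 = 0.03 * 255  # 7.65


@dataclass(frozen=True)
class MetricReport:
    snr_db: float
    psnr_db: float
    rmse: float
    mae: float
    ssim: float


def _pair(reference, test):
    r = np.asarray(reference, dtype=float)
    t = np.asarray(test, dtype=float)
    if r.shape != t.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {t.shape}")
    if r.ndim != 2:
        raise ValueError("images must be 2-D")
    return r, t


def snr(reference, test) -> float:
    """10 log10( sum r^2 / sum (r - t)^2 ), in dB; inf for identical images."""
    r, t = _pair(reference, test)
    num = float(np.sum(r * r))
    if num == 0.0:
        raise ValueError("reference image is identically zero")
    den = float(np.sum((r - t) ** 2))
    if den == 0.0:
        return float("inf")
    return 10.0 * np.log10(num / den)


def psnr(reference, test) -> float:
    """Peak SNR in dB; the peak is the maximum of the reference image."""
    r, t = _pair(reference, test)
    if not np.any(r):
        raise ValueError("reference image is identically zero")
    den = float(np.sum((r - t) ** 2))
    if den == 0.0:
        return float("inf")
    peak = float(np.max(r))
    return 10.0 * np.log10(r.size * peak * peak / den)


def rmse(reference, test) -> float:
    r, t = _pair(reference, test)
    return float(np.sqrt(np.mean((r - t) ** 2)))


def mae(reference, test) -> float:
    r, t = _pair(reference, test)
    return float(np.mean(np.abs(r - t)))


def _block_slices(shape, block):
    h, w = shape
    bh, bw = block
    for i in range(0, h, bh):
        for j in range(0, w, bw):
            yield np.s_[i : i + bh, j : j + bw]


def ssim(reference, test, block_size=(8, 8)) -> float:
    """Region-averaged structural similarity.

    Per region with means (mu_r, mu_t), population variances (th_r, th_t) and
    covariance th_rt:

        SSIM = (2 mu_r mu_t + c1)(2 th_rt + c2)
               / ((mu_r^2 + mu_t^2 + c1)(th_r + th_t + c2))

    averaged over all regions.  Equals 1 iff the images agree on every
    region.  ``block_size`` sets the partition; regions of fewer than 2
    pixels are rejected.
    """
    r, t = _pair(reference, test)
    vals = []
    for sl in _block_slices(r.shape, block_size):
        rb, tb = r[sl], t[sl]
        if rb.size < 2:
            raise ValueError("SSIM region smaller than 2 pixels")
        mu_r, mu_t = rb.mean(), tb.mean()
        th_r = rb.var()
        th_t = tb.var()
        th_rt = ((rb - mu_r) * (tb - mu_t)).mean()
        num = (2 * mu_r * mu_t + SSIM_C1) * (2 * th_rt + SSIM_C2)
        den = (mu_r**2 + mu_t**2 + SSIM_C1) * (th_r + th_t + SSIM_C2)
        vals.append(num / den)
    return float(np.mean(vals))


def report(reference, test, block_size=(8, 8)) -> MetricReport:
    """All five measures in one record."""
    return MetricReport(
        snr_db=snr(reference, test),
        psnr_db=psnr(reference, test),
        rmse=rmse(reference, test),
        mae=mae(reference, test),
        ssim=ssim(reference, test, block_size=block_size),
    )
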