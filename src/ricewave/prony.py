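"""Prony-type multi-exponential fitting of T2 decay curves and the
relaxation-rate frequency diagram used for tissue classification.

Per pixel, the echo intensities are modeled as

    y_i = b + sum_{j=1..k} C_j rho_j^i,   rho_j = exp(-lambda_j dt),  i = 1..n,

with the baseline b treated as one more geometric mode whose ratio is known
to be exactly rho = 1.  The fit is a Prony scheme of total order k + 1 with
that root constrained: dividing the characteristic polynomial by (rho - 1)
is the same as first-differencing the signal, which annihilates the
constant mode.  Concretely:

(i)   difference the echoes, w_i = y_{i+1} - y_i, and solve the order-k
      linear-prediction (forward recurrence) system for w in least squares;
(ii)  the characteristic polynomial's k roots are the decay ratios rho_j,
      mapping to rates via lambda = -ln(rho) / dt;
(iii) recover b and the amplitudes C_j by linear least squares of the
      undifferenced echoes on the geometric design matrix [1, rho_j^i];
(iv)  flag the fit invalid when any root is materially complex, nonpositive,
      or beyond 1 (growing), since no physical tissue mode corresponds to it.

Constraining the baseline root (rather than estimating it and picking the
root nearest 1 afterwards) matters in practice: when b is small relative to
the decaying amplitudes, the free formulation leaves the constant mode's
root essentially undetermined by the data, and modest noise sends it far
from 1 — the nearest-to-1 rule then mislabels the genuine decay root as the
baseline and invalidates pixels whose decay was in fact recovered well.

The model order k is selected per pixel by fitting k = 1..k_max and keeping
the valid fit with the smallest echo-domain residual, with ties broken
toward the simpler model.  Data length must satisfy n >= 2k + 1.

Rates from a region of pixels are aggregated into a 100-bin histogram over
[0, 30] 1/s, each component weighted by its amplitude; normalizing by the
total weight and the 0.3 1/s bin width yields a probability density of
tissue fractions over relaxation rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import MultiEchoSequence
from .wavelet_filter import FilterConfig, denoise

__all__ = [
    "ExponentialFit",
    "RelaxationHistogram",
    "prony_fit",
    "select_model",
    "relaxation_histogram",
    "classify_regions",
]

RATE_RANGE = (0.0, 30.0)
N_BINS = 100

#: tolerance knobs of the root filter
IMAG_TOL = 1e-8  # |Im rho| <= IMAG_TOL * |rho| counts as real
RHO_MAX_TOL = 1e-9  # rho <= 1 + RHO_MAX_TOL accepted as nongrowing


@dataclass(frozen=True)
class ExponentialFit:
    """Per-pixel multi-exponential solution; ``valid`` is False when the
    root structure is degenerate (complex/nonpositive/growing modes)."""

    k: int
    b: float
    amplitudes: np.ndarray
    rates: np.ndarray
    residual: float
    valid: bool

    @classmethod
    def invalid(cls, k: int) -> "ExponentialFit":
        return cls(
            k=k,
            b=float("nan"),
            amplitudes=np.full(k, np.nan),
            rates=np.full(k, np.nan),
            residual=float("inf"),
            valid=False,
        )


@dataclass(frozen=True)
class RelaxationHistogram:
    """Amplitude-weighted distribution of relaxation rates over [0, 30] 1/s."""

    edges: np.ndarray  # 101 edges, uniform
    weights: np.ndarray  # 100 retained amplitude masses
    density: np.ndarray  # weights normalized to integrate to 1
    discarded_mass: float  # amplitude mass with rate outside range or C <= 0

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


def prony_fit(y, dt: float, k: int) -> ExponentialFit:
    """Fit ``y_i = b + sum_j C_j exp(-i lambda_j dt)`` by the Prony scheme.

    Raises for structurally bad input (too few echoes, bad dt/k); numerical
    degeneracy (singular prediction system, unusable roots) yields an
    invalid fit instead, so per-pixel loops need no exception handling.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n < 2 * k + 1:
        raise ValueError(f"need n >= 2k+1 = {2 * k + 1}, got n = {n}")

    # first difference annihilates the constrained rho = 1 baseline mode
    w = np.diff(y)
    # forward linear prediction of order k: w[i+k] = sum_m a_m w[i+k-m]
    nw = w.size
    A = np.empty((nw - k, k))
    for m in range(k):
        A[:, m] = w[k - 1 - m : nw - 1 - m]
    rhs = w[k:]
    try:
        a, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        roots = np.roots(np.concatenate(([1.0], -a)))
    except np.linalg.LinAlgError:
        return ExponentialFit.invalid(k)

    if roots.size != k:
        return ExponentialFit.invalid(k)
    if np.any(np.abs(roots.imag) > IMAG_TOL * np.maximum(np.abs(roots), 1e-300)):
        return ExponentialFit.invalid(k)
    rho = roots.real
    if np.any(rho <= 0.0) or np.any(rho > 1.0 + RHO_MAX_TOL):
        return ExponentialFit.invalid(k)
    rho = np.minimum(rho, 1.0)
    rates = -np.log(rho) / dt

    # amplitudes: columns [1, rho_1^i, ..., rho_k^i], i = 1..n
    i = np.arange(1, n + 1)[:, None]
    design = np.hstack([np.ones((n, 1)), rho[None, :] ** i])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    model = design @ coef
    resid = float(np.linalg.norm(y - model))
    if not np.all(np.isfinite(coef)):
        return ExponentialFit.invalid(k)
    order = np.argsort(rates)
    return ExponentialFit(
        k=k,
        b=float(coef[0]),
        amplitudes=coef[1:][order],
        rates=rates[order],
        residual=resid,
        valid=True,
    )


def select_model(y, dt: float, k_max: int = 3) -> ExponentialFit:
    """Best valid Prony fit over k = 1..k_max by smallest residual.

    ``k_max`` is reduced to what the data length allows.  A larger model
    replaces a smaller one only when it improves the residual beyond a tiny
    scale-relative margin, so exact ties (already-perfect fits) resolve to
    the simplest model.  If no order yields a valid fit the returned record
    has ``valid=False`` (a no-fit pixel), never an exception.
    """
    y = np.asarray(y, dtype=float).ravel()
    k_cap = min(k_max, (y.size - 1) // 2)
    if k_cap < 1:
        raise ValueError("too few echoes for even a single-exponential fit")
    tie_margin = 1e-9 * (1.0 + float(np.linalg.norm(y)))
    best = ExponentialFit.invalid(1)
    for k in range(1, k_cap + 1):
        fit = prony_fit(y, dt, k)
        if fit.valid and fit.residual < best.residual - tie_margin:
            best = fit
    return best


def relaxation_histogram(fits) -> RelaxationHistogram:
    """Aggregate fitted components into the amplitude-weighted rate histogram.

    For every valid fit, each component with amplitude C > 0 and rate inside
    [0, 30] adds C to the bin containing its rate (half-open bins, last bin
    closed).  Components with nonpositive amplitude or out-of-range rate go
    to ``discarded_mass``, so retained weight + discarded mass equals the
    total fitted amplitude mass exactly.
    """
    lo, hi = RATE_RANGE
    edges = np.linspace(lo, hi, N_BINS + 1)
    width = (hi - lo) / N_BINS
    weights = np.zeros(N_BINS)
    discarded = 0.0
    any_valid = False
    for fit in fits:
        if not fit.valid:
            continue
        any_valid = True
        for c, lam in zip(fit.amplitudes, fit.rates):
            if c > 0 and lo <= lam <= hi:
                idx = min(int((lam - lo) / width), N_BINS - 1)
                weights[idx] += c
            else:
                discarded += c
    total = weights.sum()
    if not any_valid or total <= 0:
        raise ValueError("no retained amplitude mass; histogram undefined")
    density = weights / (total * width)
    return RelaxationHistogram(
        edges=edges, weights=weights, density=density, discarded_mass=discarded
    )


def fit_region(stack: MultiEchoSequence, mask, k_max: int = 3) -> list:
    """Per-pixel model selection over a boolean mask; returns the fits."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.echoes.shape[1:]:
        raise ValueError("mask shape must match the echo images")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty region mask")
    return [
        select_model(stack.echoes[:, r, c], stack.dt, k_max=k_max)
        for r, c in zip(rows, cols)
    ]


def classify_regions(
    stack: MultiEchoSequence,
    masks: dict,
    config: FilterConfig = FilterConfig(),
    denoise_first: bool = True,
    k_max: int = 3,
) -> dict:
    """Relaxation-rate histograms per named region of a multi-echo stack.

    With ``denoise_first`` each echo image is passed through the wavelet
    filter before the per-pixel fits; the histograms then show less
    dispersion around the true tissue rates.
    """
    echoes = stack.echoes
    if denoise_first:
        echoes = np.stack([denoise(e, config) for e in echoes])
        stack = MultiEchoSequence(echoes=echoes, dt=stack.dt)
    return {
        name: relaxation_histogram(fit_region(stack, mask, k_max=k_max))
        for name, mask in masks.items()
    }
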