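"""Synthetic phantoms, Rician noise, and multi-echo T2 relaxation stacks.

Everything the denoising and relaxometry pipelines consume can be generated
here, deterministically from a single integer seed.  The default phantom is a
piecewise-constant image with gray values spanning [0, 88] on a zero
background (the intensity range of the validation images), with a guaranteed
all-zero corner so a background patch is always available for noise
estimation.

Rician noise is produced exactly as it arises in magnitude MRI: the clean
intensity J enters the real channel, independent zero-mean Gaussians of
standard deviation sigma corrupt both channels, and the magnitude is taken:

    J_e = sqrt((J + e1)^2 + e2^2).

Multi-echo stacks follow the mono/multi-exponential T2 decay model

    y_i = b + sum_j C_j exp(-i lambda_j dt),   i = 1..n,

per pixel, with Rician noise added independently to each echo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Primitive",
    "PhantomSpec",
    "TissueMap",
    "MultiEchoSequence",
    "default_phantom_spec",
    "make_phantom",
    "add_rician_noise",
    "make_multiecho_sequence",
]

#: Gray-value range of the validation phantom.
INTENSITY_MAX = 88.0

#: Noise levels used throughout the filter-comparison experiments.
SIGMA_LEVELS = (1.0, 2.0, 5.0, 8.0, 12.0)


@dataclass(frozen=True)
class Primitive:
    """One solid shape; later primitives overwrite earlier ones.

    ``geometry`` is 'disk', 'ellipse' or 'rectangle'.  ``center`` is
    (row, col); ``extent`` is the radius for a disk, (semi_r, semi_c) for an
    ellipse, and (height, width) for a rectangle (centered).
    """

    geometry: Literal["disk", "ellipse", "rectangle"]
    center: tuple[float, float]
    extent: float | tuple[float, float]
    intensity: float


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int]
    primitives: tuple[Primitive, ...] = ()
    background_intensity: float = 0.0


@dataclass(frozen=True)
class TissueMap:
    """Per-pixel exponential components for a multi-echo simulation.

    ``components`` is a sequence of (amplitude_map, rate_map) pairs of 2-D
    arrays; an amplitude of zero switches a component off at that pixel.
    Rates are in 1/s and must lie in [0, 30], the range of brain-tissue
    relaxation rates.  ``baseline`` is the additive background term b.
    """

    baseline: np.ndarray
    components: tuple[tuple[np.ndarray, np.ndarray], ...]

    def __post_init__(self):
        if len(self.components) > 3:
            raise ValueError("at most 3 components per pixel")
        for amp, rate in self.components:
            if amp.shape != self.baseline.shape or rate.shape != self.baseline.shape:
                raise ValueError("component maps must share the baseline's shape")
            if np.any((rate < 0) | (rate > 30)):
                raise ValueError("relaxation rates must lie in [0, 30] 1/s")
            if np.any(amp < 0):
                raise ValueError("amplitudes must be nonnegative")

    def order_map(self) -> np.ndarray:
        """Per-pixel number of active (amplitude > 0) components."""
        k = np.zeros(self.baseline.shape, dtype=int)
        for amp, _ in self.components:
            k += (amp > 0).astype(int)
        return k


@dataclass(frozen=True)
class MultiEchoSequence:
    """Ordered stack of co-registered echoes with spacing dt (seconds)."""

    echoes: np.ndarray  # (n, height, width)
    dt: float

    @property
    def n(self) -> int:
        return self.echoes.shape[0]


def default_phantom_spec(shape: tuple[int, int] = (128, 128)) -> PhantomSpec:
    """Nested-shapes phantom with >= 4 gray levels spanning [0, 88].

    Concentric structures of decreasing size mimic tissue compartments; the
    corners stay at the zero background so a patch such as the top-left
    16 x 16 estimates sigma from pure noise.
    """
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    s = min(h, w)
    prims = (
        Primitive("ellipse", (cy, cx), (0.42 * s, 0.34 * s), 22.0),
        Primitive("disk", (cy, cx), 0.26 * s, 44.0),
        Primitive("rectangle", (cy - 0.08 * s, cx), (0.14 * s, 0.22 * s), 66.0),
        Primitive("disk", (cy + 0.12 * s, cx - 0.06 * s), 0.07 * s, 88.0),
        Primitive("rectangle", (cy + 0.1 * s, cx + 0.14 * s), (0.1 * s, 0.05 * s), 10.0),
    )
    return PhantomSpec(shape=shape, primitives=prims)


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic rasterization of a phantom spec into a float image."""
    vals = [spec.background_intensity] + [p.intensity for p in spec.primitives]
    for v in vals:
        if not 0.0 <= v <= INTENSITY_MAX:
            raise ValueError(f"intensity {v} outside [0, {INTENSITY_MAX}]")
    img = np.full(spec.shape, float(spec.background_intensity))
    rr, cc = np.mgrid[0 : spec.shape[0], 0 : spec.shape[1]].astype(float)
    for p in spec.primitives:
        ry, rx = p.center
        if p.geometry == "disk":
            mask = (rr - ry) ** 2 + (cc - rx) ** 2 <= float(p.extent) ** 2
        elif p.geometry == "ellipse":
            sr, sc = p.extent
            mask = ((rr - ry) / sr) ** 2 + ((cc - rx) / sc) ** 2 <= 1.0
        elif p.geometry == "rectangle":
            hh, ww = p.extent
            mask = (np.abs(rr - ry) <= hh / 2.0) & (np.abs(cc - rx) <= ww / 2.0)
        else:
            raise ValueError(f"unknown geometry {p.geometry!r}")
        img[mask] = p.intensity
    return img


def _rng_stream(seed, *key: int) -> np.random.Generator:
    # counter-based substreams: one root seed, independent children per key
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def add_rician_noise(image, sigma: float, seed) -> np.ndarray:
    """Corrupt an image with Rician noise of parameter sigma.

    Each pixel becomes sqrt((J + e1)^2 + e2^2) with e1, e2 independent
    N(0, sigma^2) draws, reproducible under ``seed`` (an int or a
    ``numpy.random.Generator``).
    """
    img = np.asarray(image, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return img.copy()
    rng = seed if isinstance(seed, np.random.Generator) else _rng_stream(seed)
    e1 = rng.normal(0.0, sigma, img.shape)
    e2 = rng.normal(0.0, sigma, img.shape)
    return np.sqrt((img + e1) ** 2 + e2**2)


def make_multiecho_sequence(
    tissue: TissueMap, dt: float, n: int, sigma: float, seed
) -> MultiEchoSequence:
    """Simulate an n-echo T2 stack from a tissue map.

    Echo i (1-based) has noise-free intensity b + sum_j C_j exp(-i lambda_j dt)
    per pixel; Rician noise of level ``sigma`` is drawn independently per
    echo from seeded substreams, so the stack is bit-reproducible and echoes
    are statistically independent.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    k_max = int(tissue.order_map().max())
    if n < 2 * k_max + 1:
        raise ValueError(f"n={n} too small: need n >= 2k+1 = {2 * k_max + 1}")
    h, w = tissue.baseline.shape
    echoes = np.empty((n, h, w))
    for i in range(1, n + 1):
        clean = tissue.baseline.copy()
        for amp, rate in tissue.components:
            clean = clean + amp * np.exp(-i * rate * dt)
        echoes[i - 1] = add_rician_noise(clean, sigma, _rng_stream(seed, i))
    return MultiEchoSequence(echoes=echoes, dt=dt)
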