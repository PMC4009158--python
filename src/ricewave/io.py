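"""Image and array I/O.

Float images are interchanged as 16-bit grayscale PNG/TIFF with a linear
intensity scaling recorded in a JSON sidecar (``<image>.json``), so the
round trip is lossless to 16-bit quantization; exact-value work should use
the plain-text formats (``.csv``/``.txt`` arrays), which round-trip floats
exactly enough for testing (repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_image", "write_image"]

_TEXT_SUFFIXES = {".csv", ".txt"}


def write_image(path, array) -> None:
    """Write a 2-D float array; format chosen by suffix.

    ``.csv``/``.txt``: plain text, full precision.  ``.png``/``.tif(f)``:
    16-bit grayscale with scale/offset sidecar JSON.
    """
    path = Path(path)
    arr = np.asarray(array, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D array")
    if path.suffix.lower() in _TEXT_SUFFIXES:
        np.savetxt(path, arr, delimiter="," if path.suffix.lower() == ".csv" else " ")
        return
    lo = float(arr.min())
    hi = float(arr.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    quant = np.round((arr - lo) / scale).astype(np.uint16)
    Image.fromarray(quant).save(path)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"offset": lo, "scale": scale})
    )


def read_image(path) -> np.ndarray:
    """Read a 2-D float array written by :func:`write_image`, or any
    grayscale image file (without a sidecar, raw pixel values are used)."""
    path = Path(path)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        delim = "," if path.suffix.lower() == ".csv" else None
        return np.atleast_2d(np.loadtxt(path, delimiter=delim))
    arr = np.asarray(Image.open(path), dtype=float)
    if arr.ndim == 3:  # collapse RGB(A) to luminance-free mean
        arr = arr[..., :3].mean(axis=-1)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        arr = arr * meta["scale"] + meta["offset"]
    return arr
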