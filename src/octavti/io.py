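"""Grayscale PNG reading/writing with the package's [0, 1] convention."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_gray_png", "write_gray_png"]


def read_gray_png(path: str | Path) -> np.ndarray:
    """Read a PNG as a float image in [0, 1] (8- or 16-bit, converted to gray)."""
    with Image.open(path) as im:
        if im.mode == "I;16":
            arr = np.asarray(im, dtype=np.float64) / 65535.0
        else:
            arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
    if arr.size == 0:
        raise ValueError(f"empty image: {path}")
    return arr


def write_gray_png(path: str | Path, image: np.ndarray, bits: int = 16) -> None:
    """Write a float image in [0, 1] as an 8- or 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if bits == 16:
        data = np.round(arr * 65535.0).astype(np.uint16)
        Image.fromarray(data).save(path)
    elif bits == 8:
        data = np.round(arr * 255.0).astype(np.uint8)
        Image.fromarray(data, mode="L").save(path)
    else:
        raise ValueError("bits must be 8 or 16")
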