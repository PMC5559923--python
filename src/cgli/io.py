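"""Raster image I/O: grayscale reading with channel selection, mask writing.

Intensities are rescaled to [0, 1] on read by dividing by the dtype's
maximum (255 for 8-bit, 65535 for 16-bit); float inputs are assumed
already scaled and are clipped.  Masks are written as 8-bit single-channel
PNGs with values {0, 255}.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

__all__ = ["read_image", "write_mask", "read_mask"]

CHANNELS = {"red": 0, "green": 1, "blue": 2}
# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path, channel: str = "gray") -> np.ndarray:
    """Read a raster image as a float64 grayscale array in [0, 1].

    RGB(A) inputs are reduced by ``channel``: one of ``"red"``,
    ``"green"``, ``"blue"`` (a single plane) or ``"gray"`` (BT.601
    luminance).  The green channel is the conventional high-contrast
    choice for fundus vessel work.
    """
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim == 3:
        if arr.shape[-1] not in (3, 4):
            raise ValueError(f"unsupported channel count {arr.shape[-1]}")
        rgb = arr[..., :3].astype(float)
        if channel == "gray":
            arr2 = rgb @ _LUMA
        elif channel in CHANNELS:
            arr2 = rgb[..., CHANNELS[channel]]
        else:
            raise ValueError(f"unknown channel {channel!r}")
        scale = _dtype_scale(arr.dtype)
        return np.clip(arr2 / scale, 0.0, 1.0)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D image data, got shape {arr.shape}")
    return np.clip(arr.astype(float) / _dtype_scale(arr.dtype), 0.0, 1.0)


def _dtype_scale(dtype) -> float:
    dtype = np.dtype(dtype)
    if dtype.kind == "u" or dtype.kind == "i":
        return float(np.iinfo(dtype).max)
    if dtype.kind == "b":
        return 1.0
    return 1.0  # float data assumed pre-scaled


def read_mask(path) -> np.ndarray:
    """Read a single-channel image as a boolean mask (nonzero = positive)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D mask data, got shape {arr.shape}")
    return arr > 0


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit {0, 255} single-channel image."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    iio.imwrite(path, (mask.astype(bool) * np.uint8(255)))
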