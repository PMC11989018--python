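"""Image loading, grayscale conversion, resizing, and fuzzy denoising.

These are the preprocessing steps applied to a histopathology tile before
superpixel segmentation: conversion of the RGB stain image to a grayscale
intensity grid, bilinear resizing to the working resolution (224x224 by
convention), and an adaptive fuzzy filter that suppresses acquisition noise
while preserving nuclear boundaries.

The fuzzy filter is a Gaussian-membership fuzzy-weighted mean: each output
pixel is the weighted average of its window, where a neighbour's weight is
its fuzzy membership ``exp(-(I_n - I_c)^2 / (2 sigma^2))`` in the "similar
to the centre" set.  Neighbours across an edge get near-zero membership, so
edges survive while in-region noise is averaged out.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

__all__ = [
    "load_image",
    "save_gray",
    "to_grayscale",
    "resize",
    "adaptive_fuzzy_filter",
]

# BT.601 luma weights (R, G, B); sum to 1 exactly.
_LUMA = np.array([0.299, 0.587, 0.114])


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG as an RGB uint8 array of shape (H, W, 3)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def save_gray(img: np.ndarray, path) -> None:
    """Write a grayscale image as 8-bit PNG."""
    arr = np.clip(np.asarray(img), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def _check_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D grayscale image, got shape {arr.shape}")
    return arr


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an H×W×3 RGB image to grayscale via BT.601 luma weights.

    Returns a float array in [0, 255] rounded to integral values so that a
    pure channel maps to the familiar quantised luma (e.g. pure red -> 76).
    """
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected 3-channel image, got shape {arr.shape}"
        )
    return np.round(arr @ _LUMA)


def resize(img: np.ndarray, h: int, w: int) -> np.ndarray:
    """Bilinear resize to (h, w); works on 2-D grayscale or H×W×3 color.

    Intensity range is preserved (bilinear interpolation is a convex
    combination of the four surrounding pixels).
    """
    if h < 8 or w < 8:
        raise ValueError("target dimensions must be >= 8")
    arr = np.asarray(img, dtype=float)
    if arr.shape[:2] == (h, w):
        return arr.copy()
    if arr.ndim == 2:
        pil = Image.fromarray(arr.astype(np.float32), mode="F")
        out = np.asarray(pil.resize((w, h), Image.BILINEAR), dtype=float)
    else:
        chans = [
            np.asarray(
                Image.fromarray(arr[..., c].astype(np.float32), mode="F").resize(
                    (w, h), Image.BILINEAR
                ),
                dtype=float,
            )
            for c in range(arr.shape[2])
        ]
        out = np.stack(chans, axis=-1)
    return out


def adaptive_fuzzy_filter(
    img: np.ndarray, window: int = 3, sigma_member: float = 30.0
) -> np.ndarray:
    """Fuzzy-weighted mean filter with Gaussian membership.

    Each output pixel is the membership-weighted mean of its ``window`` x
    ``window`` neighbourhood, with weights
    ``mu = exp(-(I_neighbor - I_center)^2 / (2 sigma_member^2))``.
    Borders use reflect padding.  Constant images are fixed points; output
    range is bounded by the input range (weighted means are convex).

    Parameters
    ----------
    window : odd int >= 3
        Side length of the square neighbourhood.
    sigma_member : float > 0
        Width of the Gaussian membership function, in intensity units.
        Small sigma preserves edges aggressively; large sigma approaches a
        plain box mean.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if sigma_member <= 0:
        raise ValueError("sigma_member must be positive")
    arr = _check_gray(img)
    r = window // 2
    padded = np.pad(arr, r, mode="reflect")
    num = np.zeros_like(arr)
    den = np.zeros_like(arr)
    inv = 1.0 / (2.0 * sigma_member * sigma_member)
    H, W = arr.shape
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            nb = padded[r + dy : r + dy + H, r + dx : r + dx + W]
            mu = np.exp(-((nb - arr) ** 2) * inv)
            num += mu * nb
            den += mu
    return num / den
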