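"""Filtering, binarization, three-class labeling and projections.

Reimplements the classic image-post-processing steps: a disc-shaped mean
filter, ≥-threshold mask conversion, labeling of the volume into biomass
(150) / internal voids (50) / background (0), and maximum intensity
projections.  Filters operate slice-wise in the xy-plane for volumes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "disc_footprint",
    "mean_filter",
    "to_grayscale8",
    "binarize",
    "three_class_label",
    "max_intensity_projection",
    "BIOMASS",
    "VOID",
    "BACKGROUND",
]

# three-class label values, on the 8-bit display scale
BIOMASS = 150
VOID = 50
BACKGROUND = 0


def disc_footprint(radius: int) -> np.ndarray:
    """Boolean raster disc: pixel included if centre distance ≤ radius."""
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def mean_filter(data: np.ndarray, radius: int) -> np.ndarray:
    """Disc-shaped arithmetic mean filter, rounded to the nearest integer.

    2D arrays are filtered directly; 3D ``(z, y, x)`` arrays slice-wise in
    the xy-plane (matching a workflow that filters individual images).
    Borders replicate edge values.  Radius 0 is the identity.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    data = np.asarray(data)
    if radius == 0:
        return data.copy()
    foot = disc_footprint(radius)
    kernel = foot.astype(np.float64) / foot.sum()

    def _filter2d(img: np.ndarray) -> np.ndarray:
        out = ndimage.correlate(img.astype(np.float64), kernel, mode="nearest")
        return np.rint(out).astype(data.dtype)

    if data.ndim == 2:
        return _filter2d(data)
    if data.ndim == 3:
        return np.stack([_filter2d(sl) for sl in data])
    raise ValueError(f"expected 2D or 3D array, got ndim={data.ndim}")


def mean_filter_rgb(pixels: np.ndarray, radius: int) -> np.ndarray:
    """Apply :func:`mean_filter` independently per colour channel."""
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB, got shape {pixels.shape}")
    return np.stack(
        [mean_filter(pixels[:, :, c], radius) for c in range(3)], axis=2
    )


def to_grayscale8(pixels: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luminance conversion of an 8-bit RGB image, rounded.

    gray = 0.299 R + 0.587 G + 0.114 B
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB, got shape {pixels.shape}")
    lum = (
        0.299 * pixels[:, :, 0].astype(np.float64)
        + 0.587 * pixels[:, :, 1]
        + 0.114 * pixels[:, :, 2]
    )
    return np.rint(lum).astype(np.uint8)


def binarize(
    data: np.ndarray, threshold: int, *, dark_target: bool = False
) -> np.ndarray:
    """Threshold an 8-bit image/volume to a {0, 255} mask.

    Values ≥ ``threshold`` become 255 (foreground).  With
    ``dark_target=True`` the polarity is inverted first, so that dark
    objects on a light background (the printed target workflow) become
    foreground.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    data = np.asarray(data)
    if dark_target:
        fg = (255 - data.astype(np.int16)) >= threshold
    else:
        fg = data >= threshold
    return np.where(fg, 255, 0).astype(np.uint8)


def _require_binary(values: np.ndarray) -> None:
    bad = np.setdiff1d(np.unique(values), [0, 255])
    if bad.size:
        raise ValueError(f"expected binary {{0, 255}} data, found values {bad.tolist()}")


def three_class_label(binary: np.ndarray, *, void_mode: str = "column") -> np.ndarray:
    """Label a binary biomass volume into biomass (150) / void (50) / background (0).

    The substratum is at z = 0 and the bulk at the top.  Two void
    definitions are available:

    ``column`` (default)
        Per A-scan column, any zero voxel strictly below the column's
        topmost biomass voxel is a void; zeros above it, and whole columns
        without biomass, are background.
    ``floodfill``
        A zero voxel is background only if it is reachable from the top
        (bulk-side) slice through zero voxels by 6-connectivity; all other
        zeros inside the volume are voids.
    """
    binary = np.asarray(binary)
    if binary.ndim != 3:
        raise ValueError(f"expected a 3D binary volume, got ndim={binary.ndim}")
    _require_binary(binary)
    biomass = binary == 255
    labels = np.zeros(binary.shape, dtype=np.uint8)
    labels[biomass] = BIOMASS
    if void_mode == "column":
        nz = binary.shape[0]
        # topmost biomass index per column; -1 where column is empty
        zidx = np.arange(nz).reshape(-1, 1, 1)
        top = np.where(biomass.any(axis=0), np.max(np.where(biomass, zidx, -1), axis=0), -1)
        under_roof = zidx < top[None, :, :]
        labels[under_roof & ~biomass] = VOID
    elif void_mode == "floodfill":
        zero = ~biomass
        structure = ndimage.generate_binary_structure(3, 1)
        comp, _ = ndimage.label(zero, structure=structure)
        bulk_ids = np.unique(comp[-1][zero[-1]])
        background = zero & np.isin(comp, bulk_ids)
        labels[zero & ~background] = VOID
    else:
        raise ValueError(f"void_mode must be 'column' or 'floodfill', got {void_mode!r}")
    return labels


def max_intensity_projection(volume: np.ndarray, axis: str = "z") -> np.ndarray:
    """Per-position maximum along a named axis of a (z, y, x) volume.

    The default z-projection yields the xy plan-view image used for
    substratum coverage and textural entropy.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3 or volume.size == 0:
        raise ValueError("expected a non-empty 3D volume")
    try:
        ax = {"z": 0, "y": 1, "x": 2}[axis]
    except KeyError:
        raise ValueError(f"axis must be one of z, y, x; got {axis!r}") from None
    return volume.max(axis=ax)
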