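"""Independent brute-force reference implementations for the test suite.

Everything here is written as plain nested loops over voxels/pixels,
deliberately avoiding the vectorised code paths of the package, so the two
routes can disagree only if one of them is wrong.
"""

from __future__ import annotations

import math

import numpy as np


def brute_mean_filter_2d(img: np.ndarray, radius: int) -> np.ndarray:
    """Disc mean filter by explicit neighbourhood enumeration, edge-replicated."""
    h, w = img.shape
    out = np.zeros_like(img)
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    for y in range(h):
        for x in range(w):
            total = 0.0
            for dy, dx in offsets:
                yy = min(max(y + dy, 0), h - 1)
                xx = min(max(x + dx, 0), w - 1)
                total += float(img[yy, xx])
            out[y, x] = round(total / len(offsets))
    return out


def brute_substratum_coverage(mip: np.ndarray) -> float:
    n = 0
    h, w = mip.shape
    for y in range(h):
        for x in range(w):
            if mip[y, x] >= 1:
                n += 1
    return 100.0 * n / (h * w)


def brute_mean_thickness(binary: np.ndarray, dz: float) -> float:
    nz, ny, nx = binary.shape
    total = 0.0
    for y in range(ny):
        for x in range(nx):
            count = 0
            for z in range(nz):
                if binary[z, y, x] == 255:
                    count += 1
            total += count * dz
    return total / (ny * nx)


def brute_three_class_label(binary: np.ndarray) -> np.ndarray:
    """Column-wise biomass/void/background labeling by explicit scanning."""
    nz, ny, nx = binary.shape
    labels = np.zeros(binary.shape, dtype=np.uint8)
    for y in range(ny):
        for x in range(nx):
            top = -1
            for z in range(nz):
                if binary[z, y, x] == 255:
                    top = z
            for z in range(nz):
                if binary[z, y, x] == 255:
                    labels[z, y, x] = 150
                elif z < top:
                    labels[z, y, x] = 50
    return labels


def brute_intrinsic_porosity(labels: np.ndarray) -> float:
    n_void = n_bio = 0
    for v in labels.ravel():
        if v == 50:
            n_void += 1
        elif v == 150:
            n_bio += 1
    if n_void + n_bio == 0:
        return float("nan")
    return 100.0 * n_void / (n_void + n_bio)


def brute_global_porosity(labels: np.ndarray) -> float:
    nz, ny, nx = labels.shape
    below = non_bio = 0
    for y in range(ny):
        for x in range(nx):
            top = -1
            for z in range(nz):
                if labels[z, y, x] == 150:
                    top = z
            for z in range(top + 1):
                below += 1
                if labels[z, y, x] != 150:
                    non_bio += 1
    if below == 0:
        return float("nan")
    return 100.0 * non_bio / below


def brute_textural_entropy(img: np.ndarray, offset: tuple[int, int]) -> float:
    """Co-occurrence entropy by an O(H·W) double loop over all pixel pairs."""
    dy, dx = offset
    h, w = img.shape
    counts: dict[tuple[int, int], int] = {}
    n = 0
    for y in range(h):
        for x in range(w):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w:
                pair = (int(img[y, x]), int(img[yy, xx]))
                counts[pair] = counts.get(pair, 0) + 1
                n += 1
    te = 0.0
    for c in counts.values():
        p = c / n
        te -= p * math.log(p)
    return te


def random_binary_volume(rng: np.random.Generator, max_side: int = 32) -> np.ndarray:
    """Random {0,255} volume with blocky structure (not pure salt-and-pepper)."""
    shape = tuple(rng.integers(4, max_side + 1, size=3))
    base = rng.random(shape) < rng.uniform(0.1, 0.7)
    return np.where(base, 255, 0).astype(np.uint8)
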