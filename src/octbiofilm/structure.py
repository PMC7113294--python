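"""Structural biofilm parameters from labeled OCT volumes.

Implements the five standard descriptors of mesoscopic biofilm structure:

* substratum coverage SC — percentage of the imaged substratum overlain by
  biomass, read off the z maximum-intensity projection;
* mean biofilm thickness L̄_F — mean over all A-scan columns of the local
  thickness L_F,i = (Σ binary column values)·Δz/255, i.e. biomass voxel
  count × effective voxel height;
* intrinsic porosity Φ_intrinsic — void fraction within the biofilm
  envelope, voids/(biomass+voids), background excluded;
* global porosity Φ_global — non-biomass fraction of everything beneath the
  bulk–biofilm interface;
* textural entropy TE — Shannon entropy (natural log) of the pixel-pair
  intensity co-occurrence probabilities of a projection image.

Percentages are reported in [0, 100]; undefined ratios (no biomass) are
returned as NaN, the package-wide missing-value marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import OCTVolume, crop_volume
from .preprocess import (
    BIOMASS,
    VOID,
    binarize,
    max_intensity_projection,
    mean_filter,
    three_class_label,
)

__all__ = [
    "HeightMap",
    "StructureReport",
    "local_thickness",
    "mean_biofilm_thickness",
    "substratum_coverage",
    "intrinsic_porosity",
    "global_porosity",
    "height_map",
    "textural_entropy",
    "structure_report",
    "MISSING",
]

MISSING = float("nan")

# the four standard co-occurrence offsets (dy, dx): 0°, 90°, 45°, 135°
FOUR_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class HeightMap:
    """Bulk–biofilm interface height per (y, x) position, in µm.

    Height is 0 exactly where the column holds no biomass; a column whose
    topmost biomass voxel has z-index k has height (k + 1)·Δz.
    """

    heights: np.ndarray
    dx: float
    dy: float

    @property
    def mean(self) -> float:
        return float(self.heights.mean())

    @property
    def max(self) -> float:
        return float(self.heights.max())


@dataclass
class StructureReport:
    """One volume's structural parameters plus the settings that produced them."""

    sc_percent: float
    mean_thickness_um: float
    phi_intrinsic_percent: float
    phi_global_percent: float
    textural_entropy: float
    n_columns: int
    flow_cell: int | None = None
    day: int | None = None
    params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "flow_cell": self.flow_cell,
            "day": self.day,
            "sc_percent": self.sc_percent,
            "mean_thickness_um": self.mean_thickness_um,
            "phi_intrinsic_percent": self.phi_intrinsic_percent,
            "phi_global_percent": self.phi_global_percent,
            "textural_entropy": self.textural_entropy,
            "n_columns": self.n_columns,
        }


def _require_binary(values: np.ndarray) -> None:
    bad = np.setdiff1d(np.unique(values), [0, 255])
    if bad.size:
        raise ValueError(f"expected binary {{0, 255}} data, found values {bad.tolist()}")


def local_thickness(column: np.ndarray, dz: float, *, mode: str = "sum") -> float:
    """Local biofilm thickness of one binary A-scan column, in µm.

    ``mode="sum"`` (default): thickness = (Σ column values)·dz/255, the
    biomass voxel count times the voxel height — internal voids do not add
    thickness.  ``mode="interface"``: thickness up to the topmost biomass
    voxel, (top index + 1)·dz, voids included.
    """
    if dz <= 0:
        raise ValueError(f"dz must be positive, got {dz}")
    column = np.asarray(column)
    _require_binary(column)
    if mode == "sum":
        return float(column.sum(dtype=np.int64)) * dz / 255.0
    if mode == "interface":
        idx = np.nonzero(column == 255)[0]
        return 0.0 if idx.size == 0 else float(idx[-1] + 1) * dz
    raise ValueError(f"mode must be 'sum' or 'interface', got {mode!r}")


def mean_biofilm_thickness(
    binary: np.ndarray, dz: float, *, mode: str = "sum"
) -> float:
    """Mean of the local thickness over all N A-scan columns, in µm.

    N is the number of A-scans in the volume; biomass-free columns count
    as zero thickness.
    """
    binary = np.asarray(binary)
    if binary.ndim != 3 or binary.size == 0:
        raise ValueError("expected a non-empty 3D binary volume")
    if dz <= 0:
        raise ValueError(f"dz must be positive, got {dz}")
    _require_binary(binary)
    n_columns = binary.shape[1] * binary.shape[2]
    if mode == "sum":
        total = binary.sum(dtype=np.int64) / 255.0
        return float(total) * dz / n_columns
    if mode == "interface":
        hm = height_map(binary, dz, dx=1.0, dy=1.0)
        return float(hm.heights.mean())
    raise ValueError(f"mode must be 'sum' or 'interface', got {mode!r}")


def substratum_coverage(mip: np.ndarray) -> float:
    """Percentage of projection pixels carrying biomass signal.

    Every pixel with value ≥ 1 in the (binary or grayscale) biomass MIP
    counts as biomass: SC = 100 · A_biofilm / (A_biofilm + A_background).
    """
    mip = np.asarray(mip)
    if mip.size == 0:
        raise ValueError("empty image")
    return 100.0 * float(np.count_nonzero(mip >= 1)) / mip.size


def intrinsic_porosity(labels: np.ndarray) -> float:
    """Void fraction within the biofilm envelope, percent.

    Φ_intrinsic = 100 · voids / (biomass + voids), counted over the whole
    labeled volume (equivalently, aggregated over all xz longitudinal
    sections); background voxels are excluded.  NaN when the volume holds
    neither biomass nor voids.
    """
    labels = np.asarray(labels)
    n_void = int(np.count_nonzero(labels == VOID))
    n_bio = int(np.count_nonzero(labels == BIOMASS))
    if n_void + n_bio == 0:
        return MISSING
    return 100.0 * n_void / (n_void + n_bio)


def global_porosity(labels: np.ndarray) -> float:
    """Non-biomass fraction of the region beneath the bulk–biofilm interface.

    Per column the interface sits just above the topmost biomass voxel;
    everything below it (biomass + voids) forms the denominator.  NaN for
    a biomass-free volume.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError(f"expected a 3D label volume, got ndim={labels.ndim}")
    biomass = labels == BIOMASS
    nz = labels.shape[0]
    zidx = np.arange(nz).reshape(-1, 1, 1)
    top = np.max(np.where(biomass, zidx, -1), axis=0)  # -1 for empty columns
    below = (top + 1).sum(dtype=np.int64)  # voxels beneath the interface
    if below == 0:
        return MISSING
    n_bio = int(np.count_nonzero(biomass))
    return 100.0 * float(below - n_bio) / float(below)


def height_map(
    binary: np.ndarray, dz: float, *, dx: float = 1.0, dy: float = 1.0
) -> HeightMap:
    """Topography of the bulk–biofilm interface from a binary volume."""
    binary = np.asarray(binary)
    if binary.ndim != 3 or binary.size == 0:
        raise ValueError("expected a non-empty 3D binary volume")
    _require_binary(binary)
    biomass = binary == 255
    nz = binary.shape[0]
    zidx = np.arange(nz).reshape(-1, 1, 1)
    top = np.max(np.where(biomass, zidx, -1), axis=0)
    heights = (top + 1).astype(np.float64) * dz
    return HeightMap(heights, dx=dx, dy=dy)


def cooccurrence_probabilities(
    image: np.ndarray,
    offset: tuple[int, int] = (0, 1),
    *,
    levels: int = 256,
    symmetric: bool = False,
) -> np.ndarray:
    """Probability table p(a, b) of ordered intensity pairs at a pixel offset.

    Counts every pixel pair (p, p + offset) inside the image, optionally
    adds the transposed counts (``symmetric``), and normalises to sum 1.
    Intensities may be binned from 256 down to ``levels`` gray levels.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={image.ndim}")
    dy, dx = offset
    if dy == 0 and dx == 0:
        raise ValueError("offset must be nonzero")
    h, w = image.shape
    if abs(dy) >= h or abs(dx) >= w:
        raise ValueError(
            f"image of shape {image.shape} is smaller than offset {offset}"
        )
    if levels < 2 or levels > 256:
        raise ValueError(f"levels must be in [2, 256], got {levels}")
    if levels != 256:
        data = (image.astype(np.int64) * levels) // 256
    else:
        data = image.astype(np.int64)

    ys = slice(max(0, -dy), h - max(0, dy))
    xs = slice(max(0, -dx), w - max(0, dx))
    a = data[ys, xs]
    b = data[max(0, dy) : h - max(0, -dy), max(0, dx) : w - max(0, -dx)]
    counts = np.bincount(
        (a * levels + b).ravel(), minlength=levels * levels
    ).reshape(levels, levels)
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def textural_entropy(
    image: np.ndarray,
    offset: tuple[int, int] = (0, 1),
    *,
    levels: int = 256,
    symmetric: bool = False,
    average_four: bool = False,
) -> float:
    """Textural entropy TE = −Σ p(a,b)·ln p(a,b) of a projection image, nats.

    Zero-probability entries are skipped.  A homogeneous image has a
    single transition (a → a) with probability 1, hence TE = 0.  With
    ``average_four`` the entropy is averaged over the four standard
    offsets (0,1), (1,0), (1,1), (1,−1).
    """

    def _one(off: tuple[int, int]) -> float:
        p = cooccurrence_probabilities(
            image, off, levels=levels, symmetric=symmetric
        )
        nz = p[p > 0]
        return float(-(nz * np.log(nz)).sum() + 0.0)  # +0.0 avoids -0.0

    if average_four:
        return float(np.mean([_one(off) for off in FOUR_OFFSETS]))
    return _one(offset)


def structure_report(
    vol: OCTVolume,
    *,
    crop_extent_mm: tuple[float, float, float] | None = None,
    filter_radius: int = 2,
    biomass_threshold: int = 1,
    void_mode: str = "column",
    thickness_mode: str = "sum",
    te_offset: tuple[int, int] = (0, 1),
    te_levels: int = 256,
    te_average_four: bool = False,
) -> StructureReport:
    """Full analysis of one OCT volume: crop → filter → binarize → label → parameters.

    TE is computed on the mean-filtered grayscale MIP (a binary projection
    has a degenerate two-level co-occurrence table); all other parameters
    come from the binary/labeled volume.  Every parameter setting is
    recorded in ``StructureReport.params``.
    """
    if crop_extent_mm is not None:
        vol = crop_volume(vol, crop_extent_mm)
    filtered = mean_filter(vol.intensities, filter_radius)
    binary = binarize(filtered, biomass_threshold)
    labels = three_class_label(binary, void_mode=void_mode)
    bin_mip = max_intensity_projection(binary)
    gray_mip = max_intensity_projection(filtered)
    dz = vol.voxel.dz
    report = StructureReport(
        sc_percent=substratum_coverage(bin_mip),
        mean_thickness_um=mean_biofilm_thickness(binary, dz, mode=thickness_mode),
        phi_intrinsic_percent=intrinsic_porosity(labels),
        phi_global_percent=global_porosity(labels),
        textural_entropy=textural_entropy(
            gray_mip, te_offset, levels=te_levels, average_four=te_average_four
        ),
        n_columns=vol.shape[1] * vol.shape[2],
        flow_cell=vol.flow_cell,
        day=vol.day,
        params={
            "crop_extent_mm": crop_extent_mm,
            "filter_radius": filter_radius,
            "biomass_threshold": biomass_threshold,
            "void_mode": void_mode,
            "thickness_mode": thickness_mode,
            "te_offset": te_offset,
            "te_levels": te_levels,
            "te_average_four": te_average_four,
            "voxel": vol.voxel,
        },
    )
    return report
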