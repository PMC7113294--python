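"""Data model and I/O for OCT C-scan volumes and calibration-target images.

The package-wide coordinate convention is fixed here: volumes are indexed
``(z, y, x)`` with ``z = 0`` at the substratum (the channel floor on which
the biofilm grows) and z increasing toward the bulk liquid.  All physical
lengths are micrometres internally; millimetres appear only at the CLI
boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelSpec",
    "OCTVolume",
    "TargetImage",
    "load_volume",
    "write_volume",
    "load_target_image",
    "crop_volume",
    "effective_axial_resolution",
    "flow_rate",
]


@dataclass(frozen=True)
class VoxelSpec:
    """Anisotropic voxel geometry of an OCT scan.

    Parameters
    ----------
    dx, dy : float
        Lateral voxel pitch in µm along x and y.
    dz_air : float
        Axial voxel pitch in air (n = 1), µm.
    refractive_index : float
        Refractive index of the imaging medium (n ≥ 1).  The effective
        axial pitch in the medium is ``dz_air / n`` and is always derived,
        never stored.
    """

    dx: float
    dy: float
    dz_air: float
    refractive_index: float = 1.0

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz_air"):
            if getattr(self, name) <= 0:
                raise ValueError(f"VoxelSpec.{name} must be positive, got {getattr(self, name)}")
        if self.refractive_index < 1:
            raise ValueError(
                f"refractive_index must be >= 1, got {self.refractive_index}"
            )

    @property
    def dz(self) -> float:
        """Effective axial voxel height in the medium, µm."""
        return effective_axial_resolution(self.dz_air, self.refractive_index)

    @property
    def spacing(self) -> tuple[float, float, float]:
        """(dz, dy, dx) in µm, matching the (z, y, x) axis order."""
        return (self.dz, self.dy, self.dx)


def effective_axial_resolution(dz_air: float, n: float) -> float:
    """Axial voxel height corrected for the refractive index of the medium.

    Light travels optically slower in the medium, so a z-step of ``dz_air``
    in air corresponds to ``dz_air / n`` of physical depth in a medium of
    refractive index ``n``.
    """
    if dz_air <= 0:
        raise ValueError(f"dz_air must be positive, got {dz_air}")
    if n < 1:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    return dz_air / n


def flow_rate(u: float, width: float, height: float) -> float:
    """Volumetric flow rate in mL/min from mean velocity and channel cross-section.

    Parameters are the mean flow velocity ``u`` (mm/s) and the channel
    ``width`` and ``height`` (mm).  1 mm³/s = 0.06 mL/min.
    """
    if u <= 0 or width <= 0 or height <= 0:
        raise ValueError("flow_rate arguments must all be positive")
    return u * width * height * 60.0 / 1000.0


@dataclass
class OCTVolume:
    """A 3D 8-bit OCT intensity volume with voxel geometry and provenance.

    ``intensities`` is indexed (z, y, x), z = 0 at the substratum.
    """

    intensities: np.ndarray
    voxel: VoxelSpec
    flow_cell: int | None = None
    day: int | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3D (z, y, x), got ndim={self.intensities.ndim}"
            )
        if self.intensities.dtype != np.uint8:
            raise ValueError(
                f"intensities must be uint8, got {self.intensities.dtype}"
            )
        if self.day is not None and self.day < 0:
            raise ValueError(f"day must be >= 0, got {self.day}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (z, y, x) in µm."""
        nz, ny, nx = self.shape
        return (nz * self.voxel.dz, ny * self.voxel.dy, nx * self.voxel.dx)

    def with_intensities(self, values: np.ndarray) -> "OCTVolume":
        """Copy of this volume with new intensity data, same geometry/metadata."""
        return replace(self, intensities=values)


@dataclass
class TargetImage:
    """2D RGB image of the printed calibration target with pixel geometry."""

    pixels: np.ndarray
    px_size_x: float
    px_size_y: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"pixels must be (H, W, 3) RGB, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {self.pixels.dtype}")
        if self.px_size_x <= 0 or self.px_size_y <= 0:
            raise ValueError("pixel sizes must be positive")

    @classmethod
    def from_field_of_view(
        cls, pixels: np.ndarray, fov_x_mm: float, fov_y_mm: float
    ) -> "TargetImage":
        """Build a TargetImage deriving µm/px from field of view ÷ pixel count."""
        pixels = np.asarray(pixels)
        h, w = pixels.shape[:2]
        return cls(pixels, fov_x_mm * 1000.0 / w, fov_y_mm * 1000.0 / h)


def _rescale_to_uint8(stack: np.ndarray) -> np.ndarray:
    """Min-max rescale a 16-bit stack to 8-bit, jointly over all pages.

    All thresholds used downstream (120, 150, 50, ≥1) live on the 8-bit
    scale, so higher bit depths are normalised on load.  The rescale is
    global so relative intensities between slices are preserved.
    """
    lo = int(stack.min())
    hi = int(stack.max())
    if hi == lo:
        return np.zeros(stack.shape, dtype=np.uint8)
    scaled = (stack.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.rint(scaled).astype(np.uint8)


def load_volume(
    path,
    voxel: VoxelSpec,
    *,
    flow_cell: int | None = None,
    day: int | None = None,
    notes: str = "",
    pages_axis: str = "z",
    flip_z: bool = True,
) -> OCTVolume:
    """Read a multi-page grayscale TIFF stack into an :class:`OCTVolume`.

    Parameters
    ----------
    path : path-like
        Multi-page TIFF; every page must have the same 2D shape.
    voxel : VoxelSpec
        Voxel geometry.  Spacing is taken from this argument, not from TIFF
        resolution tags (vendor tags are unreliable); if tags are present
        and disagree with it by more than 1 % a warning is logged.
    pages_axis : {"z", "y"}
        Whether pages are z-slices (default) or B-scans stacked along y.
    flip_z : bool
        OCT probes scan from above, so stacks usually store the bulk-side
        slice first.  The default reverses page order along z so that
        index 0 is the substratum.
    """
    with tifffile.TiffFile(str(path)) as tif:
        pages = [p.asarray() for p in tif.pages]
        _check_resolution_tags(tif, voxel, path)
    if not pages:
        raise ValueError(f"{path}: TIFF contains no pages")
    shape0 = pages[0].shape
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise ValueError(f"{path}: page {i} is not 2D (shape {page.shape})")
        if page.shape != shape0:
            raise ValueError(
                f"{path}: ragged page {i}: shape {page.shape} != {shape0}"
            )
        if page.dtype not in (np.uint8, np.uint16):
            raise ValueError(
                f"{path}: page {i} has unsupported dtype {page.dtype} "
                "(8-bit or 16-bit grayscale expected)"
            )
    stack = np.stack(pages)
    if stack.dtype == np.uint16:
        stack = _rescale_to_uint8(stack)
    if pages_axis == "y":
        stack = np.transpose(stack, (1, 0, 2))  # pages are (z, x) B-scans
    elif pages_axis != "z":
        raise ValueError(f"pages_axis must be 'z' or 'y', got {pages_axis!r}")
    if flip_z:
        stack = stack[::-1].copy()
    return OCTVolume(stack, voxel, flow_cell=flow_cell, day=day, notes=notes)


def _check_resolution_tags(tif, voxel: VoxelSpec, path) -> None:
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        if xres is None:
            return
        num, den = xres.value
        if num == 0 or (num, den) == (1, 1):  # placeholder tag, no information
            return
        # TIFF resolution is px per unit; compare µm/px against config
        tag_um_per_px = den / num * 1e4  # assumes centimetre unit, best effort
        if abs(tag_um_per_px - voxel.dx) / voxel.dx > 0.01:
            logger.warning(
                "%s: TIFF XResolution implies %.3g µm/px but config says %.3g µm/px",
                path,
                tag_um_per_px,
                voxel.dx,
            )
    except Exception:  # tag decoding is best-effort only
        return


def write_volume(path, vol: OCTVolume, *, flip_z: bool = True) -> None:
    """Write a volume as a multi-page 8-bit TIFF, inverse of :func:`load_volume`.

    With the default ``flip_z`` the file round-trips byte-identically
    through ``load_volume(..., flip_z=True)``.
    """
    stack = vol.intensities[::-1] if flip_z else vol.intensities
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def load_target_image(path, *, fov_x_mm: float = 6.7, fov_y_mm: float = 5.0) -> TargetImage:
    """Read an RGB target photograph (PNG/TIFF), deriving µm/px from the FOV."""
    import imageio.v3 as iio

    pixels = iio.imread(str(path))
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {pixels.shape}")
    return TargetImage.from_field_of_view(pixels, fov_x_mm, fov_y_mm)


def crop_volume(
    vol: OCTVolume,
    extent_mm: tuple[float, float, float],
    origin: tuple[int, int, int] = (0, 0, 0),
) -> OCTVolume:
    """Crop to a physical extent ``(x_mm, y_mm, z_mm)`` from voxel ``origin``.

    The returned shape per axis is ``floor(extent_um / spacing)``.  The
    standard analysis crop for the 0.45 mm flow channel is (7, 5, 0.45) mm.
    """
    x_mm, y_mm, z_mm = extent_mm
    ox, oy, oz = origin
    dz, dy, dx = vol.voxel.spacing
    want = (
        int(np.floor(z_mm * 1000.0 / dz)),
        int(np.floor(y_mm * 1000.0 / dy)),
        int(np.floor(x_mm * 1000.0 / dx)),
    )
    have = vol.shape
    offs = (oz, oy, ox)
    for axis, name in enumerate(("z", "y", "x")):
        if offs[axis] + want[axis] > have[axis]:
            raise ValueError(
                f"crop along {name} needs {want[axis]} voxels from offset "
                f"{offs[axis]} but only {have[axis]} are available"
            )
    nz, ny, nx = want
    sub = vol.intensities[oz : oz + nz, oy : oy + ny, ox : ox + nx].copy()
    return vol.with_intensities(sub)
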