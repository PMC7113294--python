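"""Synthetic phantoms standing in for the instrument.

Two generators make the whole pipeline testable without hardware:

* :func:`synth_biofilm_series` grows spherical-cap colonies on the channel
  floor over a series of days, carves ellipsoidal voids into them, clips
  the structure at the channel ceiling, voxelises it, and adds clipped
  Gaussian noise.  The noise-free phantom's structural parameters are
  returned as ground truth, computed by direct voxel counting inside this
  module (deliberately independent of the analysis code paths).

* :func:`synth_target_image` renders an anti-aliased 1 mm red disc at a
  known sub-pixel centre on a light background, optionally with small dark
  dust specks, emulating the photographs used for positioning-accuracy
  runs (1600 × 1200 px, 6.7 × 5.0 mm² field of view).

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import OCTVolume, TargetImage, VoxelSpec

__all__ = [
    "GrowthParams",
    "GroundTruth",
    "synth_biofilm_series",
    "synth_target_image",
    "DEFAULT_VOXEL",
]

# coarse default grid: 0.45 mm channel, dz chosen so volumes stay small;
# dz_air = 2.793 µm with n = 1.33 gives the instrument's 2.1 µm in water
DEFAULT_VOXEL = VoxelSpec(dx=20.0, dy=20.0, dz_air=19.95, refractive_index=1.33)


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the colony-growth phantom.

    Defaults emulate a fast-developing flow-cell biofilm: near-complete
    substratum coverage and a mean thickness around 150–200 µm by day 5–6.
    """

    seeding_rate_per_mm2_day: float = 0.8   # new colonies per mm² per day
    lateral_rate_um_day: float = 110.0      # colony base-radius growth
    vertical_rate_um_day: float = 45.0      # colony cap-height growth
    void_fraction: float = 0.15             # target void share inside colonies
    noise_sd: float = 8.0                   # additive Gaussian, 8-bit counts
    biomass_intensity: int = 180            # mean signal of biomass voxels
    channel_height_um: float = 450.0
    extent_x_um: float = 1000.0
    extent_y_um: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.void_fraction < 1):
            raise ValueError(f"void_fraction must be in [0, 1), got {self.void_fraction}")
        for name in ("seeding_rate_per_mm2_day", "lateral_rate_um_day",
                     "vertical_rate_um_day", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Noise-free phantom parameters by direct voxel counting."""

    day: int
    sc_percent: float
    mean_thickness_um: float
    void_fraction_percent: float
    n_biomass_voxels: int
    n_void_voxels: int


def _column_ground_truth(biomass: np.ndarray, dz: float, day: int) -> GroundTruth:
    """Count SC, thickness and under-the-roof void share on a boolean mask.

    Self-contained columnar counting (no imports from the analysis
    modules) so the ground truth is a genuinely independent oracle.
    """
    nz, ny, nx = biomass.shape
    n_bio = int(biomass.sum())
    covered = biomass.any(axis=0)
    sc = 100.0 * int(covered.sum()) / (ny * nx)
    thickness = n_bio * dz / (ny * nx)
    # voids: zero voxels strictly below the column's topmost biomass voxel
    zidx = np.arange(nz).reshape(-1, 1, 1)
    top = np.max(np.where(biomass, zidx, -1), axis=0)
    below = (zidx < top[None, :, :])
    n_void = int((below & ~biomass).sum())
    vf = 100.0 * n_void / (n_void + n_bio) if (n_void + n_bio) else float("nan")
    return GroundTruth(
        day=day,
        sc_percent=sc,
        mean_thickness_um=thickness,
        void_fraction_percent=vf,
        n_biomass_voxels=n_bio,
        n_void_voxels=n_void,
    )


def _spherical_cap_mask(
    shape: tuple[int, int, int],
    voxel: VoxelSpec,
    cx_um: float,
    cy_um: float,
    base_radius_um: float,
    height_um: float,
) -> np.ndarray:
    """Voxels inside a spherical cap sitting on z = 0.

    A cap of base radius a and height h belongs to a sphere of radius
    R = (a² + h²) / (2h) centred at z = h − R below/above the floor.
    """
    nz, ny, nx = shape
    dz, dy, dx = voxel.spacing
    a, h = base_radius_um, height_um
    if a <= 0 or h <= 0:
        return np.zeros(shape, dtype=bool)
    big_r = (a * a + h * h) / (2.0 * h)
    zc = h - big_r
    z = (np.arange(nz) + 0.5) * dz
    y = (np.arange(ny) + 0.5) * dy
    x = (np.arange(nx) + 0.5) * dx
    zz = (z - zc) ** 2
    rr = (y[:, None] - cy_um) ** 2 + (x[None, :] - cx_um) ** 2
    return (zz[:, None, None] + rr[None, :, :]) <= big_r * big_r


def _carve_voids(
    biomass: np.ndarray,
    voxel: VoxelSpec,
    void_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Carve ellipsoidal pockets until roughly the target void share is reached.

    Voids are seeded at biomass voxels that sit at least one voxel below
    their column top, so the bulk–biofilm interface stays intact and the
    carved volume remains "within the structure".
    """
    if void_fraction <= 0 or not biomass.any():
        return biomass
    nz, ny, nx = biomass.shape
    dz, dy, dx = voxel.spacing
    out = biomass.copy()
    zidx = np.arange(nz).reshape(-1, 1, 1)
    top = np.max(np.where(biomass, zidx, -1), axis=0)
    interior = biomass & (zidx < top[None, :, :])
    candidates = np.argwhere(interior)
    if candidates.size == 0:
        return out
    n_total = int(biomass.sum())
    # carved + remaining biomass = n_total, so voids/(voids+biomass) = carved/n_total
    target_voids = void_fraction * n_total
    carved = 0
    z = (np.arange(nz) + 0.5) * dz
    y = (np.arange(ny) + 0.5) * dy
    x = (np.arange(nx) + 0.5) * dx
    for _ in range(10 * len(candidates)):
        if carved >= target_voids:
            break
        cz, cy, cx = candidates[rng.integers(len(candidates))]
        # pores span a few voxels so they survive voxelisation and filtering
        rz = rng.uniform(1.5, 3.5) * dz
        ry = rng.uniform(1.5, 3.5) * dy
        rx = rng.uniform(1.5, 3.5) * dx
        ell = (
            ((z - z[cz]) / rz)[:, None, None] ** 2
            + ((y - y[cy]) / ry)[None, :, None] ** 2
            + ((x - x[cx]) / rx)[None, None, :] ** 2
        ) <= 1.0
        # only carve strictly below each column's top, keeping the roof closed
        hit = ell & out & (zidx < top[None, :, :])
        carved += int(hit.sum())
        out[hit] = False
    return out


def synth_biofilm_series(
    params: GrowthParams,
    days: int,
    voxel: VoxelSpec = DEFAULT_VOXEL,
    *,
    flow_cell: int = 1,
) -> list[tuple[OCTVolume, GroundTruth]]:
    """Simulate one flow cell over ``days`` consecutive days.

    Colonies appear at Poisson-random positions at a constant seeding rate
    and grow linearly in base radius and cap height; merging colonies
    union their masks.  The structure is clipped at the channel ceiling.
    Each day yields the noisy 8-bit volume plus noise-free ground truth.
    """
    dz = voxel.dz
    if params.channel_height_um < dz:
        raise ValueError(
            f"channel height {params.channel_height_um} µm is below one voxel ({dz} µm)"
        )
    nz = int(round(params.channel_height_um / dz))
    ny = int(round(params.extent_y_um / voxel.dy))
    nx = int(round(params.extent_x_um / voxel.dx))
    shape = (nz, ny, nx)
    rng = np.random.default_rng(params.seed)
    area_mm2 = params.extent_x_um * params.extent_y_um / 1e6

    # colony birth schedule for the whole series, day by day
    colonies: list[tuple[float, float, int]] = []  # (cx_um, cy_um, birth_day)
    out: list[tuple[OCTVolume, GroundTruth]] = []
    for day in range(days):
        n_new = rng.poisson(params.seeding_rate_per_mm2_day * area_mm2)
        for _ in range(n_new):
            colonies.append(
                (
                    rng.uniform(0, params.extent_x_um),
                    rng.uniform(0, params.extent_y_um),
                    day,
                )
            )
        biomass = np.zeros(shape, dtype=bool)
        for cx, cy, born in colonies:
            age = day - born + 1  # grows within its first day
            biomass |= _spherical_cap_mask(
                shape,
                voxel,
                cx,
                cy,
                params.lateral_rate_um_day * age,
                min(params.vertical_rate_um_day * age, params.channel_height_um),
            )
        biomass = _carve_voids(biomass, voxel, params.void_fraction, rng)
        truth = _column_ground_truth(biomass, dz, day)
        intensities = np.where(biomass, params.biomass_intensity, 0).astype(np.float64)
        if params.noise_sd > 0:
            intensities += rng.normal(0.0, params.noise_sd, size=shape)
        vol = OCTVolume(
            np.clip(np.rint(intensities), 0, 255).astype(np.uint8),
            voxel,
            flow_cell=flow_cell,
            day=day,
            notes="synthetic phantom",
        )
        out.append((vol, truth))
    return out


def synth_target_image(
    true_center_um: tuple[float, float] = (0.0, 0.0),
    dust: int = 0,
    seed: int = 0,
    *,
    width_px: int = 1600,
    height_px: int = 1200,
    fov_x_mm: float = 6.7,
    fov_y_mm: float = 5.0,
    disc_diameter_um: float = 1000.0,
) -> tuple[TargetImage, tuple[float, float]]:
    """Render a photograph of the printed target with a known centre.

    ``true_center_um`` is the (x, y) offset of the disc centre from the
    image centre, in µm; the returned second element is the absolute disc
    centre in µm image coordinates (the quantity :func:`detect_target`
    estimates).  Dust specks are small dark blobs well below the particle
    size gate.  Anti-aliasing uses the pixel's signed distance to the disc
    edge, so sub-pixel centre shifts move the rendered mass accordingly.
    """
    px_x = fov_x_mm * 1000.0 / width_px
    px_y = fov_y_mm * 1000.0 / height_px
    cx_um = width_px / 2.0 * px_x + true_center_um[0]
    cy_um = height_px / 2.0 * px_y + true_center_um[1]
    r_um = disc_diameter_um / 2.0
    if not (r_um <= cx_um <= width_px * px_x - r_um) or not (
        r_um <= cy_um <= height_px * px_y - r_um
    ):
        raise ValueError("disc does not fit fully inside the image")

    rng = np.random.default_rng(seed)
    img = np.full((height_px, width_px, 3), 245, dtype=np.float64)

    # render only inside the disc's bounding box (plus margin)
    pad = 3
    x0 = max(0, int((cx_um - r_um) / px_x) - pad)
    x1 = min(width_px, int((cx_um + r_um) / px_x) + pad)
    y0 = max(0, int((cy_um - r_um) / px_y) - pad)
    y1 = min(height_px, int((cy_um + r_um) / px_y) + pad)
    xs = (np.arange(x0, x1) + 0.5) * px_x
    ys = (np.arange(y0, y1) + 0.5) * px_y
    dist = np.sqrt((ys[:, None] - cy_um) ** 2 + (xs[None, :] - cx_um) ** 2)
    # coverage ~ linear ramp across one pixel width around the edge
    edge = (r_um - dist) / px_x + 0.5
    alpha = np.clip(edge, 0.0, 1.0)
    disc_rgb = np.array([200.0, 30.0, 30.0])
    patch = img[y0:y1, x0:x1]
    img[y0:y1, x0:x1] = patch * (1 - alpha[:, :, None]) + disc_rgb * alpha[:, :, None]

    for _ in range(dust):
        # dark speck of 1–3 px radius away from nothing in particular
        sx = rng.uniform(0, width_px)
        sy = rng.uniform(0, height_px)
        sr = rng.uniform(1.0, 3.0)
        bx0, bx1 = max(0, int(sx - sr) - 2), min(width_px, int(sx + sr) + 3)
        by0, by1 = max(0, int(sy - sr) - 2), min(height_px, int(sy + sr) + 3)
        if bx1 <= bx0 or by1 <= by0:
            continue
        gx = np.arange(bx0, bx1) + 0.5
        gy = np.arange(by0, by1) + 0.5
        d = np.sqrt((gy[:, None] - sy) ** 2 + (gx[None, :] - sx) ** 2)
        a = np.clip(sr - d + 0.5, 0.0, 1.0)
        speck = np.array([40.0, 35.0, 30.0])
        img[by0:by1, bx0:bx1] = (
            img[by0:by1, bx0:bx1] * (1 - a[:, :, None]) + speck * a[:, :, None]
        )

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return TargetImage(pixels, px_x, px_y), (cx_um, cy_um)
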