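"""Calibration-target detection and positioning-accuracy statistics.

A robotic gantry repeatedly moves an imaging probe back to the same
position; a camera photographs a printed 1 mm disc (the target) each time.
The centre of mass (CoM) of the detected target, expressed in µm, varies
from image to image; the deviations from the series mean,

    Δx_i = x_i − x̄ ,   Δy_i = y_i − ȳ ,

quantify the repeatability of the positioning.  A run passes when the
deviations stay within the optical resolution of the tomograph (8 µm) for
at least 75 % of the movements per axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .core_io import TargetImage
from .preprocess import binarize, mean_filter_rgb, to_grayscale8

__all__ = [
    "CoMRecord",
    "DeviationSet",
    "AccuracyReport",
    "detect_target",
    "com_deviations",
    "accuracy_report",
    "DEFAULT_TOLERANCE_UM",
    "nominal_disc_area_px",
]

# optical resolution of the tomograph; the positioning-accuracy criterion
DEFAULT_TOLERANCE_UM = 8.0


@dataclass(frozen=True)
class CoMRecord:
    """Detected target centroid in physical units."""

    x_com: float  # µm
    y_com: float  # µm
    area_px: int
    image_id: str = ""


@dataclass
class DeviationSet:
    """Per-image CoM deviations from the series mean, with summary statistics."""

    dx: np.ndarray  # µm, per record
    dy: np.ndarray
    records: list[CoMRecord]
    summary: dict = field(default_factory=dict)
    outlier_x: np.ndarray | None = None  # boolean flags, 1.5·IQR rule
    outlier_y: np.ndarray | None = None


@dataclass
class AccuracyReport:
    """Fraction of movements within tolerance and the pass/fail verdict."""

    tolerance_um: float
    fraction_within_x: float
    fraction_within_y: float
    iqr_halfwidth_x: float
    iqr_halfwidth_y: float
    passed: bool


def nominal_disc_area_px(
    diameter_um: float, px_size_x: float, px_size_y: float
) -> float:
    """Expected pixel area of the printed disc, π(d/2)² / (px_x·px_y)."""
    return np.pi * (diameter_um / 2.0) ** 2 / (px_size_x * px_size_y)


def detect_target(
    img: TargetImage,
    *,
    threshold: int = 120,
    filter_radius: int = 2,
    min_area_px: float | None = None,
    max_area_px: float | None = None,
    target_diameter_um: float = 1000.0,
    channel: str = "luminance",
    image_id: str = "",
) -> CoMRecord:
    """Locate the printed disc and return its centre of mass in µm.

    Pipeline: disc mean filter (radius 2 px) on the RGB image →
    8-bit grayscale → binarize (threshold 120, dark target as foreground) →
    8-connected component analysis → drop components outside the particle
    size gate → unweighted centroid of the largest survivor, scaled to µm.

    The size gate defaults to [25 %, 400 %] of the nominal disc area so
    that dust specks and partial shadows are excluded while tolerating
    threshold-driven size changes.  ``channel`` selects luminance (default)
    or a single colour channel for the grayscale step.
    """
    filtered = mean_filter_rgb(img.pixels, filter_radius)
    if channel == "luminance":
        gray = to_grayscale8(filtered)
    elif channel in ("red", "green", "blue"):
        gray = filtered[:, :, "rgb".index(channel[0])]
    else:
        raise ValueError(f"unknown channel {channel!r}")
    mask = binarize(gray, threshold, dark_target=True)

    nominal = nominal_disc_area_px(target_diameter_um, img.px_size_x, img.px_size_y)
    if min_area_px is None:
        min_area_px = 0.25 * nominal
    if max_area_px is None:
        max_area_px = 4.0 * nominal

    comp = measure.label(mask > 0, connectivity=2)
    props = [
        p
        for p in measure.regionprops(comp)
        if min_area_px <= p.area <= max_area_px
    ]
    if not props:
        raise ValueError(f"target not found in image {image_id or '<unnamed>'}")
    props.sort(key=lambda p: p.area, reverse=True)
    if len(props) > 1 and props[1].area >= 0.9 * props[0].area:
        warnings.warn(
            f"ambiguous target in image {image_id or '<unnamed>'}: "
            f"{len(props)} comparable components; choosing the largest",
            stacklevel=2,
        )
    best = props[0]
    cy, cx = best.centroid  # unweighted pixel centroid (row, col)
    # +0.5 puts coordinates at pixel centres, measured from the image edge
    return CoMRecord(
        x_com=(float(cx) + 0.5) * img.px_size_x,
        y_com=(float(cy) + 0.5) * img.px_size_y,
        area_px=int(best.area),
        image_id=image_id,
    )


def _iqr_flags(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """1.5·IQR outlier flags with linearly interpolated quartiles."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (values < lo) | (values > hi), float(lo), float(hi)


def com_deviations(records: list[CoMRecord]) -> DeviationSet:
    """Deviations of each CoM from the series mean, per axis, with summaries.

    Summary statistics per axis: mean (0 by construction), median, sample
    SD (n−1 denominator), min, max, quartiles, and 1.5·IQR outlier flags.
    Requires at least two records.
    """
    if len(records) < 2:
        raise ValueError(f"need >= 2 CoM records, got {len(records)}")
    x = np.array([r.x_com for r in records], dtype=np.float64)
    y = np.array([r.y_com for r in records], dtype=np.float64)
    dx = x - x.mean()
    dy = y - y.mean()
    summary = {}
    flags = {}
    for axis, d in (("x", dx), ("y", dy)):
        out, lo, hi = _iqr_flags(d)
        flags[axis] = out
        q1, q3 = np.percentile(d, [25, 75])
        summary[axis] = {
            "mean": float(d.mean()),
            "median": float(np.median(d)),
            "sd": float(d.std(ddof=1)),
            "min": float(d.min()),
            "max": float(d.max()),
            "q1": float(q1),
            "q3": float(q3),
            "iqr_low": lo,
            "iqr_high": hi,
            "n_outliers": int(out.sum()),
        }
    return DeviationSet(
        dx=dx,
        dy=dy,
        records=list(records),
        summary=summary,
        outlier_x=flags["x"],
        outlier_y=flags["y"],
    )


def accuracy_report(
    dev: DeviationSet, tolerance: float = DEFAULT_TOLERANCE_UM
) -> AccuracyReport:
    """Judge a deviation set against the optical-resolution criterion.

    Reports the per-axis fraction of |Δ| ≤ tolerance and the IQR
    half-width; the run passes when at least 75 % of movements fall within
    the tolerance on both axes.
    """
    if dev.dx.size == 0:
        raise ValueError("empty deviation set")
    fx = float(np.mean(np.abs(dev.dx) <= tolerance))
    fy = float(np.mean(np.abs(dev.dy) <= tolerance))
    hx = (dev.summary["x"]["q3"] - dev.summary["x"]["q1"]) / 2.0
    hy = (dev.summary["y"]["q3"] - dev.summary["y"]["q1"]) / 2.0
    return AccuracyReport(
        tolerance_um=tolerance,
        fraction_within_x=fx,
        fraction_within_y=fy,
        iqr_halfwidth_x=hx,
        iqr_halfwidth_y=hy,
        passed=fx >= 0.75 and fy >= 0.75,
    )
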