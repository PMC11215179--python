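"""Colony segmentation and the five outline indices.

The colony is segmented inside the dish interior by Otsu thresholding,
cleaned by morphological closing, hole filling and largest-component
selection.  From the mask and the dish calibration the pipeline derives

* R  — radius, mm: mean half-extent of the axis-aligned bounding box,
       ``mm_per_px · (ZL + ZS) / 4``;
* L  — perimeter, mm: boundary pixel count rescaled by the dish
       circumference, ``(nv / np) · 2π·Rp``;
* A  — area, mm²: colony-to-dish pixel ratio times dish area,
       ``(NV / NP) · π·Rp²``;
* VR — growth rate (R2−R1)/(t2−t1), mm/day;
* VW — area change speed (A2−A1)/(t2−t1), mm²/day.

Boundary pixels are mask pixels 4-adjacent to background (the 8-connected
contour); the same digitization convention underlies the dish rim count np,
so the ratio nv/np is free of the systematic bias either count carries
alone.  Negative growth is reported as-is (and flagged) rather than clamped:
degenerated strains may regress and clamping would hide data problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_closing, binary_erosion, binary_fill_holes
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.measure import find_contours, label
from skimage.morphology import disk

from .plate_io import DishCalibration, GrayImage

__all__ = [
    "MyceliumMask", "BoundingAxes", "OutlineFeatures", "TimepointPair",
    "segment_mycelium", "trace_boundary", "bounding_axes",
    "radius", "perimeter", "area", "growth_rate", "change_speed",
    "measure_outline",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class MyceliumMask:
    """Cleaned colony mask with its pixel counts (NV, nv)."""

    mask: np.ndarray
    pixel_count: int       # NV
    boundary_count: int    # nv
    empty: bool = False


@dataclass(frozen=True)
class BoundingAxes:
    """Axis-aligned bounding box extents of the colony, in pixels."""

    ZL: int  # horizontal extent (columns)
    ZS: int  # vertical extent (rows)
    corners: tuple[int, int, int, int]  # min_row, min_col, max_row, max_col


@dataclass(frozen=True)
class OutlineFeatures:
    R_mm: float
    L_mm: float
    A_mm2: float
    NV: int
    nv: int
    ZL: int
    ZS: int
    empty: bool = False


@dataclass(frozen=True)
class TimepointPair:
    """Radius/area of one plate at the two observation days."""

    R1: float
    R2: float
    A1: float
    A2: float
    t1: float = 2.0
    t2: float = 8.0

    def __post_init__(self):
        if self.t2 <= self.t1:
            raise ValueError("t2 must be greater than t1")


def _boundary_mask(mask: np.ndarray) -> np.ndarray:
    return mask & ~binary_erosion(mask, structure=_CROSS)


def segment_mycelium(
    image: GrayImage | np.ndarray,
    calib: DishCalibration,
    *,
    polarity: str = "bright",
    min_contrast: float = 10.0,
    erode_rim_px: float = 3.0,
    closing_radius: int = 2,
    min_size_px: int = 16,
) -> MyceliumMask:
    """Segment the colony inside the dish interior.

    ``polarity`` selects whether the colony is brighter or darker than the
    agar background ("bright" is the norm for white mycelium on dark
    medium).  When no gray contrast of at least ``min_contrast`` levels
    separates foreground from background the result is an *empty* mask
    (flagged, not an exception): near-blank degraded plates are legitimate
    inputs.
    """
    if polarity not in ("bright", "dark"):
        raise ValueError("polarity must be 'bright' or 'dark'")
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    interior = calib.interior_mask(pixels.shape, erode_px=erode_rim_px)
    empty = MyceliumMask(np.zeros(pixels.shape, dtype=bool), 0, 0, empty=True)
    vals = pixels[interior]
    if vals.size == 0:
        return empty

    def _saturated_or_empty() -> MyceliumMask:
        # No contrast inside the dish: either blank agar or a colony filling
        # it.  Decide against the gray level outside the dish as background
        # reference (photographs frame the dish on the imaging stage).
        outside = ~calib.interior_mask(pixels.shape, erode_px=-4.0)
        if not outside.any():
            return empty
        ref = float(np.median(pixels[outside]))
        inside = float(np.median(vals))
        covered = (inside - ref >= min_contrast) if polarity == "bright" \
            else (ref - inside >= min_contrast)
        if not covered:
            return empty
        mask = interior
        return MyceliumMask(mask=mask, pixel_count=int(mask.sum()),
                            boundary_count=int(_boundary_mask(mask).sum()))

    if vals.max() == vals.min():
        return _saturated_or_empty()
    # Otsu splits well-balanced histograms; the triangle method covers small
    # faint colonies whose foreground class is too rare for Otsu.  Keep the
    # candidate with the stronger foreground/background separation.
    best_fg, best_contrast = None, 0.0
    for threshold_fn in (threshold_otsu, threshold_triangle):
        thr = threshold_fn(vals)
        fg = (pixels > thr) if polarity == "bright" else (pixels < thr)
        fg &= interior
        if not fg.any() or fg.sum() == vals.size:
            continue
        contrast = abs(float(pixels[fg].mean()) - float(pixels[interior & ~fg].mean()))
        if contrast > best_contrast:
            best_fg, best_contrast = fg, contrast
    if best_fg is None or best_contrast < min_contrast:
        return _saturated_or_empty()
    fg = best_fg

    fg = binary_closing(fg, structure=disk(closing_radius)) & interior
    fg = binary_fill_holes(fg)
    labels = label(fg, connectivity=2)
    if labels.max() == 0:
        return empty
    sizes = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1
    mask = labels == keep
    nv_count = int(mask.sum())
    if nv_count < min_size_px:
        return empty
    return MyceliumMask(mask=mask, pixel_count=nv_count,
                        boundary_count=int(_boundary_mask(mask).sum()))


def trace_boundary(mask: MyceliumMask | np.ndarray) -> tuple[int, np.ndarray]:
    """Boundary pixel count nv and an ordered boundary polyline.

    The polyline comes from sub-pixel contour following at level 0.5 (the
    longest closed contour); the count is the exact number of mask pixels
    4-adjacent to background.
    """
    m = mask.mask if isinstance(mask, MyceliumMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask has no boundary")
    nv = int(_boundary_mask(m).sum())
    contours = find_contours(m.astype(np.float64), 0.5)
    polyline = max(contours, key=len) if contours else np.empty((0, 2))
    return nv, polyline


def bounding_axes(mask: MyceliumMask | np.ndarray) -> BoundingAxes:
    """Extents of the minimum axis-aligned bounding rectangle (ZL, ZS)."""
    m = mask.mask if isinstance(mask, MyceliumMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask has no bounding axes")
    rows, cols = np.nonzero(m)
    r0, r1 = int(rows.min()), int(rows.max())
    c0, c1 = int(cols.min()), int(cols.max())
    return BoundingAxes(ZL=c1 - c0 + 1, ZS=r1 - r0 + 1, corners=(r0, c0, r1, c1))


def radius(axes: BoundingAxes, calib: DishCalibration) -> float:
    """Colony radius R in mm: the mean of the two bounding half-extents."""
    return calib.mm_per_px * (axes.ZL + axes.ZS) / 4.0


def perimeter(mask: MyceliumMask, calib: DishCalibration) -> float:
    """Colony perimeter L in mm via the dish-circumference rescaling."""
    if mask.pixel_count == 0:
        raise ValueError("empty mask has no perimeter")
    return (mask.boundary_count / calib.rim_pixel_count) * 2.0 * np.pi * calib.dish_radius_mm


def area(mask: MyceliumMask, calib: DishCalibration) -> float:
    """Colony area A in mm² via the colony-to-dish pixel ratio."""
    return (mask.pixel_count / calib.interior_pixel_count) * np.pi * calib.dish_radius_mm ** 2


def growth_rate(pair: TimepointPair) -> float:
    """Radial growth rate VR in mm/day; negative values are flagged."""
    vr = (pair.R2 - pair.R1) / (pair.t2 - pair.t1)
    if vr < 0:
        warnings.warn("negative growth rate (colony shrank between timepoints)")
    return vr


def change_speed(pair: TimepointPair) -> float:
    """Area change speed VW in mm²/day; negative values are flagged."""
    vw = (pair.A2 - pair.A1) / (pair.t2 - pair.t1)
    if vw < 0:
        warnings.warn("negative area change speed (colony shrank between timepoints)")
    return vw


def measure_outline(
    image: GrayImage | np.ndarray,
    calib: DishCalibration,
    mask: MyceliumMask | None = None,
    **segment_kwargs,
) -> OutlineFeatures:
    """Segment (unless a mask is given) and compute R, L, A for one image."""
    if mask is None:
        mask = segment_mycelium(image, calib, **segment_kwargs)
    if mask.empty or mask.pixel_count == 0:
        return OutlineFeatures(0.0, 0.0, 0.0, 0, 0, 0, 0, empty=True)
    axes = bounding_axes(mask)
    return OutlineFeatures(
        R_mm=radius(axes, calib),
        L_mm=perimeter(mask, calib),
        A_mm2=area(mask, calib),
        NV=mask.pixel_count, nv=mask.boundary_count,
        ZL=axes.ZL, ZS=axes.ZS,
    )
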