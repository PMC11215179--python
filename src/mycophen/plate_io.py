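"""Image loading and Petri-dish calibration.

Every physical index in the pipeline is denominated through the dish: the
fitted rim supplies the mm-per-pixel scale, the rim pixel count ``np`` used
by the perimeter formula L = (nv/np)·2πRp, and the interior pixel count
``NP`` used by area A = (NV/NP)·πRp² and coverage.  Rp is the physical dish
*radius* (45 mm for the standard 90-mm dish).

Dish detection is pluggable: the default ``otsu_hough`` detector thresholds
the Sobel edge magnitude with Otsu's method, runs a coarse circular Hough
transform on a downsampled edge map, and refines the winning circle by a
least-squares fit to the full-resolution edge pixels near the rim.  A
``provided_mask`` detector accepts a known dish mask instead (useful when
ground truth is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import circle_perimeter
from skimage.filters import sobel, threshold_otsu
from skimage.measure import block_reduce
from skimage.transform import hough_circle, hough_circle_peaks


class DishDetectionError(RuntimeError):
    """No dish-like circular rim could be located."""


class AmbiguousDishError(DishDetectionError):
    """More than one plausible dish rim; candidates listed as (row, col, radius)."""

    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(f"multiple dish rim candidates: {candidates}")


@dataclass(frozen=True)
class GrayImage:
    """8-bit grayscale raster, row-major, origin top-left."""

    pixels: np.ndarray
    path: Path | None = None

    def __post_init__(self):
        p = self.pixels
        if p.ndim != 2:
            raise ValueError("GrayImage.pixels must be 2-D")
        if p.dtype != np.uint8:
            raise ValueError("GrayImage.pixels must be uint8")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class DishCalibration:
    """Fitted dish geometry and the pixel counts used by the index formulas."""

    center: tuple[float, float]        # (row, col)
    diameter_px: float
    rim_pixel_count: int               # np: 1-px digitized circle at the fitted radius
    interior_pixel_count: int          # NP: pixels with distance <= fitted radius
    dish_radius_mm: float = 45.0

    @property
    def radius_px(self) -> float:
        return self.diameter_px / 2.0

    @property
    def mm_per_px(self) -> float:
        return 2.0 * self.dish_radius_mm / self.diameter_px

    def interior_mask(self, shape: tuple[int, int], erode_px: float = 0.0) -> np.ndarray:
        """Boolean mask of pixels at distance <= radius - erode_px from the centre."""
        dy = np.arange(shape[0], dtype=np.float64)[:, None] - self.center[0]
        dx = np.arange(shape[1], dtype=np.float64)[None, :] - self.center[1]
        return np.hypot(dy, dx) <= self.radius_px - erode_px

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "diameter_px": self.diameter_px,
            "np": self.rim_pixel_count,
            "NP": self.interior_pixel_count,
            "dish_radius_mm": self.dish_radius_mm,
            "mm_per_px": self.mm_per_px,
        }


def load_grayscale(path: str | Path) -> GrayImage:
    """Load a PNG/TIFF/BMP image as 8-bit grayscale.

    Multi-channel images are converted by the unweighted channel average
    (alpha, if present, is ignored).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # truncated / unreadable raster
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr.mean(axis=2)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr.astype(np.float64)), 0, 255).astype(np.uint8)
    if arr.shape[0] < 64 or arr.shape[1] < 64:
        raise ValueError(f"image too small ({arr.shape[1]}x{arr.shape[0]}); need >= 64 px per side")
    return GrayImage(pixels=arr, path=path)


def _rasterized_circle_count(center: tuple[float, float], radius: float,
                             shape: tuple[int, int]) -> int:
    """Pixel count of the 1-px midpoint (Bresenham) circle at the fitted radius."""
    rr, cc = circle_perimeter(int(round(center[0])), int(round(center[1])),
                              int(round(radius)), method="bresenham", shape=shape)
    return len(np.unique(rr.astype(np.int64) * shape[1] + cc.astype(np.int64)))


def _kasa_fit(ys: np.ndarray, xs: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares circle fit; returns (row, col, radius)."""
    A = np.column_stack([ys, xs, np.ones_like(ys)])
    b = ys ** 2 + xs ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cy, cx = sol[0] / 2.0, sol[1] / 2.0
    r = float(np.sqrt(sol[2] + cy ** 2 + cx ** 2))
    return float(cy), float(cx), r


def detect_dish(
    image: GrayImage | np.ndarray,
    *,
    dish_radius_mm: float = 45.0,
    detector: str = "otsu_hough",
    dish_mask: np.ndarray | None = None,
    rim_search_band_px: float | None = None,
    min_radius_frac: float = 0.18,
    max_radius_frac: float = 0.49,
    min_accum: float = 0.30,
) -> DishCalibration:
    """Locate the dish rim and build the pixel-to-mm calibration.

    Raises :class:`DishDetectionError` when no circular rim is found and
    :class:`AmbiguousDishError` when several incompatible rims score equally
    well.
    """
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    shape = pixels.shape

    if detector == "provided_mask":
        if dish_mask is None:
            raise ValueError("detector='provided_mask' requires dish_mask")
        if not dish_mask.any():
            raise DishDetectionError("provided dish mask is empty")
        ys, xs = np.nonzero(dish_mask)
        cy, cx = float(ys.mean()), float(xs.mean())
        r = float(np.sqrt(dish_mask.sum() / np.pi))
        return DishCalibration(
            center=(cy, cx), diameter_px=2 * r,
            rim_pixel_count=_rasterized_circle_count((cy, cx), r, shape),
            interior_pixel_count=int(dish_mask.sum()),
            dish_radius_mm=dish_radius_mm,
        )
    if detector != "otsu_hough":
        raise ValueError(f"unknown detector: {detector!r}")

    gray = pixels.astype(np.float64) / 255.0
    edges = sobel(gray)
    if edges.max() < 1e-3:
        raise DishDetectionError("no edges found (blank image?)")
    # half the Otsu level: a bright colony must not out-shout the dish rim
    edge_mask = edges > 0.5 * threshold_otsu(edges)

    ds = max(1, min(shape) // 128)
    # block-max pooling keeps every rim pixel represented in the coarse map
    small = block_reduce(edge_mask, (ds, ds), np.max) if ds > 1 else edge_mask
    r_lo = max(8, int(min_radius_frac * min(shape) / ds))
    r_hi = max(r_lo + 2, int(max_radius_frac * min(shape) / ds))
    radii = np.arange(r_lo, r_hi + 1, 2 if ds == 1 else 1)
    hspaces = hough_circle(small, radii)

    # The dish is the *outermost* strong circle: textured colony interiors
    # support many spurious high-score small circles, so scan the normalized
    # accumulator from the largest radius downwards and stop at the first
    # radius carrying a near-complete circle.
    flat = hspaces.reshape(len(radii), -1)
    best_per_radius = flat.max(axis=1)
    global_best = float(best_per_radius.max())
    if global_best < min_accum:
        raise DishDetectionError("no circular rim found")
    qualifying = np.nonzero(best_per_radius >= max(min_accum, 0.85 * global_best))[0]
    i = int(qualifying[-1])
    plane = hspaces[i]
    cy_s, cx_s = np.unravel_index(int(plane.argmax()), plane.shape)
    r_s = float(radii[i])

    # a second, clearly separated strong centre at the same radius means
    # more than one dish-like rim in the frame
    yy, xx = np.ogrid[:plane.shape[0], :plane.shape[1]]
    suppressed = plane.copy()
    suppressed[np.hypot(yy - cy_s, xx - cx_s) <= 0.5 * r_s] = 0.0
    if suppressed.max() >= 0.9 * plane[cy_s, cx_s]:
        cy2, cx2 = np.unravel_index(int(suppressed.argmax()), plane.shape)
        raise AmbiguousDishError([
            (float(cy_s) * ds, float(cx_s) * ds, r_s * ds),
            (float(cy2) * ds, float(cx2) * ds, r_s * ds)])

    cy0, cx0, r0 = float(cy_s) * ds, float(cx_s) * ds, r_s * ds
    band = rim_search_band_px if rim_search_band_px is not None else max(4.0, 2.0 * ds + 2.0)
    dy = np.arange(shape[0], dtype=np.float64)[:, None] - cy0
    dx = np.arange(shape[1], dtype=np.float64)[None, :] - cx0
    dist = np.hypot(dy, dx)
    sel = edge_mask & (np.abs(dist - r0) <= band)
    if sel.sum() < 16:
        raise DishDetectionError("too few rim edge pixels for refinement")
    ys, xs = np.nonzero(sel)
    cy, cx, r = _kasa_fit(ys.astype(np.float64), xs.astype(np.float64))

    interior = np.hypot(
        np.arange(shape[0], dtype=np.float64)[:, None] - cy,
        np.arange(shape[1], dtype=np.float64)[None, :] - cx) <= r
    return DishCalibration(
        center=(cy, cx), diameter_px=2 * r,
        rim_pixel_count=_rasterized_circle_count((cy, cx), r, shape),
        interior_pixel_count=int(interior.sum()),
        dish_radius_mm=dish_radius_mm,
    )
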