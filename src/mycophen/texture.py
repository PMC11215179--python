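"""The five texture indices: coverage, roundness, groove depth, density, density change.

Groove depth is the contrast statistic of a gray-level co-occurrence matrix
(GLCM) computed over the colony region: radial grooves in the mycelium mat
produce alternating bright/dark ridges, and the expected squared gray-level
difference of neighbouring pixels grows monotonically with ridge amplitude.

The GLCM here is region-restricted — both pixels of a pair must lie inside
the supplied mask — which the stock rectangular-window implementations do
not support, so the co-occurrence counting is done directly (vectorised
over pixel pairs).  Defaults: 8 quantization levels over [0, 255], the four
unit offsets (0,1),(1,0),(1,1),(1,−1) averaged, symmetric, normalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .outline import MyceliumMask, OutlineFeatures
from .plate_io import DishCalibration, GrayImage

__all__ = [
    "GlcmSpec", "TextureFeatures",
    "coverage", "roundness", "glcm", "groove_depth",
    "density", "density_change", "measure_texture",
]

DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class GlcmSpec:
    """Configuration of the co-occurrence matrix behind the groove-depth index."""

    levels: int = 8
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if not self.offsets:
            raise ValueError("at least one offset required")
        for off in self.offsets:
            if tuple(off) == (0, 0):
                raise ValueError("offset (0, 0) is not allowed")

    def to_dict(self) -> dict:
        return {"levels": self.levels, "offsets": [list(o) for o in self.offsets],
                "symmetric": self.symmetric, "normalize": self.normalize}


@dataclass(frozen=True)
class TextureFeatures:
    WF_pct: float   # coverage, % of dish interior
    WP: float       # roundness L^2/(4πA)
    WC: float       # groove depth, GLCM contrast
    WB: float       # density, mean gray over the colony
    glcm_spec: GlcmSpec = GlcmSpec()


def coverage(mask: MyceliumMask, calib: DishCalibration) -> float:
    """WF: percentage of the dish interior covered by the colony."""
    if calib.interior_pixel_count == 0:
        raise ValueError("calibration has zero dish interior pixels")
    return 100.0 * mask.pixel_count / calib.interior_pixel_count


def roundness(L_mm: float, A_mm2: float) -> float:
    """WP = L²/(4πA): 1 for a perfect disk, larger for irregular outlines."""
    if A_mm2 <= 0:
        raise ValueError("area must be positive")
    return L_mm ** 2 / (4.0 * np.pi * A_mm2)


def _quantize(pixels: np.ndarray, levels: int) -> np.ndarray:
    # equal bins over [0, 255]; level = floor(g * levels / 256)
    return (pixels.astype(np.int64) * levels) // 256


def glcm(
    image: GrayImage | np.ndarray,
    region: np.ndarray | None = None,
    spec: GlcmSpec = GlcmSpec(),
) -> np.ndarray:
    """Region-restricted co-occurrence matrix, shape (levels, levels, n_offsets).

    A pixel pair contributes only if both ends lie inside ``region``.
    Raises when the region is empty or yields no valid pair at some offset.
    """
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    if pixels.ndim != 2:
        raise ValueError("image must be a 2-D raster")
    if region is None:
        region = np.ones(pixels.shape, dtype=bool)
    if region.shape != pixels.shape:
        raise ValueError("region shape must match image shape")
    if not region.any():
        raise ValueError("empty region")
    q = _quantize(pixels, spec.levels)
    nrow, ncol = pixels.shape
    out = np.zeros((spec.levels, spec.levels, len(spec.offsets)), dtype=np.float64)
    for k, (dr, dc) in enumerate(spec.offsets):
        r0, r1 = max(0, -dr), min(nrow, nrow - dr)
        c0, c1 = max(0, -dc), min(ncol, ncol - dc)
        if r0 >= r1 or c0 >= c1:
            raise ValueError(f"offset {(dr, dc)} larger than the image")
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = region[r0:r1, c0:c1] & region[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        if not valid.any():
            raise ValueError(f"no valid pixel pairs in region at offset {(dr, dc)}")
        counts = np.bincount(a[valid] * spec.levels + b[valid],
                             minlength=spec.levels ** 2).astype(np.float64)
        P = counts.reshape(spec.levels, spec.levels)
        if spec.symmetric:
            P = P + P.T
        if spec.normalize:
            P = P / P.sum()
        out[:, :, k] = P
    return out


def groove_depth(matrix: np.ndarray, spec: GlcmSpec = GlcmSpec()) -> float:
    """WC: GLCM contrast Σ (g1−g2)²·P(g1,g2), averaged over the offsets."""
    P = np.asarray(matrix, dtype=np.float64)
    if P.ndim == 2:
        P = P[:, :, None]
    sums = P.sum(axis=(0, 1))
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("groove_depth requires a normalized co-occurrence matrix")
    n = P.shape[0]
    g = np.arange(n, dtype=np.float64)
    w = (g[:, None] - g[None, :]) ** 2
    return float(np.mean([(w * P[:, :, k]).sum() for k in range(P.shape[2])]))


def density(image: GrayImage | np.ndarray, mask: MyceliumMask | np.ndarray) -> float:
    """WB: mean gray level over the colony mask (0–255; brighter = denser)."""
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    m = mask.mask if isinstance(mask, MyceliumMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask has no density")
    return float(pixels[m].mean())


def density_change(WB1: float, WB2: float, t1: float = 2.0, t2: float = 8.0) -> float:
    """WS = (WB2 − WB1)/(t2 − t1), gray levels per day."""
    if t2 <= t1:
        raise ValueError("t2 must be greater than t1")
    return (WB2 - WB1) / (t2 - t1)


def measure_texture(
    image: GrayImage | np.ndarray,
    mask: MyceliumMask,
    calib: DishCalibration,
    outline: OutlineFeatures,
    spec: GlcmSpec = GlcmSpec(),
) -> TextureFeatures:
    """All single-image texture indices for one segmented plate."""
    wf = coverage(mask, calib)
    wp = roundness(outline.L_mm, outline.A_mm2) if outline.A_mm2 > 0 else float("nan")
    wc = groove_depth(glcm(image, mask.mask, spec), spec)
    wb = density(image, mask)
    return TextureFeatures(WF_pct=wf, WP=wp, WC=wc, WB=wb, glcm_spec=spec)
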