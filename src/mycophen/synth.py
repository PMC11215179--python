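"""Synthetic Petri-dish plate generator with pixel-exact ground truth.

Renders 8-bit grayscale plates that emulate the imaging setup used for
mycelium phenotyping: a dark dish rim of known physical diameter, a roughly
elliptical colony grown from the dish centre, radial groove texture
(sinusoidal in polar angle), and additive Gaussian noise.  Every plate comes
with boolean ground-truth masks and analytic geometry so the measurement
pipeline can be validated without any real photographs.

Four strain-group presets (non-degenerated, 5th and 14th subculture,
degenerated) are shipped as qualitative defaults: the 14th subculture grows
largest but sparsest/darkest with shallow grooves, the degenerated strain
grows smallest but stays dense and grooved.  The preset numbers are free
parameters of the generator, not measurements.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ColonySpec",
    "GroundTruth",
    "TimepointPlate",
    "GroupPreset",
    "DEFAULT_GROUPS",
    "render_plate",
    "render_timepair",
    "make_cohort",
]


@dataclass(frozen=True)
class ColonySpec:
    """Parameters of one rendered plate.

    Lengths are millimetres unless the name says ``_px``; gray levels are on
    the 8-bit scale.  ``groove_count`` is the number of radial grooves per
    revolution and ``groove_amplitude`` the peak intensity modulation they
    impose on the colony interior.
    """

    image_width: int = 1280
    image_height: int = 980
    dish_center: tuple[float, float] | None = None  # (row, col); None = image centre
    dish_diameter_px: float = 800.0
    dish_physical_diameter: float = 90.0
    colony_semi_axis_h: float = 15.0
    colony_semi_axis_v: float = 15.0
    colony_base_gray: float = 170.0
    background_gray: float = 55.0
    rim_gray: float = 15.0
    rim_width_px: float = 3.0
    groove_amplitude: float = 0.0
    groove_count: int = 24
    groove_phase: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    @property
    def center(self) -> tuple[float, float]:
        if self.dish_center is not None:
            return self.dish_center
        return ((self.image_height - 1) / 2.0, (self.image_width - 1) / 2.0)

    @property
    def mm_per_px(self) -> float:
        return self.dish_physical_diameter / self.dish_diameter_px

    def validate(self) -> None:
        if self.dish_diameter_px <= 0:
            raise ValueError("dish_diameter_px must be > 0")
        r = self.dish_diameter_px / 2.0
        cy, cx = self.center
        if (cy - r < -0.5 or cx - r < -0.5
                or cy + r > self.image_height - 0.5 or cx + r > self.image_width - 0.5):
            raise ValueError("dish_diameter_px/dish_center: dish does not fit inside the image frame")
        dish_radius_mm = self.dish_physical_diameter / 2.0
        if self.colony_semi_axis_h <= 0 or self.colony_semi_axis_h > dish_radius_mm:
            raise ValueError("colony_semi_axis_h must be in (0, dish radius]")
        if self.colony_semi_axis_v <= 0 or self.colony_semi_axis_v > dish_radius_mm:
            raise ValueError("colony_semi_axis_v must be in (0, dish radius]")
        for name in ("colony_base_gray", "background_gray", "rim_gray"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must be in [0, 255]")
        if self.groove_amplitude < 0:
            raise ValueError("groove_amplitude must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.image_width < 64 or self.image_height < 64:
            raise ValueError("image_width/image_height must be >= 64 px")

    def same_dish_geometry(self, other: "ColonySpec") -> bool:
        return (self.image_width == other.image_width
                and self.image_height == other.image_height
                and self.center == other.center
                and self.dish_diameter_px == other.dish_diameter_px
                and self.dish_physical_diameter == other.dish_physical_diameter)


@dataclass
class GroundTruth:
    """Analytic truth for one rendered plate."""

    colony_mask: np.ndarray
    dish_mask: np.ndarray
    true_radius_mm: float      # mean of the two semi-axes
    true_area_mm2: float       # colony mask pixel count x mm_per_px^2
    true_perimeter_mm: float   # analytic ellipse perimeter (Ramanujan)
    true_mean_gray: float      # mean rendered gray over the colony mask
    mm_per_px: float

    def to_dict(self) -> dict:
        return {
            "true_radius_mm": self.true_radius_mm,
            "true_area_mm2": self.true_area_mm2,
            "true_perimeter_mm": self.true_perimeter_mm,
            "true_mean_gray": self.true_mean_gray,
            "mm_per_px": self.mm_per_px,
        }


@dataclass(frozen=True)
class TimepointPlate:
    day: int
    image: np.ndarray
    truth: GroundTruth
    spec: ColonySpec


def _ellipse_perimeter_mm(a: float, b: float) -> float:
    # Ramanujan's second approximation; exact to float precision for circles
    h = ((a - b) / (a + b)) ** 2
    return float(np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h))))


def render_plate(spec: ColonySpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one plate; identical spec+seed gives bit-identical pixels.

    Returns the uint8 image and its :class:`GroundTruth`.  The dish rim is a
    thin annulus whose gray level differs from both the background and the
    dish interior, so edge-based dish detection has something to find.
    """
    spec.validate()
    cy, cx = spec.center
    rows = np.arange(spec.image_height, dtype=np.float64)[:, None]
    cols = np.arange(spec.image_width, dtype=np.float64)[None, :]
    dy = rows - cy
    dx = cols - cx
    dist = np.hypot(dy, dx)
    r_dish = spec.dish_diameter_px / 2.0

    img = np.full((spec.image_height, spec.image_width), spec.background_gray, dtype=np.float64)
    dish_mask = dist <= r_dish

    a_px = spec.colony_semi_axis_h / spec.mm_per_px
    b_px = spec.colony_semi_axis_v / spec.mm_per_px
    colony_mask = (dx / a_px) ** 2 + (dy / b_px) ** 2 <= 1.0
    colony_mask &= dish_mask

    img[colony_mask] = spec.colony_base_gray
    if spec.groove_amplitude > 0:
        theta = np.arctan2(dy, dx)
        grooves = spec.groove_amplitude * np.sin(spec.groove_count * theta + spec.groove_phase)
        img[colony_mask] += grooves[colony_mask]

    rim = np.abs(dist - r_dish) <= spec.rim_width_px / 2.0
    img[rim] = spec.rim_gray

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img += rng.normal(0.0, spec.noise_sigma, img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        colony_mask=colony_mask,
        dish_mask=dish_mask,
        true_radius_mm=(spec.colony_semi_axis_h + spec.colony_semi_axis_v) / 2.0,
        true_area_mm2=float(colony_mask.sum()) * spec.mm_per_px ** 2,
        true_perimeter_mm=_ellipse_perimeter_mm(spec.colony_semi_axis_h, spec.colony_semi_axis_v),
        true_mean_gray=float(img[colony_mask].mean()) if colony_mask.any() else float("nan"),
        mm_per_px=spec.mm_per_px,
    )
    return img, truth


def render_timepair(
    spec_t1: ColonySpec,
    spec_t2: ColonySpec,
    days: tuple[int, int] = (2, 8),
) -> tuple[TimepointPlate, TimepointPlate]:
    """Render the two observation timepoints (default days 2 and 8).

    Both specs must share the dish geometry: the pair models the same plate
    photographed twice.
    """
    if not spec_t1.same_dish_geometry(spec_t2):
        raise ValueError("spec_t1 and spec_t2 must share dish geometry "
                         "(image size, dish_center, dish_diameter_px, dish_physical_diameter)")
    if days[1] <= days[0]:
        raise ValueError("days must be increasing")
    img1, gt1 = render_plate(spec_t1)
    img2, gt2 = render_plate(spec_t2)
    return (TimepointPlate(days[0], img1, gt1, spec_t1),
            TimepointPlate(days[1], img2, gt2, spec_t2))


@dataclass(frozen=True)
class GroupPreset:
    """Per-group sampling ranges for cohort simulation (uniform draws)."""

    radius_day2_mm: tuple[float, float]
    radius_day8_mm: tuple[float, float]
    base_gray_day8: tuple[float, float]
    density_rise_gray: tuple[float, float]   # gray gained between day 2 and day 8
    groove_amplitude: tuple[float, float]
    groove_count: tuple[int, int] = (20, 28)
    axis_ratio: tuple[float, float] = (0.88, 1.0)  # minor/major semi-axis
    noise_sigma: float = 3.0

    _RANGE_FIELDS = ("radius_day2_mm", "radius_day8_mm", "base_gray_day8",
                     "density_rise_gray", "groove_amplitude", "groove_count", "axis_ratio")

    def validate(self, name: str = "group") -> None:
        for f in self._RANGE_FIELDS:
            lo, hi = getattr(self, f)
            if hi < lo:
                raise ValueError(f"{name}.{f}: range upper bound below lower bound")
        if self.noise_sigma < 0:
            raise ValueError(f"{name}.noise_sigma must be >= 0")


# Qualitative ordering follows the four strain groups: the 14th subculture
# largest / sparsest / darkest with the shallowest grooves; the degenerated
# strain smallest but dense, bright and clearly grooved.
DEFAULT_GROUPS: dict[str, GroupPreset] = {
    "X2-N": GroupPreset((6.5, 8.5), (27.0, 32.0), (150.0, 175.0), (8.0, 12.0), (22.0, 30.0)),
    "X2-5": GroupPreset((6.0, 8.0), (24.0, 29.0), (105.0, 130.0), (4.0, 8.0), (12.0, 18.0)),
    "X2-14": GroupPreset((6.5, 8.5), (30.0, 35.0), (75.0, 100.0), (1.0, 4.0), (5.0, 10.0)),
    "X2-T": GroupPreset((5.0, 7.0), (15.0, 19.5), (120.0, 148.0), (6.0, 9.0), (18.0, 24.0)),
}


def _write_png(path: Path, arr: np.ndarray) -> None:
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def make_cohort(
    outdir: str | Path,
    group_params: Mapping[str, GroupPreset] | None = None,
    n_per_group: int = 30,
    seed: int = 0,
    days: Sequence[int] = (2, 8),
    image_width: int = 640,
    image_height: int = 512,
    dish_diameter_px: float = 420.0,
    dish_physical_diameter: float = 90.0,
    write_masks: bool = True,
) -> pd.DataFrame:
    """Simulate a multi-group cohort and write it to ``outdir``.

    Writes one grayscale PNG per (sample, day), a ground-truth JSON sidecar
    (plus 0/255 mask PNGs unless ``write_masks=False``), and ``manifest.csv``
    with columns sample_id, group, day, image_path.  Returns the manifest.
    Identical arguments produce byte-identical output.
    """
    groups = dict(DEFAULT_GROUPS if group_params is None else group_params)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if len(days) != 2 or days[1] <= days[0]:
        raise ValueError("days must be two increasing day numbers")
    for name, preset in groups.items():
        preset.validate(name)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for gname in groups:  # insertion order: reproducible
        preset = groups[gname]
        for i in range(n_per_group):
            sample_id = f"{gname}-{i:03d}"
            u = rng.uniform
            r2 = u(*preset.radius_day2_mm)
            r8 = max(u(*preset.radius_day8_mm), r2 + 0.5)
            g8 = u(*preset.base_gray_day8)
            g2 = g8 - u(*preset.density_rise_gray)
            amp = u(*preset.groove_amplitude)
            gcount = int(rng.integers(preset.groove_count[0], preset.groove_count[1] + 1))
            ratio = u(*preset.axis_ratio)
            phase = u(0, 2 * np.pi)
            for day, r_mm, gray in ((days[0], r2, g2), (days[1], r8, g8)):
                sub_seed = int(rng.integers(0, 2**31 - 1))
                spec = ColonySpec(
                    image_width=image_width,
                    image_height=image_height,
                    dish_diameter_px=dish_diameter_px,
                    dish_physical_diameter=dish_physical_diameter,
                    colony_semi_axis_h=r_mm,
                    colony_semi_axis_v=r_mm * ratio,
                    colony_base_gray=float(np.clip(gray, 0, 255)),
                    groove_amplitude=amp,
                    groove_count=gcount,
                    groove_phase=phase,
                    noise_sigma=preset.noise_sigma,
                    seed=sub_seed,
                )
                img, truth = render_plate(spec)
                stem = f"{sample_id}_d{day}"
                img_path = outdir / f"{stem}.png"
                _write_png(img_path, img)
                sidecar = truth.to_dict()
                sidecar.update({
                    "sample_id": sample_id, "group": gname, "day": int(day),
                    "dish_center": list(spec.center),
                    "dish_diameter_px": spec.dish_diameter_px,
                    "spec": {k: v for k, v in dataclasses.asdict(spec).items()},
                })
                if write_masks:
                    _write_png(outdir / f"{stem}_colony_mask.png",
                               truth.colony_mask.astype(np.uint8) * 255)
                    _write_png(outdir / f"{stem}_dish_mask.png",
                               truth.dish_mask.astype(np.uint8) * 255)
                    sidecar["colony_mask_path"] = f"{stem}_colony_mask.png"
                    sidecar["dish_mask_path"] = f"{stem}_dish_mask.png"
                with open(outdir / f"{stem}.json", "w") as fh:
                    json.dump(sidecar, fh, indent=1, sort_keys=True)
                rows.append({"sample_id": sample_id, "group": gname,
                             "day": int(day), "image_path": img_path.name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
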