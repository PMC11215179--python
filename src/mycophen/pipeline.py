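"""Batch orchestration: analyze a manifest of plate images into feature tables.

One row per (sample, day) with all single-image indices; samples imaged at
both observation days additionally yield the paired rates VR, VW, WS.
Per-sample failures (missing or unreadable images, no dish found) are
recorded and the run continues.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import outline, plate_io, texture

OUTLINE_FEATURES = ["R_mm", "L_mm", "A_mm2", "VR_mm_per_d", "VW_mm2_per_d"]
TEXTURE_FEATURES = ["WF_pct", "WP", "WC", "WB", "WS_gray_per_d"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable settings of the per-image measurement chain."""

    dish_radius_mm: float = 45.0
    detector: str = "otsu_hough"
    rim_search_band_px: float | None = None
    polarity: str = "bright"
    min_contrast: float = 10.0
    erode_rim_px: float = 3.0
    closing_radius: int = 2
    min_size_px: int = 16
    glcm_levels: int = 8
    glcm_offsets: tuple[tuple[int, int], ...] = texture.DEFAULT_OFFSETS
    day_pair: tuple[int, int] = (2, 8)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown analysis config keys: {sorted(bad)}")
        if "glcm_offsets" in raw:
            raw["glcm_offsets"] = tuple(tuple(o) for o in raw["glcm_offsets"])
        if "day_pair" in raw:
            raw["day_pair"] = tuple(raw["day_pair"])
        return cls(**raw)

    @property
    def glcm_spec(self) -> texture.GlcmSpec:
        return texture.GlcmSpec(levels=self.glcm_levels, offsets=self.glcm_offsets)


def analyze_image(path: str | Path, config: AnalysisConfig = AnalysisConfig()) -> dict:
    """Measure every single-image index on one plate photograph."""
    img = plate_io.load_grayscale(path)
    calib = plate_io.detect_dish(
        img, dish_radius_mm=config.dish_radius_mm, detector=config.detector,
        rim_search_band_px=config.rim_search_band_px)
    mask = outline.segment_mycelium(
        img, calib, polarity=config.polarity, min_contrast=config.min_contrast,
        erode_rim_px=config.erode_rim_px, closing_radius=config.closing_radius,
        min_size_px=config.min_size_px)
    feats = outline.measure_outline(img, calib, mask=mask)
    row = {
        "R_mm": feats.R_mm, "L_mm": feats.L_mm, "A_mm2": feats.A_mm2,
        "NV": feats.NV, "nv": feats.nv, "ZL": feats.ZL, "ZS": feats.ZS,
        "empty": feats.empty,
        "mm_per_px": calib.mm_per_px,
    }
    if feats.empty:
        row.update({"WF_pct": 0.0, "WP": float("nan"),
                    "WC": float("nan"), "WB": float("nan")})
    else:
        tex = texture.measure_texture(img, mask, calib, feats, config.glcm_spec)
        row.update({"WF_pct": tex.WF_pct, "WP": tex.WP, "WC": tex.WC, "WB": tex.WB})
    return row


def load_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    required = {"sample_id", "group", "day", "image_path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if manifest.empty:
        raise ValueError("manifest is empty")
    if manifest.duplicated(["sample_id", "day"]).any():
        raise ValueError("manifest has duplicate (sample_id, day) rows")
    return manifest


def analyze_manifest(
    manifest: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
    base_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Run the measurement chain over a manifest.

    Returns (features, paired, failures): per-image feature rows, paired
    day-to-day rates joined on sample_id, and per-row failure records.
    Image paths are resolved relative to ``base_dir`` when given.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    base = Path(base_dir) if base_dir is not None else None
    rows, failures = [], []
    for rec in manifest.to_dict("records"):
        path = Path(rec["image_path"])
        if base is not None and not path.is_absolute():
            path = base / path
        try:
            row = analyze_image(path, config)
        except Exception as exc:
            failures.append({"sample_id": rec["sample_id"], "day": rec["day"],
                             "image_path": str(path), "error": str(exc)})
            continue
        rows.append({"sample_id": rec["sample_id"], "group": rec["group"],
                     "day": int(rec["day"]), **row})
    features = pd.DataFrame(rows)

    paired_rows = []
    if not features.empty:
        d1, d2 = config.day_pair
        dt = d2 - d1
        f1 = features[features["day"] == d1].set_index("sample_id")
        f2 = features[features["day"] == d2].set_index("sample_id")
        for sid in f1.index.intersection(f2.index):
            a, b = f1.loc[sid], f2.loc[sid]
            if a["empty"] or b["empty"]:
                continue
            pair = outline.TimepointPair(R1=a["R_mm"], R2=b["R_mm"],
                                         A1=a["A_mm2"], A2=b["A_mm2"], t1=d1, t2=d2)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")  # negative rates already visible in the table
                vr = outline.growth_rate(pair)
                vw = outline.change_speed(pair)
            paired_rows.append({
                "sample_id": sid, "group": b["group"], "t1": d1, "t2": d2,
                "VR_mm_per_d": vr, "VW_mm2_per_d": vw,
                "WS_gray_per_d": texture.density_change(a["WB"], b["WB"], d1, d2),
            })
    paired = pd.DataFrame(paired_rows)
    return features, paired, failures


def day8_table(features: pd.DataFrame, paired: pd.DataFrame,
               day: int = 8) -> pd.DataFrame:
    """Merge day-8 single-image indices with the paired rates, one row per sample."""
    f = features[(features["day"] == day) & (~features["empty"])].copy()
    if paired.empty:
        return f
    return f.merge(paired.drop(columns=["group", "t1", "t2"], errors="ignore"),
                   on="sample_id", how="left")
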