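"""Enzyme-activity calculators: cellulase (anthrone method) and laccase (ABTS).

Cellulase activity is derived from the absorbance difference ΔA = A+ − A− of
measurement and control tubes read at 620 nm.  The anthrone standard curve
y = 2.5090·x − 0.0462 (x in mg/mL glucose) is inverted, scaled to the
reaction and extraction volumes, and normalised per minute and per gram of
fresh tissue:

    VCL = 1000 · (ΔA − b)/a · βf · (βt/βs) / (T·W)     [μg glucose / min / g]

With the default parameters (a = 2.5090, βf = 0.6 mL, βs = 0.05 mL,
βt = 1 mL, T = 60 min) the composed prefactor is 79.71 per unit ΔA·W⁻¹.

Laccase activity uses the published simplified endpoint form

    VLac = 78.52 · ΔA / W                              [nmol ABTS / min / g]

A parameter-composed pathway (extinction coefficient ε = 36 L/mmol/cm, path
d = 0.5 cm, βf = 0.3 mL, βs = 0.045 mL, βt = 1 mL, T = 20 min) is available
via ``use_simplified=False``; its constant (18.52) does not reconcile with
the published 78.52 and is provided for transparency only.

Negative ΔA passes through unclamped so quality problems stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AssayMeasurement", "CellulaseParams", "LaccaseParams",
    "invert_standard_curve", "cellulase_activity", "laccase_activity",
    "cellulase_prefactor", "process_assay_table",
]


@dataclass(frozen=True)
class AssayMeasurement:
    """One absorbance reading pair and the fresh sample mass in grams."""

    A_plus: float
    A_minus: float
    W: float  # g fresh weight

    def __post_init__(self):
        if self.W <= 0:
            raise ValueError("sample mass W must be positive")

    @property
    def delta_A(self) -> float:
        return self.A_plus - self.A_minus


@dataclass(frozen=True)
class CellulaseParams:
    slope: float = 2.5090       # standard-curve slope, absorbance per (mg/mL)
    intercept: float = -0.0462  # standard-curve intercept, absorbance
    beta_f: float = 0.6         # total reaction volume, mL
    beta_s: float = 0.05        # sample volume in the reaction, mL
    beta_t: float = 1.0         # extraction volume, mL
    T: float = 60.0             # reaction time, min

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be positive")
        for name in ("beta_f", "beta_s", "beta_t", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class LaccaseParams:
    epsilon: float = 36.0       # millimolar extinction coefficient of ABTS, L/mmol/cm
    d: float = 0.5              # optical path, cm
    beta_f: float = 0.3         # total reaction volume, mL
    beta_s: float = 0.045       # sample volume in the reaction, mL
    beta_t: float = 1.0         # extraction volume, mL
    T: float = 20.0             # reaction time, min
    simplified_constant: float = 78.52

    def __post_init__(self):
        for name in ("epsilon", "d", "beta_f", "beta_s", "beta_t", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def invert_standard_curve(y: float, params: CellulaseParams = CellulaseParams()) -> float:
    """Glucose concentration x (mg/mL) from absorbance y: x = (y − b)/a.

    Extrapolation below the curve zero yields a negative concentration,
    returned as-is.
    """
    return (y - params.intercept) / params.slope


def cellulase_prefactor(params: CellulaseParams = CellulaseParams()) -> float:
    """The composed constant 1000·βf·βt/(a·βs·T); 79.71 at the defaults."""
    return 1000.0 * params.beta_f * params.beta_t / (params.slope * params.beta_s * params.T)


def cellulase_activity(m: AssayMeasurement, params: CellulaseParams = CellulaseParams()) -> float:
    """VCL in μg glucose released per minute per gram fresh weight."""
    x = invert_standard_curve(m.delta_A, params)  # mg/mL in the reaction
    return 1000.0 * x * params.beta_f * (params.beta_t / params.beta_s) / (params.T * m.W)


def laccase_activity(
    m: AssayMeasurement,
    params: LaccaseParams = LaccaseParams(),
    use_simplified: bool = True,
) -> float:
    """Laccase activity in nmol ABTS oxidised per minute per gram fresh weight."""
    if use_simplified:
        return params.simplified_constant * m.delta_A / m.W
    # parameter-composed pathway: nmol in reaction = 1000·ΔA·βf/(ε·d),
    # scaled by βt/βs to the whole extract, per minute per gram
    return (1000.0 * m.delta_A * params.beta_f * params.beta_t
            / (params.epsilon * params.d * params.beta_s * params.T * m.W))


def process_assay_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add activity/units columns to a table of absorbance readings.

    Expects columns sample_id, A_plus, A_minus, W_g, assay ∈ {cellulase, laccase}.
    """
    required = {"sample_id", "A_plus", "A_minus", "W_g", "assay"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    out = df.copy()
    activities, units = [], []
    for _, row in out.iterrows():
        m = AssayMeasurement(float(row["A_plus"]), float(row["A_minus"]), float(row["W_g"]))
        kind = str(row["assay"]).strip().lower()
        if kind == "cellulase":
            activities.append(cellulase_activity(m))
            units.append("ug/min/g")
        elif kind == "laccase":
            activities.append(laccase_activity(m))
            units.append("nmol/min/g")
        else:
            raise ValueError(f"unknown assay kind: {row['assay']!r}")
    out["activity"] = activities
    out["units"] = units
    return out
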