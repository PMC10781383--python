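"""Spectrophotometric determination of leaf chlorophyll and carotenoid content.

Ethanol (95%) extracts of fresh leaf discs are read on a UV-VIS
spectrophotometer at 665 nm (chlorophyll a), 649 nm (chlorophyll b) and
470 nm (carotenoid).  The standard Lichtenthaler-type equations convert the
three absorbances to pigment concentrations in the extract (mg/L), and the
extract volume, ethanol fraction and disc area convert concentration to an
area-based content (ug/cm^2) — the quantity the imaging pipeline predicts.

Unit convention for the area conversion: mg/L is read as ug/mL, so

    content [ug/cm^2] = C [mg/L] * n * V [mL] / area [cm^2]

with n the ethanol volume fraction.  Negative concentrations (possible for
pathological absorbance combinations) are returned unclamped but trigger a
warning, so algebraic identities stay exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExtractContext",
    "chlorophyll_a",
    "chlorophyll_b",
    "total_chlorophyll",
    "total_carotenoid",
    "to_area_content",
    "absorbances_from_contents",
    "compute_lab_table",
    "read_lab_table",
    "write_lab_table",
    "LAB_TABLE_COLUMNS",
]

# Coefficients of the 95%-ethanol pigment equations (mg/L per absorbance unit).
_CHLA_665, _CHLA_649 = 13.95, -6.88
_CHLB_665, _CHLB_649 = -7.32, 24.96
_CAR_A470, _CAR_CHLA, _CAR_CHLB, _CAR_DEN = 1000.0, 2.05, 114.8, 245.0

LAB_TABLE_COLUMNS = [
    "sample_id", "layer", "A665", "A649", "A470",
    "V_mL", "n", "leaf_area_cm2", "chl_ab_ug_cm2", "car_ug_cm2",
]


@dataclass(frozen=True)
class ExtractContext:
    """Extraction parameters: ethanol fraction n, volume V (mL), disc area (cm^2)."""

    n: float = 0.95
    V: float = 10.0
    leaf_area: float = np.pi * 0.5 ** 2  # one 10-mm borer disc

    def __post_init__(self) -> None:
        if not (0 < self.n <= 1):
            raise ValueError(f"ethanol fraction n must be in (0, 1], got {self.n}")
        if self.V <= 0:
            raise ValueError(f"extract volume V must be positive, got {self.V}")
        if self.leaf_area <= 0:
            raise ValueError(f"leaf_area must be positive, got {self.leaf_area}")


def _check_finite(*values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError("absorbances must be finite")


def _warn_if_negative(c, what: str):
    if np.any(np.asarray(c) < 0):
        warnings.warn(f"negative computed {what} concentration", stacklevel=3)
    return c


def chlorophyll_a(a665, a649):
    """Chlorophyll a concentration (mg/L) = 13.95*A665 - 6.88*A649."""
    _check_finite(a665, a649)
    return _warn_if_negative(_CHLA_665 * np.asarray(a665) + _CHLA_649 * np.asarray(a649),
                             "chlorophyll a")


def chlorophyll_b(a665, a649):
    """Chlorophyll b concentration (mg/L) = 24.96*A649 - 7.32*A665."""
    _check_finite(a665, a649)
    return _warn_if_negative(_CHLB_649 * np.asarray(a649) + _CHLB_665 * np.asarray(a665),
                             "chlorophyll b")


def total_chlorophyll(a665, a649):
    """Total chlorophyll (mg/L) = Chl a + Chl b = 18.08*A649 + 6.63*A665.

    Computed as the sum of the a and b equations, which is algebraically
    identical to the combined coefficients (13.95-7.32 = 6.63 on A665,
    24.96-6.88 = 18.08 on A649).
    """
    _check_finite(a665, a649)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        total = chlorophyll_a(a665, a649) + chlorophyll_b(a665, a649)
    return _warn_if_negative(total, "total chlorophyll")


def total_carotenoid(a665, a649, a470):
    """Total carotenoid (mg/L) = (1000*A470 - 2.05*Chla - 114.8*Chlb) / 245."""
    _check_finite(a665, a649, a470)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chla = chlorophyll_a(a665, a649)
        chlb = chlorophyll_b(a665, a649)
    car = (_CAR_A470 * np.asarray(a470) - _CAR_CHLA * chla - _CAR_CHLB * chlb) / _CAR_DEN
    return _warn_if_negative(car, "carotenoid")


def to_area_content(C, ctx: ExtractContext):
    """Convert extract concentration C (mg/L) to leaf area content (ug/cm^2)."""
    if ctx.leaf_area <= 0:
        raise ValueError("leaf_area must be positive")
    return np.asarray(C) * ctx.n * ctx.V / ctx.leaf_area


def absorbances_from_contents(chl_ab, car, ctx: ExtractContext, chla_fraction: float = 0.75):
    """Invert the pigment equations: area contents -> consistent absorbances.

    Used by the synthetic lab-table generator.  The total chlorophyll
    concentration is split into a and b at ``chla_fraction`` (a:b of 3:1 is
    typical for sun leaves); the 2x2 linear system then yields A665/A649, and
    the carotenoid equation yields A470.  Round-tripping through the forward
    equations recovers chl_ab and car exactly.
    """
    chl_ab = np.asarray(chl_ab, dtype=float)
    car = np.asarray(car, dtype=float)
    scale = ctx.leaf_area / (ctx.n * ctx.V)  # ug/cm^2 -> mg/L
    c_chl = chl_ab * scale
    c_car = car * scale
    chla = chla_fraction * c_chl
    chlb = (1.0 - chla_fraction) * c_chl
    # [13.95 -6.88; -7.32 24.96] [A665; A649] = [chla; chlb]
    det = _CHLA_665 * _CHLB_649 - _CHLA_649 * _CHLB_665
    a665 = (_CHLB_649 * chla - _CHLA_649 * chlb) / det
    a649 = (_CHLA_665 * chlb - _CHLB_665 * chla) / det
    a470 = (_CAR_DEN * c_car + _CAR_CHLA * chla + _CAR_CHLB * chlb) / _CAR_A470
    return a665, a649, a470


def compute_lab_table(df: pd.DataFrame) -> pd.DataFrame:
    """Fill pigment-content columns of a lab table from its absorbance columns.

    Expects columns A665, A649, A470, V_mL, n, leaf_area_cm2 (sample_id and
    layer pass through); adds/overwrites chl_ab_ug_cm2 and car_ug_cm2.
    """
    out = df.copy()
    chl = np.empty(len(df))
    car = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        ctx = ExtractContext(n=row.n, V=row.V_mL, leaf_area=row.leaf_area_cm2)
        chl[i] = to_area_content(total_chlorophyll(row.A665, row.A649), ctx)
        car[i] = to_area_content(total_carotenoid(row.A665, row.A649, row.A470), ctx)
    out["chl_ab_ug_cm2"] = chl
    out["car_ug_cm2"] = car
    return out


def read_lab_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LAB_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"lab table missing columns: {sorted(missing)}")
    return df


def write_lab_table(df: pd.DataFrame, path) -> None:
    df.loc[:, LAB_TABLE_COLUMNS].to_csv(path, index=False)
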