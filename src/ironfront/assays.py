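"""Wet-lab assay arithmetic: ferrozine inverse calibration and spore fractions.

Implements the two in-methods computations of the study: converting 562-nm
absorbances to iron concentrations through an OLS standard curve with the
assay's reporting ceiling (350 uM) and detection limit (1 uM), and the
heat-resistant spore percentage from paired CFU counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "IronReading",
    "SporeResult",
    "ferrozine_calibrate",
    "ferrozine_invert",
    "invert_table",
    "spore_percentage",
]

FLAG_OK = "ok"
FLAG_UPPER = "at_upper_limit"
FLAG_BELOW = "below_detection"
FLAG_OVER_UNITY = "over_unity"


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line of absorbance on concentration, with reporting limits."""

    slope: float                      # absorbance units per uM
    intercept: float                  # absorbance units
    r_squared: float
    valid_range: tuple[float, float] = (0.0, 400.0)  # uM
    upper_limit: float = 350.0        # uM reporting ceiling
    detection_limit: float = 1.0      # uM

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 must be in [0, 1]")


def ferrozine_calibrate(
    standards: Union[pd.DataFrame, tuple[Sequence[float], Sequence[float]]],
    upper_limit: float = 350.0,
    detection_limit: float = 1.0,
) -> CalibrationCurve:
    """Fit the standard curve by ordinary least squares.

    ``standards`` is either a DataFrame with columns ``conc_uM, abs_562`` or a
    (concentrations, absorbances) pair.  Requires at least 3 standards with
    nonzero concentration spread.
    """
    if isinstance(standards, pd.DataFrame):
        conc = standards["conc_uM"].to_numpy(dtype=float)
        absorb = standards["abs_562"].to_numpy(dtype=float)
    else:
        conc = np.asarray(standards[0], dtype=float)
        absorb = np.asarray(standards[1], dtype=float)
    if len(conc) < 3:
        raise ValueError("need at least 3 standards to calibrate")
    if np.ptp(conc) == 0:
        raise ValueError("standards span a single concentration; cannot calibrate")
    res = stats.linregress(conc, absorb)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        valid_range=(float(conc.min()), float(conc.max())),
        upper_limit=upper_limit,
        detection_limit=detection_limit,
    )


@dataclass(frozen=True)
class IronReading:
    concentration: float  # uM as reported (clamped/censored per assay rules)
    flag: str             # 'ok' | 'at_upper_limit' | 'below_detection'


def ferrozine_invert(absorbance: float, curve: CalibrationCurve) -> IronReading:
    """Invert an absorbance to a reported iron concentration.

    Raw inversion ``(absorbance - intercept)/slope``; values above the
    reporting ceiling are censored to it (flagged), values below the
    detection limit are flagged, and negative inversions are clamped to 0.
    """
    raw = (float(absorbance) - curve.intercept) / curve.slope
    if raw > curve.upper_limit:
        return IronReading(curve.upper_limit, FLAG_UPPER)
    if raw < 0.0:
        return IronReading(0.0, FLAG_BELOW)
    if raw < curve.detection_limit:
        return IronReading(raw, FLAG_BELOW)
    return IronReading(raw, FLAG_OK)


def invert_table(absorbances: Sequence[float], curve: CalibrationCurve) -> pd.DataFrame:
    """Vectorized :func:`ferrozine_invert` returning a reporting table."""
    readings = [ferrozine_invert(a, curve) for a in np.asarray(absorbances, dtype=float)]
    return pd.DataFrame(
        {
            "abs_562": np.asarray(absorbances, dtype=float),
            "conc_uM": [r.concentration for r in readings],
            "qualifier": [r.flag for r in readings],
        }
    )


@dataclass(frozen=True)
class SporeResult:
    percent: float
    flag: str  # 'ok' | 'over_unity'


def spore_percentage(cfu_after_heat: float, cfu_before_heat: float) -> SporeResult:
    """Heat-resistant spore percentage: 100 * after / before.

    Values above 100% (plating noise) are allowed but flagged.
    """
    if cfu_before_heat <= 0:
        raise ValueError("cfu_before_heat must be > 0")
    if cfu_after_heat < 0:
        raise ValueError("cfu_after_heat must be >= 0")
    pct = 100.0 * cfu_after_heat / cfu_before_heat
    return SporeResult(pct, FLAG_OVER_UNITY if pct > 100.0 else FLAG_OK)
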