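"""Shape diagnostics of area-vs-time trajectories.

The model predicts biphasic footprint growth: an early phase in which the
area grows approximately linearly in time, followed for the producer by
deceleration to a fixed area and for the non-producer by near-exponential
expansion until the dish boundary.  These helpers quantify both shapes with
ordinary least-squares fits over explicitly defined windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PhaseFit", "early_linear_fit", "late_exponential_fit"]


@dataclass(frozen=True)
class PhaseFit:
    r_squared: float
    slope: float
    intercept: float
    n_points: int
    t_window: tuple[float, float]


def _ols(t: np.ndarray, y: np.ndarray) -> PhaseFit:
    if len(t) < 3:
        raise ValueError("need at least 3 points in the phase window")
    res = stats.linregress(t, y)
    return PhaseFit(
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=len(t),
        t_window=(float(t[0]), float(t[-1])),
    )


def early_linear_fit(
    times: np.ndarray,
    areas: np.ndarray,
    lo_frac: float = 0.2,
    hi_frac: float = 0.8,
) -> PhaseFit:
    """Linear fit of area(t) over the growth phase of the S-shaped curve.

    The window is the straight mid-segment, read as in routine growth-curve
    analysis between ``lo_frac`` and ``hi_frac`` of the final area: it
    excludes the initial lag and the deceleration (or boundary-clamped) tail
    and straddles the inflection where expansion is fastest.
    """
    times = np.asarray(times, dtype=float)
    areas = np.asarray(areas, dtype=float)
    final = areas[-1]
    mask = (areas >= lo_frac * final) & (areas <= hi_frac * final)
    return _ols(times[mask], areas[mask])


def late_exponential_fit(
    times: np.ndarray,
    areas: np.ndarray,
    R_dish: float,
    lo_frac: float = 0.3,
    hi_frac: float = 0.95,
) -> PhaseFit:
    """Linear fit of log(area) over the late pre-boundary phase.

    The window holds the front radius between ``lo_frac`` and ``hi_frac`` of
    the dish radius, excluding the early transient and the boundary-clamped
    tail.  A high R^2 indicates exponential expansion.
    """
    times = np.asarray(times, dtype=float)
    areas = np.asarray(areas, dtype=float)
    s = np.sqrt(areas / np.pi)
    mask = (s >= lo_frac * R_dish) & (s <= hi_frac * R_dish) & (areas > 0)
    return _ols(times[mask], np.log(areas[mask]))
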