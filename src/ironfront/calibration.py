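"""Fitting the expansion model to footprint area time series.

Mirrors the study's procedure of matching the model to the non-producing
mutant and the wild type in turn: stage 1 fits the growth/mechanics
parameters against the non-producer series with kb = 0 (where chelation
parameters are irrelevant); stage 2 freezes those and fits the chelation
parameters against the producer series.  The search runs in log-parameter
space with a bounded Nelder-Mead simplex; plain least squares on areas is
the objective throughout.

The nondimensionalization symmetry ({F0, Fh, Fc, Cc, kb} * c, kp / c leaves
the dynamics invariant) means the fitted chelation parameters are identified
only as the product kb*kp; :func:`chelation_group` reports that group.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .grid import RadialGrid
from .model import ModelParameters, ScaledParameters, redimensionalize
from .solver import StepControl, Trajectory, detect_arrest, simulate

__all__ = [
    "AreaSeries",
    "FitResult",
    "area_objective",
    "fit_two_stage",
    "sweep_initial_iron",
    "chelation_group",
    "read_area_csv",
    "write_area_csv",
]

logger = logging.getLogger(__name__)

PRODUCER = "producer"
NON_PRODUCER = "non_producer"

#: objective value returned when the forward simulation fails
FAILURE_PENALTY = 1e12

DEFAULT_STAGE1_FIELDS = ("kappa0", "kf", "Fh")
DEFAULT_STAGE2_FIELDS = ("kb", "Fc")


@dataclass(frozen=True)
class AreaSeries:
    """One (time, area) observation series with its regime label."""

    times: np.ndarray      # h, strictly increasing
    areas: np.ndarray      # cm^2, nonnegative
    regime: str            # 'producer' | 'non_producer'
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "areas", a)
        if t.shape != a.shape or t.ndim != 1 or len(t) == 0:
            raise ValueError("times and areas must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("areas must be >= 0")
        if self.regime not in (PRODUCER, NON_PRODUCER):
            raise ValueError(f"regime must be '{PRODUCER}' or '{NON_PRODUCER}'")


@dataclass
class FitResult:
    """Outcome of the two-stage calibration."""

    params: ModelParameters
    objective: float
    residuals: dict[str, np.ndarray]        # per-regime observed - model
    n_fev: int
    n_iter: int
    converged: bool
    bounds: dict[str, tuple[float, float]]  # natural-unit bounds searched
    stage_objectives: dict[str, float] = field(default_factory=dict)


def read_area_csv(path: Union[str, Path], regime: str) -> list[AreaSeries]:
    """Read series in the ``t_h,area_cm2[,replicate]`` schema."""
    df = pd.read_csv(path)
    if "t_h" not in df.columns or "area_cm2" not in df.columns:
        raise ValueError("area CSV must have columns t_h, area_cm2[, replicate]")
    if "replicate" in df.columns:
        return [
            AreaSeries(g["t_h"].to_numpy(), g["area_cm2"].to_numpy(), regime, int(rep))
            for rep, g in df.groupby("replicate", sort=True)
        ]
    return [AreaSeries(df["t_h"].to_numpy(), df["area_cm2"].to_numpy(), regime)]


def write_area_csv(series_list: Sequence[AreaSeries], path: Union[str, Path]) -> None:
    frames = []
    for s in series_list:
        frame = pd.DataFrame({"t_h": s.times, "area_cm2": s.areas})
        if s.replicate is not None:
            frame["replicate"] = s.replicate
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# objective

def _simulate_regime(
    params: ModelParameters,
    regime: str,
    t_end: float,
    grid: Optional[RadialGrid],
    control: Optional[StepControl],
) -> Trajectory:
    p = params.as_mutant() if regime == NON_PRODUCER else params
    return simulate(p, grid=grid, t_end=t_end, sample_every=max(t_end / 480.0, 1e-3),
                    control=control)


def area_objective(
    params: ModelParameters,
    series_list: Sequence[AreaSeries],
    grid: Optional[RadialGrid] = None,
    control: Optional[StepControl] = None,
) -> float:
    """Sum of squared area residuals over all series.

    Producer series are compared against a kb>0 simulation, non-producer
    series against the same parameters with kb forced to 0; model areas are
    linearly interpolated at the observation times.  A failing simulation
    yields a large finite penalty instead of an exception.
    """
    if len(series_list) == 0:
        raise ValueError("need at least one observation series")
    total = 0.0
    trajs: dict[str, Trajectory] = {}
    for series in series_list:
        if series.regime not in trajs:
            t_end = max(s.times[-1] for s in series_list if s.regime == series.regime)
            try:
                trajs[series.regime] = _simulate_regime(params, series.regime, t_end, grid, control)
            except Exception as exc:  # noqa: BLE001 - penalty path by contract
                logger.warning("simulation failed during objective evaluation: %s", exc)
                return FAILURE_PENALTY * (1.0 + sum(float(np.sum(s.areas**2)) for s in series_list))
        model = trajs[series.regime].interp_area(series.times)
        total += float(np.sum((model - series.areas) ** 2))
    return total


def residual_series(
    params: ModelParameters,
    series_list: Sequence[AreaSeries],
    grid: Optional[RadialGrid] = None,
    control: Optional[StepControl] = None,
) -> dict[str, np.ndarray]:
    """Per-regime concatenated residuals (observed - model)."""
    out: dict[str, list[np.ndarray]] = {}
    trajs: dict[str, Trajectory] = {}
    for series in series_list:
        if series.regime not in trajs:
            t_end = max(s.times[-1] for s in series_list if s.regime == series.regime)
            trajs[series.regime] = _simulate_regime(params, series.regime, t_end, grid, control)
        model = trajs[series.regime].interp_area(series.times)
        out.setdefault(series.regime, []).append(series.areas - model)
    return {k: np.concatenate(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# two-stage fit

def chelation_group(params: ModelParameters) -> float:
    """The identifiable chelation combination kb * kp."""
    return params.kb * params.kp


def _default_bounds(
    init: ModelParameters, names: Sequence[str], span: float
) -> dict[str, tuple[float, float]]:
    out = {}
    for name in names:
        v = getattr(init, name)
        if v <= 0:
            raise ValueError(f"cannot build multiplicative bounds around {name}={v}")
        out[name] = (v / span, v * span)
    return out


def _fit_stage(
    base: ModelParameters,
    names: Sequence[str],
    series_list: Sequence[AreaSeries],
    bounds: dict[str, tuple[float, float]],
    grid: Optional[RadialGrid],
    control: Optional[StepControl],
    maxfev: int,
    force_mutant: bool,
) -> tuple[ModelParameters, object]:
    x0 = np.log([getattr(base, n) for n in names])
    log_bounds = [(np.log(bounds[n][0]), np.log(bounds[n][1])) for n in names]

    def build(x: np.ndarray) -> ModelParameters:
        p = base.replace(**{n: float(np.exp(xi)) for n, xi in zip(names, x)})
        return p.as_mutant() if force_mutant else p

    def fun(x: np.ndarray) -> float:
        return area_objective(build(x), series_list, grid=grid, control=control)

    # Termination is governed by parameter resolution: 1% in log space, below
    # which the adaptive-stepping jitter of the simulated objective dominates
    # any real SSE difference.  The function tolerance is a loose guard scaled
    # to the data's signal power (the SSE noise floor is O(cv^2 * sum a^2)).
    signal = sum(float(np.sum(s.areas**2)) for s in series_list)
    res = minimize(
        fun,
        x0,
        method="Nelder-Mead",
        bounds=log_bounds,
        options={
            "maxfev": maxfev,
            "xatol": 1e-2,
            "fatol": 1e-2 * max(signal, 1.0),
            "adaptive": False,
        },
    )
    fitted = base.replace(**{n: float(np.exp(xi)) for n, xi in zip(names, res.x)})
    return fitted, res


def fit_two_stage(
    producer: Union[AreaSeries, Sequence[AreaSeries]],
    non_producer: Union[AreaSeries, Sequence[AreaSeries]],
    init: Union[ModelParameters, ScaledParameters],
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    stage1_fields: Sequence[str] = DEFAULT_STAGE1_FIELDS,
    stage2_fields: Sequence[str] = DEFAULT_STAGE2_FIELDS,
    grid: Optional[RadialGrid] = None,
    control: Optional[StepControl] = None,
    maxfev_per_stage: int = 200,
    bounds_span: float = 30.0,
) -> FitResult:
    """Two-stage calibration: non-producer first, then producer.

    Stage 1 fits ``stage1_fields`` (growth/mechanics; default kappa0, kf, Fh)
    to the non-producer series with kb = 0, so chelation parameters cannot
    influence it.  Stage 2 fixes those values and fits ``stage2_fields``
    (default kb and Fc; kp is held, so kb carries the identifiable kb*kp
    group) to the producer series.  Parameters are searched as logs inside
    multiplicative box bounds (default ``init/bounds_span .. init*bounds_span``).
    Deterministic given the inputs.
    """
    if isinstance(init, ScaledParameters):
        init = redimensionalize(init)
    prod = [producer] if isinstance(producer, AreaSeries) else list(producer)
    nonp = [non_producer] if isinstance(non_producer, AreaSeries) else list(non_producer)
    if not prod or not nonp:
        raise ValueError("both producer and non-producer series are required")
    for s in prod:
        if s.regime != PRODUCER:
            raise ValueError("producer argument contains a non-producer series")
    for s in nonp:
        if s.regime != NON_PRODUCER:
            raise ValueError("non_producer argument contains a producer series")

    all_names = list(stage1_fields) + list(stage2_fields)
    if bounds is None:
        bounds = _default_bounds(init, all_names, bounds_span)

    stage1_params, res1 = _fit_stage(
        init, stage1_fields, nonp, bounds, grid, control, maxfev_per_stage, force_mutant=True
    )
    stage2_params, res2 = _fit_stage(
        stage1_params, stage2_fields, prod, bounds, grid, control, maxfev_per_stage,
        force_mutant=False,
    )

    final = stage2_params
    objective = area_objective(final, prod + nonp, grid=grid, control=control)
    return FitResult(
        params=final,
        objective=objective,
        residuals=residual_series(final, prod + nonp, grid=grid, control=control),
        n_fev=int(res1.nfev + res2.nfev),
        n_iter=int(res1.nit + res2.nit),
        converged=bool(res1.success and res2.success),
        bounds=bounds,
        stage_objectives={"non_producer": float(res1.fun), "producer": float(res2.fun)},
    )


# ---------------------------------------------------------------------------
# initial-iron sweep

def sweep_initial_iron(
    params: ModelParameters,
    F0_values: Sequence[float],
    t_end: float = 160.0,
    grid_cells: int = 900,
    control: Optional[StepControl] = None,
) -> pd.DataFrame:
    """Simulate the producer regime across initial iron levels.

    Returns one row per F0 (sorted ascending): final area, arrest time (NaN
    while still expanding), halo width at the end of the run, and a status
    column; per-run failures are recorded without aborting the sweep.
    """
    from .solver import halo_profile

    if any(f0 <= 0 for f0 in F0_values):
        raise ValueError("F0 values must be positive")
    rows = []
    for f0 in sorted(F0_values):
        p = params.replace(F0=float(f0), Cc=params.Cc * f0 / params.F0)
        grid = RadialGrid.from_radius(p.R_dish, grid_cells)
        try:
            traj = simulate(p, grid=grid, t_end=t_end, control=control,
                            snapshot_times=[t_end])
            end_state = traj.snapshots[-1]
            halo = halo_profile(end_state, p, grid)
            rows.append(
                {
                    "F0_uM": f0,
                    "final_area_cm2": float(traj.area[-1]),
                    "arrest_time_h": traj.arrest_time if traj.arrested else np.nan,
                    "halo_width_cm": halo.halo_width if halo.halo_width is not None else np.nan,
                    "status": "arrested" if traj.arrested else "expanding",
                }
            )
        except Exception as exc:  # noqa: BLE001 - sweep continues by contract
            logger.warning("sweep run F0=%s failed: %s", f0, exc)
            rows.append(
                {
                    "F0_uM": f0,
                    "final_area_cm2": np.nan,
                    "arrest_time_h": np.nan,
                    "halo_width_cm": np.nan,
                    "status": f"failed: {exc}",
                }
            )
    return pd.DataFrame(rows)
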