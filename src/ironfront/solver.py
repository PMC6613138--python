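"""Moving-boundary solver for radially symmetric biofilm expansion.

Discretizes the coupled system on the agar disc: reaction-diffusion of
pulcherriminic acid A, pulcherrimin C and free iron F on a fixed uniform
radial grid, an elliptic pressure problem inside the moving footprint
``r < s(t)``, and explicit advancement of the front from the Darcy edge
velocity.

Scheme
------
Strang-style splitting per step: half reaction, full implicit diffusion
(backward Euler, symmetric tridiagonal solve, no-flux at r=0 and r=R_dish),
half reaction, then front advance.  The reaction substep is an exact cascade
of closed-form updates (linear production, exponential utilization decay, the
analytic solution of the bilinear chelation pair A + F -> C), so it is
unconditionally positive and transfers iron between F, C and the consumed
pool without leakage.  The time step adapts to a 5% per-step relative-change
cap on each field and a one-cell cap on front motion, halving on rejection.

The footprint indicator B(r) = B0 for r < s uses exact partial-annulus
weights in the edge cell.  Pressure is solved on a front-fixed subgrid
``xi = r/s``; the edge velocity is evaluated from the flux identity of the
radial Poisson problem, ``v = (1/s) * integral_0^s g(r) r dr``, which the
elliptic solve satisfies and which makes v >= 0 structural.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.linalg import solveh_banded

from .grid import RadialGrid
from .model import ModelParameters, growth_rate

__all__ = [
    "SimulationState",
    "Trajectory",
    "ArrestResult",
    "HaloProfile",
    "initial_state",
    "solve_pressure",
    "diffusion_step",
    "advance_one_step",
    "simulate",
    "detect_arrest",
    "halo_profile",
    "iron_budget",
    "write_trajectory_csv",
    "read_trajectory_csv",
]


@dataclass(frozen=True)
class SimulationState:
    """Fields on the grid plus front position, time, and iron accounting."""

    t: float                 # elapsed time (h)
    s: float                 # front radius (cm)
    A: np.ndarray            # pulcherriminic acid (uM)
    C: np.ndarray            # pulcherrimin (uM)
    F: np.ndarray            # free iron (uM)
    consumed_iron: float     # cumulative utilization sink, annular integral
    initial_iron: float      # annular integral of F at t=0 (for closure audits)

    def validate(self, grid: RadialGrid) -> None:
        for name in ("A", "C", "F"):
            f = getattr(self, name)
            if f.shape != (grid.n_cells,):
                raise ValueError(f"field {name} has wrong shape {f.shape}")
            if np.any(~np.isfinite(f)):
                raise ValueError(f"field {name} contains non-finite values")
            if np.any(f < 0):
                raise ValueError(f"field {name} has negative entries")
        if not (0 < self.s <= grid.R_dish + 1e-12):
            raise ValueError(f"front radius s={self.s} outside (0, R_dish]")


def initial_state(params: ModelParameters, grid: RadialGrid) -> SimulationState:
    """Uniform iron F0, no acid, no deposit, front at s0."""
    n = grid.n_cells
    F = np.full(n, params.F0)
    return SimulationState(
        t=0.0,
        s=params.s0,
        A=np.zeros(n),
        C=np.zeros(n),
        F=F,
        consumed_iron=0.0,
        initial_iron=grid.total(F),
    )


@dataclass
class Trajectory:
    """Sampled time course of the front, footprint area and iron budget."""

    times: np.ndarray            # h, strictly increasing
    front: np.ndarray            # s(t), cm
    area: np.ndarray             # pi * s^2, cm^2
    total_acid: np.ndarray       # annular integral of A
    free_iron: np.ndarray        # annular integral of F
    chelated_iron: np.ndarray    # annular integral of C
    consumed_iron: np.ndarray    # cumulative utilization sink
    initial_iron: float
    R_dish: float
    reached_boundary: bool
    arrested: bool = False
    arrest_time: Optional[float] = None
    snapshots: list[SimulationState] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def interp_area(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.area)


# ---------------------------------------------------------------------------
# implicit radial diffusion

class _DiffusionWorkspace:
    """Caches the banded backward-Euler matrices, keyed by (D, dt)."""

    def __init__(self, grid: RadialGrid):
        self.grid = grid
        # conductances D-free: 2*pi*r_edge/dr at interior edges
        edges = grid.edges[1:-1]
        self._cond = 2.0 * np.pi * edges / grid.dr
        self._areas = grid.cell_areas
        self._cache: dict[tuple[float, float], np.ndarray] = {}

    def _matrix(self, D: float, dt: float) -> np.ndarray:
        key = (D, dt)
        ab = self._cache.get(key)
        if ab is None:
            n = self.grid.n_cells
            w = D * dt * self._cond
            diag = self._areas.copy()
            diag[:-1] += w
            diag[1:] += w
            ab = np.zeros((2, n))
            ab[0, 1:] = -w          # superdiagonal (symmetric)
            ab[1] = diag
            if len(self._cache) > 64:
                self._cache.clear()
            self._cache[key] = ab
        return ab

    def step(self, f: np.ndarray, D: float, dt: float) -> np.ndarray:
        if D == 0.0:
            return f.copy()
        ab = self._matrix(D, dt)
        return solveh_banded(ab, self._areas * f)


def diffusion_step(field: np.ndarray, D: float, dt: float, grid: RadialGrid) -> np.ndarray:
    """One backward-Euler step of radial diffusion with no-flux boundaries.

    Finite-volume form: the flux between cells i and i+1 is
    ``-D * 2*pi*r_edge * (f[i+1]-f[i]) / dr``; the axis needs no special
    regularization because the inner edge of cell 0 sits at r=0 and carries
    zero area.  Discrete annular mass is conserved to solver roundoff and a
    nonnegative field stays nonnegative (the matrix is an M-matrix).
    """
    if np.any(np.asarray(field) < 0):
        raise ValueError("field must be nonnegative")
    if D < 0:
        raise ValueError("diffusivity must be >= 0")
    if not dt > 0:
        raise ValueError("dt must be > 0")
    return _DiffusionWorkspace(grid).step(np.asarray(field, dtype=float), D, dt)


# ---------------------------------------------------------------------------
# pressure / edge velocity

def _edge_velocity(grid: RadialGrid, s: float, g_cells: np.ndarray, frac: np.ndarray) -> float:
    """v = (1/s) * integral_0^s g r dr via partial-annulus midpoint quadrature."""
    integral = float(np.dot(g_cells * frac, grid.r)) * grid.dr
    return max(integral / s, 0.0)


def solve_pressure(
    grid: RadialGrid,
    s: float,
    g_field: np.ndarray,
    lam: float,
    n_nodes: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Solve the radial Poisson problem for pressure inside the footprint.

    ``(1/r) d/dr (r lam dp/dr) = -g`` on (0, s) with symmetry at r=0 and
    p(s)=0, discretized on a front-fixed subgrid xi = r/s with ``n_nodes``
    cell-centered nodes (defaults to the number of main-grid cells inside the
    footprint).  Returns ``(r_nodes, p, edge_velocity)`` where the edge
    velocity ``-lam dp/dr|_s`` is evaluated through the exact flux identity
    ``v = (1/s) int_0^s g r dr`` (independent of lam, as the Poisson problem
    itself scales with 1/lam).

    ``g_field`` is the growth rate sampled on the *main* grid's cell centers;
    it is interpolated onto the subgrid.
    """
    if lam <= 0:
        raise ValueError("Darcy mobility lam must be > 0")
    if s <= grid.dr:
        raise ValueError(
            f"footprint radius s={s:g} is not resolved (dr={grid.dr:g}); use a finer grid"
        )
    g_field = np.asarray(g_field, dtype=float)
    if np.any(g_field < 0):
        raise ValueError("growth rate field must be >= 0")
    if n_nodes is None:
        n_nodes = max(16, int(round(s / grid.dr)))
    h = 1.0 / n_nodes
    xi = (np.arange(n_nodes) + 0.5) * h
    r_nodes = xi * s
    g_nodes = np.interp(r_nodes, grid.r, g_field)

    # FV in xi: flux between nodes ~ xi_edge*(p[i+1]-p[i])/h; Dirichlet p=0 at
    # xi=1 enters through the half-cell flux of the last node.
    w = (xi[:-1] + 0.5 * h) / h  # interior edge positions xi_e over h
    diag = np.zeros(n_nodes)
    diag[:-1] += w
    diag[1:] += w
    diag[-1] += 1.0 / (0.5 * h)  # boundary half-cell, xi_edge = 1
    ab = np.zeros((2, n_nodes))
    ab[0, 1:] = -w
    ab[1] = diag
    rhs = (s * s / lam) * g_nodes * xi * h
    p = solveh_banded(ab, rhs)
    v = _edge_velocity_from_subgrid(s, g_nodes, xi, h)
    return r_nodes, p, v


def _edge_velocity_from_subgrid(s: float, g_nodes: np.ndarray, xi: np.ndarray, h: float) -> float:
    return max(float(s * np.dot(g_nodes, xi) * h), 0.0)


# ---------------------------------------------------------------------------
# reaction substep: exact positive cascade

def _chelation_exact(A: np.ndarray, F: np.ndarray, kpt: float) -> np.ndarray:
    """Amount X chelated by A + F -> C over an interval with exponent kp*dt.

    Closed-form solution of dA/dt = dF/dt = -kp A F:
    ``X = A F expm1(z) / (A expm1(z) + d)`` with ``d = A - F``, ``z = d kp dt``.
    Exact, positive, and bounded by min(A, F).
    """
    d = A - F
    z = np.clip(d * kpt, -60.0, 60.0)
    em = np.expm1(z)
    denom = A * em + d
    with np.errstate(divide="ignore", invalid="ignore"):
        X = np.where(np.abs(denom) > 0, A * F * em / np.where(denom == 0, 1.0, denom), 0.0)
    # d -> 0 limit: X = A^2 kpt / (1 + A kpt)
    small = np.abs(z) < 1e-8
    if np.any(small):
        X = np.where(small, A * A * kpt / (1.0 + A * kpt), X)
    return np.clip(X, 0.0, np.minimum(A, F))


def _reaction_substep(
    A: np.ndarray,
    C: np.ndarray,
    F: np.ndarray,
    b: np.ndarray,
    params: ModelParameters,
    dt: float,
    grid: RadialGrid,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Exact cascade: P/2, U/2, chelation, U/2, P/2.

    P = linear production kb*b; U = exponential utilization decay exp(-kf*b*dt);
    chelation via the closed-form bimolecular solution.  Returns updated
    fields and the annular-integrated iron consumed by utilization.
    """
    consumed = 0.0
    A = A + (0.5 * dt * params.kb) * b
    if params.kf > 0:
        decay = np.exp(-0.5 * dt * params.kf * b)
        Fn = F * decay
        consumed += grid.total(F - Fn)
        F = Fn
    if params.kp > 0:
        X = _chelation_exact(A, F, params.kp * dt)
        A = A - X
        F = F - X
        C = C + X
    if params.kf > 0:
        Fn = F * decay
        consumed += grid.total(F - Fn)
        F = Fn
    A = A + (0.5 * dt * params.kb) * b
    return A, C, F, consumed


# ---------------------------------------------------------------------------
# stepping

def advance_one_step(
    state: SimulationState,
    params: ModelParameters,
    grid: RadialGrid,
    dt: float,
    workspace: Optional[_DiffusionWorkspace] = None,
) -> SimulationState:
    """One operator-split step: reaction/2, diffusion, reaction/2, front move."""
    if workspace is None:
        workspace = _DiffusionWorkspace(grid)
    b = grid.coverage(state.s) * params.B0
    half = 0.5 * dt

    A, C, F, used1 = _reaction_substep(state.A, state.C, state.F, b, params, half, grid)
    _check_fields("reaction (first half)", A, C, F)

    A = workspace.step(A, params.DA, dt)
    C = workspace.step(C, params.DC, dt)
    F = workspace.step(F, params.DF, dt)
    _check_fields("implicit diffusion", A, C, F)

    A, C, F, used2 = _reaction_substep(A, C, F, b, params, half, grid)
    _check_fields("reaction (second half)", A, C, F)

    # Heun front update: the edge velocity depends on s through the footprint
    # integral, so a predictor-corrector pass makes the front second order
    g = growth_rate(F, params)
    frac = b / params.B0 if params.B0 > 0 else b
    v0 = _edge_velocity(grid, state.s, g, frac)
    s_pred = min(state.s + dt * v0, grid.R_dish)
    frac_pred = grid.coverage(s_pred)
    v1 = _edge_velocity(grid, s_pred, g, frac_pred)
    s_new = min(state.s + 0.5 * dt * (v0 + v1), grid.R_dish)

    return SimulationState(
        t=state.t + dt,
        s=s_new,
        A=A,
        C=C,
        F=F,
        consumed_iron=state.consumed_iron + used1 + used2,
        initial_iron=state.initial_iron,
    )


def _check_fields(substep: str, *fields: np.ndarray) -> None:
    for name, f in zip("ACF", fields):
        if np.any(~np.isfinite(f)):
            raise RuntimeError(f"non-finite {name} after substep '{substep}'")
        if np.any(f < -1e-12):
            raise RuntimeError(f"negative {name} after substep '{substep}'")


@dataclass(frozen=True)
class StepControl:
    """Adaptive time-step policy."""

    dt_max: float = 0.5          # h
    dt_init: Optional[float] = None
    max_halvings: int = 40
    rel_change_cap: float = 0.05  # per-step cap on each field's relative change
    front_cells_cap: float = 1.0  # cap on front motion in units of dr
    grow_after: int = 4           # consecutive easy accepts before doubling dt


def simulate(
    params: ModelParameters,
    grid: Optional[RadialGrid] = None,
    t_end: float = 160.0,
    sample_every: float = 1.0 / 3.0,
    control: Optional[StepControl] = None,
    snapshot_times: Optional[list[float]] = None,
    vel_tol: float = 1e-3,
    arrest_window: float = 5.0,
) -> Trajectory:
    """Integrate the moving-boundary system and sample the trajectory.

    Steps adaptively (halving dt when any field changes by more than the
    per-step cap or the front crosses more than one cell; doubling back after
    sustained easy accepts), records front/area/budget at every accepted step,
    and linearly interpolates those records onto the requested sampling
    cadence.  Snapshots are the first accepted states at or after each
    requested time.  Deterministic: identical inputs give identical output.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    if grid is None:
        grid = RadialGrid.from_radius(params.R_dish, 900)
    if abs(grid.R_dish - params.R_dish) > 1e-9 * params.R_dish:
        raise ValueError("grid radius does not match params.R_dish")
    if control is None:
        control = StepControl()

    workspace = _DiffusionWorkspace(grid)
    state = initial_state(params, grid)
    floor = 0.01 * params.F0 if params.F0 > 0 else 1e-6

    # dt ladder: dt_max / 2^k keeps the diffusion-matrix cache tiny
    dt = control.dt_init if control.dt_init is not None else control.dt_max / 16.0
    dt = min(dt, control.dt_max)

    rec_t = [0.0]
    rec_s = [state.s]
    rec_A = [grid.total(state.A)]
    rec_F = [grid.total(state.F)]
    rec_C = [grid.total(state.C)]
    rec_used = [0.0]
    snap_queue = sorted(snapshot_times) if snapshot_times else []
    snapshots: list[SimulationState] = []
    if snap_queue and snap_queue[0] <= 0.0:
        while snap_queue and snap_queue[0] <= 0.0:
            snapshots.append(state)
            snap_queue.pop(0)

    easy_accepts = 0
    while state.t < t_end - 1e-12:
        dt_try = min(dt, t_end - state.t)
        halvings = 0
        while True:
            trial = advance_one_step(state, params, grid, dt_try, workspace)
            if _step_acceptable(state, trial, grid, control, floor):
                break
            halvings += 1
            if halvings > control.max_halvings:
                raise RuntimeError(
                    "time step rejected after maximum halvings at "
                    f"t={state.t:.6g} h (s={state.s:.6g} cm, dt={dt_try:.3g})"
                )
            dt_try *= 0.5
            dt = dt_try
            easy_accepts = 0
        state = trial
        if halvings == 0:
            easy_accepts += 1
            if easy_accepts >= control.grow_after and dt < control.dt_max:
                dt = min(dt * 2.0, control.dt_max)
                easy_accepts = 0
        rec_t.append(state.t)
        rec_s.append(state.s)
        rec_A.append(grid.total(state.A))
        rec_F.append(grid.total(state.F))
        rec_C.append(grid.total(state.C))
        rec_used.append(state.consumed_iron)
        while snap_queue and state.t >= snap_queue[0] - 1e-12:
            snapshots.append(state)
            snap_queue.pop(0)

    n_samples = int(round(t_end / sample_every)) + 1
    times = np.linspace(0.0, t_end, n_samples)
    rec_t_arr = np.asarray(rec_t)
    s_samp = np.interp(times, rec_t_arr, np.asarray(rec_s))
    traj = Trajectory(
        times=times,
        front=s_samp,
        area=np.pi * s_samp**2,
        total_acid=np.interp(times, rec_t_arr, np.asarray(rec_A)),
        free_iron=np.interp(times, rec_t_arr, np.asarray(rec_F)),
        chelated_iron=np.interp(times, rec_t_arr, np.asarray(rec_C)),
        consumed_iron=np.interp(times, rec_t_arr, np.asarray(rec_used)),
        initial_iron=state.initial_iron,
        R_dish=grid.R_dish,
        reached_boundary=bool(state.s >= grid.R_dish - 1e-9),
        snapshots=snapshots,
    )
    arrest = detect_arrest(traj, vel_tol=vel_tol, window=arrest_window)
    traj.arrested = arrest.arrested
    traj.arrest_time = arrest.time
    return traj


def _step_acceptable(
    state: SimulationState,
    trial: SimulationState,
    grid: RadialGrid,
    control: StepControl,
    floor: float,
) -> bool:
    if (trial.s - state.s) > control.front_cells_cap * grid.dr:
        return False
    for name in ("A", "C", "F"):
        old = getattr(state, name)
        new = getattr(trial, name)
        scale = max(float(old.max()), float(new.max()), floor)
        if float(np.abs(new - old).max()) > control.rel_change_cap * scale:
            return False
    return True


# ---------------------------------------------------------------------------
# trajectory analysis

@dataclass(frozen=True)
class ArrestResult:
    arrested: bool
    time: Optional[float]          # h; first time the front stays slow
    terminal_area: Optional[float]  # cm^2


def detect_arrest(traj: Trajectory, vel_tol: float = 1e-3, window: float = 5.0) -> ArrestResult:
    """Declare arrest when the windowed mean front velocity stays below tol.

    The arrest time is the earliest sample after which every forward-windowed
    mean of ds/dt remains below ``vel_tol`` (cm/h) through the end of the run.
    A run whose front reached the dish boundary, or whose velocity never
    settles below tolerance, is 'expanding'.
    """
    if len(traj.times) < 3:
        raise ValueError("need at least 3 trajectory samples to assess arrest")
    if traj.reached_boundary or traj.front[-1] >= traj.R_dish - 1e-9:
        return ArrestResult(False, None, None)
    t = traj.times
    v = np.diff(traj.front) / np.diff(t)
    t_mid = 0.5 * (t[:-1] + t[1:])
    # forward-windowed mean velocity at each interval midpoint
    slow = np.empty(len(v), dtype=bool)
    j_hi = np.searchsorted(t_mid, t_mid + window, side="right")
    csum = np.concatenate([[0.0], np.cumsum(v)])
    for i in range(len(v)):
        hi = max(j_hi[i], i + 1)
        slow[i] = (csum[hi] - csum[i]) / (hi - i) < vel_tol
    # earliest index from which 'slow' holds through the end
    if not slow[-1]:
        return ArrestResult(False, None, None)
    idx = len(slow) - 1
    while idx > 0 and slow[idx - 1]:
        idx -= 1
    return ArrestResult(True, float(t[idx]), float(traj.area[-1]))


@dataclass(frozen=True)
class HaloProfile:
    r_halo: Optional[float]               # outermost radius with C > Cc
    halo_width: Optional[float]           # r_halo - s
    iron_depletion_radius: Optional[float]  # outermost radius with F < Fc


def halo_profile(state: SimulationState, params: ModelParameters, grid: RadialGrid) -> HaloProfile:
    """Threshold radii of the pulcherrimin halo and the iron-depleted zone.

    Radii are outermost cell centers crossing the thresholds.  A non-producer
    run (C identically zero) has no halo.
    """
    r = grid.r
    above = np.nonzero(state.C > params.Cc)[0]
    if above.size:
        r_halo = float(r[above[-1]])
        halo = HaloProfile(r_halo, r_halo - state.s, None)
    else:
        halo = HaloProfile(None, None, None)
    depleted = np.nonzero(state.F < params.Fc)[0]
    if depleted.size:
        halo = dataclasses.replace(halo, iron_depletion_radius=float(r[depleted[-1]]))
    return halo


def iron_budget(state: SimulationState, grid: RadialGrid) -> tuple[float, float, float, float]:
    """(free, chelated, consumed, relative closure error) of the iron pool."""
    free = grid.total(state.F)
    chel = grid.total(state.C)
    used = state.consumed_iron
    if state.initial_iron > 0:
        err = abs(free + chel + used - state.initial_iron) / state.initial_iron
    else:
        err = 0.0
    return free, chel, used, err


# ---------------------------------------------------------------------------
# CSV IO

_TRAJ_COLUMNS = [
    "t_h", "s_cm", "area_cm2", "free_iron", "chelated_iron", "consumed_iron", "arrested_flag",
]


def write_trajectory_csv(traj: Trajectory, path: Union[str, Path]) -> None:
    arrested_flag = np.zeros(len(traj.times), dtype=int)
    if traj.arrested and traj.arrest_time is not None:
        arrested_flag[traj.times >= traj.arrest_time] = 1
    df = pd.DataFrame(
        {
            "t_h": traj.times,
            "s_cm": traj.front,
            "area_cm2": traj.area,
            "free_iron": traj.free_iron,
            "chelated_iron": traj.chelated_iron,
            "consumed_iron": traj.consumed_iron,
            "arrested_flag": arrested_flag,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_trajectory_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    return df


def write_snapshots_csv(
    snapshots: list[SimulationState], grid: RadialGrid, path: Union[str, Path]
) -> None:
    """Long-format columnar dump of field snapshots keyed by time."""
    frames = []
    for st in snapshots:
        frames.append(
            pd.DataFrame(
                {
                    "t_h": st.t,
                    "r_cm": grid.r,
                    "A_uM": st.A,
                    "C_uM": st.C,
                    "F_uM": st.F,
                    "s_cm": st.s,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
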