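"""Synthetic inputs emulating the study's measurements.

Three generators, all seeded and bit-reproducible:

* footprint area time courses (time-lapse imaging every 20 min over 160 h,
  three biological repeats), produced by the forward model plus multiplicative
  measurement noise with a small additive floor;
* a ferrozine standard curve (absorbance at 562 nm over 0-400 uM FeCl3);
* paired before/after-heat CFU counts for sporulation assays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import NON_PRODUCER, PRODUCER, AreaSeries
from .grid import RadialGrid
from .model import ModelParameters
from .solver import StepControl, simulate

__all__ = [
    "NoiseSpec",
    "generate_area_series",
    "generate_ferrozine_standards",
    "generate_spore_counts",
]

FERROZINE_RANGE = (0.0, 400.0)  # assay validity range, uM


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for synthetic area series.

    Multiplicative Gaussian noise with coefficient of variation ``cv``
    (segmentation error scales with footprint size) plus an additive Gaussian
    floor with standard deviation ``floor`` (cm^2).  ``seed`` makes every
    replicate stream reproducible.
    """

    cv: float = 0.02
    floor: float = 0.01
    seed: int = 0
    #: optional per-replicate biological variability: each replicate's growth
    #: and production rates are jittered by this lognormal CV (off by default)
    param_jitter_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.floor < 0 or self.param_jitter_cv < 0:
            raise ValueError("noise cv, floor and param_jitter_cv must be >= 0")


def generate_area_series(
    params: ModelParameters,
    regime: str,
    cadence: float = 1.0 / 3.0,
    t_end: float = 160.0,
    noise: Optional[NoiseSpec] = None,
    n_replicates: int = 3,
    grid: Optional[RadialGrid] = None,
    control: Optional[StepControl] = None,
) -> list[AreaSeries]:
    """Simulate one regime and sample noisy replicate area series.

    The deterministic trajectory is simulated once (kb forced to 0 for the
    non-producer regime) and sampled on the cadence grid; each replicate r
    then applies ``area' = clip(area*(1+eps) + eta, 0, pi*R_dish^2)`` with
    ``eps ~ N(0, cv)``, ``eta ~ N(0, floor)`` drawn from a stream seeded with
    ``seed + r``.  With noise off the samples equal the trajectory exactly.
    """
    if cadence <= 0 or t_end <= 0:
        raise ValueError("cadence and t_end must be > 0")
    if noise is None:
        noise = NoiseSpec()
    p = params.as_mutant() if regime == NON_PRODUCER else params
    if regime not in (PRODUCER, NON_PRODUCER):
        raise ValueError(f"regime must be '{PRODUCER}' or '{NON_PRODUCER}'")
    traj = simulate(p, grid=grid, t_end=t_end, sample_every=cadence, control=control)
    times = traj.times
    areas = traj.area
    max_area = np.pi * params.R_dish**2
    out = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(noise.seed + rep)
        rep_areas = areas
        if noise.param_jitter_cv > 0:
            # biological replicate variability: jitter growth and production
            jitter = np.exp(rng.normal(0.0, noise.param_jitter_cv, size=2))
            p_rep = p.replace(kappa0=p.kappa0 * jitter[0], kb=p.kb * jitter[1])
            rep_areas = simulate(
                p_rep, grid=grid, t_end=t_end, sample_every=cadence, control=control
            ).area
        if noise.cv == 0 and noise.floor == 0:
            noisy = rep_areas.copy()
        else:
            eps = rng.normal(0.0, noise.cv, size=len(rep_areas)) if noise.cv > 0 else 0.0
            eta = rng.normal(0.0, noise.floor, size=len(rep_areas)) if noise.floor > 0 else 0.0
            noisy = np.clip(rep_areas * (1.0 + eps) + eta, 0.0, max_area)
        out.append(AreaSeries(times.copy(), noisy, regime, replicate=rep))
    return out


def generate_ferrozine_standards(
    concentrations: Optional[Sequence[float]] = None,
    slope: float = 0.002,
    intercept: float = 0.05,
    sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic ferrozine standard curve: absorbance at 562 nm vs FeCl3.

    Defaults to a 9-point curve over 0-400 uM.  Absorbance is
    ``intercept + slope*concentration + N(0, sd)``; concentrations outside
    the assay range raise.
    """
    if concentrations is None:
        concentrations = np.linspace(FERROZINE_RANGE[0], FERROZINE_RANGE[1], 9)
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < FERROZINE_RANGE[0]) or np.any(conc > FERROZINE_RANGE[1]):
        raise ValueError(f"concentrations must lie in {FERROZINE_RANGE} uM (assay range)")
    absorbance = intercept + slope * conc
    if sd > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, sd, size=conc.shape)
    return pd.DataFrame({"conc_uM": conc, "abs_562": absorbance})


def generate_spore_counts(
    true_fraction: float, total_cfu: float, seed: int = 0
) -> tuple[int, int]:
    """Paired CFU counts (before heat, after 80C heat kill).

    ``cfu_before ~ Poisson(total_cfu)``; each counted CFU survives heating
    independently with probability ``true_fraction`` (the heat-resistant
    spore fraction), so ``cfu_after ~ Binomial(cfu_before, true_fraction)``.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must be in [0, 1]")
    if total_cfu <= 0:
        raise ValueError("total_cfu must be > 0")
    rng = np.random.default_rng(seed)
    before = int(rng.poisson(total_cfu))
    after = int(rng.binomial(before, true_fraction)) if before > 0 else 0
    return before, after
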