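"""Kinetics and parameters of iron-chelation-limited biofilm expansion.

The model describes a *Bacillus subtilis* colony biofilm growing on an iron-
supplemented agar disc.  Biomass of constant density ``B0`` occupies a disc of
radius ``s(t)``; growth-induced pressure drives radial expansion through a
Darcy closure (``v = -lam * grad p``).  The biofilm secretes pulcherriminic
acid ``A``, which diffuses into the agar and irreversibly chelates free ferric
iron ``F`` into the insoluble deposit pulcherrimin ``C``:

    production:   -> A            at rate  kb * B
    chelation:    A + F -> C      at rate  kp * F * A      (mass action)
    utilization:  F -> (biomass)  at rate  kf * B * F

The specific growth rate is a Hill response to free iron with a hard cutoff:
``g(F) = kappa0 * F^m / (Fh^m + F^m)`` for ``F >= Fc`` and ``g = 0`` below
``Fc``.  Setting ``kb = 0`` models non-producing (yvmC/cypX-type) mutants.

Everything in this module is discretization-free: the kinetic laws, the
parameter container with its validity checks, the nondimensionalization, and
flat key-value config IO.
"""

from __future__ import annotations

import dataclasses
import json
import math
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Union

import numpy as np

__all__ = [
    "ModelParameters",
    "ScaledParameters",
    "default_parameters",
    "growth_rate",
    "reaction_rates",
    "nondimensionalize",
    "redimensionalize",
    "load_parameters",
    "save_parameters",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants, diffusivities, thresholds and geometry.

    Units: concentrations in uM, time in hours, length in cm.  Biomass density
    is dimensionless (normalized to ``B0 = 1``); pressure units are absorbed
    into the Darcy mobility ``lam`` since only the product ``lam * grad p`` is
    observable.
    """

    kappa0: float = 0.08  # maximal specific growth rate (1/h)
    Fh: float = 5.0       # free iron at half-maximal growth (uM)
    m: float = 2.0        # Hill exponent of the growth response (>= 1)
    Fc: float = 1.0       # minimum free iron supporting growth (uM)
    lam: float = 1.0      # Darcy mobility (pressure units absorbed)
    kb: float = 12.0      # pulcherriminic acid production rate (uM/h per B0)
    kp: float = 0.0067    # chelation rate constant (1/(uM h))
    kf: float = 0.015     # iron utilization rate constant (1/h per B0)
    DA: float = 0.02      # pulcherriminic acid diffusivity (cm^2/h)
    DC: float = 1e-4      # pulcherrimin (deposit) diffusivity (cm^2/h)
    DF: float = 0.02      # free iron diffusivity (cm^2/h)
    F0: float = 50.0      # initial uniform free iron (uM)
    B0: float = 1.0       # biomass density inside the footprint (normalized)
    s0: float = 0.25      # initial footprint radius (cm)
    R_dish: float = 4.5   # agar disc radius (cm)
    Cc: float = 0.5       # pulcherrimin visibility / halo threshold (uM)
    fc_ramp: float = 0.0  # optional smoothing half-width of the Fc cutoff (uM)

    def __post_init__(self) -> None:
        nonneg = (
            "kappa0", "Fh", "Fc", "lam", "kb", "kp", "kf",
            "DA", "DC", "DF", "F0", "B0", "s0", "R_dish", "Cc", "fc_ramp",
        )
        for name in nonneg:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
        if self.m < 1:
            raise ValueError(f"Hill exponent m must be >= 1, got {self.m}")
        if not self.s0 < self.R_dish:
            raise ValueError(
                f"initial radius s0={self.s0} must be smaller than R_dish={self.R_dish}"
            )

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def as_mutant(self) -> "ModelParameters":
        """Non-producing regime: pulcherriminic acid synthesis off (kb = 0)."""
        return self.replace(kb=0.0)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def default_parameters() -> ModelParameters:
    """Calibrated default parameter set (50 uM FeCl3, 9-cm dish conditions).

    Chosen so that the producer regime arrests after ~2-3 days with a
    pulcherrimin halo beyond the front, while the non-producing regime expands
    to the dish boundary within the 160 h observation window.
    """
    return ModelParameters()


@dataclass(frozen=True)
class ScaledParameters:
    """Dimensionless parameter groups plus the reference scales that made them.

    Reference scales: concentration ``F0``, time ``1/kappa0``, length
    ``R_dish``.  With those, the growth number is identically 1; iron and halo
    thresholds become fractions of the initial iron; rate constants collapse
    into the chelation, production and utilization numbers; diffusivities into
    ratios ``D / (kappa0 R^2)``.  The Darcy mobility passes through unchanged
    (its pressure units are absorbed, so it forms no independent group).
    """

    growth_number: float        # kappa0 * t_ref == 1 by construction
    halfsat: float              # Fh / F0
    hill_m: float               # m (already dimensionless)
    iron_cutoff: float          # Fc / F0
    chelation_number: float     # kp * F0 / kappa0
    production_number: float    # kb * B0 / (kappa0 * F0)
    utilization_number: float   # kf * B0 / kappa0
    diff_acid: float            # DA / (kappa0 * R_dish^2)
    diff_deposit: float         # DC / (kappa0 * R_dish^2)
    diff_iron: float            # DF / (kappa0 * R_dish^2)
    mobility: float             # lam, pass-through
    halo_threshold: float       # Cc / F0
    s0_frac: float              # s0 / R_dish
    cutoff_ramp: float          # fc_ramp / F0
    # reference scales (dimensional) needed to invert the scaling
    conc_scale: float           # F0 (uM)
    time_scale: float           # 1/kappa0 (h)
    length_scale: float         # R_dish (cm)
    biomass_scale: float        # B0


def nondimensionalize(params: ModelParameters) -> ScaledParameters:
    """Scale the model by F0 (concentration), 1/kappa0 (time), R_dish (length)."""
    if params.kappa0 <= 0 or params.F0 <= 0 or params.R_dish <= 0:
        raise ValueError("nondimensionalization requires kappa0, F0, R_dish > 0")
    k, F0, R = params.kappa0, params.F0, params.R_dish
    diff = 1.0 / (k * R * R)
    return ScaledParameters(
        growth_number=1.0,
        halfsat=params.Fh / F0,
        hill_m=params.m,
        iron_cutoff=params.Fc / F0,
        chelation_number=params.kp * F0 / k,
        production_number=params.kb * params.B0 / (k * F0),
        utilization_number=params.kf * params.B0 / k,
        diff_acid=params.DA * diff,
        diff_deposit=params.DC * diff,
        diff_iron=params.DF * diff,
        mobility=params.lam,
        halo_threshold=params.Cc / F0,
        s0_frac=params.s0 / R,
        cutoff_ramp=params.fc_ramp / F0,
        conc_scale=F0,
        time_scale=1.0 / k,
        length_scale=R,
        biomass_scale=params.B0,
    )


def redimensionalize(scaled: ScaledParameters) -> ModelParameters:
    """Invert :func:`nondimensionalize` using the stored reference scales."""
    F0 = scaled.conc_scale
    k = 1.0 / scaled.time_scale
    R = scaled.length_scale
    B0 = scaled.biomass_scale
    diff = k * R * R
    return ModelParameters(
        kappa0=k,
        Fh=scaled.halfsat * F0,
        m=scaled.hill_m,
        Fc=scaled.iron_cutoff * F0,
        lam=scaled.mobility,
        kb=scaled.production_number * k * F0 / B0,
        kp=scaled.chelation_number * k / F0,
        kf=scaled.utilization_number * k / B0,
        DA=scaled.diff_acid * diff,
        DC=scaled.diff_deposit * diff,
        DF=scaled.diff_iron * diff,
        F0=F0,
        B0=B0,
        s0=scaled.s0_frac * R,
        R_dish=R,
        Cc=scaled.halo_threshold * F0,
        fc_ramp=scaled.cutoff_ramp * F0,
    )


def growth_rate(F: ArrayLike, params: ModelParameters) -> ArrayLike:
    """Specific biomass growth rate g(F) (1/h).

    Hill response ``kappa0 * F^m / (Fh^m + F^m)`` with a hard cutoff g = 0 for
    F below the minimum supporting level Fc.  If ``params.fc_ramp > 0`` the
    cutoff is softened by a C1 smoothstep rising over
    ``[Fc, Fc + 2*fc_ramp]`` (numerical convenience, off by default; g stays
    exactly 0 below Fc either way).
    """
    F_arr = np.asarray(F, dtype=float)
    if np.any(F_arr < 0):
        raise ValueError("free iron concentration F must be >= 0")
    with np.errstate(over="ignore"):
        Fm = np.power(F_arr, params.m)
        hill = params.kappa0 * Fm / (params.Fh ** params.m + Fm)
    hill = np.where(np.isnan(hill), params.kappa0, hill)  # F -> inf limit
    if params.fc_ramp > 0:
        x = np.clip((F_arr - params.Fc) / (2.0 * params.fc_ramp), 0.0, 1.0)
        gate = x * x * (3.0 - 2.0 * x)
    else:
        gate = np.where(F_arr >= params.Fc, 1.0, 0.0)
    out = hill * gate
    if np.isscalar(F) or np.ndim(F) == 0:
        return float(out)
    return out


def reaction_rates(
    A: ArrayLike, C: ArrayLike, F: ArrayLike, B: ArrayLike, params: ModelParameters
) -> tuple[ArrayLike, ArrayLike, ArrayLike]:
    """Reaction parts of dA/dt, dC/dt, dF/dt (diffusion excluded).

        dA/dt = kb*B - kp*F*A
        dC/dt = +kp*F*A
        dF/dt = -kp*F*A - kf*B*F

    The chelation flux kp*F*A enters C with the exact opposite sign it leaves
    F with, so iron is conserved pointwise: dF + dC = -kf*B*F.
    """
    A_arr, C_arr, F_arr = (np.asarray(x, dtype=float) for x in (A, C, F))
    if np.any(A_arr < 0) or np.any(C_arr < 0) or np.any(F_arr < 0):
        raise ValueError("concentrations A, C, F must be >= 0")
    B_arr = np.asarray(B, dtype=float)
    chel = params.kp * F_arr * A_arr
    dA = params.kb * B_arr - chel
    dC = chel
    dF = -chel - params.kf * B_arr * F_arr
    if np.ndim(A) == 0 and np.ndim(F) == 0 and np.ndim(B) == 0:
        return float(dA), float(dC), float(dF)
    return dA, dC, dF


# ---------------------------------------------------------------------------
# flat key-value config IO

_FIELD_NAMES = tuple(f.name for f in dataclasses.fields(ModelParameters))


def parameters_from_dict(data: dict[str, Any]) -> ModelParameters:
    """Build parameters from a flat mapping; unknown keys are rejected."""
    unknown = sorted(set(data) - set(_FIELD_NAMES))
    if unknown:
        raise ValueError(f"unknown parameter keys: {', '.join(unknown)}")
    return ModelParameters(**{k: float(v) for k, v in data.items()})


def load_parameters(path: Union[str, Path]) -> ModelParameters:
    """Read a parameter set from a flat TOML or JSON file (by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = json.load(fh)
    return parameters_from_dict(data)


def save_parameters(params: ModelParameters, path: Union[str, Path]) -> None:
    """Write a parameter set as flat TOML or JSON (by suffix)."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".toml":
        lines = [f"{k} = {float(v)!r}" for k, v in data.items()]
        path.write_text("\n".join(lines) + "\n")
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")
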