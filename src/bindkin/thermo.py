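"""Thermodynamic links between rate constants, affinity and pre-equilibria.

The central identity is ΔG = RT ln K_d with K_d = k_off / k_on (molar), so
on the log10 scale

    ΔG = ln(10) · R · T · (log10 k_off − log10 k_on)   [kcal/mol]

At 298.15 K the prefactor ln(10)·RT is ≈ 1.3643 kcal/mol per log10 unit.
A pair of rate-constant models therefore yields an affinity model with no
extra parameters, which is what lets affinities act as the held-out test
signal for selecting a (k_on, k_off) model pair.

The conformational-selection pre-equilibrium between bound-like and
unbound-like conformers of the free proteins is K = exp(−ΔE/RT), the ratio
of the two ensembles' Boltzmann factors, and the observed association rate
is the intrinsic rate of the bound-like subpopulation scaled by its
occupancy K/(1+K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Molar gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.9872041e-3


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and gas constant used in every conversion."""

    temperature: float = 298.15  # kelvin
    gas_constant: float = R_KCAL  # kcal / (mol K)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def rt(self) -> float:
        """R·T in kcal/mol."""
        return self.gas_constant * self.temperature

    @property
    def ln10_rt(self) -> float:
        """ln(10)·R·T — kcal/mol per log10 unit of K_d."""
        return math.log(10.0) * self.rt


DEFAULT_CONTEXT = ThermoContext()


def _check_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def dg_from_log_rates(log10_kon, log10_koff, ctx: ThermoContext = DEFAULT_CONTEXT):
    """Binding free energy (kcal/mol) from log10 rate constants.

    ΔG = ln(10)·RT·(log10 k_off − log10 k_on).  Negative for sub-molar K_d.
    Accepts scalars or arrays (broadcast).
    """
    kon = _check_finite("log10_kon", log10_kon)
    koff = _check_finite("log10_koff", log10_koff)
    out = ctx.ln10_rt * (koff - kon)
    return float(out) if out.ndim == 0 else out


def log_kd_from_dg(dg, ctx: ThermoContext = DEFAULT_CONTEXT):
    """log10 of the dissociation constant (molar) from ΔG in kcal/mol."""
    arr = _check_finite("dg", dg)
    out = arr / ctx.ln10_rt
    return float(out) if out.ndim == 0 else out


def preequilibrium_constant(delta_e, ctx: ThermoContext = DEFAULT_CONTEXT):
    """Equilibrium constant between bound-like and unbound-like conformers.

    ``delta_e`` is the energy of the bound-like conformational ensemble
    minus the unbound-like one, kcal/mol.  K = exp(−ΔE/RT) > 0.
    """
    arr = _check_finite("delta_e", delta_e)
    out = np.exp(-arr / ctx.rt)
    return float(out) if out.ndim == 0 else out


def composite_kon(K, kon_bound, occupancy_form: bool = True):
    """Observed association rate under conformational selection.

    With pre-equilibrium constant ``K`` and intrinsic association rate
    ``kon_bound`` (M^-1 s^-1) of the bound-like subpopulation, the
    composite rate is kon_bound · K/(1+K): association is proportional to
    the fraction of unbound molecules already in the bound conformation.
    ``occupancy_form=False`` selects the small-K linearisation K·kon_bound.
    """
    karr = _check_finite("K", K)
    kon = _check_finite("kon_bound", kon_bound)
    if np.any(karr <= 0):
        raise ValueError("pre-equilibrium constant K must be positive")
    if np.any(kon <= 0):
        raise ValueError("kon_bound must be positive")
    out = karr * kon if not occupancy_form else (karr / (1.0 + karr)) * kon
    return float(out) if np.ndim(out) == 0 else out
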