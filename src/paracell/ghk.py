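"""Constant-field electrodiffusion: dilution potentials and permeability splits.

Two relations are implemented for a barrier permeable to Na+ and Cl- only:

* the Goldman-Hodgkin-Katz (GHK) zero-current *dilution potential*

      V = (RT/F) * ln[(beta*C_Na,b + C_Cl,a) / (beta*C_Na,a + C_Cl,b)]

  where ``beta = P_Na/P_Cl`` and subscripts a/b denote apical/basal baths;
  potentials are apical-minus-basal, so with the apical bath diluted a
  cation-selective barrier (beta > 1) gives a positive potential;

* the Kimizuka-Koketsu decomposition of the zero-current transepithelial
  conductance G = 1/TER into per-ion permeability-concentration products

      G = (F^2/RT) * (P_Na * C_Na + P_Cl * C_Cl)

  with C the per-ion mean of the apical and basal concentrations (logarithmic
  mean by default, the form consistent with constant-field flux under a
  standing gradient) in mol/cm^3, giving P in cm/s.

The inversions (potential -> beta, and TER + beta -> P_Na, P_Cl) are
closed-form and exact up to floating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .physics import BODY_TEMP, PhysicalContext
from .solutions import BathPair

__all__ = [
    "SelectivityResult",
    "PermeabilityResult",
    "NernstRangeError",
    "nernst_potential",
    "dilution_potential_limits",
    "ghk_forward_potential",
    "ghk_invert_beta",
    "kk_conductance",
    "kk_split_permeabilities",
    "KK_VARIANTS",
]

#: mM -> mol/cm^3
_MM_TO_MOL_PER_CM3 = 1e-6

KK_VARIANTS = ("log_mean", "arithmetic_mean", "basal")


class NernstRangeError(ValueError):
    """Measured potential outside the physically attainable Nernst interval."""


@dataclass(frozen=True)
class SelectivityResult:
    """Cation selectivity ratio beta = P_Na/P_Cl."""

    beta: float

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")


@dataclass(frozen=True)
class PermeabilityResult:
    """Absolute paracellular permeabilities in cm/s with their ratio."""

    p_na: float
    p_cl: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.p_na > 0 and self.p_cl > 0):
            raise ValueError("permeabilities must be positive")
        if abs(self.beta - self.p_na / self.p_cl) > 1e-9 * self.beta:
            raise ValueError("beta inconsistent with p_na/p_cl")


def _check_baths(baths: BathPair) -> tuple[float, float, float, float]:
    na_a, na_b = baths.na
    cl_a, cl_b = baths.cl
    if min(na_a, na_b, cl_a, cl_b) <= 0:
        raise ValueError(
            "GHK requires positive Na+ and Cl- concentrations on both sides; "
            f"got Na (a,b)=({na_a},{na_b}) Cl (a,b)=({cl_a},{cl_b}) mM"
        )
    return na_a, na_b, cl_a, cl_b


def nernst_potential(c_apical: float, c_basal: float, valence: int,
                     ctx: PhysicalContext = BODY_TEMP) -> float:
    """Nernst equilibrium potential (apical minus basal) in mV for one ion."""
    return 1e3 * ctx.thermal_voltage / valence * math.log(c_basal / c_apical)


def dilution_potential_limits(baths: BathPair, ctx: PhysicalContext = BODY_TEMP
                              ) -> tuple[float, float]:
    """Open interval (mV) of attainable dilution potentials.

    The Cl(-)-only limit (beta -> 0) and Na(+)-only limit (beta -> inf) bound
    every mixed-selectivity potential; returned as (lower, upper).
    """
    na_a, na_b, cl_a, cl_b = _check_baths(baths)
    v_na = nernst_potential(na_a, na_b, +1, ctx)
    v_cl = nernst_potential(cl_a, cl_b, -1, ctx)
    return min(v_na, v_cl), max(v_na, v_cl)


def ghk_forward_potential(beta: float, baths: BathPair,
                          ctx: PhysicalContext = BODY_TEMP) -> float:
    """Zero-current dilution potential in mV for selectivity ``beta`` = P_Na/P_Cl."""
    if not beta > 0:
        raise ValueError(f"beta must be positive, got {beta}")
    na_a, na_b, cl_a, cl_b = _check_baths(baths)
    ratio = (beta * na_b + cl_a) / (beta * na_a + cl_b)
    return 1e3 * ctx.thermal_voltage * math.log(ratio)


def ghk_invert_beta(dilution_potential_mv: float, baths: BathPair,
                    ctx: PhysicalContext = BODY_TEMP) -> SelectivityResult:
    """Closed-form inversion of the dilution potential to beta = P_Na/P_Cl.

    Raises
    ------
    ValueError
        If the baths carry no NaCl gradient (beta unidentifiable).
    NernstRangeError
        If the potential lies at or beyond a single-ion Nernst limit.
    """
    na_a, na_b, cl_a, cl_b = _check_baths(baths)
    if not baths.has_nacl_gradient:
        raise ValueError(
            "beta is unidentifiable without a NaCl gradient "
            f"(apical and basal NaCl are both {baths.apical.nacl} mM)"
        )
    lo, hi = dilution_potential_limits(baths, ctx)
    if not lo < dilution_potential_mv < hi:
        raise NernstRangeError(
            f"potential {dilution_potential_mv:.4f} mV outside the open Nernst "
            f"interval ({lo:.4f}, {hi:.4f}) mV for these baths"
        )
    x = math.exp(1e-3 * dilution_potential_mv / ctx.thermal_voltage)
    beta = (cl_a - x * cl_b) / (x * na_a - na_b)
    return SelectivityResult(beta=beta)


def _mean_concentration(c_apical_mm: float, c_basal_mm: float, variant: str) -> float:
    """Per-ion concentration term of the conductance decomposition, in mol/cm^3."""
    if variant == "log_mean":
        if c_apical_mm == c_basal_mm:
            c = c_apical_mm
        else:
            c = (c_apical_mm - c_basal_mm) / math.log(c_apical_mm / c_basal_mm)
    elif variant == "arithmetic_mean":
        c = 0.5 * (c_apical_mm + c_basal_mm)
    elif variant == "basal":
        c = c_basal_mm
    else:
        raise ValueError(f"unknown KK concentration variant {variant!r}; choose from {KK_VARIANTS}")
    return c * _MM_TO_MOL_PER_CM3


def kk_conductance(p_na: float, beta: float, baths: BathPair,
                   ctx: PhysicalContext = BODY_TEMP, variant: str = "log_mean") -> float:
    """Forward Kimizuka-Koketsu: conductance G (S/cm^2) from P_Na (cm/s) and beta."""
    if not (p_na > 0 and beta > 0):
        raise ValueError("p_na and beta must be positive")
    na_a, na_b, cl_a, cl_b = _check_baths(baths)
    c_na = _mean_concentration(na_a, na_b, variant)
    c_cl = _mean_concentration(cl_a, cl_b, variant)
    return (p_na * c_na + (p_na / beta) * c_cl) / ctx.rt_over_f2


def kk_split_permeabilities(ter: float, beta: float, baths: BathPair,
                            ctx: PhysicalContext = BODY_TEMP,
                            variant: str = "log_mean") -> PermeabilityResult:
    """Split TER (Ohm cm^2) and beta into absolute P_Na and P_Cl (cm/s)."""
    if not ter > 0:
        raise ValueError(f"TER must be positive, got {ter} Ohm cm^2")
    if not beta > 0:
        raise ValueError(f"beta must be positive, got {beta}")
    na_a, na_b, cl_a, cl_b = _check_baths(baths)
    c_na = _mean_concentration(na_a, na_b, variant)
    c_cl = _mean_concentration(cl_a, cl_b, variant)
    g = 1.0 / ter
    p_na = g * ctx.rt_over_f2 / (c_na + c_cl / beta)
    return PermeabilityResult(p_na=p_na, p_cl=p_na / beta, beta=beta)
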