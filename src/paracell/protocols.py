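"""Experimental protocols: osmotic-condition presets and time-course summaries.

Each preset replaces the apical and/or basal bath at time 0 with a solution-A
variant (70/140/210 mM NaCl, with or without 130 mM of an impermeant
counter-osmolyte).  The driving stimulus is the *relative apical
hyposmolality*: a negative apical-minus-basal osmotic gradient, whichever side
was manipulated to produce it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .series import BathSchedule
from .solutions import BathPair, Solution, SOLUTION_A, replacement_solution

__all__ = [
    "ConditionPreset",
    "CONDITION_PRESETS",
    "DeltaSummary",
    "delta_115min",
    "recovery_metrics",
    "fit_relaxation",
]

#: osmotic gradients smaller than this (mOsm/L) count as isosmotic; the
#: sucrose-balanced presets are off by 10 mOsm/L (130 sucrose vs 140 units of NaCl)
ISOSMOTIC_BAND = 50.0


@dataclass(frozen=True)
class ConditionPreset:
    """A named bath protocol: initial apical/basal pair plus timed switches."""

    name: str
    apical: Solution
    basal: Solution
    switch_events: tuple[tuple[float, BathPair], ...] = ()

    def schedule(self) -> BathSchedule:
        return BathSchedule(BathPair(self.apical, self.basal), list(self.switch_events))

    @property
    def osmotic_gradient(self) -> float:
        """Initial apical-minus-basal nominal osmolarity, mOsm/L."""
        return BathPair(self.apical, self.basal).osmotic_gradient

    @property
    def osmotic_class(self) -> str:
        """'isosmotic', 'apical_hyposmotic' (the stimulus) or 'apical_hyperosmotic'."""
        g = self.osmotic_gradient
        if abs(g) <= ISOSMOTIC_BAND:
            return "isosmotic"
        return "apical_hyposmotic" if g < 0 else "apical_hyperosmotic"


def _preset(name: str, apical: Solution, basal: Solution,
            switches: tuple[tuple[float, BathPair], ...] = ()) -> ConditionPreset:
    return ConditionPreset(name, apical, basal, switches)


_A70 = replacement_solution(70)
_A70_SUC = replacement_solution(70, "sucrose")
_A140 = replacement_solution(140)
_A140_SUC = replacement_solution(140, "sucrose")
_A210 = replacement_solution(210)

#: The eight condition matrix presets (solution replaced at t = 0) plus the
#: reversibility protocol, which removes the osmotic gradient at 120 min by
#: adding sucrose apically while keeping apical NaCl at 70 mM (no change in
#: the NaCl gradient, hence no liquid-junction disturbance).
CONDITION_PRESETS: dict[str, ConditionPreset] = {p.name: p for p in [
    _preset("apical_isosmotic", _A70_SUC, _A140),
    _preset("apical_hyposmotic", _A70, _A140),
    _preset("basal_isosmotic", _A140, _A70_SUC),
    _preset("basal_hyposmotic", _A140, _A70),
    _preset("basal_hyperosmotic", _A140, _A210),
    _preset("basal_hyperosmotic_apical_sucrose", _A140_SUC, _A210),
    _preset("apical_hyperosmotic", _A210, _A140),
    _preset("apical_hyperosmotic_basal_sucrose", _A210, _A140_SUC),
    _preset("reversibility", _A70, _A140,
            ((120.0, BathPair(_A70_SUC, _A140)),)),
]}


@dataclass(frozen=True)
class DeltaSummary:
    """Signed change of P_Na and P_Cl over the 115-min observation window
    (value at 5 min minus value at 120 min), per replicate."""

    delta_p_na: float
    delta_p_cl: float
    condition: str = ""


def _nearest_row(series: pd.DataFrame, time: float, tolerance: float) -> pd.Series:
    gap = (series["time_min"] - time).abs()
    i = gap.idxmin()
    if gap[i] > tolerance:
        raise ValueError(
            f"no record within {tolerance} min of t={time} min "
            f"(nearest at {series['time_min'][i]} min)"
        )
    return series.loc[i]


def delta_115min(series: pd.DataFrame, condition: str = "",
                 t_early: float = 5.0, t_late: float = 120.0,
                 tolerance: float = 2.5) -> DeltaSummary:
    """Early-minus-late permeability change: value(5 min) - value(120 min).

    ``series`` is a permeability table as produced by
    :func:`paracell.series.compute_permeability_series`; the anchor times are
    matched to the nearest record within ``tolerance`` minutes.
    """
    early = _nearest_row(series, t_early, tolerance)
    late = _nearest_row(series, t_late, tolerance)
    return DeltaSummary(
        delta_p_na=float(early["p_na_cm_s"] - late["p_na_cm_s"]),
        delta_p_cl=float(early["p_cl_cm_s"] - late["p_cl_cm_s"]),
        condition=condition,
    )


def recovery_metrics(series: pd.DataFrame, switch_time: float = 120.0,
                     tolerance: float = 2.5) -> tuple[float, float, float]:
    """Selectivity before, at, and 5 min after gradient removal.

    Returns (beta at 5 min, beta at ``switch_time``, beta at
    ``switch_time`` + 5 min), each from the nearest record.
    """
    return tuple(
        float(_nearest_row(series, t, tolerance)["beta"])
        for t in (5.0, switch_time, switch_time + 5.0)
    )


def fit_relaxation(time: np.ndarray, beta: np.ndarray
                   ) -> tuple[float, float, float]:
    """Fit a single-exponential relaxation beta(t) = b_inf + (b0 - b_inf) e^(-t/tau).

    Returns (b0, b_inf, tau).  Used to recover the simulator's latent
    selectivity endpoints from an analyzed time course; degenerate (constant)
    series return the constant with tau = inf.
    """
    time = np.asarray(time, float)
    beta = np.asarray(beta, float)
    ok = np.isfinite(beta)
    time, beta = time[ok], beta[ok]
    if time.size < 3 or np.ptp(beta) < 1e-12 * max(1.0, abs(beta[0])):
        b = float(np.mean(beta))
        return b, b, np.inf

    def model(t, b0, b_inf, tau):
        return b_inf + (b0 - b_inf) * np.exp(-t / tau)

    span = max(np.ptp(time), 1.0)
    p0 = (beta[0], beta[-1], span / 3.0)
    popt, _ = curve_fit(model, time, beta, p0=p0,
                        bounds=([0.0, 0.0, 1e-3], [np.inf, np.inf, np.inf]),
                        maxfev=20000)
    return float(popt[0]), float(popt[1]), float(popt[2])
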