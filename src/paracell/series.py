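"""Raw measurement series, blank-filter correction, and the permeability pipeline.

A run produces two timed series from the volt-ohm meter: the epithelium-bearing
filter ("sample") and a cell-free filter measured under the identical bath
schedule ("blank").  The blank's resistance and potential — the filter plus the
electrodes' liquid-junction offset — are subtracted at each time point; the
corrected TER and dilution potential then feed the GHK inversion and the
Kimizuka-Koketsu split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ghk import (
    NernstRangeError,
    ghk_invert_beta,
    kk_split_permeabilities,
)
from .physics import BODY_TEMP, PhysicalContext
from .solutions import BathPair

__all__ = [
    "MeasurementRecord",
    "MeasurementSeries",
    "CorrectedRecord",
    "PairingError",
    "BathSchedule",
    "blank_correct",
    "compute_permeability_series",
]

log = logging.getLogger(__name__)


class PairingError(ValueError):
    """Sample and blank series cannot be matched time point by time point."""


@dataclass(frozen=True)
class MeasurementRecord:
    """One raw reading: time (min since solution replacement), resistance
    (Ohm cm^2, area-normalized), potential (mV, apical minus basal)."""

    time: float
    resistance: float
    potential: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")


@dataclass
class MeasurementSeries:
    """A timed series of raw readings from one filter."""

    time: np.ndarray
    resistance: np.ndarray
    potential: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.resistance = np.asarray(self.resistance, dtype=float)
        self.potential = np.asarray(self.potential, dtype=float)
        if not self.time.shape == self.resistance.shape == self.potential.shape:
            raise ValueError("time, resistance and potential must have equal length")
        if self.time.size and np.any(self.time < 0):
            raise ValueError("times must be >= 0")

    def __len__(self) -> int:
        return self.time.size

    @property
    def records(self) -> list[MeasurementRecord]:
        return [MeasurementRecord(t, r, v)
                for t, r, v in zip(self.time, self.resistance, self.potential)]


@dataclass(frozen=True)
class CorrectedRecord:
    """Blank-corrected reading: TER and dilution potential, with QC flags."""

    time: float
    ter: float
    dilution_potential: float
    flags: tuple[str, ...] = ()

    @property
    def valid(self) -> bool:
        return not self.flags


def blank_correct(sample: MeasurementSeries, blank: MeasurementSeries,
                  time_tolerance: float = 0.5) -> list[CorrectedRecord]:
    """Subtract the blank filter's resistance and potential at each time point.

    Each sample time is matched to the nearest blank time within
    ``time_tolerance`` minutes.  Records whose corrected TER is not positive
    are flagged ``nonpositive_ter`` (and excluded from downstream permeability
    math) rather than dropped.

    Raises
    ------
    PairingError
        Listing orphan times, if any sample time has no blank partner.
    """
    if len(sample) == 0:
        return []
    if len(blank) == 0:
        raise PairingError(f"blank series is empty; orphan sample times {list(sample.time)}")
    idx = np.abs(sample.time[:, None] - blank.time[None, :]).argmin(axis=1)
    gaps = np.abs(sample.time - blank.time[idx])
    orphans = sample.time[gaps > time_tolerance]
    if orphans.size:
        raise PairingError(
            f"no blank reading within {time_tolerance} min of sample times "
            f"{[float(t) for t in orphans]}"
        )
    out: list[CorrectedRecord] = []
    for i, j in enumerate(idx):
        ter = float(sample.resistance[i] - blank.resistance[j])
        dv = float(sample.potential[i] - blank.potential[j])
        flags: tuple[str, ...] = ()
        if ter <= 0:
            flags = ("nonpositive_ter",)
            log.warning("t=%.2f min: corrected TER %.3f Ohm cm^2 is not positive; flagged",
                        sample.time[i], ter)
        out.append(CorrectedRecord(float(sample.time[i]), ter, dv, flags))
    return out


@dataclass
class BathSchedule:
    """Piecewise-constant bath composition: an initial pair plus timed switches."""

    initial: BathPair
    switch_events: list[tuple[float, BathPair]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.switch_events = sorted(self.switch_events, key=lambda e: e[0])

    def baths_at(self, time: float) -> BathPair:
        if time < 0:
            raise ValueError(f"schedule covers t >= 0 only, got {time}")
        baths = self.initial
        for t_switch, pair in self.switch_events:
            if time >= t_switch:
                baths = pair
            else:
                break
        return baths

    def epochs(self, t_end: float) -> list[tuple[float, float, BathPair]]:
        """(start, end, baths) intervals covering [0, t_end]."""
        bounds = [0.0] + [t for t, _ in self.switch_events if t < t_end] + [t_end]
        return [(a, b, self.baths_at(a)) for a, b in zip(bounds[:-1], bounds[1:])]


def compute_permeability_series(
    corrected: Sequence[CorrectedRecord],
    schedule: BathSchedule,
    ctx: PhysicalContext = BODY_TEMP,
    kk_variant: str = "log_mean",
) -> pd.DataFrame:
    """Run GHK inversion + Kimizuka-Koketsu split over a corrected series.

    Returns a DataFrame with columns ``time_min, ter_ohm_cm2,
    dilution_potential_mV, beta, p_na_cm_s, p_cl_cm_s, flags``.  Flagged or
    uninvertible records carry NaN results and a non-empty ``flags`` string;
    nothing is silently dropped.
    """
    rows = []
    for rec in corrected:
        baths = schedule.baths_at(rec.time)
        beta = p_na = p_cl = math.nan
        flags = list(rec.flags)
        if rec.valid:
            try:
                beta = ghk_invert_beta(rec.dilution_potential, baths, ctx).beta
                split = kk_split_permeabilities(rec.ter, beta, baths, ctx, kk_variant)
                p_na, p_cl = split.p_na, split.p_cl
            except NernstRangeError as err:
                flags.append("potential_out_of_range")
                log.warning("t=%.2f min: %s", rec.time, err)
        else:
            log.info("t=%.2f min skipped: %s", rec.time, ";".join(rec.flags))
        rows.append({
            "time_min": rec.time,
            "ter_ohm_cm2": rec.ter,
            "dilution_potential_mV": rec.dilution_potential,
            "beta": beta,
            "p_na_cm_s": p_na,
            "p_cl_cm_s": p_cl,
            "flags": ";".join(flags),
        })
    return pd.DataFrame(rows)
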