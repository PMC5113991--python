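"""Bath solution compositions and derived ion concentrations / osmolarities.

The measurement buffers are variants of a HEPES-buffered saline ("solution A":
140 mM NaCl, 5 mM KCl, 1 mM MgCl2, 1 mM CaCl2, 5 mM glucose, 10 mM
HEPES-NaOH).  Experimental conditions replace the NaCl concentration (70, 140
or 210 mM) and optionally add 130 mM sucrose or mannitol to rebalance
osmolarity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "Solution",
    "BathPair",
    "nominal_osmolarity",
    "SOLUTION_A",
    "replacement_solution",
]

# ideal-dissociation particle counts per formula unit (no osmotic coefficients)
_DISSOCIATION = {
    "nacl": 2,
    "kcl": 2,
    "mgcl2": 3,
    "cacl2": 3,
    "glucose": 1,
    "hepes_naoh": 2,
    "sucrose": 1,
    "mannitol": 1,
}


@dataclass(frozen=True)
class Solution:
    """A named bath composition; all concentrations in mM."""

    name: str
    nacl: float = 0.0
    kcl: float = 0.0
    mgcl2: float = 0.0
    cacl2: float = 0.0
    glucose: float = 0.0
    hepes_naoh: float = 0.0
    sucrose: float = 0.0
    mannitol: float = 0.0

    def __post_init__(self) -> None:
        for solute in _DISSOCIATION:
            value = getattr(self, solute)
            if value < 0:
                raise ValueError(
                    f"{self.name}: concentration of {solute} must be >= 0, got {value} mM"
                )

    @property
    def sodium(self) -> float:
        """Total Na+ concentration in mM (NaCl plus the NaOH titrating HEPES)."""
        return self.nacl + self.hepes_naoh

    @property
    def chloride(self) -> float:
        """Total Cl- concentration in mM (from NaCl, KCl and the divalent chlorides)."""
        return self.nacl + self.kcl + 2.0 * self.mgcl2 + 2.0 * self.cacl2


def nominal_osmolarity(sol: Solution) -> float:
    """Ideal-dissociation osmolarity in mOsm/L (sum of particle counts x mM)."""
    return sum(n * getattr(sol, solute) for solute, n in _DISSOCIATION.items())


#: The base measurement buffer.
SOLUTION_A = Solution(
    "solution_A", nacl=140, kcl=5, mgcl2=1, cacl2=1, glucose=5, hepes_naoh=10
)


def replacement_solution(
    nacl_mm: float, counter_osmolyte: str | None = None, counter_mm: float = 130.0
) -> Solution:
    """A solution-A variant with altered NaCl and optional osmolyte back-fill.

    Parameters
    ----------
    nacl_mm : float
        NaCl concentration, typically 70, 140 or 210 mM.
    counter_osmolyte : {"sucrose", "mannitol", None}
        Membrane-impermeant osmolyte added (130 mM by default) to offset the
        osmotic effect of the NaCl change.
    """
    name = f"solA_{nacl_mm:g}NaCl"
    sol = replace(SOLUTION_A, name=name, nacl=nacl_mm)
    if counter_osmolyte is None:
        return sol
    if counter_osmolyte not in ("sucrose", "mannitol"):
        raise ValueError(f"unknown counter-osmolyte {counter_osmolyte!r}")
    name = f"{name}_{counter_mm:g}{counter_osmolyte}"
    return replace(sol, name=name, **{counter_osmolyte: counter_mm})


@dataclass(frozen=True)
class BathPair:
    """Apical and basal bath solutions; supplies the ion concentrations of the GHK/KK math."""

    apical: Solution
    basal: Solution

    @property
    def na(self) -> tuple[float, float]:
        """(apical, basal) Na+ in mM."""
        return self.apical.sodium, self.basal.sodium

    @property
    def cl(self) -> tuple[float, float]:
        """(apical, basal) Cl- in mM."""
        return self.apical.chloride, self.basal.chloride

    @property
    def has_nacl_gradient(self) -> bool:
        return self.apical.nacl != self.basal.nacl

    @property
    def osmotic_gradient(self) -> float:
        """Apical minus basal nominal osmolarity (mOsm/L); negative = apical hyposmotic."""
        return nominal_osmolarity(self.apical) - nominal_osmolarity(self.basal)
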