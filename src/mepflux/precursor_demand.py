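"""DMADP/IDP demand stoichiometry of prenyl diphosphate product classes.

Every prenyl diphosphate chain of n C5 units starts from 1 mole DMADP and
elongates with (n - 1) moles IDP: isoprene/DMADP (C5) needs no IDP, GDP
(C10) 1, FDP (C15) 2, GGDP (C20) 3.  C40 tetraterpenes (carotenoids) and
the chlorophyll phytol side chain are accounted as GGDP equivalents (C40
as 2x GGDP), since both derive from a C20 precursor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

from .exceptions import InvalidClassError, NegativeMolesError, ZeroDemandError

__all__ = [
    "PrenylClass",
    "DemandProfile",
    "BalanceReport",
    "unit_demand",
    "profile_demand",
    "supply_vs_demand",
]

_NAMED_CLASSES = {
    "isoprene": 1,
    "dmadp": 1,
    "c5": 1,
    "gdp": 2,
    "c10": 2,
    "fdp": 3,
    "c15": 3,
    "ggdp": 4,
    "c20": 4,
}

#: Classes expanded to GGDP equivalents (name -> moles of GGDP per mole).
_GGDP_EQUIVALENTS = {
    "c40": 2.0,
    "tetraterpene": 2.0,
    "carotenoid": 2.0,
    "chlorophyll": 1.0,  # one phytol (C20) side chain per chlorophyll
    "phytol": 1.0,
}


@dataclass(frozen=True)
class PrenylClass:
    """A prenyl diphosphate class identified by its count of C5 units."""

    name: str
    n_units: int

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise InvalidClassError(f"n_units must be >= 1, got {self.n_units}")

    @classmethod
    def from_name(cls, name: str) -> "PrenylClass":
        """Resolve a class name: a named class, or generic "C5n" (n >= 1)."""
        key = name.strip().lower()
        if key in _NAMED_CLASSES:
            return cls(name=name.strip(), n_units=_NAMED_CLASSES[key])
        match = re.fullmatch(r"c(\d+)", key)
        if match:
            carbons = int(match.group(1))
            if carbons >= 5 and carbons % 5 == 0:
                return cls(name=name.strip(), n_units=carbons // 5)
        raise InvalidClassError(
            f"unknown prenyl class {name!r}; expected one of "
            f"{sorted(_NAMED_CLASSES)} or a C5-multiple like 'C25'"
        )


@dataclass(frozen=True)
class DemandProfile:
    """Aggregate DMADP and IDP demand of a terpenoid product profile."""

    per_class: dict[str, tuple[float, float]]  # name -> (dmadp moles, idp moles)
    dmadp_moles: float
    idp_moles: float

    @property
    def idp_per_dmadp(self) -> float:
        """Demand ratio IDP/DMADP (inf if the profile needs only IDP)."""
        if self.dmadp_moles == 0:
            return float("inf") if self.idp_moles > 0 else 0.0
        return self.idp_moles / self.dmadp_moles


@dataclass(frozen=True)
class BalanceReport:
    """Limiting-reagent balance of C5 precursor supply against demand.

    All quantities are per unit of total C5 flux entering terpenoid
    biosynthesis; one of the two leftovers is always zero.
    """

    supply_dmadp: float
    supply_idp: float
    max_product_rate: float
    leftover_dmadp: float
    leftover_idp: float
    limiting: str  # "DMADP" | "IDP" | "balanced"


def unit_demand(cls: PrenylClass) -> tuple[float, float]:
    """Moles of (DMADP, IDP) consumed per mole of product: (1, n_units - 1)."""
    return (1.0, float(cls.n_units - 1))


def profile_demand(profile: Mapping[str | PrenylClass, float]) -> DemandProfile:
    """Aggregate unit demands over a {class: moles} product profile.

    GGDP-equivalent entries (C40, carotenoid, chlorophyll, phytol) are
    expanded to GGDP before demand accounting.
    """
    per_class: dict[str, tuple[float, float]] = {}
    total_d = total_i = 0.0
    for key, moles in profile.items():
        if moles < 0:
            raise NegativeMolesError(f"negative moles for class {key!r}: {moles}")
        if isinstance(key, PrenylClass):
            cls, label = key, key.name
        else:
            label = key
            lowered = key.strip().lower()
            if lowered in _GGDP_EQUIVALENTS:
                cls = PrenylClass.from_name("GGDP")
                moles = moles * _GGDP_EQUIVALENTS[lowered]
            else:
                cls = PrenylClass.from_name(key)
        d_unit, i_unit = unit_demand(cls)
        d, i = d_unit * moles, i_unit * moles
        prev = per_class.get(label, (0.0, 0.0))
        per_class[label] = (prev[0] + d, prev[1] + i)
        total_d += d
        total_i += i
    return DemandProfile(per_class=per_class, dmadp_moles=total_d, idp_moles=total_i)


def supply_vs_demand(supply_dmadp_frac: float, profile: DemandProfile) -> BalanceReport:
    """Limiting-reagent arithmetic for a given DMADP share of the C5 supply.

    Per unit of total C5 flux, the supply is (frac, 1 - frac) of
    (DMADP, IDP); the maximum product formation rate is
    min(supply_D/demand_D, supply_I/demand_I), and the non-limiting
    species is left over.  Conservation holds exactly for both species.
    """
    if not 0 < supply_dmadp_frac < 1:
        raise ValueError("supply_dmadp_frac must lie strictly between 0 and 1")
    d_dem, i_dem = profile.dmadp_moles, profile.idp_moles
    if d_dem == 0 and i_dem == 0:
        raise ZeroDemandError("profile demands neither DMADP nor IDP")
    supply_d = supply_dmadp_frac
    supply_i = 1.0 - supply_dmadp_frac
    rate_d = supply_d / d_dem if d_dem > 0 else float("inf")
    rate_i = supply_i / i_dem if i_dem > 0 else float("inf")
    rate = min(rate_d, rate_i)
    leftover_d = supply_d - rate * d_dem
    leftover_i = supply_i - rate * i_dem
    if abs(rate_d - rate_i) < 1e-15 * max(rate_d, rate_i):
        limiting = "balanced"
        leftover_d = leftover_i = 0.0
    elif rate_d < rate_i:
        limiting = "DMADP"
        leftover_d = 0.0  # snap: (supply/demand)*demand can miss by one ulp
    else:
        limiting = "IDP"
        leftover_i = 0.0
    return BalanceReport(
        supply_dmadp=supply_d,
        supply_idp=supply_i,
        max_product_rate=rate,
        leftover_dmadp=leftover_d,
        leftover_idp=leftover_i,
        limiting=limiting,
    )
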