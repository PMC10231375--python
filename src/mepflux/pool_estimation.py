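"""Plastidial pool-size estimation from final labeling fractions.

Each MEP intermediate's plastidial share is estimated by referencing its
final labeling fraction to that of isoprene, which is assumed to be of
purely plastidial origin.  Ratios slightly above 1 (possible under
measurement noise) are clamped to 1 with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .exceptions import (
    DuplicateMetaboliteError,
    MissingMetaboliteError,
    NoPlastidialReferenceError,
    ZeroPoolError,
)
from .label_model import PoolSizes

__all__ = [
    "METABOLITE_ORDER",
    "MetabolitePoolRecord",
    "plastidial_fraction",
    "plastidial_pool",
    "build_pool_sizes",
]

logger = logging.getLogger(__name__)

#: Chain order (A, B, C, D) of the required metabolites.
METABOLITE_ORDER = ("DXP", "MEcDP", "HMBDP", "IDP+DMADP")


@dataclass(frozen=True)
class MetabolitePoolRecord:
    """Total pool (nmol gFW^-1) and final labeling fraction of one metabolite."""

    name: str
    total_pool: float
    final_fraction: float

    def __post_init__(self) -> None:
        if self.name not in METABOLITE_ORDER:
            raise ValueError(
                f"unknown metabolite {self.name!r}; expected one of {METABOLITE_ORDER}"
            )
        if self.total_pool < 0:
            raise ValueError(f"total_pool must be >= 0, got {self.total_pool}")
        if not 0 <= self.final_fraction <= 1:
            raise ValueError(f"final_fraction must be in [0, 1], got {self.final_fraction}")


def plastidial_fraction(metabolite_final_fraction: float, isoprene_final_fraction: float) -> float:
    """Share of a metabolite's pool attributed to the plastid.

    The ratio of the metabolite's final labeling fraction to isoprene's.
    Values above 1 are clamped to 1 with a warning (noise can push the raw
    ratio slightly past the reference).

    Raises
    ------
    NoPlastidialReferenceError
        If the isoprene reference fraction is zero.
    """
    if not 0 <= metabolite_final_fraction <= 1:
        raise ValueError("metabolite final fraction must be in [0, 1]")
    if not 0 <= isoprene_final_fraction <= 1:
        raise ValueError("isoprene final fraction must be in [0, 1]")
    if isoprene_final_fraction == 0:
        raise NoPlastidialReferenceError(
            "isoprene final labeling fraction is zero; no plastidial reference"
        )
    ratio = metabolite_final_fraction / isoprene_final_fraction
    if ratio > 1:
        logger.warning(
            "plastidial fraction %.4g exceeds 1 (metabolite more labeled than "
            "isoprene); clamping to 1",
            ratio,
        )
        return 1.0
    return ratio


def plastidial_pool(record: MetabolitePoolRecord, isoprene_final_fraction: float) -> float:
    """Plastidial pool size: total pool times the plastidial fraction."""
    return record.total_pool * plastidial_fraction(record.final_fraction, isoprene_final_fraction)


def build_pool_sizes(
    records: Iterable[MetabolitePoolRecord], isoprene_final_fraction: float
) -> PoolSizes:
    """Assemble plastidial pools of all four chain metabolites into PoolSizes.

    Requires exactly one record per metabolite in METABOLITE_ORDER; every
    resulting plastidial pool must be strictly positive to enter the flux
    model.
    """
    by_name: dict[str, MetabolitePoolRecord] = {}
    for record in records:
        if record.name in by_name:
            raise DuplicateMetaboliteError(f"duplicate record for {record.name!r}")
        by_name[record.name] = record
    missing = [name for name in METABOLITE_ORDER if name not in by_name]
    if missing:
        raise MissingMetaboliteError(f"missing metabolite record(s): {missing}")
    pools = {}
    for name in METABOLITE_ORDER:
        value = plastidial_pool(by_name[name], isoprene_final_fraction)
        if value <= 0:
            raise ZeroPoolError(
                f"plastidial pool of {name!r} computed to {value}; must be > 0"
            )
        pools[name] = value
    return PoolSizes(
        dxp=pools["DXP"],
        mecdp=pools["MEcDP"],
        hmbdp=pools["HMBDP"],
        idp_dmadp=pools["IDP+DMADP"],
    )
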