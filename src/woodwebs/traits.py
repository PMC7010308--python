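"""Species traits from raw branch and beetle measurements.

* wood density (g/cm^3): oven-dry weight over dry volume, averaged over
  a species' branches — a hardness proxy;
* percent daily decomposition, PDD (%/day): percent mass lost per day
  of field exposure, averaged per species;
* body-size index, BSI (mm^2): body length x width per individual,
  averaged per species — an energetic-requirement proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .core_data import TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "BranchMeasurement",
    "BeetleMeasurement",
    "wood_density",
    "pdd",
    "bsi",
    "trait_table_from_measurements",
]


@dataclass(frozen=True)
class BranchMeasurement:
    """One branch section of a host species."""

    species: str
    dry_weight: float  # g
    dry_volume: float  # cm^3
    initial_weight: float  # g
    final_weight: float  # g
    exposure_days: int

    def __post_init__(self) -> None:
        if self.dry_volume <= 0:
            raise ValueError(f"{self.species}: dry volume must be > 0")
        if min(self.dry_weight, self.initial_weight, self.final_weight) < 0:
            raise ValueError(f"{self.species}: weights must be >= 0")
        if self.exposure_days <= 0:
            raise ValueError(f"{self.species}: exposure days must be > 0")


@dataclass(frozen=True)
class BeetleMeasurement:
    """One photographed individual of a beetle species."""

    species: str
    length: float  # mm
    width: float  # mm

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError(f"{self.species}: body dimensions must be > 0")


def _per_species(values: dict[str, list[float]]) -> dict[str, float]:
    return {sp: float(np.mean(v)) for sp, v in sorted(values.items())}


def wood_density(measurements: Iterable[BranchMeasurement]) -> dict[str, float]:
    """Mean dry weight / dry volume (g/cm^3) per host species."""
    acc: dict[str, list[float]] = {}
    for m in measurements:
        d = m.dry_weight / m.dry_volume
        if d == 0:
            logger.warning("%s: zero dry weight gives zero density", m.species)
        acc.setdefault(m.species, []).append(d)
    return _per_species(acc)


def pdd(
    measurements: Iterable[BranchMeasurement], *, literal_remaining: bool = False
) -> dict[str, float]:
    """Percent daily decomposition per host species.

    Default reading: percent mass lost per exposure day,
    ``100 * ((initial - final) / initial) / days``.  With
    ``literal_remaining=True`` the complementary percent-mass-remaining
    per day, ``100 * (1 - (initial - final)/initial) / days``, is
    returned instead.  Weight gain (negative loss) is kept and flagged.
    """
    acc: dict[str, list[float]] = {}
    for m in measurements:
        if m.initial_weight == 0:
            raise ValueError(f"{m.species}: initial weight must be > 0 for PDD")
        loss = (m.initial_weight - m.final_weight) / m.initial_weight
        value = 100.0 * ((1.0 - loss) if literal_remaining else loss) / m.exposure_days
        if loss < 0:
            logger.warning(
                "%s: branch gained weight (%.3g%%); PDD is negative", m.species, -100 * loss
            )
        acc.setdefault(m.species, []).append(value)
    return _per_species(acc)


def bsi(measurements: Iterable[BeetleMeasurement]) -> dict[str, float]:
    """Mean body length x width (mm^2) per beetle species."""
    acc: dict[str, list[float]] = {}
    for m in measurements:
        acc.setdefault(m.species, []).append(m.length * m.width)
    return _per_species(acc)


def trait_table_from_measurements(
    branches: Iterable[BranchMeasurement],
    beetles: Iterable[BeetleMeasurement],
) -> TraitTable:
    """Assemble a trait table from raw measurements."""
    branches = list(branches)
    density = wood_density(branches)
    decomposition = pdd(branches)
    body = bsi(beetles)
    rows = [
        {
            "species": sp,
            "role": "host",
            "wood_density": density[sp],
            "pdd": decomposition[sp],
            "bsi": np.nan,
        }
        for sp in density
    ] + [
        {
            "species": sp,
            "role": "beetle",
            "wood_density": np.nan,
            "pdd": np.nan,
            "bsi": body[sp],
        }
        for sp in body
    ]
    return TraitTable(pd.DataFrame(rows))
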