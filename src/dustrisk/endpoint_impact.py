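"""Endpoint impact characterization of dust particles.

Converts the elemental inventory of a fixed particle mass (1 g by default,
emitted to air) into endpoint impacts: for each impact category c,

    impact_c = Σ_i  (c_i [mg/kg] · basis_mass [g] · 10⁻⁹ [kg per mg/kg·g]) · CF_{i,c}

with CF the endpoint characterization factor (DALY/kg for the human-toxicity
categories, species.yr/kg for the ecotoxicity categories). The two human
categories sum to the human-health total (DALY); the three ecotoxicity
categories sum to the ecological total (species.yr). In practice the
freshwater and marine contributions are orders of magnitude below the
terrestrial one, so at display precision the ecological total coincides with
the terrestrial value; the implementation always sums all three.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .dataio import CompositionTable
from .refdata import (CharacterizationFactor, ECO_CATEGORIES, HUMAN_CATEGORIES,
                      IMPACT_CATEGORIES)

__all__ = ["ImpactResult", "characterize_impacts", "aggregate_endpoints",
           "impacts_to_frame", "write_impact_table"]

logger = logging.getLogger(__name__)

#: kg of element emitted per (mg/kg concentration × g of particles)
_KG_PER_MGKG_G = 1e-9


@dataclass(frozen=True)
class ImpactResult:
    """Endpoint impacts of one sample's particles at a given basis mass."""

    sample: str
    categories: dict[str, float]  # category -> DALY or species.yr
    human_health_total: float     # DALY
    ecological_total: float       # species.yr
    basis_mass: float             # g of particles


def characterize_impacts(comp: CompositionTable,
                         factors: Iterable[CharacterizationFactor],
                         basis_mass: float = 1.0) -> list[ImpactResult]:
    """Characterize every sample of a composition table.

    Chromium should be speciated beforehand (factor tables carry Cr(VI) and
    Cr(III), not total Cr). Elements without a factor in a category contribute
    zero there; the set of uncharacterized elements is logged once.
    """
    if basis_mass <= 0:
        raise ValueError(f"basis_mass must be > 0 g, got {basis_mass}")
    factors = list(factors)
    for f in factors:
        if f.factor < 0:
            raise ValueError(f"negative characterization factor for {f.element!r}/{f.category!r}")
    cf: dict[tuple[str, str], float] = {}
    for f in factors:
        cf[(f.element, f.category)] = cf.get((f.element, f.category), 0.0) + f.factor
    covered = {f.element for f in factors}

    results: list[ImpactResult] = []
    missing: set[str] = set()
    for sample in comp.samples:
        conc = comp.concentrations(sample)
        missing |= set(conc) - covered
        cats: dict[str, float] = {}
        for cat in IMPACT_CATEGORIES:
            cats[cat] = float(math.fsum(
                c_i * basis_mass * _KG_PER_MGKG_G * cf[(el, cat)]
                for el, c_i in conc.items() if (el, cat) in cf))
        hh, eco = aggregate_endpoints(cats)
        results.append(ImpactResult(sample=sample, categories=cats,
                                    human_health_total=hh, ecological_total=eco,
                                    basis_mass=basis_mass))
    if missing:
        logger.info("%d element(s) without characterization factors contributed 0: %s",
                    len(missing), sorted(missing))
    return results


def aggregate_endpoints(categories) -> tuple[float, float]:
    """Sum category values into (human-health DALY, ecological species.yr).

    Accepts either a category→value mapping or an :class:`ImpactResult`.
    """
    if isinstance(categories, ImpactResult):
        categories = categories.categories
    hh = float(math.fsum(categories.get(c, 0.0) for c in HUMAN_CATEGORIES))
    eco = float(math.fsum(categories.get(c, 0.0) for c in ECO_CATEGORIES))
    return hh, eco


def impacts_to_frame(results: Sequence[ImpactResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"sample": r.sample}
        row.update({c: r.categories.get(c, 0.0) for c in IMPACT_CATEGORIES})
        row["human_health_total"] = r.human_health_total
        row["ecological_total"] = r.ecological_total
        row["basis_mass_g"] = r.basis_mass
        rows.append(row)
    return pd.DataFrame(rows)


def write_impact_table(results: Sequence[ImpactResult], path) -> None:
    impacts_to_frame(results).to_csv(path, index=False)
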