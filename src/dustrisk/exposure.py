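"""Exposure quantities: exposure-point concentration, chromium speciation and
average daily intake.

The exposure-point concentration (EPC) is the "reasonable maximum exposure"
value of the PM₁₀ series — by default the one-sided Student-t 95% upper
confidence limit of the arithmetic mean, the baseline recommendation for
approximately normal data. The average daily intake (ADI) through inhalation
of a dust-borne element is

    ADI = C_i · (C_PM10 / 1000) · InhR · EF · ED / (BW · AT · 10⁶)   [mg/kg-day]

with C_i the element concentration in dust (mg/kg), C_PM10 the EPC (µg/m³),
and the exposure parameters from an :class:`~dustrisk.refdata.ExposureProfile`.
The 1/1000 converts µg→mg of dust per m³ of air; the 1/10⁶ converts mg of
dust to kg of dust so that mg-element/kg-dust cancels cleanly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .dataio import CompositionTable
from .refdata import ExposureProfile

__all__ = [
    "ExposurePointConcentration",
    "DailyIntake",
    "EPC_METHODS",
    "exposure_point_concentration",
    "speciate_chromium",
    "speciate_composition",
    "average_daily_intake",
]

EPC_METHODS = ("t_ucl95", "mean", "max")

IntakeKind = Literal["non-carcinogenic", "carcinogenic"]


@dataclass(frozen=True)
class ExposurePointConcentration:
    """An EPC value (µg/m³) with the sample size and procedure that produced it."""

    value: float
    n: int
    method: str


@dataclass(frozen=True)
class DailyIntake:
    """Average daily intake of one element for one receptor, mg/kg-day."""

    element: str
    receptor: str
    kind: str
    adi: float


def exposure_point_concentration(values: Sequence[float],
                                 method: str = "t_ucl95") -> ExposurePointConcentration:
    """Exposure-point concentration of a µg/m³ series.

    ``t_ucl95`` returns mean + t₀.₉₅,ₙ₋₁ · s/√n with s the sample standard
    deviation (one-sided 95% UCL of the mean; requires n ≥ 2). ``mean`` and
    ``max`` are available as conservative-to-simple alternatives. The result
    is never below the arithmetic mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute an exposure-point concentration of an empty series")
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    if method not in EPC_METHODS:
        raise ValueError(f"unknown EPC method {method!r}; expected one of {EPC_METHODS}")
    mean = float(x.mean())
    if method == "mean":
        value = mean
    elif method == "max":
        value = float(x.max())
    else:
        if x.size < 2:
            raise ValueError("t_ucl95 needs at least 2 observations for a dispersion estimate")
        s = float(x.std(ddof=1))
        t = float(stats.t.ppf(0.95, df=x.size - 1))
        value = mean + t * s / math.sqrt(x.size)
    return ExposurePointConcentration(value=value, n=int(x.size), method=method)


def speciate_chromium(total_cr: float,
                      ratio_cr6_to_cr3: tuple[float, float] = (1.0, 6.0)) -> tuple[float, float]:
    """Split total chromium into (Cr(VI), Cr(III)) by a fixed species ratio.

    With the default 1:6 ratio the hexavalent fraction is 1/7 of total Cr.
    Mass is conserved: cr3 is computed as the remainder, so cr6 + cr3
    recovers the total to the last floating-point digit.
    """
    a, b = ratio_cr6_to_cr3
    if a <= 0 or b <= 0:
        raise ValueError(f"speciation weights must both be > 0, got {ratio_cr6_to_cr3}")
    if total_cr < 0:
        raise ValueError(f"total chromium must be ≥ 0, got {total_cr}")
    cr6 = total_cr * a / (a + b)
    cr3 = total_cr - cr6  # exact mass balance by construction
    return cr6, cr3


def speciate_composition(comp: CompositionTable, element: str = "Cr",
                         ratio_cr6_to_cr3: tuple[float, float] = (1.0, 6.0),
                         cr6_label: str = "Cr(VI)", cr3_label: str = "Cr(III)") -> CompositionTable:
    """Replace total-Cr rows of a composition table with the two species.

    Samples without a total-Cr row (or with species already present) are left
    untouched. The below-LOD flag of the total propagates to both species.
    """
    import pandas as pd

    df = comp.data
    mask = df["element"] == element
    if not mask.any():
        return comp
    keep = df[~mask]
    new_rows = []
    for _, row in df[mask].iterrows():
        cr6, cr3 = speciate_chromium(float(row["concentration"]), ratio_cr6_to_cr3)
        for label, value in ((cr6_label, cr6), (cr3_label, cr3)):
            new_rows.append({"sample": row["sample"], "city": row["city"],
                             "element": label, "concentration": value,
                             "below_lod": bool(row["below_lod"])})
    out = pd.concat([keep, pd.DataFrame(new_rows)], ignore_index=True)
    return CompositionTable(out)


def average_daily_intake(c_i: float, c_pm10: float, profile: ExposureProfile,
                         kind: IntakeKind, element: str = "") -> DailyIntake:
    """ADI of one element through inhalation, mg per kg body weight per day.

    ``kind`` selects the averaging time: ``non-carcinogenic`` → at_nc,
    ``carcinogenic`` → at_ca. Exactly linear in both ``c_i`` and ``c_pm10``.
    """
    if c_i < 0:
        raise ValueError(f"element concentration must be ≥ 0, got {c_i}")
    if c_pm10 < 0:
        raise ValueError(f"C_PM10 must be ≥ 0, got {c_pm10}")
    if kind == "non-carcinogenic":
        at = profile.at_nc
    elif kind == "carcinogenic":
        at = profile.at_ca
    else:
        raise ValueError(f"kind must be 'non-carcinogenic' or 'carcinogenic', got {kind!r}")
    adi = (c_i * (c_pm10 / 1000.0) * profile.inhr * profile.ef * profile.ed
           / (profile.bw * at * 1e6))
    return DailyIntake(element=element, receptor=profile.receptor, kind=kind, adi=adi)
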