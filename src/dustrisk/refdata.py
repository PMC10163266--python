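"""Reference data for inhalation risk assessment.

Exposure-parameter profiles for the receptor classes (adult, child), inhalation
toxicity reference values (RfC, IUR), endpoint characterization factors
(DALY/kg and species.yr/kg) and the regulatory decision thresholds. Bundled
defaults can be overridden from user CSV files with the documented schemas:

* profiles:  ``receptor,inhr,ef,ed,bw,at_nc,at_ca``
* toxicity:  ``element,rfc,iur,source``
* factors:   ``element,category,factor``

All files are UTF-8 CSV with a header row and ``.`` as the decimal separator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ExposureProfile",
    "ToxicityRecord",
    "CharacterizationFactor",
    "Thresholds",
    "IMPACT_CATEGORIES",
    "HUMAN_CATEGORIES",
    "ECO_CATEGORIES",
    "default_profiles",
    "load_exposure_profiles",
    "write_exposure_profiles",
    "load_toxicity_table",
    "write_toxicity_table",
    "load_characterization_factors",
    "write_characterization_factors",
]

#: The five endpoint impact categories handled by the characterization step.
HUMAN_CATEGORIES = (
    "human carcinogenic toxicity",
    "human non-carcinogenic toxicity",
)
ECO_CATEGORIES = (
    "freshwater ecotoxicity",
    "marine ecotoxicity",
    "terrestrial ecotoxicity",
)
IMPACT_CATEGORIES = HUMAN_CATEGORIES + ECO_CATEGORIES


class SchemaError(ValueError):
    """A CSV input did not match its documented schema."""


@dataclass(frozen=True)
class ExposureProfile:
    """Exposure parameters of one receptor class.

    Parameters
    ----------
    receptor : str
        Receptor label, e.g. ``"adult"`` or ``"child"``.
    inhr : float
        Inhalation rate, m³/day.
    ef : float
        Exposure frequency, days/year (≤ 366).
    ed : float
        Exposure duration, years.
    bw : float
        Body weight, kg.
    at_nc : float
        Averaging time for non-carcinogenic effects, days (ED × 365 by
        convention).
    at_ca : float
        Averaging time for carcinogenic effects, days (70 y × 365 d by
        convention).
    """

    receptor: str
    inhr: float
    ef: float
    ed: float
    bw: float
    at_nc: float
    at_ca: float

    def __post_init__(self) -> None:
        if not self.receptor:
            raise ValueError("receptor label must be non-empty")
        for name in ("inhr", "ef", "ed", "bw", "at_nc", "at_ca"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(
                    f"exposure parameter {name!r} must be finite and > 0, got {v}"
                )
        if self.ef > 366:
            raise ValueError(f"exposure frequency ef={self.ef} exceeds 366 days/year")

    def replace(self, **kwargs) -> "ExposureProfile":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ToxicityRecord:
    """Inhalation toxicity reference values for one element.

    ``rfc`` is the reference concentration in mg/m³ (non-carcinogenic
    benchmark); ``iur`` is the inhalation unit risk in (µg/m³)⁻¹ (carcinogenic
    slope). At least one of the two must be present. ``source`` records the
    provenance of the numbers.
    """

    element: str
    rfc: float | None = None
    iur: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element identifier must be non-empty")
        if self.rfc is None and self.iur is None:
            raise ValueError(
                f"toxicity record for {self.element!r} needs at least one of rfc/iur"
            )
        for name in ("rfc", "iur"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} for {self.element!r} must be ≥ 0, got {v}")


@dataclass(frozen=True)
class CharacterizationFactor:
    """Endpoint characterization factor for one element and impact category.

    ``factor`` is the endpoint impact per kg of the element emitted to air:
    DALY/kg for the human-toxicity categories, species.yr/kg for the
    ecotoxicity categories.
    """

    element: str
    category: str
    factor: float

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element identifier must be non-empty")
        if self.category not in IMPACT_CATEGORIES:
            raise ValueError(
                f"unknown impact category {self.category!r}; "
                f"expected one of {sorted(IMPACT_CATEGORIES)}"
            )
        if not math.isfinite(self.factor):
            raise ValueError(f"factor for {self.element!r} must be finite")


@dataclass(frozen=True)
class Thresholds:
    """Regulatory decision values for hazard index and cancer risk.

    HI above ``hi_limit`` (strictly) flags non-carcinogenic risk. Cancer risk
    at or below ``cr_acceptable`` is acceptable; between ``cr_acceptable``
    (exclusive) and ``cr_tolerable_upper`` (inclusive) is tolerable for
    regulatory purposes; above that, unacceptable.
    """

    hi_limit: float = 1.0
    cr_acceptable: float = 1e-6
    cr_tolerable_upper: float = 1e-4

    def __post_init__(self) -> None:
        if self.hi_limit <= 0:
            raise ValueError("hi_limit must be > 0")
        if not (0 < self.cr_acceptable < self.cr_tolerable_upper):
            raise ValueError("need 0 < cr_acceptable < cr_tolerable_upper")


# ---------------------------------------------------------------------------
# loaders


def _bundled(name: str) -> Path:
    return resources.files("dustrisk.data").joinpath(name)  # type: ignore[return-value]


def _read_csv(path, columns: Iterable[str], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # parse failure, missing file
        raise SchemaError(f"could not read {what} table from {path}: {exc}") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{what} table {path} is missing columns {sorted(missing)}")
    return df


def default_profiles() -> dict[str, ExposureProfile]:
    """The bundled adult and child exposure profiles (US EPA defaults)."""
    return load_exposure_profiles(None)


def load_exposure_profiles(path=None) -> dict[str, ExposureProfile]:
    """Load exposure profiles, keyed by receptor label.

    With ``path=None`` the bundled defaults are returned: an adult
    (InhR 15 m³/d, EF 350 d/y, ED 26 y, BW 80 kg, AT 9490/25550 d) and a
    2–6-year-old child (InhR 12.5, ED 6, BW 15, AT 2190/25550).
    """
    src = _bundled("exposure_profiles.csv") if path is None else path
    df = _read_csv(src, ("receptor", "inhr", "ef", "ed", "bw", "at_nc", "at_ca"),
                   "exposure profile")
    profiles: dict[str, ExposureProfile] = {}
    for idx, row in df.iterrows():
        label = str(row["receptor"])
        if label in profiles:
            raise SchemaError(f"duplicate receptor {label!r} at row {idx}")
        try:
            profiles[label] = ExposureProfile(
                receptor=label,
                inhr=float(row["inhr"]), ef=float(row["ef"]), ed=float(row["ed"]),
                bw=float(row["bw"]), at_nc=float(row["at_nc"]), at_ca=float(row["at_ca"]),
            )
        except ValueError as exc:
            raise SchemaError(f"invalid profile at row {idx} ({label!r}): {exc}") from exc
    return profiles


def write_exposure_profiles(profiles: Mapping[str, ExposureProfile], path) -> None:
    rows = [
        {"receptor": p.receptor, "inhr": p.inhr, "ef": p.ef, "ed": p.ed,
         "bw": p.bw, "at_nc": p.at_nc, "at_ca": p.at_ca}
        for p in profiles.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_toxicity_table(path=None) -> dict[str, ToxicityRecord]:
    """Load RfC/IUR records keyed by element.

    With ``path=None`` returns the bundled demonstration snapshot covering the
    usual dust-borne elements of concern (Cr(VI), Cr(III), As, Co, Ni, Mn, Zn,
    Cu, Pb, Cd). The snapshot is dated, carries a provenance column, and is a
    non-authoritative stand-in for a current screening-level lookup; override
    per element for regulatory work.
    """
    src = _bundled("toxicity_snapshot.csv") if path is None else path
    df = _read_csv(src, ("element", "rfc", "iur"), "toxicity")
    if "source" not in df.columns:
        df["source"] = ""
    dup = df["element"][df["element"].duplicated()].tolist()
    if dup:
        raise SchemaError(f"duplicate toxicity rows for elements {sorted(set(dup))}")
    records: dict[str, ToxicityRecord] = {}
    for idx, row in df.iterrows():
        rfc = None if pd.isna(row["rfc"]) else float(row["rfc"])
        iur = None if pd.isna(row["iur"]) else float(row["iur"])
        try:
            rec = ToxicityRecord(element=str(row["element"]), rfc=rfc, iur=iur,
                                 source="" if pd.isna(row["source"]) else str(row["source"]))
        except ValueError as exc:
            raise SchemaError(f"invalid toxicity row {idx}: {exc}") from exc
        records[rec.element] = rec
    return records


def write_toxicity_table(records: Mapping[str, ToxicityRecord], path) -> None:
    rows = [
        {"element": r.element, "rfc": r.rfc, "iur": r.iur, "source": r.source}
        for r in records.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_characterization_factors(path=None) -> list[CharacterizationFactor]:
    """Load endpoint characterization factors.

    With ``path=None`` returns the bundled demonstration set; like the
    toxicity snapshot it is labeled non-authoritative — endpoint factor tables
    are maintained externally and users supply their own for real studies.
    Negative factors are rejected here so downstream impacts stay ≥ 0.
    """
    src = _bundled("characterization_factors_demo.csv") if path is None else path
    df = _read_csv(src, ("element", "category", "factor"), "characterization factor")
    factors: list[CharacterizationFactor] = []
    for idx, row in df.iterrows():
        try:
            cf = CharacterizationFactor(
                element=str(row["element"]),
                category=str(row["category"]).strip().lower(),
                factor=float(row["factor"]),
            )
        except ValueError as exc:
            raise SchemaError(f"invalid factor row {idx}: {exc}") from exc
        if cf.factor < 0:
            raise SchemaError(f"negative factor at row {idx} for {cf.element!r}")
        factors.append(cf)
    return factors


def write_characterization_factors(factors: Iterable[CharacterizationFactor], path) -> None:
    rows = [{"element": f.element, "category": f.category, "factor": f.factor}
            for f in factors]
    pd.DataFrame(rows).to_csv(path, index=False)
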