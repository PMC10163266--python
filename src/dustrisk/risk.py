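"""Hazard quotients, hazard indices, cancer risks and the per-site assessment.

Non-carcinogenic risk uses the reference dose derived from the inhalation
reference concentration,

    RfD = RfC · InhR / BW            [mg/kg-day]
    HQ  = ADI_nc / RfD               HI = Σ_i HQ_i

and carcinogenic risk uses the inhalation unit risk,

    CR  = ADI_ca · IUR · 10³ · BW / InhR

summed over carcinogens. HI strictly above the decision limit (default 1)
flags non-carcinogenic risk; cancer risk at or below 10⁻⁶ is acceptable,
between 10⁻⁶ and 10⁻⁴ tolerable, above 10⁻⁴ unacceptable.

Two assessment modes are provided. ``strict`` applies the equations literally
with each receptor's own parameters; BW and InhR then cancel between the
intake and risk formulas, so CR has the closed form
``c_i · c_pm10 · ef · ed · iur / (at_ca · 10⁶)`` and HQ is identical across
receptors whenever at_nc = ed · 365. ``replicate`` instead uses a single
adult-derived RfD and adult BW/InhR factor for every receptor and lets each
non-reference receptor's carcinogenic averaging time equal its at_nc; this is
the convention implied by published site tables whose child/adult ratios
(HI ≈ 4.44, CR ≈ 11.97) are incompatible with the literal equations. Neither
mode is labeled "correct"; the report echoes which one produced it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import refdata
from .dataio import CompositionTable, PMSeries
from .exposure import (DailyIntake, ExposurePointConcentration,
                       average_daily_intake, exposure_point_concentration,
                       speciate_composition)
from .refdata import ExposureProfile, Thresholds, ToxicityRecord

__all__ = [
    "ReferenceDose",
    "SiteRisk",
    "RiskReport",
    "reference_dose",
    "hazard_quotient",
    "hazard_index",
    "cancer_risk",
    "total_cancer_risk",
    "classify_hazard_index",
    "classify_cancer_risk",
    "assess_sites",
]

logger = logging.getLogger(__name__)

MODES = ("strict", "replicate")


@dataclass(frozen=True)
class ReferenceDose:
    """Inhalation reference dose of one element for one receptor, mg/kg-day."""

    element: str
    receptor: str
    rfd: float


@dataclass(frozen=True)
class SiteRisk:
    """Risk indices of one sample for one receptor."""

    sample: str
    receptor: str
    hq_by_element: dict[str, float]
    hi: float
    cr_by_element: dict[str, float]
    cr_total: float
    hi_band: str
    cr_band: str


@dataclass
class RiskReport:
    """Per-site risk assessment results plus the configuration that made them.

    ``sites`` holds one :class:`SiteRisk` per (sample, receptor); the scalar
    attributes echo the assessment configuration so a report is
    self-describing.
    """

    sites: list[SiteRisk]
    mode: str
    c_pm10: ExposurePointConcentration
    thresholds: Thresholds
    profiles: dict[str, ExposureProfile]
    warnings: list[str] = field(default_factory=list)

    def site(self, sample: str, receptor: str) -> SiteRisk:
        for s in self.sites:
            if s.sample == sample and s.receptor == receptor:
                return s
        raise KeyError((sample, receptor))

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: one row per (sample, receptor, element)."""
        rows = []
        for s in self.sites:
            elements = sorted(set(s.hq_by_element) | set(s.cr_by_element))
            if not elements:
                elements = [""]
            for el in elements:
                rows.append({
                    "sample": s.sample, "receptor": s.receptor, "element": el,
                    "hq": s.hq_by_element.get(el, np.nan),
                    "cr": s.cr_by_element.get(el, np.nan),
                    "hi": s.hi, "cr_total": s.cr_total,
                    "hi_band": s.hi_band, "cr_band": s.cr_band,
                    "mode": self.mode, "c_pm10_used": self.c_pm10.value,
                })
        cols = ["sample", "receptor", "element", "hq", "cr", "hi", "cr_total",
                "hi_band", "cr_band", "mode", "c_pm10_used"]
        return pd.DataFrame(rows, columns=cols)

    def summary_frame(self) -> pd.DataFrame:
        """One row per (sample, receptor) with HI, total CR and bands."""
        rows = [{
            "sample": s.sample, "receptor": s.receptor, "hi": s.hi,
            "cr_total": s.cr_total, "hi_band": s.hi_band, "cr_band": s.cr_band,
        } for s in self.sites]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RiskReport":
        """Rebuild a report from :meth:`to_frame` output (round-trip loader).

        Configuration not represented in the tidy frame (thresholds, exposure
        profiles, EPC sample size and method) is restored as defaults.
        """
        sites: list[SiteRisk] = []
        for (sample, receptor), grp in df.groupby(["sample", "receptor"], sort=True):
            hq = {str(r["element"]): float(r["hq"]) for _, r in grp.iterrows()
                  if pd.notna(r["hq"])}
            cr = {str(r["element"]): float(r["cr"]) for _, r in grp.iterrows()
                  if pd.notna(r["cr"])}
            first = grp.iloc[0]
            sites.append(SiteRisk(
                sample=str(sample), receptor=str(receptor),
                hq_by_element=hq, hi=float(first["hi"]),
                cr_by_element=cr, cr_total=float(first["cr_total"]),
                hi_band=str(first["hi_band"]), cr_band=str(first["cr_band"]),
            ))
        c_pm10 = float(df["c_pm10_used"].iloc[0]) if len(df) else 0.0
        mode = str(df["mode"].iloc[0]) if len(df) else "strict"
        return cls(sites=sites, mode=mode,
                   c_pm10=ExposurePointConcentration(c_pm10, n=0, method="loaded"),
                   thresholds=Thresholds(), profiles=refdata.default_profiles())


# ---------------------------------------------------------------------------
# element-level operations


def reference_dose(tox: ToxicityRecord, profile: ExposureProfile,
                   rfd_mode: str = "receptor",
                   fixed_profile: ExposureProfile | None = None) -> ReferenceDose:
    """RfD = RfC · InhR / BW.

    ``receptor`` mode uses the receptor's own InhR and BW; ``fixed`` mode uses
    one reference profile (the adult by default) for every receptor, which is
    what the ``replicate`` assessment mode requires.
    """
    if tox.rfc is None:
        raise ValueError(f"element {tox.element!r} has no RfC; exclude it from HQ upstream")
    if rfd_mode == "receptor":
        basis = profile
    elif rfd_mode == "fixed":
        basis = fixed_profile if fixed_profile is not None else refdata.default_profiles()["adult"]
    else:
        raise ValueError(f"rfd_mode must be 'receptor' or 'fixed', got {rfd_mode!r}")
    return ReferenceDose(element=tox.element, receptor=profile.receptor,
                         rfd=tox.rfc * basis.inhr / basis.bw)


def hazard_quotient(adi: DailyIntake, rfd: ReferenceDose) -> float:
    """HQ = ADI / RfD for one element (non-carcinogenic intake only)."""
    if adi.kind != "non-carcinogenic":
        raise ValueError("hazard quotient needs a non-carcinogenic intake")
    if adi.element and rfd.element and adi.element != rfd.element:
        raise ValueError(f"element mismatch: intake {adi.element!r} vs RfD {rfd.element!r}")
    if rfd.rfd <= 0:
        raise ValueError(
            f"RfD for {rfd.element!r} is zero; the element must be excluded, not divided")
    return adi.adi / rfd.rfd


def hazard_index(hqs: Iterable[float]) -> float:
    """HI = exact sum of hazard quotients (empty → 0 with a warning)."""
    hqs = list(hqs)
    if any(h < 0 for h in hqs):
        raise ValueError("hazard quotients must be ≥ 0")
    if not hqs:
        logger.warning("hazard index over an empty quotient collection is 0")
        return 0.0
    return float(math.fsum(hqs))


def cancer_risk(adi: DailyIntake, tox: ToxicityRecord, profile: ExposureProfile,
                cr_mode: str = "receptor",
                fixed_profile: ExposureProfile | None = None) -> float:
    """CR = ADI · IUR · 10³ · BW/InhR (carcinogenic intake only).

    The 10³ converts the mg/kg-day intake back to µg-based units matching the
    IUR; BW/InhR comes from the receptor (``receptor`` mode) or from a single
    reference profile for all receptors (``fixed`` mode).
    """
    if adi.kind != "carcinogenic":
        raise ValueError("cancer risk needs a carcinogenic intake")
    if tox.iur is None:
        raise ValueError(f"element {tox.element!r} has no IUR; exclude it from CR upstream")
    if adi.element and tox.element and adi.element != tox.element:
        raise ValueError(f"element mismatch: intake {adi.element!r} vs IUR {tox.element!r}")
    if cr_mode == "receptor":
        basis = profile
    elif cr_mode == "fixed":
        basis = fixed_profile if fixed_profile is not None else refdata.default_profiles()["adult"]
    else:
        raise ValueError(f"cr_mode must be 'receptor' or 'fixed', got {cr_mode!r}")
    return adi.adi * tox.iur * 1e3 * basis.bw / basis.inhr


def total_cancer_risk(crs: Iterable[float]) -> float:
    """Exact sum of element cancer risks (empty → 0 with a warning)."""
    crs = list(crs)
    if any(c < 0 for c in crs):
        raise ValueError("cancer risks must be ≥ 0")
    if not crs:
        logger.warning("total cancer risk over an empty collection is 0")
        return 0.0
    return float(math.fsum(crs))


def classify_hazard_index(hi: float, thresholds: Thresholds = Thresholds()) -> str:
    """``risk`` iff HI strictly exceeds the decision limit, else ``no_risk``."""
    if hi < 0:
        raise ValueError("hazard index must be ≥ 0")
    return "risk" if hi > thresholds.hi_limit else "no_risk"


def classify_cancer_risk(cr: float, thresholds: Thresholds = Thresholds()) -> str:
    """Band a cancer risk: acceptable (≤ 10⁻⁶), tolerable (≤ 10⁻⁴), else
    unacceptable. Both boundaries are inclusive ("at or lower than")."""
    if cr < 0:
        raise ValueError("cancer risk must be ≥ 0")
    if cr <= thresholds.cr_acceptable:
        return "acceptable"
    if cr <= thresholds.cr_tolerable_upper:
        return "tolerable"
    return "unacceptable"


# ---------------------------------------------------------------------------
# pipeline


def assess_sites(comp: CompositionTable, pm: PMSeries,
                 profiles: Mapping[str, ExposureProfile] | None = None,
                 tox: Mapping[str, ToxicityRecord] | None = None,
                 thresholds: Thresholds | None = None,
                 mode: str = "strict",
                 epc_method: str = "t_ucl95",
                 cr_ratio: tuple[float, float] = (1.0, 6.0),
                 reference_receptor: str = "adult") -> RiskReport:
    """Run the full per-site assessment: the analogue of a published site table.

    Pipeline: PM₁₀ exposure-point concentration → chromium speciation →
    per-element ADI (both kinds) per receptor → HQ/HI and CR/total CR →
    classification. Elements lacking an RfC are omitted from HI, those lacking
    an IUR from CR — each omission is logged and counted in
    ``report.warnings`` rather than silently zeroed.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    profiles = dict(profiles) if profiles is not None else refdata.default_profiles()
    tox = dict(tox) if tox is not None else refdata.load_toxicity_table()
    thresholds = thresholds if thresholds is not None else Thresholds()

    epc = exposure_point_concentration(pm.pm10, method=epc_method)
    comp = speciate_composition(comp, ratio_cr6_to_cr3=cr_ratio)

    overlap = set(comp.elements) & set(tox)
    if not overlap:
        raise ValueError(
            "no overlap between composition elements and the toxicity table; "
            f"composition has {sorted(comp.elements)}")

    if reference_receptor not in profiles:
        raise ValueError(f"reference receptor {reference_receptor!r} not among profiles")
    ref_profile = profiles[reference_receptor]
    param_mode = "receptor" if mode == "strict" else "fixed"

    warnings: list[str] = []
    skipped_rfc = sorted(el for el in overlap if tox[el].rfc is None)
    skipped_iur = sorted(el for el in overlap if tox[el].iur is None)
    if skipped_rfc:
        msg = f"{len(skipped_rfc)} element(s) without RfC omitted from HI: {skipped_rfc}"
        logger.warning(msg)
        warnings.append(msg)
    if skipped_iur:
        msg = f"{len(skipped_iur)} element(s) without IUR omitted from CR: {skipped_iur}"
        logger.warning(msg)
        warnings.append(msg)
    no_tox = sorted(set(comp.elements) - set(tox))
    if no_tox:
        msg = f"{len(no_tox)} element(s) without any toxicity record ignored: {no_tox}"
        logger.info(msg)
        warnings.append(msg)

    sites: list[SiteRisk] = []
    for sample in comp.samples:
        conc = comp.concentrations(sample)
        for receptor, profile in profiles.items():
            # replicate mode: non-reference receptors average carcinogenic
            # intake over their at_nc instead of the lifetime at_ca
            if mode == "replicate" and receptor != reference_receptor:
                intake_profile = profile.replace(at_ca=profile.at_nc)
            else:
                intake_profile = profile
            hq_by_element: dict[str, float] = {}
            cr_by_element: dict[str, float] = {}
            for el in sorted(overlap):
                c_i = conc.get(el)
                if c_i is None:
                    continue
                rec = tox[el]
                if rec.rfc is not None and rec.rfc > 0:
                    adi_nc = average_daily_intake(c_i, epc.value, intake_profile,
                                                  "non-carcinogenic", element=el)
                    rfd = reference_dose(rec, profile, rfd_mode=param_mode,
                                         fixed_profile=ref_profile)
                    hq_by_element[el] = hazard_quotient(adi_nc, rfd)
                elif rec.rfc == 0:
                    msg = f"element {el!r} has RfC=0; excluded from HI for {sample}/{receptor}"
                    logger.warning(msg)
                    if msg not in warnings:
                        warnings.append(msg)
                if rec.iur is not None:
                    adi_ca = average_daily_intake(c_i, epc.value, intake_profile,
                                                  "carcinogenic", element=el)
                    cr_by_element[el] = cancer_risk(adi_ca, rec, profile,
                                                    cr_mode=param_mode,
                                                    fixed_profile=ref_profile)
            hi = hazard_index(hq_by_element.values())
            cr_total = total_cancer_risk(cr_by_element.values())
            sites.append(SiteRisk(
                sample=sample, receptor=receptor,
                hq_by_element=hq_by_element, hi=hi,
                cr_by_element=cr_by_element, cr_total=cr_total,
                hi_band=classify_hazard_index(hi, thresholds),
                cr_band=classify_cancer_risk(cr_total, thresholds),
            ))
    return RiskReport(sites=sites, mode=mode, c_pm10=epc, thresholds=thresholds,
                      profiles=profiles, warnings=warnings)
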