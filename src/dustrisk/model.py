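"""Model/Results front door over the assessment pipeline.

:class:`InhalationRiskModel` binds a composition table, a PM series and the
reference data; ``fit()`` runs the full assessment and returns a
:class:`RiskResults` carrying per-site indices, classification bands, the
exposure-point concentration and a ``summary()`` table.
:class:`EndpointImpactModel` does the same for endpoint characterization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from . import dataio, refdata
from .dataio import CompositionTable, PMSeries
from .endpoint_impact import ImpactResult, characterize_impacts, impacts_to_frame
from .exposure import speciate_composition
from .refdata import (CharacterizationFactor, ExposureProfile, Thresholds,
                      ToxicityRecord)
from .risk import RiskReport, assess_sites

__all__ = ["InhalationRiskModel", "RiskResults",
           "EndpointImpactModel", "ImpactResults"]


class InhalationRiskModel:
    """Inhalation health-risk model for dust-borne heavy metals.

    Parameters
    ----------
    composition : CompositionTable
        Per-sample element concentrations (mg/kg); total Cr is speciated
        during fitting.
    pm_series : PMSeries
        Daily PM series from which the PM₁₀ exposure-point concentration is
        estimated.
    toxicity, profiles, thresholds
        Reference data; bundled defaults when omitted.
    mode : {"strict", "replicate"}
        ``strict`` applies the intake/risk equations literally per receptor;
        ``replicate`` follows the convention of the published site tables
        (adult-derived RfD and BW/InhR for all receptors, non-carcinogenic
        averaging time reused for child carcinogenic intake).
    epc_method : {"t_ucl95", "mean", "max"}
        Exposure-point concentration estimator.
    cr_speciation : (float, float)
        Cr(VI):Cr(III) weights, default 1:6.
    """

    def __init__(self, composition: CompositionTable, pm_series: PMSeries,
                 toxicity: Mapping[str, ToxicityRecord] | None = None,
                 profiles: Mapping[str, ExposureProfile] | None = None,
                 thresholds: Thresholds | None = None,
                 mode: str = "strict", epc_method: str = "t_ucl95",
                 cr_speciation: tuple[float, float] = (1.0, 6.0)):
        self.composition = composition
        self.pm_series = pm_series
        self.toxicity = dict(toxicity) if toxicity is not None else refdata.load_toxicity_table()
        self.profiles = dict(profiles) if profiles is not None else refdata.default_profiles()
        self.thresholds = thresholds if thresholds is not None else Thresholds()
        self.mode = mode
        self.epc_method = epc_method
        self.cr_speciation = cr_speciation

    @classmethod
    def from_csv(cls, composition_path, pm_path, toxicity_path=None,
                 profiles_path=None, lod: float = 1.0, lod_policy: str = "half",
                 **kwargs) -> "InhalationRiskModel":
        """Build a model straight from the documented CSV inputs."""
        comp = dataio.read_composition_table(composition_path, lod=lod, lod_policy=lod_policy)
        pm = dataio.read_pm_series(pm_path)
        tox = refdata.load_toxicity_table(toxicity_path)
        profiles = refdata.load_exposure_profiles(profiles_path)
        return cls(comp, pm, toxicity=tox, profiles=profiles, **kwargs)

    def fit(self) -> "RiskResults":
        report = assess_sites(self.composition, self.pm_series,
                              profiles=self.profiles, tox=self.toxicity,
                              thresholds=self.thresholds, mode=self.mode,
                              epc_method=self.epc_method,
                              cr_ratio=self.cr_speciation)
        return RiskResults(model=self, report=report)


@dataclass
class RiskResults:
    """Fitted per-site risk indices with classification and diagnostics."""

    model: InhalationRiskModel
    report: RiskReport

    @property
    def c_pm10(self) -> float:
        """Exposure-point PM₁₀ concentration used, µg/m³."""
        return self.report.c_pm10.value

    @property
    def hazard_index(self) -> pd.Series:
        df = self.report.summary_frame()
        return df.set_index(["sample", "receptor"])["hi"]

    @property
    def cancer_risk(self) -> pd.Series:
        df = self.report.summary_frame()
        return df.set_index(["sample", "receptor"])["cr_total"]

    def summary(self) -> str:
        """Human-readable assessment table (HI, total CR, bands per site)."""
        df = self.report.summary_frame().copy()
        df["hi"] = df["hi"].map(lambda v: f"{v:.3g}")
        df["cr_total"] = df["cr_total"].map(lambda v: f"{v:.3g}")
        epc = self.report.c_pm10
        lines = [
            "Inhalation risk assessment",
            "=" * 58,
            f"mode: {self.report.mode}    EPC method: {epc.method}",
            f"C_PM10 (exposure-point): {epc.value:.4g} ug/m3  (n={epc.n})",
            f"thresholds: HI > {self.report.thresholds.hi_limit:g}; "
            f"CR bands at {self.report.thresholds.cr_acceptable:g} / "
            f"{self.report.thresholds.cr_tolerable_upper:g}",
            "-" * 58,
            df.to_string(index=False),
        ]
        if self.report.warnings:
            lines += ["-" * 58] + [f"note: {w}" for w in self.report.warnings]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        dataio.write_risk_report(self.report, path)

    def plot_hazard_index(self, ax=None):
        """Bar plot of HI per site, one bar group per receptor."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        df = self.report.summary_frame()
        pivot = df.pivot(index="sample", columns="receptor", values="hi")
        pivot.plot.bar(ax=ax)
        ax.axhline(self.report.thresholds.hi_limit, color="crimson", ls="--", lw=1,
                   label=f"HI = {self.report.thresholds.hi_limit:g}")
        ax.set_ylabel("hazard index")
        ax.legend()
        return ax


class EndpointImpactModel:
    """Endpoint characterization of particles (DALY and species.yr per basis mass)."""

    def __init__(self, composition: CompositionTable,
                 factors: Iterable[CharacterizationFactor] | None = None,
                 basis_mass: float = 1.0, speciate: bool = True,
                 cr_speciation: tuple[float, float] = (1.0, 6.0)):
        self.composition = composition
        self.factors = (list(factors) if factors is not None
                        else refdata.load_characterization_factors())
        self.basis_mass = basis_mass
        self.speciate = speciate
        self.cr_speciation = cr_speciation

    def fit(self) -> "ImpactResults":
        comp = self.composition
        if self.speciate:
            comp = speciate_composition(comp, ratio_cr6_to_cr3=self.cr_speciation)
        results = characterize_impacts(comp, self.factors, basis_mass=self.basis_mass)
        return ImpactResults(model=self, results=results)


@dataclass
class ImpactResults:
    """Fitted endpoint impacts per sample."""

    model: EndpointImpactModel
    results: list[ImpactResult]

    def to_frame(self) -> pd.DataFrame:
        return impacts_to_frame(self.results)

    def summary(self) -> str:
        df = self.to_frame()
        fmt = df.copy()
        for col in df.columns:
            if col != "sample":
                fmt[col] = df[col].map(lambda v: f"{v:.3g}")
        return "\n".join([
            f"Endpoint impact characterization (basis: "
            f"{self.model.basis_mass:g} g of particles, emitted to air)",
            "=" * 72,
            fmt.to_string(index=False),
        ])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
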