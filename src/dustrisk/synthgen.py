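"""Seeded generator of synthetic dust-monitoring campaigns.

Emulates the statistical structure the assessment assumes, without any field
data: per-element log-normal concentrations (the standard model for strictly
positive, right-skewed environmental concentration data) modulated by
per-site multiplicative offsets, and a daily PM series that is log-normal at
baseline with occasional dust-event days multiplied by a fixed magnitude —
the spiky pattern of an arid-region campaign whose events push both size
fractions past the WHO 24-h guidelines.

The seeding contract derives an independent stream per element (and one for
the PM model) from the root seed via hashed sub-keys, so adding or removing
an element never perturbs the draws of the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

from .dataio import CompositionTable, PMSeries

__all__ = [
    "ElementModel", "SiteModel", "PMModel", "GeneratorConfig",
    "default_config", "load_config", "save_config",
    "generate_composition", "generate_pm_series", "generate_campaign",
]


@dataclass(frozen=True)
class ElementModel:
    """Log-normal concentration model: geometric mean (mg/kg) and GSD (≥ 1)."""

    gm: float
    gsd: float

    def __post_init__(self) -> None:
        if self.gm <= 0:
            raise ValueError(f"geometric mean must be > 0, got {self.gm}")
        if self.gsd < 1:
            raise ValueError(f"geometric standard deviation must be ≥ 1, got {self.gsd}")


@dataclass(frozen=True)
class SiteModel:
    """A sampling site: its city label and a multiplicative enrichment offset."""

    city: str
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.offset <= 0:
            raise ValueError(f"site offset must be > 0, got {self.offset}")


@dataclass(frozen=True)
class PMModel:
    """Daily PM₂.₅/PM₁₀ model, µg/m³.

    Baseline days are log-normal (gm, gsd per fraction); with probability
    ``event_prob`` a day is a dust event and both fractions are multiplied by
    ``event_magnitude``. PM₂.₅ is clipped to PM₁₀ per day.
    """

    gm_pm25: float = 40.0
    gsd_pm25: float = 1.6
    gm_pm10: float = 55.0
    gsd_pm10: float = 1.6
    event_prob: float = 0.2
    event_magnitude: float = 4.0
    n_days: int = 150
    start: str = "2021-04-01"

    def __post_init__(self) -> None:
        for name in ("gm_pm25", "gm_pm10"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("gsd_pm25", "gsd_pm10"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        if not 0 <= self.event_prob <= 1:
            raise ValueError(f"event_prob must be in [0, 1], got {self.event_prob}")
        if self.event_magnitude < 1:
            raise ValueError(f"event_magnitude must be ≥ 1, got {self.event_magnitude}")
        if self.n_days < 1:
            raise ValueError("n_days must be ≥ 1")
        if self.gm_pm10 < self.gm_pm25:
            raise ValueError("PM₁₀ baseline must be ≥ PM₂.₅ baseline")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full campaign configuration: elements, sites, replication, PM model, seed."""

    elements: dict[str, ElementModel]
    sites: dict[str, SiteModel]
    pm: PMModel = PMModel()
    n_samples: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("config needs at least one element")
        if not self.sites:
            raise ValueError("config needs at least one site")
        if self.n_samples < 1:
            raise ValueError("n_samples must be ≥ 1")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


#: Crustal-dominated element panel typical of arid-basin dust: major crustal
#: elements at percent-level concentrations, trace metals at mg/kg levels.
_DEFAULT_ELEMENTS: dict[str, tuple[float, float]] = {
    "Fe": (35000, 1.4), "Ca": (50000, 1.4), "Al": (60000, 1.4),
    "K": (18000, 1.4), "Mg": (15000, 1.4), "Na": (10000, 1.5),
    "Ti": (3000, 1.5), "Mn": (600, 1.6), "Ba": (400, 1.6),
    "Sr": (300, 1.6), "V": (70, 1.7), "Zn": (80, 1.8),
    "Cr": (80, 1.8), "Ni": (40, 1.8), "Cu": (30, 1.8),
    "Pb": (20, 1.9), "Co": (12, 1.8), "As": (8, 2.0),
    "Mo": (1.5, 2.0), "Cd": (0.3, 2.0),
}

#: Eleven sites around a seasonal playa, grouped into five cities, with mild
#: enrichment offsets (one city somewhat enriched, one depleted).
_DEFAULT_SITES: dict[str, tuple[str, float]] = {
    "D1": ("Jiroft", 1.10), "D2": ("Jiroft", 1.05), "D3": ("Jiroft", 1.00),
    "D4": ("Roodbar Jonoob", 1.05), "D5": ("Roodbar Jonoob", 0.95),
    "D6": ("Ghaleh Ganj", 0.90), "D7": ("Ghaleh Ganj", 0.95),
    "D8": ("Kahnooj", 0.80), "D9": ("Kahnooj", 1.00),
    "D10": ("Iranshahr", 1.00), "D11": ("Iranshahr", 1.30),
}


def default_config(seed: int = 0) -> GeneratorConfig:
    """The bundled arid-playa campaign: 11 sites, 20 elements, 150 days."""
    return GeneratorConfig(
        elements={el: ElementModel(gm, gsd) for el, (gm, gsd) in _DEFAULT_ELEMENTS.items()},
        sites={s: SiteModel(city, off) for s, (city, off) in _DEFAULT_SITES.items()},
        pm=PMModel(),
        n_samples=1,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# YAML config


def load_config(path) -> GeneratorConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    elements = {el: ElementModel(**spec) for el, spec in raw["elements"].items()}
    sites = {s: SiteModel(**spec) for s, spec in raw["sites"].items()}
    pm = PMModel(**raw.get("pm", {}))
    return GeneratorConfig(elements=elements, sites=sites, pm=pm,
                           n_samples=int(raw.get("n_samples", 1)),
                           seed=int(raw.get("seed", 0)))


def save_config(config: GeneratorConfig, path) -> None:
    raw = {
        "elements": {el: {"gm": m.gm, "gsd": m.gsd} for el, m in config.elements.items()},
        "sites": {s: {"city": m.city, "offset": m.offset} for s, m in config.sites.items()},
        "pm": {k: getattr(config.pm, k) for k in
               ("gm_pm25", "gsd_pm25", "gm_pm10", "gsd_pm10",
                "event_prob", "event_magnitude", "n_days", "start")},
        "n_samples": config.n_samples,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# generation


def _stream(seed: int, domain: int, key: str) -> np.random.Generator:
    """Independent RNG stream keyed by (root seed, domain, hashed name)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, domain, zlib.crc32(key.encode())]))


def generate_composition(config: GeneratorConfig) -> CompositionTable:
    """Draw a per-sample element concentration table.

    Each element draws ``n_samples`` values per site from its own stream, in
    fixed site order; concentration = gm · site offset · exp(σ·z) with
    σ = ln(GSD). GSD = 1 degenerates to exactly gm · offset. Deterministic
    given (config, seed).
    """
    rows = []
    site_items = list(config.sites.items())
    for el, model in config.elements.items():
        rng = _stream(config.seed, 1, el)
        sigma = math.log(model.gsd)
        for site, smodel in site_items:
            z = rng.standard_normal(config.n_samples)
            values = model.gm * smodel.offset * np.exp(sigma * z)
            for k in range(config.n_samples):
                sample = site if config.n_samples == 1 else f"{site}-{k + 1}"
                rows.append({"sample": sample, "city": smodel.city, "element": el,
                             "concentration": float(values[k]), "below_lod": False})
    return CompositionTable(pd.DataFrame(rows))


def generate_pm_series(config: GeneratorConfig) -> PMSeries:
    """Draw the daily PM₂.₅/PM₁₀ series.

    Baseline log-normal days; event days (Bernoulli ``event_prob``) have both
    fractions multiplied by ``event_magnitude``; PM₂.₅ is clipped to PM₁₀
    after scaling so the per-day size ordering always holds. Deterministic
    given (config, seed).
    """
    pmc = config.pm
    rng = _stream(config.seed, 2, "pm")
    n = pmc.n_days
    z25 = rng.standard_normal(n)
    z10 = rng.standard_normal(n)
    events = rng.random(n) < pmc.event_prob
    pm25 = pmc.gm_pm25 * np.exp(math.log(pmc.gsd_pm25) * z25)
    pm10 = pmc.gm_pm10 * np.exp(math.log(pmc.gsd_pm10) * z10)
    mult = np.where(events, pmc.event_magnitude, 1.0)
    pm25 *= mult
    pm10 *= mult
    pm25 = np.minimum(pm25, pm10)
    start = date.fromisoformat(pmc.start)
    dates = [start + timedelta(days=i) for i in range(n)]
    return PMSeries(pd.DataFrame({"date": pd.to_datetime(dates),
                                  "pm25": pm25, "pm10": pm10}))


def generate_campaign(config: GeneratorConfig) -> tuple[CompositionTable, PMSeries]:
    """Generate the composition table and PM series of one campaign."""
    return generate_composition(config), generate_pm_series(config)
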