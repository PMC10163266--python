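"""Measurement input readers, report writers and guideline summaries.

The canonical composition layout is long/tidy — one row per (sample, element)
— which tolerates element panels that differ between sites; a wide-format
convenience reader is provided for spreadsheet-style tables. Values reported
below the detection limit may be written as ``<LOD`` cells and are resolved at
ingest by an explicit policy, never silently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .refdata import SchemaError

__all__ = [
    "CompositionTable",
    "PMSeries",
    "GuidelineSummary",
    "WHO_PM25_24H",
    "WHO_PM10_24H",
    "read_composition_table",
    "read_composition_wide",
    "write_composition_table",
    "read_pm_series",
    "write_pm_series",
    "summarize_guideline_exceedance",
    "write_risk_report",
    "read_risk_report",
]

logger = logging.getLogger(__name__)

#: WHO 24-hour air-quality guideline values, µg/m³ (2021 revision).
WHO_PM25_24H = 15.0
WHO_PM10_24H = 45.0

LOD_POLICIES = ("half", "zero", "keep")

_COMP_COLS = ["sample", "city", "element", "concentration", "below_lod"]


@dataclass(frozen=True)
class CompositionTable:
    """Per-sample element concentrations in dust, mg element / kg dust.

    ``data`` columns: sample, city, element, concentration (mg/kg),
    below_lod (bool). (sample, element) pairs are unique and concentrations
    non-negative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = set(_COMP_COLS) - set(df.columns)
        if missing:
            raise SchemaError(f"composition table missing columns {sorted(missing)}")
        if (df["concentration"] < 0).any():
            bad = df.loc[df["concentration"] < 0, ["sample", "element"]]
            raise ValueError(f"negative concentrations for {bad.to_records(index=False).tolist()}")
        dup = df.duplicated(subset=["sample", "element"])
        if dup.any():
            pairs = df.loc[dup, ["sample", "element"]].to_records(index=False).tolist()
            raise ValueError(f"duplicate (sample, element) rows: {pairs}")
        object.__setattr__(self, "data", df.reset_index(drop=True)[_COMP_COLS])

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    @property
    def elements(self) -> list[str]:
        return list(dict.fromkeys(self.data["element"]))

    def city_of(self, sample: str) -> str:
        rows = self.data.loc[self.data["sample"] == sample, "city"]
        return str(rows.iloc[0]) if len(rows) else ""

    def concentrations(self, sample: str) -> dict[str, float]:
        sub = self.data[self.data["sample"] == sample]
        return dict(zip(sub["element"], sub["concentration"].astype(float)))


@dataclass(frozen=True)
class PMSeries:
    """Daily PM₂.₅ and PM₁₀ concentrations, µg/m³, on unique ordered dates."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = {"date", "pm25", "pm10"} - set(df.columns)
        if missing:
            raise SchemaError(f"PM series missing columns {sorted(missing)}")
        df = df.copy()
        df["date"] = pd.to_datetime(df["date"])
        if df["date"].duplicated().any():
            dups = df.loc[df["date"].duplicated(), "date"].dt.strftime("%Y-%m-%d").tolist()
            raise ValueError(f"duplicate dates in PM series: {dups}")
        for col in ("pm25", "pm10"):
            neg = df[col] < 0
            if neg.any():
                when = df.loc[neg, "date"].dt.strftime("%Y-%m-%d").tolist()
                raise ValueError(f"negative {col} on {when}")
        if not df["date"].is_monotonic_increasing:
            logger.warning("PM series dates were unordered; sorting")
            df = df.sort_values("date")
        object.__setattr__(self, "data", df.reset_index(drop=True)[["date", "pm25", "pm10"]])

    def __len__(self) -> int:
        return len(self.data)

    @property
    def pm25(self) -> np.ndarray:
        return self.data["pm25"].to_numpy(dtype=float)

    @property
    def pm10(self) -> np.ndarray:
        return self.data["pm10"].to_numpy(dtype=float)


@dataclass(frozen=True)
class GuidelineSummary:
    """Exceedance statistics of a PM series against 24-h guideline values."""

    n_days: int
    guideline_pm25: float
    guideline_pm10: float
    exceed_days_pm25: int
    exceed_days_pm10: int
    exceed_fraction_pm25: float
    exceed_fraction_pm10: float
    mean_pm25: float
    mean_pm10: float
    max_pm25: float
    max_pm10: float


# ---------------------------------------------------------------------------
# composition ingest


def _resolve_lod(raw, lod: float, policy: str) -> tuple[float, bool]:
    """Resolve one concentration cell to (value, below_lod)."""
    if isinstance(raw, str):
        s = raw.strip()
        if s.startswith("<"):
            rest = s[1:].strip()
            cell_lod = float(rest) if rest else lod
            if policy == "half":
                return cell_lod / 2.0, True
            if policy == "zero":
                return 0.0, True
            return cell_lod, True  # keep: carry the LOD itself
        raw = float(s)
    value = float(raw)
    return value, False


def read_composition_table(path, lod: float = 1.0, lod_policy: str = "half") -> CompositionTable:
    """Read a long/tidy composition CSV (sample,city,element,concentration).

    Cells written as ``<x`` (or bare ``<``, taking the default ``lod``) are
    below the detection limit and resolved per ``lod_policy``: ``half`` →
    LOD/2 (the common risk-assessment convention), ``zero`` → 0, ``keep`` →
    the LOD itself. The below-LOD flag is retained either way.
    """
    if lod_policy not in LOD_POLICIES:
        raise ValueError(f"lod_policy must be one of {LOD_POLICIES}, got {lod_policy!r}")
    df = pd.read_csv(path, comment="#", dtype={"concentration": str})
    missing = {"sample", "element", "concentration"} - set(df.columns)
    if missing:
        raise SchemaError(f"composition file {path} missing columns {sorted(missing)}")
    if "city" not in df.columns:
        df["city"] = ""
    resolved = [_resolve_lod(v, lod, lod_policy) for v in df["concentration"]]
    df["concentration"] = [v for v, _ in resolved]
    df["below_lod"] = [b for _, b in resolved]
    return CompositionTable(df[_COMP_COLS])


def read_composition_wide(path, lod: float = 1.0, lod_policy: str = "half",
                          city_map: Mapping[str, str] | None = None) -> CompositionTable:
    """Read a wide composition CSV: one row per sample, one column per element.

    Expects a ``sample`` column (and optionally ``city``); every other column
    is an element. Melted to the canonical long layout.
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    if "sample" not in df.columns:
        raise SchemaError(f"wide composition file {path} needs a 'sample' column")
    id_vars = ["sample"] + (["city"] if "city" in df.columns else [])
    long = df.melt(id_vars=id_vars, var_name="element", value_name="concentration")
    if "city" not in long.columns:
        long["city"] = ""
    if city_map:
        long["city"] = long["sample"].map(dict(city_map)).fillna(long["city"])
    resolved = [_resolve_lod(v, lod, lod_policy) for v in long["concentration"]]
    long["concentration"] = [v for v, _ in resolved]
    long["below_lod"] = [b for _, b in resolved]
    return CompositionTable(long[_COMP_COLS])


def write_composition_table(comp: CompositionTable, path) -> None:
    comp.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PM series


def read_pm_series(path) -> PMSeries:
    """Read a daily PM CSV with columns date (ISO-8601), pm25, pm10.

    Unordered rows are sorted with a warning; gaps between dates are allowed
    and logged.
    """
    df = pd.read_csv(path, comment="#")
    series = PMSeries(df)
    dates = series.data["date"]
    if len(dates) > 1:
        gaps = int((dates.diff().dt.days > 1).sum())
        if gaps:
            logger.info("PM series has %d gap(s) between consecutive dates", gaps)
    return series


def write_pm_series(series: PMSeries, path) -> None:
    out = series.data.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def summarize_guideline_exceedance(series: PMSeries,
                                   guideline_pm25: float = WHO_PM25_24H,
                                   guideline_pm10: float = WHO_PM10_24H) -> GuidelineSummary:
    """Count days strictly above each 24-h guideline, with mean and maximum.

    The comparison is strict (``>``): a day exactly at the guideline is not an
    exceedance, so counts are unambiguous.
    """
    if len(series) == 0:
        raise ValueError("PM series is empty")
    pm25, pm10 = series.pm25, series.pm10
    n = len(series)
    e25 = int((pm25 > guideline_pm25).sum())
    e10 = int((pm10 > guideline_pm10).sum())
    return GuidelineSummary(
        n_days=n,
        guideline_pm25=guideline_pm25, guideline_pm10=guideline_pm10,
        exceed_days_pm25=e25, exceed_days_pm10=e10,
        exceed_fraction_pm25=e25 / n, exceed_fraction_pm10=e10 / n,
        mean_pm25=float(pm25.mean()), mean_pm10=float(pm10.mean()),
        max_pm25=float(pm25.max()), max_pm10=float(pm10.max()),
    )


# ---------------------------------------------------------------------------
# risk report serialization


def _sig2(x: float) -> str:
    """Display formatting at 2 significant figures (3 for cancer risks is not
    needed: stored full-precision values sit alongside)."""
    if x == 0:
        return "0"
    return f"{x:.2g}"

_REPORT_COLS = [
    "sample", "receptor", "element", "hq", "cr", "hi", "cr_total",
    "hi_band", "cr_band", "mode", "c_pm10_used",
    "hi_display", "cr_total_display",
]


def write_risk_report(report, path) -> None:
    """Serialize a risk report as tidy CSV, one row per sample/receptor/element.

    Site-level columns (hi, cr_total, bands, mode, c_pm10_used) repeat across
    the element block of each (sample, receptor). Values are stored at full
    precision; ``hi_display``/``cr_total_display`` carry the 2-significant-
    figure rendering used in report tables.
    """
    df = report.to_frame()
    df = df.sort_values(["sample", "receptor", "element"]).reset_index(drop=True)
    df["hi_display"] = df["hi"].map(_sig2)
    df["cr_total_display"] = df["cr_total"].map(_sig2)
    df[_REPORT_COLS].to_csv(path, index=False)


def read_risk_report(path):
    """Load a CSV written by :func:`write_risk_report` back into a RiskReport."""
    from .risk import RiskReport  # local import: avoid cycle

    df = pd.read_csv(path, comment="#")
    missing = set(_REPORT_COLS) - {"hi_display", "cr_total_display"} - set(df.columns)
    if missing:
        raise SchemaError(f"risk report {path} missing columns {sorted(missing)}")
    return RiskReport.from_frame(df)
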