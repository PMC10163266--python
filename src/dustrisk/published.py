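"""Published Jazmurian-basin summary tables bundled as consistency fixtures.

Two small tables printed at 2–3 significant figures: the per-site hazard
indices / total cancer risks for adult and child receptors, and the per-site
endpoint impacts per 1 g of particles. They carry no raw measurements — the
underlying concentration data are unpublished — but their internal structure
(child/adult ratios, endpoint additivity) pins down the assessment
conventions the package's ``replicate`` mode implements.
"""

from __future__ import annotations

import pandas as pd

from .refdata import _bundled

__all__ = ["load_site_risk_table", "load_site_impact_table"]


def load_site_risk_table() -> pd.DataFrame:
    """Site-level HI and total CR (adult, child) for the 11 published sites."""
    return pd.read_csv(_bundled("jazmurian_site_risk.csv"), comment="#")


def load_site_impact_table() -> pd.DataFrame:
    """Per-site endpoint impacts per 1 g of particles for the 11 published sites."""
    return pd.read_csv(_bundled("jazmurian_site_impacts.csv"), comment="#")
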