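"""Lifetime fatal secondary-cancer risk from organ equivalent dose.

Risk = NCRP Report 116 lifetime fatal-cancer probability coefficient
(% per Sv, Table 7.2: breast 0.20, lung 0.85) times the organ equivalent
dose in Sv.  For photons the equivalent dose in Sv equals the absorbed dose
in Gy, so an organ dose in mSv converts directly.  Cells are rounded
half-up to two decimals, matching the printed convention (a 2.2 mSv
contralateral-breast dose rounds to 0.00%).

Breast risks use the contralateral-breast dose; lung risks the ipsilateral-
lung dose.  The heart has no cancer-risk coefficient here; the literature
excess-relative-risk slope for ischaemic heart disease (~17% per Gy) is
exposed as an informational constant only, never a computed endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .dosimetry import DoseTable

__all__ = [
    "RiskCoefficient",
    "DEFAULT_COEFFICIENTS",
    "HEART_ERR_SLOPE_PER_GY",
    "lifetime_risk",
    "risk_table",
]


@dataclass(frozen=True)
class RiskCoefficient:
    """Lifetime fatal-cancer probability for one site, % per Sv."""

    site: str
    pct_per_sv: float


DEFAULT_COEFFICIENTS = (
    RiskCoefficient("breast", 0.20),
    RiskCoefficient("lung", 0.85),
)

#: Literature-cited excess-relative-risk slope for ischaemic heart disease,
#: per Gy of heart dose.  Informational context only; not a computed endpoint.
HEART_ERR_SLOPE_PER_GY = 0.17

_RISK_SOURCE_ORGAN = {"breast": "contralateral_breast", "lung": "ipsilateral_lung"}


def lifetime_risk(dose_msv: float, pct_per_sv: float) -> float:
    """Lifetime risk (%) = coefficient (%/Sv) x dose (Sv), rounded half-up to 2 decimals."""
    if dose_msv < 0:
        raise ValueError("dose must be >= 0")
    raw = Decimal(repr(dose_msv)) * Decimal(repr(pct_per_sv)) / Decimal(1000)
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def risk_table(dose_table: DoseTable, coefficients=DEFAULT_COEFFICIENTS) -> pd.DataFrame:
    """Lifetime-risk table (%) per cancer site and technique.

    Rows are the risk sites with their coefficient; columns preserve the
    dose table's technique ordering.
    """
    rows = {}
    for coef in coefficients:
        organ = _RISK_SOURCE_ORGAN[coef.site]
        rows[coef.site] = [coef.pct_per_sv] + [
            lifetime_risk(dose_table.get(organ, t, "mSv"), coef.pct_per_sv)
            for t in dose_table.techniques
        ]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["pct_per_sv", *dose_table.techniques]
    )
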