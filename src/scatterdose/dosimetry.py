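"""Organ doses from tally energies; the hybrid total; contribution decomposition.

Tally energy depositions (MeV per source history) become organ doses by
normalising to the prescription: the treated-breast tally is pinned to the
prescription dose and every organ tally is scaled by the same factor, so the
absolute source calibration cancels.  Organ doses are reported in Gy for the
treated breast and heart (cardiomyopathy context) and in mSv otherwise
(secondary-cancer context); for photons the radiation weighting factor is 1,
so mSv = mGy numerically.

The hybrid method adds the measured head-leakage/room-back-scatter component
(power-law model evaluated at the organ's distance from the field edge,
times the central-axis dose) to the Monte Carlo internal/modifier scatter.

The contribution decomposition attributes the beam-modifier ("compensator")
component by paired-run subtraction: same seed and histories with and
without the modifier; the difference per organ is the compensator share.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .leakage import LeakageModel

__all__ = [
    "ORGANS",
    "ORGAN_UNITS",
    "TECHNIQUES",
    "TALLY_TO_ORGAN",
    "DEFAULT_ORGAN_FIELD_DISTANCES_CM",
    "DoseTable",
    "normalize_to_prescription",
    "hybrid_total",
    "contribution_decomposition",
    "assemble_dose_table",
]

ORGANS = ("treated_breast", "contralateral_breast", "spleen", "ipsilateral_lung", "heart")
ORGAN_UNITS = {
    "treated_breast": "Gy",
    "contralateral_breast": "mSv",
    "spleen": "mSv",
    "ipsilateral_lung": "mSv",
    "heart": "Gy",
}
TECHNIQUES = ("pbsi", "hdr_catheter", "wedge", "imrt", "3dcrt_pbi")

TALLY_TO_ORGAN = {
    "left_breast": "treated_breast",
    "right_breast": "contralateral_breast",
    "spleen": "spleen",
    "ipsilateral_lung": "ipsilateral_lung",
    "heart_lad": "heart",
}

#: Distance (cm) from the field edge used for the leakage term, per organ.
#: The spleen's 5 cm is the anatomical statement; the others are phantom
#: geometry estimates carried as configuration.
DEFAULT_ORGAN_FIELD_DISTANCES_CM = {
    "contralateral_breast": 3.0,
    "spleen": 5.0,
    "ipsilateral_lung": 4.0,
    "heart": 3.0,
}


class DoseTable:
    """Per-organ, per-technique doses; stored in Gy, displayed in row units.

    Rows follow the fixed organ ordering; the printed precision is integers
    for mSv rows and one decimal for Gy rows.
    """

    def __init__(self, data_gy: pd.DataFrame):
        missing = [o for o in ORGANS if o not in data_gy.index]
        if missing:
            raise ValueError(f"dose table missing organ rows: {missing}")
        if len(data_gy.columns) == 0:
            raise ValueError("dose table needs at least one technique column")
        self.data_gy = data_gy.loc[list(ORGANS)].astype(float)
        if (self.data_gy.to_numpy() < 0).any():
            raise ValueError("doses must be >= 0")

    @property
    def techniques(self):
        return tuple(self.data_gy.columns)

    def get(self, organ: str, technique: str, unit: str | None = None) -> float:
        """Dose for one cell, in ``unit`` (default: the organ's display unit)."""
        gy = float(self.data_gy.loc[organ, technique])
        unit = unit or ORGAN_UNITS[organ]
        return gy if unit == "Gy" else gy * 1000.0

    def column(self, technique: str) -> dict:
        """Organ doses of one technique as ``{organ: (value, unit)}`` at printed precision."""
        out = {}
        for organ in ORGANS:
            unit = ORGAN_UNITS[organ]
            v = self.get(organ, technique, unit)
            out[organ] = (round(v, 1) if unit == "Gy" else round(v), unit)
        return out

    def display(self) -> pd.DataFrame:
        """Paper-shaped frame: values in row units at printed precision."""
        rows = {}
        for organ in ORGANS:
            unit = ORGAN_UNITS[organ]
            vals = [self.get(organ, t, unit) for t in self.techniques]
            vals = [round(v, 1) if unit == "Gy" else int(round(v)) for v in vals]
            rows[organ] = [unit] + vals
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["unit", *self.techniques]
        )

    def to_csv(self, path):
        df = self.display().reset_index(names="organ")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DoseTable":
        df = pd.read_csv(path).set_index("organ")
        units = df.pop("unit")
        gy = df.astype(float)
        for organ, unit in units.items():
            if unit == "mSv":
                gy.loc[organ] = gy.loc[organ] / 1000.0
        return cls(gy)

    def __eq__(self, other):
        return isinstance(other, DoseTable) and self.display().equals(other.display())


def normalize_to_prescription(tally_results, protocol, phantom) -> dict:
    """Convert tally energies into organ doses pinned to the prescription.

    ``tally_results`` maps tally id -> object with a ``mean`` (MeV per
    history); the treated-breast tally is scaled to exactly the prescription
    dose and all organs share the scale factor.  Tally mass uses the tally
    volume and the density of the material at its centre (lung tallies are
    low-density).  Returns ``{organ: dose_gy}``.
    """
    dose_per_hist = {}
    for tid, organ in TALLY_TO_ORGAN.items():
        if tid not in tally_results:
            continue
        tally = phantom.tally(tid)
        rid = phantom.region_at(tally.center)
        region = next(r for r in phantom.geometry.ordered_regions if r.id == rid)
        mass_g = tally.volume_cc * region.material.density
        dose_per_hist[organ] = tally_results[tid].mean / mass_g
    if "treated_breast" not in dose_per_hist or dose_per_hist["treated_breast"] <= 0:
        raise ValueError("treated-breast tally mean must be > 0 for normalization")
    scale = protocol.prescription_gy / dose_per_hist["treated_breast"]
    return {organ: scale * d for organ, d in dose_per_hist.items()}


def hybrid_total(
    mc_scatter_gy: float,
    leakage_model: LeakageModel | None,
    distance_cm: float,
    field_cm,
    central_axis_gy: float,
) -> float:
    """Total organ dose = Monte Carlo scatter + leakage fraction x central-axis dose."""
    if leakage_model is None:
        return mc_scatter_gy
    if distance_cm <= 0:
        raise ValueError("organ distance from field edge must be > 0")
    return mc_scatter_gy + float(leakage_model.fraction(distance_cm, field_cm)) * central_axis_gy


def contribution_decomposition(open_doses, modifier_doses, leakage_doses) -> pd.DataFrame:
    """Split total organ dose into internal-scatter / compensator / head-leakage %.

    All three arguments map organ -> dose (same unit).  The compensator share
    is the paired-run difference (with-modifier minus open); differences that
    come out negative (statistical fluctuation) are clamped to zero with a
    warning.  Rows sum to 100 within 0.1.
    """
    rows = {}
    for organ in open_doses:
        internal = open_doses[organ]
        comp = modifier_doses.get(organ, internal) - internal
        if comp < 0:
            warnings.warn(
                f"negative compensator component for {organ} ({comp:.3g}); clamped to 0",
                stacklevel=2,
            )
            comp = 0.0
        leak = leakage_doses.get(organ, 0.0)
        total = internal + comp + leak
        if total <= 0:
            rows[organ] = (np.nan, np.nan, np.nan)
            continue
        rows[organ] = (
            100.0 * internal / total,
            100.0 * comp / total,
            100.0 * leak / total,
        )
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["internal_scatter", "compensator", "head_leakage"]
    )


def assemble_dose_table(columns: dict) -> DoseTable:
    """Build a DoseTable from per-technique organ-dose columns ``{tech: {organ: Gy}}``.

    Column order follows the canonical technique ordering where present.
    """
    if not columns:
        raise ValueError("need at least one technique column")
    ordered = [t for t in TECHNIQUES if t in columns]
    ordered += [t for t in columns if t not in ordered]
    df = pd.DataFrame({t: pd.Series(columns[t]) for t in ordered})
    return DoseTable(df)
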