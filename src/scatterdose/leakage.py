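"""Head-leakage and room back-scatter model: power-law fits to out-of-field measurements.

Out-of-field dose from treatment-head leakage and room back-scatter is too
improbable to estimate by simulating photons through the head, so the hybrid
method measures it: relative dose (fraction of the central-axis dose) at
5 cm depth, 2.5 / 7 / 10 / 19 / 28 cm from the beam axis, for 16 x 20 and
8 x 20 cm^2 half-beam fields.  Each field size is fitted with a power law
``dose = a * distance**b`` in log-log space; unseen field sizes interpolate
the coefficients linearly in field area.

The packaged measurement fixture is synthetic (the experiment's ionisation-
chamber data are not published numerically): configurable generating power
laws honouring the two qualitative anchors -- the fraction drops below 1% of
the central-axis dose away from the field, and the larger field runs ~20%
hotter (room back-scatter).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MEASUREMENT_DISTANCES_CM",
    "FIELD_SIZES_CM",
    "DEFAULT_GENERATING_LAWS",
    "LeakageModel",
    "fit_power_law",
    "leakage_fraction",
    "generate_leakage_fixture",
    "fit_leakage_model",
]

MEASUREMENT_DISTANCES_CM = (2.5, 7.0, 10.0, 19.0, 28.0)
MEASUREMENT_DEPTH_CM = 5.0
FIELD_SIZES_CM = ((16.0, 20.0), (8.0, 20.0))

#: Generating power laws (a, b) per field size for the synthetic fixture;
#: the 16 x 20 field is 20% above the 8 x 20 field at every distance.
DEFAULT_GENERATING_LAWS = {(16.0, 20.0): (0.036, -1.2), (8.0, 20.0): (0.030, -1.2)}

_COLUMNS = ["distance_cm", "depth_cm", "field_w_cm", "field_l_cm", "relative_dose"]


def fit_power_law(measurements: pd.DataFrame):
    """Least-squares power-law fit ``dose = a * d**b`` in log-log space.

    ``measurements`` needs columns ``distance_cm`` and ``relative_dose`` (one
    field size).  Returns ``(a, b, residual_rms)`` where the residual is in
    log space.  Two points give the exact interpolating power law.
    """
    d = measurements["distance_cm"].to_numpy(dtype=float)
    y = measurements["relative_dose"].to_numpy(dtype=float)
    if len(np.unique(d)) < 2:
        raise ValueError("need >= 2 distinct distances")
    if np.any(d <= 0) or np.any(y <= 0):
        raise ValueError("distances and doses must be positive")
    b, log_a = np.polyfit(np.log(d), np.log(y), 1)
    resid = np.log(y) - (log_a + b * np.log(d))
    return float(np.exp(log_a)), float(b), float(np.sqrt(np.mean(resid**2)))


@dataclass
class LeakageModel:
    """Per-field-size power-law coefficients with linear-in-area interpolation."""

    coefficients: dict  # {(w, l): (a, b)}

    def __post_init__(self):
        for (w, l), (a, b) in self.coefficients.items():
            if a <= 0:
                raise ValueError(f"a must be > 0 for field {(w, l)}")
            if b >= 0:
                raise ValueError(f"b must be < 0 (dose falls with distance), field {(w, l)}")

    def fraction(self, distance_cm: float, field_cm) -> float:
        """Relative out-of-field dose at ``distance_cm`` for the given field size."""
        if np.any(np.asarray(distance_cm) <= 0):
            raise ValueError("distance must be > 0")
        area = float(np.prod(field_cm))
        areas = np.array([w * l for (w, l) in self.coefficients])
        coefs = np.array(list(self.coefficients.values()))
        order = np.argsort(areas)
        a = np.interp(area, areas[order], coefs[order, 0])
        b = np.interp(area, areas[order], coefs[order, 1])
        return a * np.asarray(distance_cm, dtype=float) ** b

    def to_json(self, path):
        payload = {f"{w:g}x{l:g}": [a, b] for (w, l), (a, b) in self.coefficients.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            payload = json.load(fh)
        coefs = {}
        for key, (a, b) in payload.items():
            w, l = (float(x) for x in key.split("x"))
            coefs[(w, l)] = (a, b)
        return cls(coefs)


def leakage_fraction(model: LeakageModel, distance_cm: float, field_cm) -> float:
    """Evaluate the field-size-specific power law (module-surface convenience)."""
    return model.fraction(distance_cm, field_cm)


def generate_leakage_fixture(
    seed: int = 0,
    noise_sigma: float = 0.05,
    laws: dict | None = None,
) -> pd.DataFrame:
    """Synthetic out-of-field measurement table emulating the water-phantom experiment.

    Measurements at the five standard distances, 5 cm depth, both field
    sizes, drawn from the generating power laws with seeded multiplicative
    log-normal noise.  ``noise_sigma=0`` returns values exactly on the laws.
    """
    laws = laws or DEFAULT_GENERATING_LAWS
    rng = np.random.default_rng(seed)
    rows = []
    for (w, l), (a, b) in laws.items():
        for d in MEASUREMENT_DISTANCES_CM:
            value = a * d**b
            if noise_sigma > 0:
                value *= float(np.exp(rng.normal(0.0, noise_sigma)))
            rows.append((d, MEASUREMENT_DEPTH_CM, w, l, value))
    return pd.DataFrame(rows, columns=_COLUMNS)


def fit_leakage_model(measurements: pd.DataFrame) -> LeakageModel:
    """Fit one power law per field size present in a measurement table."""
    coefs = {}
    for (w, l), grp in measurements.groupby(["field_w_cm", "field_l_cm"]):
        a, b, _ = fit_power_law(grp)
        coefs[(float(w), float(l))] = (a, b)
    return LeakageModel(coefs)
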