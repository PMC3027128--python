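"""Fixtures and oracle geometries so every pipeline stage is testable offline.

Three families:

* :func:`table2_fixture` -- the published per-organ, per-technique dose table
  embedded verbatim as the single source of truth for printed doses (it is a
  transcription of reported results, never a simulation output, and feeds
  the risk stage and report shapes);
* :func:`generate_leakage_fixture` (re-exported from :mod:`.leakage`) -- the
  synthetic out-of-field measurement table;
* :func:`oracle_phantoms` -- miniature geometries with closed-form answers
  (pure-absorber slab for exp(-mu t) transmission, a weak uniform absorber
  with two scoring spheres for the inverse-square law, a water sphere with a
  centred tally as an energy-conservation stress case).

Everything regenerates bit-identically from a seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dosimetry import DoseTable
from .geometry import Box, Geometry, Region, Sphere
from .leakage import generate_leakage_fixture
from .phantom import Phantom, TallyVolume
from .physics import DEFAULT_ENERGY_GRID, Material, default_materials

__all__ = [
    "table2_fixture",
    "oracle_phantoms",
    "absorber_slab_phantom",
    "inverse_square_phantom",
    "water_sphere_phantom",
    "uniform_absorber",
    "generate_leakage_fixture",
    "write_fixture_bundle",
]

# Published organ doses (row unit: mSv except where noted in Gy) per technique.
_TABLE2_MSV = {
    #                    pbsi   hdr_catheter  wedge   imrt   3dcrt_pbi
    "treated_breast": (90e3, 34e3, 50e3, 50e3, 38.5e3),     # Gy row
    "contralateral_breast": (2.2, 230.0, 1695.0, 206.0, 140.0),
    "spleen": (44.0, 1171.0, 2300.0, 810.0, 130.0),
    "ipsilateral_lung": (790.0, 2471.0, 582.0, 121.0, 80.0),
    "heart": (700.0, 3600.0, 2700.0, 1100.0, 700.0),        # Gy row (0.7 ... Gy)
}
_TECHS = ("pbsi", "hdr_catheter", "wedge", "imrt", "3dcrt_pbi")


def table2_fixture() -> DoseTable:
    """The printed per-organ dose table as a :class:`DoseTable` (verbatim)."""
    df = pd.DataFrame(_TABLE2_MSV, index=_TECHS).T / 1000.0  # -> Gy
    return DoseTable(df)


def uniform_absorber(mu_per_cm: float, name: str = "absorber") -> Material:
    """Synthetic pure-photoelectric material with a flat linear attenuation.

    Every interaction absorbs the photon locally, so transmission through a
    thickness ``t`` is exactly ``exp(-mu t)`` -- the textbook oracle.
    """
    grid = DEFAULT_ENERGY_GRID
    return Material(
        name, 1.0, grid,
        photoelectric=np.full_like(grid, mu_per_cm),
        incoherent=np.zeros_like(grid),
        coherent=np.zeros_like(grid),
    )


def _vacuum():
    return default_materials()["vacuum"]


def absorber_slab_phantom(mu_per_cm: float = 0.5, thickness_cm: float = 2.0) -> Phantom:
    """Pure-absorber slab normal to +x; default mu*t = 1 so transmission = 1/e."""
    regions = [
        Region("slab", Box((0.0, -50.0, -50.0), (thickness_cm, 50.0, 50.0)),
               uniform_absorber(mu_per_cm), 10),
        Region("world", Box((-60.0, -60.0, -60.0), (60.0, 60.0, 60.0)), _vacuum(), 0),
    ]
    return Phantom(Geometry(regions), [], ((0, -50, -50), (thickness_cm, 50, 50)),
                   {"mu_per_cm": mu_per_cm, "thickness_cm": thickness_cm})


def inverse_square_phantom(
    mu_per_cm: float = 0.02, r_near: float = 5.0, r_far: float = 10.0, tally_radius: float = 2.0
) -> Phantom:
    """Weak uniform absorber with two scoring spheres at r and 2r from the origin.

    With a point isotropic source at the origin, the expected deposition per
    unit mass in each sphere follows the attenuated inverse-square fluence;
    the dose ratio between the spheres is ~ (r_far/r_near)^2 up to the
    exp(-mu r) correction.
    """
    tallies = [
        TallyVolume("near", (r_near, 0.0, 0.0), tally_radius,
                    4.0 / 3.0 * np.pi * tally_radius**3),
        TallyVolume("far", (r_far, 0.0, 0.0), tally_radius,
                    4.0 / 3.0 * np.pi * tally_radius**3),
    ]
    regions = [
        Region("medium", Sphere((0.0, 0.0, 0.0), 40.0), uniform_absorber(mu_per_cm), 10),
        Region("world", Box((-50.0, -50.0, -50.0), (50.0, 50.0, 50.0)), _vacuum(), 0),
    ]
    return Phantom(Geometry(regions), tallies, ((-40,) * 3, (40,) * 3),
                   {"mu_per_cm": mu_per_cm, "r_near": r_near, "r_far": r_far,
                    "tally_radius": tally_radius})


def water_sphere_phantom(radius_cm: float = 10.0) -> Phantom:
    """A single water sphere in vacuum with a small centred tally."""
    mats = default_materials()
    tallies = [TallyVolume("center", (0.0, 0.0, 0.0), 0.53738, 0.65)]
    regions = [
        Region("water", Sphere((0.0, 0.0, 0.0), radius_cm), mats["water"], 10),
        Region("world", Box((-50.0, -50.0, -50.0), (50.0, 50.0, 50.0)), mats["vacuum"], 0),
    ]
    return Phantom(Geometry(regions), tallies, ((-radius_cm,) * 3, (radius_cm,) * 3),
                   {"radius_cm": radius_cm})


def oracle_phantoms() -> dict:
    """All miniature oracle geometries keyed by name."""
    return {
        "absorber_slab": absorber_slab_phantom(),
        "inverse_square": inverse_square_phantom(),
        "water_sphere": water_sphere_phantom(),
    }


def write_fixture_bundle(out_dir, seed: int = 0):
    """Write every fixture (leakage CSV, dose-table CSV, oracle descriptions) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    generate_leakage_fixture(seed).to_csv(out / "leakage_measurements.csv", index=False)
    table2_fixture().to_csv(out / "organ_dose_table.csv")
    descriptions = {name: ph.config for name, ph in oracle_phantoms().items()}
    with open(out / "oracle_phantoms.json", "w") as fh:
        json.dump(descriptions, fh, indent=1, sort_keys=True)
    return out
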