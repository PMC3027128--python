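"""Anthropomorphic chest phantom: slab torso, breasts, lungs, heart, spleen, tallies.

The phantom realises the printed constraints of the reference anatomy -- a
small-breasted left-sided patient: overall bounding box 26 x 12.2 x 70 cm
(width x height x length, within 5% of the nominal 12 x 26 x 70 cm), 520 cc
breast volumes, small (0.65 cc) spherical tally volumes in both breasts, at
the anterior heart (LAD position) and in the posterior ipsilateral lung, and
a 150 cc spherical spleen tally centred 5 cm inferior to the breast-field
inferior edge.

Coordinate convention (right-handed, lengths in cm): origin at the phantom
centre, +x patient-left, +y anterior, +z superior.  The treated breast is
the LEFT breast (+x side).

Realisation choices (the reference gives bounding dimensions and volumes,
not surface equations): the torso is a water-equivalent slab, thicker in the
abdomen (inferior to the field) so the 150 cc spleen tally fits; breasts are
half-ellipsoid domes protruding anteriorly from the chest-wall plane y = 0,
their height bounded by the 12.2 cm overall thickness, their lateral
footprint leaving a midline gap between the breasts (so tangential beams can
clear the contralateral dome), and their superior-inferior semi-axis solved
so each dome is exactly 520 cc.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .geometry import (
    WORLD_EXIT,
    Box,
    Ellipsoid,
    Geometry,
    HalfSpace,
    Intersection,
    Sphere,
    Union,
)
from .geometry import Region
from .physics import Material, default_materials

__all__ = [
    "TallyVolume",
    "Phantom",
    "DEFAULT_PHANTOM_CONFIG",
    "build_phantom",
    "mc_region_volume",
    "axial_slice_mask",
    "export_axial_slice",
    "load_phantom_config",
    "save_phantom_config",
    "config_hash",
]


def _sphere_radius_for_volume(volume_cc: float) -> float:
    return (3.0 * volume_cc / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class TallyVolume:
    """A spherical scoring volume (not a material region)."""

    id: str
    center: tuple
    radius: float
    nominal_volume_cc: float

    def __post_init__(self):
        analytic = 4.0 / 3.0 * np.pi * self.radius**3
        if abs(analytic - self.nominal_volume_cc) > 0.01 * self.nominal_volume_cc:
            raise ValueError(
                f"tally {self.id}: analytic volume {analytic:.3f} cc deviates "
                f">1% from nominal {self.nominal_volume_cc} cc"
            )

    @property
    def volume_cc(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3


@dataclass
class Phantom:
    """Regions + tally volumes + bounding box, ready for transport."""

    geometry: Geometry
    tallies: list
    bounding_box: tuple  # ((xlo,ylo,zlo), (xhi,yhi,zhi)) of the anatomy
    config: dict = field(default_factory=dict)

    def region_at(self, point) -> str:
        return self.geometry.region_at(point)

    def distance_to_boundary(self, point, direction):
        return self.geometry.distance_to_boundary(point, direction)

    def tally(self, tally_id: str) -> TallyVolume:
        for t in self.tallies:
            if t.id == tally_id:
                return t
        raise KeyError(tally_id)


# Default geometry parameters (cm / cc).  Tally centres are configuration,
# not constants: the reference describes their anatomical placement but
# prints no coordinates.
DEFAULT_PHANTOM_CONFIG = {
    "half_width": 13.0,
    "half_length": 35.0,
    "thorax_thickness": 6.1,      # slab y in [-6.1, 0]
    "abdomen_anterior": 6.1,      # abdomen box y in [-6.1, +6.1]
    "thorax_z_min": 5.0,          # abdomen occupies z < this
    "breast": {
        "volume_cc": 520.0,
        "dome_height": 6.1,       # anterior semi-axis of the half-ellipsoid dome
        "dome_half_width": 4.8,   # lateral semi-axis; leaves a midline gap
        "center_x": 6.5,
        "center_z": 15.0,
    },
    "chest_wall_thickness": 1.0,
    "lung": {"center": [6.5, -3.5, 15.0], "semi_axes": [4.5, 2.6, 9.0]},
    "heart": {"center": [2.0, -3.0, 10.0], "semi_axes": [3.0, 2.5, 3.5]},
    "spleen": {"center": [6.5, 0.0, 0.0], "radius": 3.7},
    "world_half_extent": 130.0,
    "tallies": {
        # treated-breast tally on the brachytherapy prescription surface
        # (target centre + 3 cm along (1,1,1)/sqrt(3)): the HDR dose is
        # prescribed to the 85% isodose surface and the seed-implant dose to
        # the minimal peripheral dose, and the point is off the dwell/seed
        # lattice; for tangential beams the point is mid-field, so external
        # normalisation is unaffected
        "left_breast": {"center": [8.232, 4.232, 16.732], "volume_cc": 0.65},
        "right_breast": {"center": [-8.232, 4.232, 16.732], "volume_cc": 0.65},
        "heart_lad": {"center": [2.0, -1.3, 10.0], "volume_cc": 0.65},
        "ipsilateral_lung": {"center": [9.0, -4.8, 15.0], "volume_cc": 0.65},
        "spleen": {"center": [6.5, 0.0, 0.0], "volume_cc": 150.0},
    },
}


def _merge(base: dict, overrides: dict | None) -> dict:
    out = {}
    for k, v in base.items():
        out[k] = dict(_merge(v, None)) if isinstance(v, dict) else v
    for k, v in (overrides or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def build_phantom(
    config: dict | None = None,
    materials: dict[str, Material] | None = None,
    extra_regions: list | None = None,
) -> Phantom:
    """Build the chest phantom (plus optional beam-line regions, e.g. wedges).

    Returns a :class:`Phantom` whose geometry contains the regions
    ``{left_breast, right_breast, left_lung, right_lung, heart, chest_wall,
    spleen, body, world_air}`` and the five named tally volumes.
    """
    cfg = _merge(DEFAULT_PHANTOM_CONFIG, config)
    mats = materials or default_materials()

    hw = cfg["half_width"]
    hl = cfg["half_length"]
    tt = cfg["thorax_thickness"]
    ya = cfg["abdomen_anterior"]
    z0 = cfg["thorax_z_min"]

    bcfg = cfg["breast"]
    a_y = bcfg["dome_height"]
    a_x = bcfg["dome_half_width"]
    # superior-inferior semi-axis solved so each half-ellipsoid dome is exactly
    # the configured breast volume: V = (2/3) pi a_x a_y a_z
    a_z = 3.0 * bcfg["volume_cc"] / (2.0 * np.pi * a_x * a_y)
    bx, bz = bcfg["center_x"], bcfg["center_z"]

    def breast(sign):
        return Intersection(
            (
                Ellipsoid((sign * bx, 0.0, bz), (a_x, a_y, a_z)),
                HalfSpace((0.0, -1.0, 0.0), 0.0),  # y >= 0
            )
        )
    lung = cfg["lung"]
    heart = cfg["heart"]
    spleen = cfg["spleen"]

    body_shape = Union(
        (
            Box((-hw, -tt, z0), (hw, 0.0, hl)),        # thorax slab
            Box((-hw, -tt, -hl), (hw, ya, z0)),        # abdomen (thicker)
        )
    )
    world = cfg["world_half_extent"]

    regions = [
        Region("heart", Ellipsoid(tuple(heart["center"]), tuple(heart["semi_axes"])), mats["soft_tissue"], 70),
        Region("left_lung", Ellipsoid(tuple(lung["center"]), tuple(lung["semi_axes"])), mats["lung"], 61),
        Region(
            "right_lung",
            Ellipsoid((-lung["center"][0], lung["center"][1], lung["center"][2]), tuple(lung["semi_axes"])),
            mats["lung"],
            60,
        ),
        Region("left_breast", breast(+1), mats["soft_tissue"], 51),
        Region("right_breast", breast(-1), mats["soft_tissue"], 50),
        Region("spleen", Sphere(tuple(spleen["center"]), spleen["radius"]), mats["soft_tissue"], 45),
        Region(
            "chest_wall",
            Box((-hw, -cfg["chest_wall_thickness"], z0), (hw, 0.0, hl)),
            mats["soft_tissue"],
            30,
        ),
        Region("body", body_shape, mats["soft_tissue"], 20),
        Region("world_air", Box((-world, -world, -world), (world, world, world)), mats["air"], 0),
    ]
    regions.extend(extra_regions or [])

    tallies = []
    for tid, tcfg in cfg["tallies"].items():
        tallies.append(
            TallyVolume(
                tid,
                tuple(tcfg["center"]),
                _sphere_radius_for_volume(tcfg["volume_cc"]),
                tcfg["volume_cc"],
            )
        )

    bbox = ((-hw, -tt, -hl), (hw, max(ya, a_y), hl))
    phantom = Phantom(Geometry(regions), tallies, bbox, cfg)

    # Sanity: every tally centre must sit inside a real anatomical region.
    for t in tallies:
        rid = phantom.region_at(t.center)
        if rid in (WORLD_EXIT, "world_air"):
            raise ValueError(f"tally {t.id} centred outside the anatomy ({rid})")
    return phantom


def mc_region_volume(phantom: Phantom, region_id: str, n: int = 200_000, rng=None) -> float:
    """Monte Carlo volume (cc) of a region by rejection sampling in the bounding box."""
    rng = rng or np.random.default_rng(0)
    lo, hi = np.asarray(phantom.bounding_box[0]), np.asarray(phantom.bounding_box[1])
    pts = rng.uniform(lo, hi, size=(n, 3))
    idx = phantom.geometry.region_index(pts)
    names = [r.id for r in phantom.geometry.ordered_regions]
    target = names.index(region_id)
    frac = float(np.mean(idx == target))
    return frac * float(np.prod(hi - lo))


def axial_slice_mask(phantom: Phantom, z: float, resolution: float = 0.5):
    """Debug export: grid of region indices in the axial plane at height ``z``.

    Returns ``(xs, ys, mask)``; write ``mask`` as a CSV grid for visual checks.
    """
    lo, hi = phantom.bounding_box
    xs = np.arange(lo[0], hi[0] + resolution / 2, resolution)
    ys = np.arange(lo[1], hi[1] + resolution / 2, resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
    mask = phantom.geometry.region_index(pts).reshape(gy.shape)
    return xs, ys, mask


def export_axial_slice(phantom: Phantom, z: float, path, resolution: float = 0.5):
    """Write the axial region-index mask at height ``z`` as a CSV grid (debug aid)."""
    import pandas as pd

    xs, ys, mask = axial_slice_mask(phantom, z, resolution)
    pd.DataFrame(mask, index=np.round(ys, 3), columns=np.round(xs, 3)).to_csv(path)


def load_phantom_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_phantom_config(cfg: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping, for run manifests."""
    return hashlib.sha256(yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:12]
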