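"""The five adjuvant breast-radiotherapy technique configurations.

Techniques and prescriptions:

* ``wedge``       -- whole-breast, 50 Gy / 25 fx, opposed 16 x 20 cm tangents
                     with 30 deg steel wedges (rho = 7.81 g/cm^3);
* ``imrt``        -- whole-breast field-in-field ("virtual wedge"/breast IMRT),
                     50 Gy / 25 fx, 80% open + 20% half-blocked segment;
* ``3dcrt_pbi``   -- partial-breast 3D-CRT, 38.5 Gy / 10 fx, 8 x 20 cm tangents;
* ``hdr_catheter``-- multi-catheter Ir-192 HDR, 34 Gy / 10 fx to the 85% isodose,
                     dwells on a 1 cm grid across a 3 cm-radius (113 cc) target,
                     10 Ci source;
* ``pbsi``        -- permanent breast seed implant, 100 Pd-103 seeds of 2.7 U
                     (0.2088 Ci total), 90 Gy.

External beams are modelled as point sources at 100 cm SAD collimated to the
field aperture.  Tangents are realised as opposed half-beam-blocked fields
(effective transverse width = half the nominal collimator setting, matching
the half-beam setup of the out-of-field measurements) tilted 45 deg
anterior-posterior in the axial plane: on the slab phantom this covers the
treated dome and clips lung and anterior heart while keeping the
contralateral-breast and posterior-lung tallies out of both primary cones.
Brachytherapy emitters radiate isotropically (4 pi) from the dwell/seed
positions.

Dwell times use a uniform-loading point-source dose model (inverse-square
times exponential tissue attenuation) prescribed on the target-sphere
surface; the vendor inverse-planning optimiser is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Polytope, Region
from .physics import (
    SourceSpectrum,
    bremsstrahlung_6mv,
    default_materials,
    ir192_spectrum,
    pd103_spectrum,
)

__all__ = [
    "ProtocolConfig",
    "BeamConfig",
    "SeedPlan",
    "DwellPlan",
    "PROTOCOL_NAMES",
    "make_protocol",
    "sphere_volume",
    "seeds_total_activity",
    "make_seed_plan",
    "make_dwell_plan",
    "dwell_dose_rate",
    "balloon_doses",
    "TangentialBeamEmitter",
    "IsotropicPointsEmitter",
    "wedge_regions",
    "make_emitter",
]

PROTOCOL_NAMES = ("wedge", "imrt", "3dcrt_pbi", "hdr_catheter", "pbsi")

#: Air-kerma strength per apparent activity for Pd-103, U/mCi.
PD103_U_PER_MCI = 1.293
#: Air-kerma strength per apparent activity for Ir-192, U/Ci.
IR192_U_PER_CI = 4037.0
#: Pd-103 half-life, days.
PD103_HALF_LIFE_DAYS = 16.99

#: Default treated-volume centre (the left-breast target), cm.
DEFAULT_TARGET_CENTER = (6.5, 2.5, 15.0)


@dataclass
class BeamConfig:
    """Opposed tangential beam pair on the slab phantom.

    The nominal field size is the collimator setting; tangents are half-beam
    blocked (as in the out-of-field leakage measurements), so the effective
    transverse aperture is half the nominal width, slightly offset anterior.
    With the default 45 deg tilt this covers the treated dome while keeping
    the contralateral-breast and posterior-lung tallies outside both primary
    cones.
    """

    isocenter: tuple = (6.5, 1.5, 15.0)
    tilt_deg: float = 45.0
    sad_cm: float = 100.0
    field_cm: tuple = (16.0, 20.0)
    lung_margin_cm: float = 1.0
    #: transverse coordinate of the deep (posterior) field edge at the
    #: isocentre plane; -2.9 cm puts the deepest primary ray ~1 cm into the
    #: lung below the treated dome (the lung margin)
    deep_edge_u_cm: float = -2.9
    #: anterior jaw limit sparing the contralateral dome (reduced flash)
    anterior_edge_max_u_cm: float = 4.1

    @property
    def axes(self):
        """(e_axis_lateral, e_axis_medial, e_u, e_v): beam axes and aperture axes."""
        g = np.radians(self.tilt_deg)
        lateral = np.array([-np.cos(g), -np.sin(g), 0.0])   # travel direction, +x source
        e_u = np.array([-np.sin(g), np.cos(g), 0.0])
        e_v = np.array([0.0, 0.0, 1.0])
        return lateral, -lateral, e_u, e_v

    @property
    def sources(self):
        iso = np.asarray(self.isocenter)
        lateral, medial, _, _ = self.axes
        return iso - self.sad_cm * lateral, iso - self.sad_cm * medial

    @property
    def aperture_u(self):
        """Effective transverse aperture (u_lo, u_hi) at the isocentre plane, cm.

        Half-beam rule: effective width is half the nominal setting, anchored
        at the deep (lung-margin) edge and clipped at the anterior jaw limit.
        """
        lo = self.deep_edge_u_cm
        return (lo, min(lo + self.field_cm[0] / 2.0, self.anterior_edge_max_u_cm))

    @property
    def aperture_v(self):
        half = self.field_cm[1] / 2.0
        return (-half, half)


@dataclass
class ProtocolConfig:
    """One technique: prescription, source model, geometry, modifier."""

    name: str
    prescription_gy: float
    fractions: int
    source: str                      # "6mv" | "ir192" | "pd103"
    beam: BeamConfig | None = None
    modifier: dict = field(default_factory=dict)
    target_center: tuple = DEFAULT_TARGET_CENTER
    target_radius_cm: float = 3.0
    uses_linac: bool = True          # head leakage applies

    @property
    def field_cm(self):
        return self.beam.field_cm if self.beam else None


_DEFAULTS = {
    "wedge": dict(
        prescription_gy=50.0, fractions=25, source="6mv",
        beam=BeamConfig(field_cm=(16.0, 20.0)),
        modifier={"kind": "wedge", "angle_deg": 30.0, "material": "steel"},
    ),
    "imrt": dict(
        prescription_gy=50.0, fractions=25, source="6mv",
        beam=BeamConfig(field_cm=(16.0, 20.0)),
        modifier={"kind": "field_in_field", "segment_weight": 0.2, "open_weight": 0.8},
    ),
    "3dcrt_pbi": dict(
        prescription_gy=38.5, fractions=10, source="6mv",
        # partial-breast field: narrower aperture centred on the target
        beam=BeamConfig(field_cm=(8.0, 20.0), deep_edge_u_cm=-1.3),
    ),
    "hdr_catheter": dict(
        prescription_gy=34.0, fractions=10, source="ir192", beam=None, uses_linac=False,
        modifier={"source_activity_ci": 10.0, "dwell_pitch_cm": 1.0},
    ),
    "pbsi": dict(
        prescription_gy=90.0, fractions=1, source="pd103", beam=None, uses_linac=False,
        modifier={"n_seeds": 100, "seed_strength_u": 2.7},
    ),
}


def make_protocol(name: str, **overrides) -> ProtocolConfig:
    """Return the named technique with its reference defaults; overrides allowed."""
    if name not in _DEFAULTS:
        raise ValueError(f"unknown protocol {name!r}; choose from {PROTOCOL_NAMES}")
    cfg = ProtocolConfig(name=name, **_DEFAULTS[name])
    return replace(cfg, **overrides) if overrides else cfg


def sphere_volume(radius_cm: float) -> float:
    """Sphere volume in cc; a 3 cm-radius target is 113 cc."""
    if radius_cm < 0:
        raise ValueError("radius must be >= 0")
    return 4.0 / 3.0 * np.pi * radius_cm**3


def seeds_total_activity(
    n_seeds: int, strength_u: float, kerma_to_activity_factor: float = PD103_U_PER_MCI
) -> float:
    """Total apparent activity (Ci) of ``n_seeds`` seeds of ``strength_u`` each.

    100 seeds x 2.7 U at 1.293 U/mCi -> 0.2088 Ci.
    """
    if n_seeds <= 0 or strength_u <= 0 or kerma_to_activity_factor <= 0:
        raise ValueError("all inputs must be positive")
    return n_seeds * (strength_u / kerma_to_activity_factor) / 1000.0


def _lattice_in_sphere(radius: float, pitch: float) -> np.ndarray:
    """Cubic-lattice points (pitch spacing, origin included) inside a sphere."""
    k = int(np.floor(radius / pitch))
    ax = np.arange(-k, k + 1) * pitch
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.einsum("ij,ij->i", pts, pts) <= radius**2 + 1e-12]
    return pts[np.argsort(np.einsum("ij,ij->i", pts, pts), kind="stable")]


@dataclass
class SeedPlan:
    """Permanent-implant seed positions and strengths."""

    positions: np.ndarray            # (n, 3) cm
    strength_u: float
    total_activity_ci: float
    half_life_days: float = PD103_HALF_LIFE_DAYS


def make_seed_plan(
    target_radius_cm: float = 3.0,
    n_seeds: int = 100,
    rng=None,
    center=DEFAULT_TARGET_CENTER,
    strength_u: float = 2.7,
    jitter_cm: float = 0.2,
) -> SeedPlan:
    """Seeds on a jittered regular lattice filling the target sphere.

    The lattice pitch is ``(V_target / n)**(1/3)`` (~1.04 cm for 100 seeds in
    113 cc); a single-seed plan sits at the target centre.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    center = np.asarray(center, dtype=float)
    if n_seeds == 1:
        pts = np.zeros((1, 3))
    else:
        rng = rng if rng is not None else np.random.default_rng(0)
        pitch = (sphere_volume(target_radius_cm) / n_seeds) ** (1.0 / 3.0)
        lattice = _lattice_in_sphere(target_radius_cm * 1.5, pitch)[:n_seeds]
        pts = lattice + rng.uniform(-jitter_cm, jitter_cm, size=lattice.shape)
        r = np.linalg.norm(pts, axis=1)
        over = r > target_radius_cm
        pts[over] *= (target_radius_cm / r[over])[:, None] * 0.999
    return SeedPlan(
        positions=pts + center,
        strength_u=strength_u,
        total_activity_ci=seeds_total_activity(n_seeds, strength_u),
    )


@dataclass
class DwellPlan:
    """HDR dwell positions (1 cm grid) with uniform dwell times."""

    positions: np.ndarray
    dwell_times_s: np.ndarray
    source_activity_ci: float
    total_time_s: float
    prescription_gy: float
    fractions: int


def dwell_dose_rate(
    dwell_positions: np.ndarray,
    points: np.ndarray,
    activity_ci: float,
    mu_eff_cm: float = 0.03,
    u_per_ci: float = IR192_U_PER_CI,
    dose_rate_const_gy_per_h_u: float = 0.0111,
) -> np.ndarray:
    """Point-source dose rate (Gy/h) at ``points`` with the full source at every dwell.

    Inverse-square times exponential tissue attenuation:
    ``sum_i  S_k * Lambda * exp(-mu r_i) / r_i^2``.
    """
    sk = activity_ci * u_per_ci
    d = points[:, None, :] - dwell_positions[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    r = np.maximum(r, 1e-6)
    return sk * dose_rate_const_gy_per_h_u * (np.exp(-mu_eff_cm * r) / r**2).sum(axis=1)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def make_dwell_plan(
    target_radius_cm: float = 3.0,
    source_activity_ci: float = 10.0,
    prescription_gy: float = 34.0,
    fractions: int = 10,
    center=DEFAULT_TARGET_CENTER,
    pitch_cm: float = 1.0,
    mu_eff_cm: float = 0.03,
    n_surface: int = 512,
) -> DwellPlan:
    """Uniform-loading dwell plan delivering the prescription at the target surface.

    Dwells sit on a ``pitch_cm`` grid inside the target sphere; the total
    dwell time is solved so that the *median* point-source dose over the
    prescription surface equals the per-fraction prescription (the median is
    the robust peripheral-dose statistic: lattice dwells can lie exactly on
    the sphere, which makes the surface *mean* of 1/r^2 ill-defined).
    Doubling the activity halves the total time.
    """
    if min(target_radius_cm, source_activity_ci, prescription_gy) <= 0:
        raise ValueError("inputs must be positive")
    center = np.asarray(center, dtype=float)
    pts = _lattice_in_sphere(target_radius_cm, pitch_cm) + center
    surface = center + target_radius_cm * _fibonacci_sphere(n_surface)
    rate_sum = dwell_dose_rate(pts, surface, source_activity_ci, mu_eff_cm)
    per_fraction = prescription_gy / fractions
    # uniform loading: dose(p) = (T_fx / n_dwell) * rate_sum(p)
    t_fx_h = per_fraction * len(pts) / float(np.median(rate_sum))
    total_s = t_fx_h * 3600.0 * fractions
    return DwellPlan(
        positions=pts,
        dwell_times_s=np.full(len(pts), total_s / len(pts)),
        source_activity_ci=source_activity_ci,
        total_time_s=total_s,
        prescription_gy=prescription_gy,
        fractions=fractions,
    )


def balloon_doses(catheter_doses: dict) -> dict:
    """Balloon-applicator organ doses from the catheter-HDR column: +44%.

    ``catheter_doses`` maps organ -> (value, unit); values are multiplied by
    1.44 and rounded to the printed precision (integers for mSv, one decimal
    for Gy).
    """
    out = {}
    for organ, (value, unit) in catheter_doses.items():
        scaled = value * 1.44
        out[organ] = (round(scaled, 1) if unit == "Gy" else round(scaled), unit)
    return out


# ---------------------------------------------------------------------------
# Emitters
# ---------------------------------------------------------------------------

class IsotropicPointsEmitter:
    """Photons emitted isotropically (4 pi) from a set of source points."""

    def __init__(self, points: np.ndarray, spectrum: SourceSpectrum, weights=None):
        self.points = np.asarray(points, dtype=float)
        self.spectrum = spectrum
        w = np.ones(len(self.points)) if weights is None else np.asarray(weights, float)
        self.probs = w / w.sum()

    def sample(self, n, rng):
        idx = rng.choice(len(self.points), size=n, p=self.probs)
        pos = self.points[idx]
        mu = rng.uniform(-1.0, 1.0, n)
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        s = np.sqrt(1.0 - mu**2)
        dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), mu])
        e = self.spectrum.sample(rng, size=n)
        return pos, dirs, e, np.ones(n)


class TangentialBeamEmitter:
    """Opposed tangential point-source beams collimated to a rectangular aperture.

    ``segments`` is a list of ``(probability, (u_lo, u_hi), (v_lo, v_hi))``
    aperture rectangles in the isocentre plane; an open field is a single
    segment with probability 1.  Field-in-field is expressed as two segments.
    """

    def __init__(self, beam: BeamConfig, spectrum: SourceSpectrum, segments=None):
        self.beam = beam
        self.spectrum = spectrum
        self.segments = segments or [(1.0, beam.aperture_u, beam.aperture_v)]
        probs = np.array([s[0] for s in self.segments], dtype=float)
        self.seg_probs = probs / probs.sum()

    def sample(self, n, rng):
        iso = np.asarray(self.beam.isocenter)
        lateral, medial, e_u, e_v = self.beam.axes
        src_lat, src_med = self.beam.sources

        side = rng.random(n) < 0.5
        sources = np.where(side[:, None], src_lat[None, :], src_med[None, :])

        seg_idx = rng.choice(len(self.segments), size=n, p=self.seg_probs)
        u = np.empty(n)
        v = np.empty(n)
        for k, (_, (ulo, uhi), (vlo, vhi)) in enumerate(self.segments):
            m = seg_idx == k
            u[m] = rng.uniform(ulo, uhi, int(m.sum()))
            v[m] = rng.uniform(vlo, vhi, int(m.sum()))
        aperture = iso[None, :] + u[:, None] * e_u[None, :] + v[:, None] * e_v[None, :]
        dirs = aperture - sources
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        e = self.spectrum.sample(rng, size=n)
        return sources, dirs, e, np.ones(n)


def wedge_regions(
    beam: BeamConfig,
    materials=None,
    angle_deg: float = 30.0,
    distance_from_source_cm: float = 75.0,
    priority_base: int = 81,
) -> list:
    """Steel wedge prisms (one per beam) as convex polytopes in the beam path.

    The wedge sits ``distance_from_source_cm`` from each point source with its
    thickness growing along +u (anterior-medial) at tan(angle); the transverse
    extent matches the diverged field at that plane.
    """
    mats = materials or default_materials()
    tan_w = np.tan(np.radians(angle_deg))
    iso = np.asarray(beam.isocenter)
    _, _, e_u, e_v = beam.axes
    frac = distance_from_source_cm / beam.sad_cm
    u_lo, u_hi = (u * frac for u in beam.aperture_u)
    v_lo, v_hi = (v * frac for v in beam.aperture_v)

    regions = []
    for j, src in enumerate(beam.sources):
        a = iso - src
        a = a / np.linalg.norm(a)
        b = src + distance_from_source_cm * a
        normals = [
            -a,                      # axial start: a.(p - b) >= 0
            a - tan_w * e_u,         # wedge face: xi <= (u - u_lo) * tan
            e_u, -e_u, e_v, -e_v,
        ]
        offsets = [
            -float(a @ b),
            float((a - tan_w * e_u) @ b) - u_lo * tan_w,
            float(e_u @ b) + u_hi,
            -float(e_u @ b) - u_lo,
            float(e_v @ b) + v_hi,
            -float(e_v @ b) - v_lo,
        ]
        extent = abs(u_hi - u_lo) * tan_w + (u_hi - u_lo) + (v_hi - v_lo)
        regions.append(
            Region(
                f"wedge_{'lateral' if j == 0 else 'medial'}",
                Polytope(normals, offsets, bounds_hint=(b - extent, b + extent)),
                mats["steel"],
                priority_base + j,
            )
        )
    return regions


def make_emitter(protocol: ProtocolConfig, materials=None, plan_rng=None):
    """Build the source emitter and any beam-line modifier regions for a technique.

    Returns ``(emitter, extra_regions)``.  ``plan_rng`` seeds the seed-plan
    jitter for PBSI (dwell and beam geometry are deterministic).
    """
    if protocol.source == "6mv":
        spectrum = bremsstrahlung_6mv()
        beam = protocol.beam
        segments = None
        if protocol.modifier.get("kind") == "field_in_field":
            (u_lo, u_hi), (v_lo, v_hi) = beam.aperture_u, beam.aperture_v
            u_mid = 0.5 * (u_lo + u_hi)
            segments = [
                (protocol.modifier["open_weight"], (u_lo, u_hi), (v_lo, v_hi)),
                (protocol.modifier["segment_weight"], (u_lo, u_mid), (v_lo, v_hi)),
            ]
        emitter = TangentialBeamEmitter(beam, spectrum, segments)
        extra = []
        if protocol.modifier.get("kind") == "wedge":
            extra = wedge_regions(beam, materials, protocol.modifier["angle_deg"])
        return emitter, extra

    if protocol.source == "ir192":
        plan = make_dwell_plan(
            target_radius_cm=protocol.target_radius_cm,
            source_activity_ci=protocol.modifier.get("source_activity_ci", 10.0),
            prescription_gy=protocol.prescription_gy,
            fractions=protocol.fractions,
            center=protocol.target_center,
            pitch_cm=protocol.modifier.get("dwell_pitch_cm", 1.0),
        )
        return IsotropicPointsEmitter(plan.positions, ir192_spectrum(), plan.dwell_times_s), []

    if protocol.source == "pd103":
        plan = make_seed_plan(
            target_radius_cm=protocol.target_radius_cm,
            n_seeds=protocol.modifier.get("n_seeds", 100),
            rng=plan_rng,
            center=protocol.target_center,
            strength_u=protocol.modifier.get("seed_strength_u", 2.7),
        )
        return IsotropicPointsEmitter(plan.positions, pd103_spectrum()), []

    raise ValueError(f"unknown source kind {protocol.source!r}")
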