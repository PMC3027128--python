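"""Monte Carlo photon random walk with per-tally energy deposition and batch statistics.

The engine transports photons through a :class:`~scatterdose.geometry.Geometry`
under the kerma approximation: at every interaction the energy transferred to
charged particles is deposited locally at the interaction site (photoelectric
absorbs the full photon energy; Compton deposits the electron energy and the
scattered photon continues; pair production deposits ``E - 1.022`` MeV and
emits two back-to-back 0.511 MeV annihilation photons; photons falling below
the low-energy cutoff deposit their remainder).  Energy is therefore conserved
exactly per history: deposited + escaped = emitted.

Depositions are scored when they fall inside spherical tally volumes.  A run
is divided into batches with independent, deterministically derived random
substreams; the batch means give the tally mean and the relative error
``R = S_xbar / xbar`` (standard error of the mean over the mean), with
``R < 5%`` conventionally considered reliable.

Everything is vectorised over photon arrays; a batch of 10^5 histories is a
handful of numpy passes per flight step.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .geometry import Geometry
from .physics import ELECTRON_REST_MEV, PAIR_THRESHOLD_MEV, compton_scatter

__all__ = [
    "PhotonState",
    "TallyResult",
    "TrackResult",
    "SimulationResult",
    "TransportSettings",
    "TransportEngine",
    "relative_error",
    "run_simulation",
    "track",
]

_PUSH = 1e-6  # cm, nudge across surfaces


@dataclass
class PhotonState:
    """One photon: position (cm), unit direction, energy (MeV), statistical weight."""

    position: tuple
    direction: tuple
    energy: float
    weight: float = 1.0

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("direction must be unit-norm")
        if self.energy <= 0:
            raise ValueError("energy must be > 0")
        if not 0 < self.weight <= 1:
            raise ValueError("weight must be in (0, 1]")


def relative_error(batch_values) -> float:
    """Relative error R = (s / sqrt(n)) / mean over batch means.

    Returns ``inf`` if the mean is zero.  Requires at least two batches.
    """
    x = np.asarray(batch_values, dtype=float)
    if x.size < 2:
        raise ValueError("relative error needs >= 2 batches")
    mean = x.mean()
    if mean == 0:
        return float("inf")
    s = x.std(ddof=1)
    return float(s / np.sqrt(x.size) / abs(mean))


@dataclass
class TallyResult:
    """Per-tally deposition: batch values (MeV per source history), mean and R."""

    tally_id: str
    batch_values: np.ndarray
    n_histories: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.batch_values))

    @property
    def relative_error(self) -> float:
        return relative_error(self.batch_values)

    @property
    def reliable(self) -> bool:
        """True when R is below the conventional 5% reliability threshold."""
        return self.relative_error < 0.05


@dataclass
class TrackResult:
    """Outcome of a single-photon track: tally hits and the energy ledger."""

    deposits: list  # [(tally_id, MeV)]
    deposited_total: float
    escaped: float


@dataclass
class SimulationResult:
    tallies: dict
    n_histories: int
    n_batches: int
    seed: int
    emitted_energy: float
    deposited_energy: float
    escaped_energy: float
    runtime_s: float
    per_history_deposited: np.ndarray | None = None
    per_history_escaped: np.ndarray | None = None
    per_history_emitted: np.ndarray | None = None

    def __getitem__(self, tally_id: str) -> TallyResult:
        return self.tallies[tally_id]


@dataclass
class TransportSettings:
    """Physics options for the random walk.

    cutoff_mev: photons below this deposit locally (default 5 keV).
    coherent_max_mev: coherent (Rayleigh) scattering is only simulated below
        this energy (it matters for Pd-103, not for MV beams).
    russian_roulette: optional weight roulette below ``rr_threshold`` with
        survival weight multiplied by ``rr_factor`` (off by default; it
        preserves energy only in expectation).
    """

    cutoff_mev: float = 0.005
    coherent_max_mev: float = 0.1
    russian_roulette: bool = False
    rr_threshold: float = 0.1
    rr_factor: float = 10.0
    max_flight_steps: int = 200_000


def _rotate(directions, cos_theta, phi):
    """Rotate unit vectors by polar angle (cos_theta) and azimuth phi."""
    d = directions
    sin_theta = np.sqrt(np.maximum(0.0, 1.0 - cos_theta**2))
    # pick a helper axis not parallel to d
    helper = np.zeros_like(d)
    use_z = np.abs(d[:, 2]) < 0.99
    helper[use_z, 2] = 1.0
    helper[~use_z, 0] = 1.0
    u = np.cross(d, helper)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    out = (
        cos_theta[:, None] * d
        + sin_theta[:, None] * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v)
    )
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


def _isotropic(n, rng):
    mu = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - mu**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), mu])


class TransportEngine:
    """Vectorised photon transport through a geometry with spherical tallies."""

    def __init__(self, geometry: Geometry, tallies=(), settings: TransportSettings | None = None):
        self.geometry = geometry
        self.tallies = list(tallies)
        self.settings = settings or TransportSettings()
        self._build_material_tables()

    def _build_material_tables(self):
        s = self.settings
        regions = self.geometry.ordered_regions
        mats = []
        self._region_mat = np.empty(len(regions), dtype=np.int64)
        for i, reg in enumerate(regions):
            if reg.material not in mats:
                mats.append(reg.material)
            self._region_mat[i] = mats.index(reg.material)
        self._materials = mats
        self._tables = []
        for m in mats:
            grid = m.energies
            coh = np.where(grid <= s.coherent_max_mev, m.coherent, 0.0)
            comps = np.stack([m.photoelectric, m.incoherent, coh, m.pair])
            tot = comps.sum(axis=0) * m.density  # linear attenuation 1/cm
            self._tables.append(
                {
                    "logE": np.log(grid),
                    "log_mu": np.log(np.maximum(tot, 1e-300)),
                    "comps": comps * m.density,
                    "vacuum": bool(np.all(tot <= 0)),
                }
            )

    def _mu_total(self, mat_idx, energies):
        mu = np.zeros_like(energies)
        logE = np.log(energies)
        for i, tab in enumerate(self._tables):
            sel = mat_idx == i
            if not sel.any() or tab["vacuum"]:
                continue
            mu[sel] = np.exp(np.interp(logE[sel], tab["logE"], tab["log_mu"]))
        return np.where(mu < 1e-290, 0.0, mu)

    def _channel(self, mat_idx, energies, rng):
        """Sample interaction channel index: 0 PE, 1 Compton, 2 coherent, 3 pair."""
        n = len(energies)
        channel = np.ones(n, dtype=np.int64)  # default compton
        u = rng.random(n)
        for i, tab in enumerate(self._tables):
            sel = mat_idx == i
            if not sel.any() or tab["vacuum"]:
                continue
            e = energies[sel]
            comps = np.stack([np.interp(e, self._materials[i].energies, c) for c in tab["comps"]])
            tot = comps.sum(axis=0)
            cum = np.cumsum(comps, axis=0) / tot
            channel[sel] = np.minimum((u[sel][None, :] >= cum).sum(axis=0), 3)
        return channel

    def run_batch(self, emitter, n: int, rng, hist_offset=0, track_energy=False):
        """Transport ``n`` histories; returns (tally_sums MeV, ledger dict)."""
        s = self.settings
        pos, dirs, energy, weight = emitter.sample(n, rng)
        pos = np.array(pos, dtype=float)
        dirs = np.array(dirs, dtype=float)
        energy = np.array(energy, dtype=float)
        weight = np.array(weight, dtype=float)
        hist = np.arange(n, dtype=np.int64)
        emitted = energy * weight

        tally_centers = np.array([t.center for t in self.tallies], dtype=float)
        tally_r2 = np.array([t.radius**2 for t in self.tallies], dtype=float)
        tally_sums = np.zeros(len(self.tallies))

        dep_hist = np.zeros(n) if track_energy else None
        esc_hist = np.zeros(n) if track_energy else None
        deposited_total = 0.0
        escaped_total = 0.0
        pending = []  # secondaries: (pos, dir, E, w, hist)

        def score(points, amounts, hists):
            nonlocal deposited_total
            deposited_total += float(amounts.sum())
            for k in range(len(self.tallies)):
                d = points - tally_centers[k]
                m = np.einsum("ij,ij->i", d, d) < tally_r2[k]
                if m.any():
                    tally_sums[k] += float(amounts[m].sum())
            if dep_hist is not None:
                np.add.at(dep_hist, hists, amounts)

        for _ in range(s.max_flight_steps):
            if len(energy) == 0:
                if not pending:
                    break
                pos = np.concatenate([p[0] for p in pending])
                dirs = np.concatenate([p[1] for p in pending])
                energy = np.concatenate([p[2] for p in pending])
                weight = np.concatenate([p[3] for p in pending])
                hist = np.concatenate([p[4] for p in pending])
                pending = []

            ridx = self.geometry.region_index(pos)
            # photons in the enclosing near-vacuum region whose rays cannot
            # re-enter the anatomy or beam line are retired as escaped
            outside = ridx < 0
            in_world = ridx == self.geometry.world_index
            if in_world.any():
                iw = np.flatnonzero(in_world)
                gone = self.geometry.escapes_inner(pos[iw], dirs[iw])
                outside[iw[gone]] = True
            if outside.any():
                esc = energy[outside] * weight[outside]
                escaped_total += float(esc.sum())
                if esc_hist is not None:
                    np.add.at(esc_hist, hist[outside], esc)
                keep = ~outside
                pos, dirs, energy, weight, hist, ridx = (
                    pos[keep], dirs[keep], energy[keep], weight[keep], hist[keep], ridx[keep]
                )
                if len(energy) == 0:
                    continue

            mat_idx = self._region_mat[ridx]
            mu = self._mu_total(mat_idx, energy)
            with np.errstate(divide="ignore"):
                free_path = np.where(mu > 0, -np.log1p(-rng.random(len(energy))) / np.where(mu > 0, mu, 1.0), np.inf)
            d_surf = self.geometry.nearest_crossing(pos, dirs)
            interact = free_path < d_surf
            step = np.where(interact, free_path, d_surf + _PUSH)
            # photons in unbounded vacuum with no surface ahead: retire them
            lost = ~np.isfinite(step)
            if lost.any():
                esc = energy[lost] * weight[lost]
                escaped_total += float(esc.sum())
                if esc_hist is not None:
                    np.add.at(esc_hist, hist[lost], esc)
                keep = ~lost
                pos, dirs, energy, weight, hist, mat_idx, interact, step = (
                    pos[keep], dirs[keep], energy[keep], weight[keep],
                    hist[keep], mat_idx[keep], interact[keep], step[keep],
                )
                if len(energy) == 0:
                    continue
            pos = pos + step[:, None] * dirs

            if interact.any():
                ii = np.flatnonzero(interact)
                ch = self._channel(mat_idx[ii], energy[ii], rng)
                kill = np.zeros(len(energy), dtype=bool)

                pe = ii[ch == 0]
                if len(pe):
                    score(pos[pe], energy[pe] * weight[pe], hist[pe])
                    kill[pe] = True

                co = ii[ch == 1]
                if len(co):
                    e_new, theta = compton_scatter(energy[co], rng)
                    score(pos[co], (energy[co] - e_new) * weight[co], hist[co])
                    phi = rng.uniform(0.0, 2.0 * np.pi, len(co))
                    dirs[co] = _rotate(dirs[co], np.cos(theta), phi)
                    energy[co] = e_new

                ry = ii[ch == 2]
                if len(ry):
                    # Thomson-like coherent angular sampling, no energy change
                    mu_c = np.empty(len(ry))
                    todo = np.ones(len(ry), dtype=bool)
                    while todo.any():
                        cand = rng.uniform(-1.0, 1.0, int(todo.sum()))
                        acc = rng.random(int(todo.sum())) <= 0.5 * (1.0 + cand**2)
                        idx = np.flatnonzero(todo)[acc]
                        mu_c[idx] = cand[acc]
                        todo[idx] = False
                    phi = rng.uniform(0.0, 2.0 * np.pi, len(ry))
                    dirs[ry] = _rotate(dirs[ry], mu_c, phi)

                pp = ii[ch == 3]
                if len(pp):
                    score(pos[pp], (energy[pp] - PAIR_THRESHOLD_MEV) * weight[pp], hist[pp])
                    new_dirs = _isotropic(len(pp), rng)
                    dirs[pp] = new_dirs
                    energy[pp] = ELECTRON_REST_MEV
                    pending.append(
                        (pos[pp].copy(), -new_dirs, np.full(len(pp), ELECTRON_REST_MEV),
                         weight[pp].copy(), hist[pp].copy())
                    )

                low = (energy < s.cutoff_mev) & ~kill
                if low.any():
                    score(pos[low], energy[low] * weight[low], hist[low])
                    kill[low] = True

                if s.russian_roulette:
                    cand = (weight < s.rr_threshold) & ~kill
                    if cand.any():
                        die = rng.random(int(cand.sum())) >= 1.0 / s.rr_factor
                        idx = np.flatnonzero(cand)
                        kill[idx[die]] = True
                        surv = idx[~die]
                        weight[surv] *= s.rr_factor

                keep = ~kill
                pos, dirs, energy, weight, hist, mat_idx = (
                    pos[keep], dirs[keep], energy[keep], weight[keep], hist[keep], mat_idx[keep]
                )
        else:
            raise RuntimeError("flight step limit exceeded")

        ledger = {
            "emitted": float(emitted.sum()),
            "deposited": deposited_total,
            "escaped": escaped_total,
            "emitted_per_history": emitted,
            "deposited_per_history": dep_hist,
            "escaped_per_history": esc_hist,
        }
        return tally_sums, ledger


def run_simulation(
    geometry: Geometry,
    emitter,
    tallies,
    n_histories: int,
    n_batches: int = 20,
    seed: int = 0,
    settings: TransportSettings | None = None,
    track_energy: bool = False,
) -> SimulationResult:
    """Run ``n_histories`` split into batches with per-batch derived substreams.

    Deterministic given ``seed``.  ``n_histories`` must divide evenly into
    ``n_batches`` (>= 2).
    """
    if n_histories <= 0:
        raise ValueError("n_histories must be > 0")
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    if n_histories % n_batches:
        raise ValueError("n_histories must be divisible by n_batches")
    per_batch = n_histories // n_batches
    engine = TransportEngine(geometry, tallies, settings)
    streams = np.random.SeedSequence(seed).spawn(n_batches)

    t0 = time.perf_counter()
    sums = np.zeros((len(engine.tallies), n_batches))
    emitted = deposited = escaped = 0.0
    dep_h, esc_h, emit_h = ([], [], []) if track_energy else (None, None, None)
    for b in range(n_batches):
        rng = np.random.default_rng(streams[b])
        batch_sums, ledger = engine.run_batch(emitter, per_batch, rng, track_energy=track_energy)
        sums[:, b] = batch_sums
        emitted += ledger["emitted"]
        deposited += ledger["deposited"]
        escaped += ledger["escaped"]
        if track_energy:
            emit_h.append(ledger["emitted_per_history"])
            dep_h.append(ledger["deposited_per_history"])
            esc_h.append(ledger["escaped_per_history"])
    runtime = time.perf_counter() - t0

    results = {
        t.id: TallyResult(t.id, sums[k] / per_batch, n_histories)
        for k, t in enumerate(engine.tallies)
    }
    return SimulationResult(
        tallies=results,
        n_histories=n_histories,
        n_batches=n_batches,
        seed=seed,
        emitted_energy=emitted,
        deposited_energy=deposited,
        escaped_energy=escaped,
        runtime_s=runtime,
        per_history_deposited=np.concatenate(dep_h) if track_energy else None,
        per_history_escaped=np.concatenate(esc_h) if track_energy else None,
        per_history_emitted=np.concatenate(emit_h) if track_energy else None,
    )


class _SinglePhotonEmitter:
    def __init__(self, photon: PhotonState):
        self.photon = photon

    def sample(self, n, rng):
        p = self.photon
        return (
            np.tile(np.asarray(p.position, dtype=float), (n, 1)),
            np.tile(np.asarray(p.direction, dtype=float), (n, 1)),
            np.full(n, p.energy),
            np.full(n, p.weight),
        )


def track(geometry_or_phantom, photon: PhotonState, rng, cutoff: float = 0.005) -> TrackResult:
    """Transport a single photon and return its tally deposits and energy ledger.

    ``deposited_total + escaped == energy * weight`` holds to 1e-9 relative
    (Russian roulette off).
    """
    geometry = getattr(geometry_or_phantom, "geometry", geometry_or_phantom)
    tallies = getattr(geometry_or_phantom, "tallies", [])
    engine = TransportEngine(geometry, tallies, TransportSettings(cutoff_mev=cutoff))

    # per-tally deposits need per-tally bookkeeping; rerun scoring with one history
    tally_sums, ledger = engine.run_batch(_SinglePhotonEmitter(photon), 1, rng, track_energy=True)
    deposits = [
        (t.id, float(tally_sums[k])) for k, t in enumerate(engine.tallies) if tally_sums[k] > 0
    ]
    return TrackResult(
        deposits=deposits,
        deposited_total=float(ledger["deposited"]),
        escaped=float(ledger["escaped"]),
    )
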