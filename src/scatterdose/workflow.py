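"""Pipeline orchestration: technique simulation -> organ doses -> risk.

Glue between the modules: build the phantom (plus any beam modifiers),
run the transport engine for a technique, normalise tallies to the
prescription, add the measured-leakage term for linac techniques (the
hybrid method), and assemble the published-table-shaped dose/contribution/risk reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dosimetry import (
    DEFAULT_ORGAN_FIELD_DISTANCES_CM,
    assemble_dose_table,
    contribution_decomposition,
    normalize_to_prescription,
)
from .leakage import LeakageModel, fit_leakage_model, generate_leakage_fixture
from .phantom import build_phantom
from .physics import default_materials
from .protocols import make_emitter, make_protocol
from .transport import SimulationResult, TransportSettings, run_simulation

__all__ = [
    "TechniqueRun",
    "simulate_protocol",
    "technique_doses",
    "leakage_column",
    "wedge_decomposition",
    "run_study",
    "default_leakage_model",
]


def default_leakage_model(seed: int = 0) -> LeakageModel:
    """Leakage model fitted to the default synthetic measurement fixture."""
    return fit_leakage_model(generate_leakage_fixture(seed))


@dataclass
class TechniqueRun:
    protocol: object
    result: SimulationResult
    mc_doses_gy: dict       # organ -> Gy, Monte Carlo component only
    total_doses_gy: dict    # organ -> Gy, hybrid total


def simulate_protocol(
    name: str,
    n_histories: int,
    n_batches: int = 20,
    seed: int = 0,
    phantom_config: dict | None = None,
    settings: TransportSettings | None = None,
    without_modifier: bool = False,
):
    """Run transport for one technique; returns ``(protocol, phantom, SimulationResult)``.

    ``without_modifier`` strips the beam modifier (the open-field partner of
    a wedge run, used for the paired contribution decomposition).
    """
    protocol = make_protocol(name)
    if without_modifier and protocol.modifier.get("kind") == "wedge":
        protocol = make_protocol(name)
        protocol.modifier = {}
    materials = default_materials()
    plan_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    emitter, extra = make_emitter(protocol, materials, plan_rng=plan_rng)
    phantom = build_phantom(phantom_config, materials, extra_regions=extra)
    result = run_simulation(
        phantom.geometry, emitter, phantom.tallies,
        n_histories=n_histories, n_batches=n_batches, seed=seed, settings=settings,
    )
    return protocol, phantom, result


def leakage_column(protocol, leakage_model: LeakageModel | None, distances=None) -> dict:
    """Leakage-term organ doses (Gy) for a linac technique; zeros for brachytherapy."""
    distances = distances or DEFAULT_ORGAN_FIELD_DISTANCES_CM
    out = {organ: 0.0 for organ in distances}
    if leakage_model is None or not protocol.uses_linac:
        return out
    for organ, d in distances.items():
        out[organ] = float(
            leakage_model.fraction(d, protocol.field_cm) * protocol.prescription_gy
        )
    return out


def technique_doses(
    name: str,
    n_histories: int,
    seed: int = 0,
    leakage_model: LeakageModel | None = None,
    n_batches: int = 20,
    phantom_config: dict | None = None,
    settings: TransportSettings | None = None,
) -> TechniqueRun:
    """Full hybrid organ doses for one technique at one seed."""
    protocol, phantom, result = simulate_protocol(
        name, n_histories, n_batches, seed, phantom_config, settings
    )
    mc = normalize_to_prescription(result.tallies, protocol, phantom)
    leak = leakage_column(protocol, leakage_model)
    total = dict(mc)
    for organ, extra_gy in leak.items():
        if organ in total and organ != "treated_breast":
            total[organ] = mc[organ] + extra_gy
    return TechniqueRun(protocol, result, mc, total)


def wedge_decomposition(
    n_histories: int,
    seed: int = 0,
    leakage_model: LeakageModel | None = None,
    n_batches: int = 20,
    settings: TransportSettings | None = None,
):
    """Paired wedge/open runs (same seed) -> contribution table + dose columns.

    Returns ``(contributions, wedge_run, open_run)`` where contributions is
    the internal/compensator/leakage percentage frame over the scatter organs.
    """
    protocol, phantom_w, res_w = simulate_protocol(
        "wedge", n_histories, n_batches, seed, settings=settings
    )
    _, phantom_o, res_o = simulate_protocol(
        "wedge", n_histories, n_batches, seed, settings=settings, without_modifier=True
    )
    wedge_mc = normalize_to_prescription(res_w.tallies, protocol, phantom_w)
    open_mc = normalize_to_prescription(res_o.tallies, protocol, phantom_o)
    leak = leakage_column(protocol, leakage_model)
    organs = [o for o in wedge_mc if o != "treated_breast"]
    table = contribution_decomposition(
        {o: open_mc[o] for o in organs},
        {o: wedge_mc[o] for o in organs},
        {o: leak.get(o, 0.0) for o in organs},
    )
    return table, (protocol, res_w, wedge_mc), (protocol, res_o, open_mc)


def run_study(
    n_histories: int = 200_000,
    seed: int = 0,
    leakage_model: LeakageModel | None = None,
    techniques=("pbsi", "hdr_catheter", "wedge", "imrt", "3dcrt_pbi"),
    n_batches: int = 20,
):
    """Simulate every technique at one seed and assemble the dose table.

    Desk-scale convenience for the CLI and worked examples; the directional
    acceptance comparisons pool several seeds at larger history counts.
    """
    if leakage_model is None:
        leakage_model = default_leakage_model()
    columns = {}
    runs = {}
    for name in techniques:
        run = technique_doses(name, n_histories, seed, leakage_model, n_batches)
        columns[name] = run.total_doses_gy
        runs[name] = run
    return assemble_dose_table(columns), runs
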