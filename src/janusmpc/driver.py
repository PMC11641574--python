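"""Run orchestration: the interleaved MD/MPC/reaction loop, seeding,
logging, checkpointing, fixture scenarios and parameter sweeps.

One run = repeat { md_steps_per_mpc velocity-Verlet steps, each followed
by the surface-reaction pass } then { one MPC collision with a fresh grid
shift, then bulk regeneration }, until the configured total time.  Three
named RNG streams (initialization, MPC shifts/axes, reactions) are
spawned from the single master seed so toggling one stochastic component
does not perturb the others.  Identical (config, seed) pairs produce
bit-identical logs, including across checkpoint/restart.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _walltime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig
from .geometry import build_motor
from .md import (PairPotentialTable, SystemState, init_force_cache,
                 make_state, md_interval)
from .mpc import assign_cells, mpc_collision_step, sample_grid_shift
from .observables import Frame, ObservableSeries
from .reactions import (ReactionCounters, ReactionRules,
                        bulk_regeneration_step, species_census,
                        surface_reaction_step)

logger = logging.getLogger("janusmpc")

_LOG_COLUMNS = [
    "cycle", "t", "E_kin", "E_pot", "E_tot", "T_kin",
    "P_x", "P_y", "P_z",
    "com_x", "com_y", "com_z", "vcom_x", "vcom_y", "vcom_z",
    "u_x", "u_y", "u_z", "vu",
    "N_A", "N_I", "N_B", "n_rxn1", "n_rxn2", "n_regen",
]


class ConservationError(RuntimeError):
    """A conservation law drifted beyond the configured tolerance."""


# ----------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------
def make_fixture_scenario(scale: str = "tiny", **overrides) -> SimulationConfig:
    """Desk-scale stand-ins for the full 30^3 production box.

    ``micro`` (unit tests, seconds), ``tiny`` (invariant suites, tens of
    seconds) and ``small`` (propulsion physics, minutes) share all
    physical constants with the production defaults and only shrink the
    box, the solvent density and the particle counts.
    """
    scales = {
        "micro": dict(Lx=10.0, Ly=10.0, Lz=10.0, ns=3.0, NE0=40, NE1=40,
                      Nin=60, total_time=5.0),
        "tiny": dict(Lx=12.0, Ly=12.0, Lz=12.0, ns=5.0, NE0=80, NE1=80,
                     Nin=200, total_time=25.0),
        "small": dict(Lx=16.0, Ly=16.0, Lz=16.0, ns=10.0, NE0=300, NE1=300,
                      Nin=500, total_time=50.0),
    }
    if scale not in scales:
        raise ValueError(f"unknown fixture scale {scale!r}; "
                         f"choose from {sorted(scales)}")
    params = dict(scales[scale])
    params.update(overrides)
    return SimulationConfig(**params).validate()


# ----------------------------------------------------------------------
# run result and manifest
# ----------------------------------------------------------------------
@dataclass
class RunResult:
    log: pd.DataFrame
    manifest: dict
    state: SystemState
    counters: ReactionCounters
    frames: list = field(default_factory=list)

    @property
    def series(self) -> ObservableSeries:
        return ObservableSeries.from_log(self.log)

    def mean_vu(self, burn_in_frac: float = 0.2) -> float:
        from .observables import axial_velocity_stats
        return axial_velocity_stats(self.series, burn_in_frac).mean


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _spawn_streams(seed: int):
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3)
    return {name: np.random.default_rng(child)
            for name, child in zip(("init", "mpc", "reactions"), children)}


# ----------------------------------------------------------------------
# checkpointing
# ----------------------------------------------------------------------
def save_checkpoint(path, state: SystemState, rngs: dict,
                    counters: ReactionCounters, cycle: int,
                    config: SimulationConfig, cache=None) -> None:
    """Self-describing binary container with the full loop state."""
    rng_states = {name: rng.bit_generator.state for name, rng in rngs.items()}
    meta = {
        "config": config.to_dict(),
        "rng_states": rng_states,
        "counters": vars(counters),
        "cycle": cycle,
        "time": state.time,
        "version": __version__,
    }
    np.savez_compressed(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        mpos=state.mpos, mvel=state.mvel, mmass=state.mmass,
        mspecies=state.mspecies, msigma=state.msigma,
        spring_i=state.spring_i, spring_j=state.spring_j,
        spring_r0=state.spring_r0,
        spos=state.spos, svel=state.svel, sspecies=state.sspecies,
        scalars=np.array([state.ms, state.ks]),
        box=state.box,
        f_solvent=(cache.f_solvent if cache is not None
                   else np.zeros_like(state.spos)),
        f_motor=(cache.f_motor if cache is not None
                 else np.zeros_like(state.mpos)))


def load_checkpoint(path):
    """Restore (config, state, rngs, counters, cycle) from a checkpoint."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        state = SystemState(
            mpos=data["mpos"], mvel=data["mvel"], mmass=data["mmass"],
            mspecies=data["mspecies"], msigma=data["msigma"],
            spring_i=data["spring_i"], spring_j=data["spring_j"],
            spring_r0=data["spring_r0"],
            spos=data["spos"], svel=data["svel"], sspecies=data["sspecies"],
            ms=float(data["scalars"][0]), ks=float(data["scalars"][1]),
            box=data["box"], time=float(meta["time"]))
        force_arrays = (data["f_solvent"], data["f_motor"])
    config = SimulationConfig.from_dict(meta["config"])
    rngs = {}
    for name, saved in meta["rng_states"].items():
        rng = np.random.default_rng(0)
        rng.bit_generator.state = saved
        rngs[name] = rng
    counters = ReactionCounters(**meta["counters"])
    return config, state, rngs, counters, int(meta["cycle"]), force_arrays


# ----------------------------------------------------------------------
# the main loop
# ----------------------------------------------------------------------
def _log_row(cycle: int, state: SystemState, potential: float,
             counters: ReactionCounters) -> list:
    ke = state.kinetic_energy()
    p = state.total_momentum()
    com = state.motor_com
    vcom = state.motor_com_velocity
    u = state.motor_axis
    census = species_census(state)
    return [cycle, state.time, ke, potential, ke + potential,
            state.kinetic_temperature(),
            p[0], p[1], p[2], com[0], com[1], com[2],
            vcom[0], vcom[1], vcom[2], u[0], u[1], u[2],
            float(vcom @ u),
            census["N_A"], census["N_I"], census["N_B"],
            counters.n_surface_1, counters.n_surface_2, counters.n_regen]


def _make_frame(state: SystemState) -> Frame:
    return Frame(time=state.time, positions=state.spos.copy(),
                 velocities=state.svel.copy(),
                 species=state.sspecies.copy(),
                 center=state.motor_center_wrapped.copy(),
                 axis=state.motor_axis.copy(),
                 motor_velocity=state.motor_com_velocity.copy(),
                 box=state.box.copy())


def run_simulation(config: SimulationConfig, n_cycles: int | None = None,
                   frame_stride: int = 0, outdir=None,
                   reactions_enabled: bool = True,
                   _resume=None) -> RunResult:
    """Run the full MD-MPC loop; see the module docstring for the scheme.

    ``frame_stride`` > 0 stores a solvent snapshot every that many MPC
    cycles (for field analyses).  ``reactions_enabled=False`` turns off
    both the surface cascade and bulk regeneration (plain MD-MPC).
    Raises :class:`ConservationError` (after writing a diagnostic
    checkpoint when ``outdir`` is set) if the total energy drifts beyond
    ``config.max_energy_drift``.
    """
    t_start = _walltime.time()
    if _resume is None:
        config = config.validate()
        motor = build_motor(config)
        rngs = _spawn_streams(config.seed)
        state = make_state(config, motor, rngs["init"])
        counters = ReactionCounters()
        start_cycle = 0
    else:
        state, rngs, counters, start_cycle, force_arrays = _resume
    if n_cycles is None:
        n_cycles = config.n_mpc_cycles
    table = PairPotentialTable.from_config(config)
    rules = ReactionRules.from_config(config)
    rng_rxn = rngs["reactions"] if config.surface_reaction_prob < 1.0 else None
    dt = config.t_md
    n_md = int(config.md_steps_per_mpc)
    n_inner = int(config.md_inner_substeps)
    box = state.box

    cache = init_force_cache(state, table)
    if _resume is not None:
        # restore the exact force arrays so the first half-kick after a
        # restart is bit-identical to the uninterrupted run
        cache.f_solvent[:] = force_arrays[0]
        cache.f_motor[:] = force_arrays[1]
    rows = []
    if start_cycle == 0:
        rows.append(_log_row(0, state, cache.potential, counters))
    e_ref = state.kinetic_energy() + cache.potential
    n_species_ref = state.n_solvent
    frames: list[Frame] = []

    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    for cycle in range(start_cycle + 1, start_cycle + n_cycles + 1):
        for _ in range(n_md):
            md_interval(state, table, cache, dt, n_inner)
            if reactions_enabled:
                surface_reaction_step(state, cache, rules, rng_rxn, counters)
        shift = sample_grid_shift(config.a0, rngs["mpc"])
        cells, ncells = assign_cells(state.spos, shift, config.a0, box)
        state.svel = mpc_collision_step(state.svel, cells, ncells,
                                        config.rotation_angle, rngs["mpc"])
        if reactions_enabled:
            bulk_regeneration_step(state, rules, config.t_mpc,
                                   rngs["reactions"], counters)
        rows.append(_log_row(cycle, state, cache.potential, counters))
        if frame_stride > 0 and cycle % frame_stride == 0:
            frames.append(_make_frame(state))

        e_now = rows[-1][4]
        if abs(e_now - e_ref) > config.max_energy_drift * abs(e_ref):
            if outdir is not None:
                save_checkpoint(outdir / "diagnostic_checkpoint.npz", state,
                                rngs, counters, cycle, config, cache)
            raise ConservationError(
                f"total energy drifted from {e_ref:.6g} to {e_now:.6g} "
                f"at cycle {cycle} (tolerance {config.max_energy_drift:g})")
        if state.n_solvent != n_species_ref:
            raise ConservationError("solvent particle count changed")

    log = pd.DataFrame(rows, columns=_LOG_COLUMNS)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "streams": ["init", "mpc", "reactions"],
        "version": __version__,
        "n_cycles": int(start_cycle + n_cycles),
        "wall_time_s": round(_walltime.time() - t_start, 3),
        "outputs": {},
    }
    result = RunResult(log=log, manifest=manifest, state=state,
                       counters=counters, frames=frames)
    if outdir is not None:
        log_path = outdir / "log.csv"
        log.to_csv(log_path, index=False, float_format="%.12g")
        ckpt_path = outdir / "checkpoint.npz"
        save_checkpoint(ckpt_path, state, rngs, counters,
                        start_cycle + n_cycles, config, cache)
        for p in (log_path, ckpt_path):
            manifest["outputs"][p.name] = _sha256(p)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    result._rngs = rngs  # continuation hook for in-process restarts
    return result


def continue_simulation(checkpoint_path, n_cycles: int,
                        frame_stride: int = 0, outdir=None,
                        reactions_enabled: bool = True) -> RunResult:
    """Resume a checkpointed run; bit-identical to an uninterrupted run."""
    config, state, rngs, counters, cycle, force_arrays = load_checkpoint(
        checkpoint_path)
    return run_simulation(config, n_cycles=n_cycles, frame_stride=frame_stride,
                          outdir=outdir, reactions_enabled=reactions_enabled,
                          _resume=(state, rngs, counters, cycle,
                                   force_arrays))


# ----------------------------------------------------------------------
# sweeps
# ----------------------------------------------------------------------
def sweep(config: SimulationConfig, phi_values, r2_values=None,
          seeds=(0,), n_cycles: int | None = None,
          runner=None) -> pd.DataFrame:
    """Coverage / outer-radius sweep: one independent run per grid point.

    Returns a tidy table (R2, phi, seed, mean_vu, se_vu, status) suitable
    for :func:`janusmpc.observables.fit_power_law`.  ``runner`` is a
    testing hook: a callable ``(config) -> (mean_vu, se_vu)`` replacing
    the full simulation.
    """
    if r2_values is None:
        r2_values = [config.R2]
    rows = []
    for r2 in r2_values:
        for phi in phi_values:
            for seed in seeds:
                cfg = config.replace(R2=float(r2), phi=float(phi),
                                     seed=int(seed))
                try:
                    if runner is not None:
                        mean_vu, se_vu = runner(cfg)
                    else:
                        res = run_simulation(cfg, n_cycles=n_cycles)
                        from .observables import axial_velocity_stats
                        stats_ = axial_velocity_stats(
                            res.series, cfg.burn_in_frac)
                        mean_vu, se_vu = stats_.mean, stats_.se
                    rows.append([r2, phi, seed, mean_vu, se_vu, "ok"])
                except Exception as exc:  # keep sweeping past failed points
                    logger.warning("sweep point R2=%s phi=%s seed=%s failed: %s",
                                   r2, phi, seed, exc)
                    rows.append([r2, phi, seed, float("nan"), float("nan"),
                                 f"failed: {exc}"])
    return pd.DataFrame(rows, columns=["R2", "phi", "seed", "mean_vu",
                                       "se_vu", "status"])
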