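"""Deterministic molecular dynamics between MPC collision steps.

Motor beads interact with solvent particles through the purely repulsive
shifted-truncated (WCA) Lennard-Jones potential with species-dependent
well depth and bead-dependent size parameter; motor particles are tied
together by harmonic springs.  Solvent-solvent and bead-bead non-bonded
forces are absent by construction (point-like solvent couples to itself
only through MPC collisions; the spring network maintains the motor
shape).  Integration is velocity Verlet with periodic boundaries for the
solvent; motor coordinates are kept unwrapped so its center of mass and
axis are always well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .config import E0, E1, RC_FACTOR, SPECIES_A, SimulationConfig
from .geometry import Motor


class OverlapError(ValueError):
    """Two interacting particles at (numerically) zero separation."""


class NumericalBlowupError(RuntimeError):
    """Non-finite force or velocity during integration."""


# ----------------------------------------------------------------------
# elementary potentials
# ----------------------------------------------------------------------
def wca_potential_and_force(r, eps: float, sigma: float):
    """WCA potential and radial force magnitude at separation(s) ``r``.

    V(r) = 4 eps [ (sigma/r)^12 - (sigma/r)^6 + 1/4 ]   for r < 2^(1/6) sigma
    and exactly zero beyond; the force -dV/dr is always >= 0 (repulsive).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise OverlapError("particle overlap: separation r <= 0")
    rc = RC_FACTOR * sigma
    inside = r < rc
    s6 = np.where(inside, (sigma / r) ** 6, 0.0)
    v = np.where(inside, 4.0 * eps * (s6 * s6 - s6 + 0.25), 0.0)
    f = np.where(inside, 24.0 * eps * (2.0 * s6 * s6 - s6) / r, 0.0)
    if v.ndim == 0:
        return float(v), float(f)
    return v, f


def spring_force(ri, rj, ks: float, r0: float):
    """Equal and opposite harmonic forces on particles i and j.

    Magnitude ks * |r_ij - r0| along the connecting line; returns
    ``(f_i, f_j)``.
    """
    ri = np.asarray(ri, dtype=float)
    rj = np.asarray(rj, dtype=float)
    d = ri - rj
    r = float(np.linalg.norm(d))
    if r == 0.0:
        if r0 > 0.0:
            raise OverlapError("coincident spring endpoints with r0 > 0: "
                               "force direction undefined")
        return np.zeros(3), np.zeros(3)
    fmag = -ks * (r - r0)
    fi = fmag * d / r
    return fi, -fi


@dataclass
class PairPotentialTable:
    """Per (solvent species, bead species) WCA parameters.

    ``eps`` is (3, 3) indexed by (A/I/B, E0/E1/E2); size parameters,
    cutoffs and reaction radii are per bead type.  The potential is zero
    at and beyond the cutoff 2^(1/6) sigma_beta, hence continuous there.
    """

    eps: np.ndarray
    sigma_by_type: np.ndarray
    rc_by_type: np.ndarray
    rrxn_by_type: np.ndarray

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "PairPotentialTable":
        sigma = np.array([config.sigma1, config.sigma1, config.sigma2])
        rc = RC_FACTOR * sigma
        rrxn = rc + config.reaction_shell
        return cls(eps=config.epsilon_matrix(), sigma_by_type=sigma,
                   rc_by_type=rc, rrxn_by_type=rrxn)

    @property
    def max_radius(self) -> float:
        return float(np.max(self.rrxn_by_type))


# ----------------------------------------------------------------------
# system state
# ----------------------------------------------------------------------
@dataclass
class SystemState:
    """Motor + solvent + periodic box + clock.

    Solvent positions are wrapped into [0, L); motor positions are
    unwrapped (the motor is compact, so its internal distances never need
    the minimum image).
    """

    mpos: np.ndarray       # motor particle positions (unwrapped)
    mvel: np.ndarray
    mmass: np.ndarray
    mspecies: np.ndarray   # INTERNAL/E0/E1/E2 codes
    msigma: np.ndarray
    spring_i: np.ndarray
    spring_j: np.ndarray
    spring_r0: np.ndarray
    spos: np.ndarray       # solvent positions, wrapped
    svel: np.ndarray
    sspecies: np.ndarray   # A/I/B codes, int8
    ms: float
    ks: float
    box: np.ndarray
    time: float = 0.0

    @property
    def n_solvent(self) -> int:
        return len(self.spos)

    @property
    def bead_idx(self) -> np.ndarray:
        return np.flatnonzero(self.msigma > 0)

    @property
    def motor_mass(self) -> float:
        return float(np.sum(self.mmass))

    @property
    def motor_com(self) -> np.ndarray:
        return self.mmass @ self.mpos / self.motor_mass

    @property
    def motor_com_velocity(self) -> np.ndarray:
        return self.mmass @ self.mvel / self.motor_mass

    @property
    def motor_axis(self) -> np.ndarray:
        c0 = self.mpos[self.mspecies == E0].mean(axis=0)
        c1 = self.mpos[self.mspecies == E1].mean(axis=0)
        u = c0 - c1
        return u / np.linalg.norm(u)

    @property
    def motor_center_wrapped(self) -> np.ndarray:
        """Inner-shell bead centroid wrapped into the box."""
        inner = (self.mspecies == E0) | (self.mspecies == E1)
        return np.mod(self.mpos[inner].mean(axis=0), self.box)

    def kinetic_energy(self) -> float:
        ke_s = 0.5 * self.ms * float(np.sum(self.svel * self.svel))
        ke_m = 0.5 * float(np.sum(self.mmass * np.sum(self.mvel ** 2, axis=1)))
        return ke_s + ke_m

    def total_momentum(self) -> np.ndarray:
        return (self.ms * self.svel.sum(axis=0)
                + self.mmass @ self.mvel)

    def kinetic_temperature(self) -> float:
        n = self.n_solvent + len(self.mpos)
        return 2.0 * self.kinetic_energy() / (3.0 * n)


def make_state(config: SimulationConfig, motor: Motor,
               rng: np.random.Generator) -> SystemState:
    """Place the motor at the box center and fill the box with fuel.

    Solvent particles (all species A initially) are inserted uniformly
    outside every bead's interaction range and outside the motor
    interior; velocities are Maxwell-Boltzmann at T with the total system
    momentum zeroed and the kinetic energy rescaled to exactly (3N/2) kB T.
    """
    box = config.box
    center = box / 2.0
    mpos = motor.positions + center
    n = config.n_solvent
    bead = motor.sigmas > 0
    bpos_w = np.mod(mpos[bead], box)
    margin = RC_FACTOR * motor.sigmas[bead] + 0.05
    tree = cKDTree(bpos_w, boxsize=box)
    spos = np.zeros((0, 3))
    while len(spos) < n:
        batch = rng.uniform(0.0, 1.0, size=(int(1.2 * (n - len(spos))) + 64, 3)) * box
        d, j = tree.query(batch, k=1)
        ok = d > margin[j]
        dc = batch - center
        dc -= np.round(dc / box) * box
        ok &= np.sum(dc * dc, axis=1) > config.R1 ** 2
        spos = np.vstack([spos, batch[ok]])
    spos = spos[:n]
    svel = rng.normal(0.0, math.sqrt(config.T / config.ms), size=(n, 3))
    # zero total momentum (motor starts at rest), then set T exactly
    svel -= svel.mean(axis=0)
    ke = 0.5 * config.ms * np.sum(svel * svel)
    svel *= math.sqrt(1.5 * n * config.T / ke)
    return SystemState(
        mpos=mpos, mvel=np.zeros_like(mpos), mmass=motor.masses.copy(),
        mspecies=motor.species.copy(), msigma=motor.sigmas.copy(),
        spring_i=motor.spring_i.copy(), spring_j=motor.spring_j.copy(),
        spring_r0=motor.spring_r0.copy(),
        spos=spos, svel=svel,
        sspecies=np.full(n, SPECIES_A, dtype=np.int8),
        ms=config.ms, ks=config.ks, box=box.astype(float))


# ----------------------------------------------------------------------
# forces
# ----------------------------------------------------------------------
@dataclass
class Forces:
    """Force evaluation result.

    ``f_solvent_cand`` holds forces only for the ``candidates`` rows (the
    solvent particles within the motor's bounding sphere); all other
    solvent particles are force-free.  ``zone1``/``zone2``/``in_cutoff``
    are per-candidate flags used by the reaction step.
    """

    f_motor: np.ndarray
    candidates: np.ndarray
    f_solvent_cand: np.ndarray
    potential: float
    zone1: np.ndarray
    zone2: np.ndarray
    in_cutoff: np.ndarray

    def full_solvent_forces(self, n: int) -> np.ndarray:
        f = np.zeros((n, 3))
        f[self.candidates] = self.f_solvent_cand
        return f


def _spring_forces(state: SystemState):
    f = np.zeros_like(state.mpos)
    if len(state.spring_i) == 0:
        return f, 0.0
    d = state.mpos[state.spring_i] - state.mpos[state.spring_j]
    r = np.linalg.norm(d, axis=1)
    stretch = r - state.spring_r0
    u = 0.5 * state.ks * float(np.sum(stretch * stretch))
    fmag = (-state.ks * stretch / r)[:, None] * d
    np.add.at(f, state.spring_i, fmag)
    np.add.at(f, state.spring_j, -fmag)
    return f, u


def _candidate_solvent(state: SystemState, reach: float) -> np.ndarray:
    """Solvent particles inside the motor bounding sphere (+ reach margin)."""
    center = state.motor_center_wrapped
    bead = state.bead_idx
    rel_b = state.mpos[bead] - (state.mpos[(state.mspecies == E0)
                                           | (state.mspecies == E1)].mean(axis=0))
    r_motor = float(np.sqrt(np.max(np.sum(rel_b * rel_b, axis=1))))
    rbound = r_motor + reach + 0.35
    d = state.spos - center
    d -= np.round(d / state.box) * state.box
    return np.flatnonzero(np.sum(d * d, axis=1) < rbound * rbound)


def compute_forces(state: SystemState, table: PairPotentialTable) -> Forces:
    """All forces: WCA solvent-bead pairs via the cell list, plus springs.

    The returned per-particle forces satisfy Newton's third law pair by
    pair, so the net force over the whole system vanishes.
    """
    box = state.box
    bead = state.bead_idx
    bpos_w = np.mod(state.mpos[bead], box)
    bspecies = state.mspecies[bead].astype(np.int64)
    edge_min = table.max_radius
    ncx = max(1, int(box[0] / edge_min))
    ncy = max(1, int(box[1] / edge_min))
    ncz = max(1, int(box[2] / edge_min))
    edge = float(box[0] / ncx)
    # non-cubic boxes: fall back to the largest edge so one scalar works
    if not (abs(box[0] / ncx - box[1] / ncy) < 1e-9
            and abs(box[0] / ncx - box[2] / ncz) < 1e-9):
        edge = float(max(box[0] / ncx, box[1] / ncy, box[2] / ncz))
        ncx = max(1, int(round(box[0] / edge)))
        ncy = max(1, int(round(box[1] / edge)))
        ncz = max(1, int(round(box[2] / edge)))
        edge = float(max(box[0] / ncx, box[1] / ncy, box[2] / ncz))
    cellstart, cellorder = _kernels.bead_cell_csr(bpos_w, edge, ncx, ncy, ncz)
    cand = _candidate_solvent(state, table.max_radius)
    fs, fb, u_wca, zone1, zone2, anycut, overlap = _kernels.solvent_bead_forces(
        state.spos, state.sspecies.astype(np.int64), cand,
        bpos_w, bspecies, table.eps,
        table.sigma_by_type ** 2, table.rc_by_type ** 2,
        table.rrxn_by_type ** 2,
        box.astype(float), edge, ncx, ncy, ncz, cellstart, cellorder)
    if overlap >= 0:
        raise OverlapError(f"solvent particle {overlap} overlaps a motor bead")
    f_motor, u_spring = _spring_forces(state)
    f_motor[bead] += fb
    return Forces(f_motor=f_motor, candidates=cand, f_solvent_cand=fs,
                  potential=u_wca + u_spring, zone1=zone1, zone2=zone2,
                  in_cutoff=anycut)


def compute_forces_bruteforce(state: SystemState,
                              table: PairPotentialTable) -> Forces:
    """O(N^2) reference force evaluation (oracle for the cell list).

    Evaluates every solvent-bead pair with the minimum image convention;
    intended for small systems only.
    """
    box = state.box
    bead = state.bead_idx
    bpos_w = np.mod(state.mpos[bead], box)
    btype = state.mspecies[bead].astype(int) - 1
    n = state.n_solvent
    fs = np.zeros((n, 3))
    fb = np.zeros((len(bead), 3))
    zone1 = np.zeros(n, dtype=np.uint8)
    zone2 = np.zeros(n, dtype=np.uint8)
    anycut = np.zeros(n, dtype=np.uint8)
    u = 0.0
    d = state.spos[:, None, :] - bpos_w[None, :, :]
    d -= np.round(d / box) * box
    r2 = np.sum(d * d, axis=2)
    rc2 = table.rc_by_type[btype] ** 2
    rrxn2 = table.rrxn_by_type[btype] ** 2
    inz = r2 < rrxn2[None, :]
    zone1 |= np.any(inz & (btype == 1)[None, :], axis=1)
    zone2 |= np.any(inz & (btype == 2)[None, :], axis=1)
    hit = r2 < rc2[None, :]
    anycut |= np.any(hit, axis=1)
    ii, jj = np.nonzero(hit)
    if len(ii):
        if np.any(r2[ii, jj] < 1e-12):
            raise OverlapError("solvent particle overlaps a motor bead")
        eps = table.eps[state.sspecies[ii].astype(int), btype[jj]]
        s2 = table.sigma_by_type[btype[jj]] ** 2 / r2[ii, jj]
        s6 = s2 ** 3
        u = float(np.sum(4.0 * eps * (s6 * s6 - s6 + 0.25)))
        fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2[ii, jj]
        fvec = fr[:, None] * d[ii, jj]
        np.add.at(fs, ii, fvec)
        np.add.at(fb, jj, -fvec)
    f_motor, u_spring = _spring_forces(state)
    f_motor[bead] += fb
    cand = np.arange(n)
    return Forces(f_motor=f_motor, candidates=cand, f_solvent_cand=fs,
                  potential=u + u_spring, zone1=zone1, zone2=zone2,
                  in_cutoff=anycut)


# ----------------------------------------------------------------------
# fused MD intervals (production path)
# ----------------------------------------------------------------------
#: Verlet-list skin [a0]; far above the largest possible relative
#: solvent-bead displacement within one MD interval (~0.02 at T=1/6)
NEIGHBOR_SKIN = 0.08


def _grid_params(box: np.ndarray, table: PairPotentialTable,
                 skin: float = 0.0):
    edge_min = table.max_radius + skin
    ncx = max(1, int(box[0] / edge_min))
    ncy = max(1, int(box[1] / edge_min))
    ncz = max(1, int(box[2] / edge_min))
    edge = float(max(box[0] / ncx, box[1] / ncy, box[2] / ncz))
    return edge, ncx, ncy, ncz


@dataclass
class ForceCache:
    """Persistent full-size force arrays between MD intervals.

    ``f_solvent`` rows outside ``candidates`` are exactly zero (particles
    beyond the motor's bounding sphere feel no force).  The zone/cutoff
    flags refer to the rows of ``candidates`` and describe the state at
    the end of the last completed interval.
    """

    f_solvent: np.ndarray
    f_motor: np.ndarray
    candidates: np.ndarray
    potential: float
    zone1: np.ndarray
    zone2: np.ndarray
    in_cutoff: np.ndarray


def init_force_cache(state: SystemState, table: PairPotentialTable) -> ForceCache:
    forces = compute_forces(state, table)
    return ForceCache(
        f_solvent=forces.full_solvent_forces(state.n_solvent),
        f_motor=forces.f_motor.copy(),
        candidates=forces.candidates,
        potential=forces.potential,
        zone1=forces.zone1, zone2=forces.zone2, in_cutoff=forces.in_cutoff)


def md_interval(state: SystemState, table: PairPotentialTable,
                cache: ForceCache, dt: float, n_inner: int) -> None:
    """Advance one MD interval ``dt`` with ``n_inner`` Verlet substeps.

    The candidate set and a candidate -> bead Verlet neighbor list are
    refreshed once per interval (bounding-sphere margin and list skin far
    exceed one interval's displacement); force-free solvent streams
    ballistically in the same pass.
    """
    bead = state.bead_idx
    inner = (state.mspecies == E0) | (state.mspecies == E1)
    center = np.mod(state.mpos[inner].mean(axis=0), state.box)
    rel_b = state.mpos[bead] - state.mpos[inner].mean(axis=0)
    r_motor = float(np.sqrt(np.max(np.sum(rel_b * rel_b, axis=1))))
    rbound = r_motor + table.max_radius + 0.35
    cand = _kernels.select_and_stream(state.spos, state.svel, state.box,
                                      center, rbound * rbound, dt)
    edge, ncx, ncy, ncz = _grid_params(state.box, table, NEIGHBOR_SKIN)
    rlist = table.max_radius + NEIGHBOR_SKIN
    u, zone1, zone2, anycut, overlap = _kernels.verlet_substeps(
        state.spos, state.svel, cache.f_solvent, state.sspecies, cand,
        state.mpos, state.mvel, cache.f_motor, state.mmass, bead,
        state.mspecies[bead].astype(np.int64),
        state.spring_i, state.spring_j, state.spring_r0, state.ks,
        table.eps, table.sigma_by_type ** 2, table.rc_by_type ** 2,
        table.rrxn_by_type ** 2, state.box, edge, ncx, ncy, ncz,
        rlist * rlist, n_inner, dt, state.ms)
    if overlap == -2:
        raise NumericalBlowupError("neighbor-list overflow (unphysical "
                                   "particle pile-up near the motor)")
    if overlap >= 0:
        raise OverlapError(f"solvent particle {overlap} overlaps a motor bead")
    state.time += dt
    cache.candidates = cand
    cache.potential = float(u)
    cache.zone1, cache.zone2, cache.in_cutoff = zone1, zone2, anycut
    if not np.isfinite(u):
        raise NumericalBlowupError(f"non-finite potential at t={state.time:.4f}")


# ----------------------------------------------------------------------
# integration (single-step reference path)
# ----------------------------------------------------------------------
def velocity_verlet_step(state: SystemState, table: PairPotentialTable,
                         forces: Forces, dt: float) -> Forces:
    """One velocity-Verlet step (half kick, drift, half kick) in place.

    Returns the forces at the new positions (to be reused as the cached
    forces for the next step).  Solvent positions are wrapped back into
    the periodic box after the drift; motor positions stay unwrapped.
    """
    inv_ms = 0.5 * dt / state.ms
    state.svel[forces.candidates] += inv_ms * forces.f_solvent_cand
    state.mvel += (0.5 * dt) * forces.f_motor / state.mmass[:, None]
    state.spos += dt * state.svel
    np.mod(state.spos, state.box, out=state.spos)
    state.mpos += dt * state.mvel
    state.time += dt
    new = compute_forces(state, table)
    state.svel[new.candidates] += inv_ms * new.f_solvent_cand
    state.mvel += (0.5 * dt) * new.f_motor / state.mmass[:, None]
    if not (np.all(np.isfinite(new.f_motor))
            and np.all(np.isfinite(new.f_solvent_cand))):
        bad = np.flatnonzero(~np.all(np.isfinite(new.f_motor), axis=1))
        which = f"motor particle {bad[0]}" if len(bad) else "a solvent particle"
        raise NumericalBlowupError(f"non-finite force on {which} "
                                   f"at t={state.time:.4f}")
    return new
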