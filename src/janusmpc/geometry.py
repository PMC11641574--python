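"""Janus motor construction.

The motor is a bead-spring body: two hemispherical caps of enzyme beads
(inert E0 and catalytic E1) on an inner shell of radius ``R1``, a partial
hemispherical shell of secondary-enzyme beads (E2) at radius ``R2``
covering an area fraction ``phi`` of the layer over the E1 side, and
``Nin`` internal point masses that carry mass and inertia only.  Every
particle is tied to its neighbours by harmonic springs whose rest lengths
equal the build-time separations, so the assembly moves as a nearly rigid
body while remaining an ordinary MD object.

Bead placement is deterministic (low-discrepancy lattices), so the motor
geometry is reproducible independently of the simulation seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .config import E0, E1, E2, INTERNAL, RC_FACTOR, SimulationConfig

logger = logging.getLogger("janusmpc")

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

#: fixed seed for internal-particle placement; geometry never depends on
#: the run seed
_INTERNAL_PLACEMENT_SEED = 1905


class GeometryError(ValueError):
    """Inconsistent motor geometry."""


# ----------------------------------------------------------------------
# point lattices
# ----------------------------------------------------------------------
#: plastic number, the basis of the R2 low-discrepancy sequence
_PLASTIC = 1.32471795724474602596


def _r2_sequence(n: int) -> tuple[np.ndarray, np.ndarray]:
    """First ``n`` terms of the 2D R2 (Roberts) low-discrepancy sequence,
    anchored so the first term is (0, 0).  Every prefix is near-uniform
    on the unit square."""
    k = np.arange(n)
    x1 = (k / _PLASTIC) % 1.0
    x2 = (k / _PLASTIC ** 2) % 1.0
    return x1, x2


def _rotate_z_to(points: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Rotate points so that +z maps onto ``axis`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, axis))
    if c > 1.0 - 1e-12:
        return points
    if c < -1.0 + 1e-12:  # antipodal: rotate pi about x
        return points * np.array([1.0, -1.0, -1.0])
    k = np.cross(z, axis)
    k /= np.linalg.norm(k)
    s = math.sqrt(max(0.0, 1.0 - c * c))
    return (points * c
            + np.cross(k, points) * s
            + np.outer(points @ k, k) * (1.0 - c))


def sample_shell_points(n: int, radius: float, region: str = "sphere",
                        axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Near-uniform deterministic points on a sphere or hemisphere shell.

    Parameters
    ----------
    n : number of points (>= 0).
    radius : shell radius (> 0).
    region : ``"sphere"`` for the full shell (Fibonacci lattice) or
        ``"hemisphere"`` for the half shell around ``axis``.  The
        hemisphere lattice is *nested*: its first point is the pole and
        every prefix of it is itself near-uniform, which is what allows
        partial E2 coverage to stay uniform.
    axis : pole direction for the hemisphere case.

    Returns
    -------
    (n, 3) array with every row at distance ``radius`` from the origin;
    for a hemisphere every row has a non-negative component along ``axis``.
    """
    if n < 0:
        raise ValueError(f"point count must be >= 0, got {n}")
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if n == 0:
        return np.zeros((0, 3))
    k = np.arange(n)
    if region == "sphere":
        z = 1.0 - (2.0 * k + 1.0) / n
        phi_az = k * GOLDEN_ANGLE
    elif region == "hemisphere":
        # nested lattice: z=1 (the pole) first, near-uniform prefixes;
        # a small equatorial margin keeps every bead strictly on its
        # hemisphere even under the slight axis tilt of a finite lattice
        x1, x2 = _r2_sequence(n)
        z = 1.0 - (1.0 - 0.02) * x1
        phi_az = 2.0 * math.pi * x2
    else:
        raise ValueError(f"unknown region {region!r}")
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.column_stack([rho * np.cos(phi_az), rho * np.sin(phi_az), z])
    if region == "hemisphere":
        pts = _rotate_z_to(pts, np.asarray(axis, dtype=float))
    return pts * radius


# ----------------------------------------------------------------------
# coverage fraction <-> bead count
# ----------------------------------------------------------------------
def ne2_from_phi(phi: float, sigma2: float, R2: float) -> int:
    """Number of E2 beads realizing area coverage ``phi`` of the outer layer.

    The coverage fraction is defined as phi = NE2 * (2^(1/6) sigma2)^2 / (2 R2^2):
    each bead claims a square patch of side equal to its WCA cutoff
    diameter on the hemisphere of area 2 pi R2^2 (the pi cancels in the
    convention).
    """
    if sigma2 <= 0 or R2 <= 0:
        raise ValueError("sigma2 and R2 must be > 0")
    if phi < 0:
        raise ValueError(f"phi must be >= 0, got {phi}")
    ne2 = int(round(phi * 2.0 * R2 * R2 / (RC_FACTOR * sigma2) ** 2))
    if phi > 1.0:
        logger.warning("phi=%.3g > 1 implies NE2=%d beyond geometric packing "
                       "of the shell", phi, ne2)
    return ne2


def phi_from_ne2(ne2: int, sigma2: float, R2: float) -> float:
    """Area coverage fraction realized by ``ne2`` beads on the outer layer."""
    if sigma2 <= 0 or R2 <= 0:
        raise ValueError("sigma2 and R2 must be > 0")
    if ne2 < 0:
        raise ValueError(f"NE2 must be >= 0, got {ne2}")
    phi = ne2 * (RC_FACTOR * sigma2) ** 2 / (2.0 * R2 * R2)
    if phi > 1.0:
        logger.warning("NE2=%d corresponds to phi=%.3g > 1 (over-packed shell)",
                       ne2, phi)
    return phi


# ----------------------------------------------------------------------
# the motor body
# ----------------------------------------------------------------------
@dataclass
class Motor:
    """Bead-spring Janus motor centred at the origin with axis +z at build.

    ``positions`` holds, in order, the E0 beads, E1 beads, E2 beads and
    internal particles; ``species`` uses the codes E0=1, E1=2, E2=3,
    INTERNAL=0.  ``sigmas`` is the per-particle LJ size parameter (0 for
    internal particles, which do not interact with solvent).
    """

    positions: np.ndarray          # (N, 3)
    species: np.ndarray            # (N,) int8
    masses: np.ndarray             # (N,)
    sigmas: np.ndarray             # (N,)
    spring_i: np.ndarray           # (S,) int
    spring_j: np.ndarray           # (S,) int
    spring_r0: np.ndarray          # (S,)
    R1: float = 2.9
    R2: float = 4.2
    sigma1: float = 0.3
    sigma2: float = 0.2
    ns_ref: float = 20.0           # solvent density, for the buoyancy report

    # -- derived ------------------------------------------------------
    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def bead_mask(self) -> np.ndarray:
        return self.species != INTERNAL

    @property
    def counts(self) -> dict:
        return {name: int(np.sum(self.species == code))
                for name, code in [("E0", E0), ("E1", E1), ("E2", E2),
                                   ("internal", INTERNAL)]}

    @property
    def ne2(self) -> int:
        return int(np.sum(self.species == E2))

    @property
    def phi(self) -> float:
        return phi_from_ne2(self.ne2, self.sigma2, self.R2)

    @property
    def total_mass(self) -> float:
        return float(np.sum(self.masses))

    @property
    def com(self) -> np.ndarray:
        return self.masses @ self.positions / self.total_mass

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from the E1-hemisphere COM to the E0-hemisphere COM."""
        c0 = self.positions[self.species == E0].mean(axis=0)
        c1 = self.positions[self.species == E1].mean(axis=0)
        u = c0 - c1
        return u / np.linalg.norm(u)

    def moment_of_inertia(self) -> float:
        """Mean principal moment of inertia about the COM."""
        r = self.positions - self.com
        r2 = np.sum(r * r, axis=1)
        tensor = np.zeros((3, 3))
        for a in range(3):
            for b in range(3):
                tensor[a, b] = np.sum(
                    self.masses * ((r2 if a == b else 0.0) - r[:, a] * r[:, b]))
        return float(np.trace(tensor) / 3.0)

    def buoyancy_report(self) -> dict:
        """Diagnostic: actual mass/inertia vs the neutrally buoyant sphere.

        The reference values use an effective hydrodynamic radius
        R = R1 + sigma1; the printed component masses are authoritative,
        the neutral-buoyancy relation M = (4/3) pi ns R^3 is reported
        only for comparison.
        """
        R = self.R1 + self.sigma1
        m_buoy = 4.0 / 3.0 * math.pi * self.ns_ref * R ** 3
        return {
            "mass": self.total_mass,
            "neutral_buoyancy_mass": m_buoy,
            "mass_ratio": self.total_mass / m_buoy,
            "moment_of_inertia": self.moment_of_inertia(),
            "rigid_sphere_inertia": 0.4 * self.total_mass * R ** 2,
        }

    def spring_graph_connected(self) -> bool:
        n = self.n_particles
        if n == 0:
            return True
        data = np.ones(len(self.spring_i))
        adj = coo_matrix((data, (self.spring_i, self.spring_j)), shape=(n, n))
        ncomp, _ = connected_components(adj, directed=False)
        return ncomp == 1

    def to_xyz(self, path, comment: str = "janusmpc motor") -> None:
        """Write an extended-XYZ record (species tag, x, y, z)."""
        names = {INTERNAL: "IN", E0: "E0", E1: "E1", E2: "E2"}
        with open(path, "w") as fh:
            fh.write(f"{self.n_particles}\n")
            fh.write(f"{comment} Properties=species:S:1:pos:R:3\n")
            for s, p in zip(self.species, self.positions):
                fh.write(f"{names[int(s)]} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}\n")


# ----------------------------------------------------------------------
def _sample_ball(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in a ball of given radius (rejection from the cube)."""
    out = np.zeros((0, 3))
    while len(out) < n:
        cand = rng.uniform(-radius, radius, size=(2 * n + 16, 3))
        cand = cand[np.sum(cand * cand, axis=1) < radius * radius]
        out = np.vstack([out, cand])
    return out[:n]


def _build_springs(positions: np.ndarray, species: np.ndarray,
                   k_neighbors: int = 6, bead_internal_struts: int = 16,
                   e2_struts: int = 8):
    """Spring topology holding the body nearly rigid at ks = 60.

    Local 6-nearest-neighbour springs (union over both endpoints) set the
    connectivity; radial struts from every bead to its 16 nearest
    internal particles suppress the soft bending modes of the bead
    shells, and struts from each E2 bead to its 8 nearest inner-shell
    beads make the outer layer co-move.  Rest lengths equal the build
    separations, so the network is initially stress-free.  Tuned so the
    RMS radial bead fluctuation stays below 5% of the bead size on the
    desk-scale fixtures (local springs alone are an order of magnitude
    too floppy).
    """
    n = len(positions)
    pairs = set()
    if n > 1:
        tree = cKDTree(positions)
        kq = min(k_neighbors + 1, n)
        _, idx = tree.query(positions, k=kq)
        for i in range(n):
            for j in np.atleast_1d(idx[i])[1:]:
                pairs.add((min(i, int(j)), max(i, int(j))))
    internal = np.flatnonzero(species == INTERNAL)
    beads = np.flatnonzero(species != INTERNAL)
    if bead_internal_struts and len(internal) and len(beads):
        tree_in = cKDTree(positions[internal])
        kq = min(bead_internal_struts, len(internal))
        _, idx = tree_in.query(positions[beads], k=kq)
        idx = np.atleast_2d(idx.reshape(len(beads), -1))
        for a, i in enumerate(beads):
            for j in idx[a]:
                g = int(internal[int(j)])
                pairs.add((min(int(i), g), max(int(i), g)))
    inner = np.flatnonzero((species == E0) | (species == E1))
    outer = np.flatnonzero(species == E2)
    if len(outer) and len(inner):
        tree_b = cKDTree(positions[inner])
        kq = min(e2_struts, len(inner))
        _, idx = tree_b.query(positions[outer], k=kq)
        idx = np.atleast_2d(idx.reshape(len(outer), -1))
        for a, i in enumerate(outer):
            for j in idx[a]:
                g = int(inner[int(j)])
                pairs.add((min(int(i), g), max(int(i), g)))
    if pairs:
        si, sj = map(np.array, zip(*sorted(pairs)))
    else:
        si = sj = np.zeros(0, dtype=int)
    r0 = np.linalg.norm(positions[si] - positions[sj], axis=1)
    return si.astype(np.int64), sj.astype(np.int64), r0


def build_motor(config: SimulationConfig) -> Motor:
    """Construct the Janus motor from a validated configuration.

    The motor axis is +z: E0 beads occupy the +z hemisphere, E1 beads the
    -z hemisphere, and the E2 shell covers the layer over the E1 side.
    """
    if config.R2 <= config.R1 + config.sigma1:
        raise GeometryError(
            f"R2={config.R2} <= R1+sigma1={config.R1 + config.sigma1}: "
            "inner and outer shells interpenetrate")
    up = np.array([0.0, 0.0, 1.0])
    p_e0 = sample_shell_points(config.NE0, config.R1, "hemisphere", up)
    p_e1 = sample_shell_points(config.NE1, config.R1, "hemisphere", -up)
    ne2 = ne2_from_phi(config.phi, config.sigma2, config.R2)
    p_e2 = sample_shell_points(ne2, config.R2, "hemisphere", -up)
    rng = np.random.default_rng(_INTERNAL_PLACEMENT_SEED)
    p_in = _sample_ball(config.Nin, 0.98 * config.R1, rng)

    positions = np.vstack([p_e0, p_e1, p_e2, p_in])
    species = np.concatenate([
        np.full(config.NE0, E0), np.full(config.NE1, E1),
        np.full(ne2, E2), np.full(config.Nin, INTERNAL),
    ]).astype(np.int8)
    masses = np.concatenate([
        np.full(config.NE0, config.m_out), np.full(config.NE1, config.m_out),
        np.full(ne2, config.m2), np.full(config.Nin, config.m_in),
    ])
    sigmas = np.concatenate([
        np.full(config.NE0, config.sigma1), np.full(config.NE1, config.sigma1),
        np.full(ne2, config.sigma2), np.zeros(config.Nin),
    ])
    si, sj, r0 = _build_springs(positions, species)
    motor = Motor(positions=positions, species=species, masses=masses,
                  sigmas=sigmas, spring_i=si, spring_j=sj, spring_r0=r0,
                  R1=config.R1, R2=config.R2, sigma1=config.sigma1,
                  sigma2=config.sigma2, ns_ref=config.ns)
    if not motor.spring_graph_connected():
        raise GeometryError("spring network is not a single connected body")
    return motor


def open_polar_cap(motor: Motor, cap_half_angle: float) -> Motor:
    """Remove E2 beads within ``cap_half_angle`` of the pole at theta=0.

    Theta is the polar angle measured from -u (the outward direction over
    the catalytic hemisphere).  Removing a polar cap opens the outer shell
    near theta=0 while leaving every other particle and every spring among
    the survivors untouched; the coverage fraction is recomputed from the
    surviving bead count.
    """
    if not 0.0 <= cap_half_angle <= math.pi / 2.0 + 1e-12:
        raise ValueError("cap half-angle must be in [0, pi/2]")
    if cap_half_angle == 0.0:
        return motor
    u = motor.axis
    inner = (motor.species == E0) | (motor.species == E1)
    center = motor.positions[inner].mean(axis=0)
    rel = motor.positions - center
    r = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore"):
        cos_theta = rel @ (-u) / np.where(r > 0, r, 1.0)
    remove = (motor.species == E2) & (cos_theta > math.cos(cap_half_angle))
    keep = ~remove
    old_to_new = -np.ones(motor.n_particles, dtype=np.int64)
    old_to_new[keep] = np.arange(int(np.sum(keep)))
    smask = keep[motor.spring_i] & keep[motor.spring_j]
    return Motor(
        positions=motor.positions[keep].copy(),
        species=motor.species[keep].copy(),
        masses=motor.masses[keep].copy(),
        sigmas=motor.sigmas[keep].copy(),
        spring_i=old_to_new[motor.spring_i[smask]],
        spring_j=old_to_new[motor.spring_j[smask]],
        spring_r0=motor.spring_r0[smask].copy(),
        R1=motor.R1, R2=motor.R2, sigma1=motor.sigma1, sigma2=motor.sigma2,
        ns_ref=motor.ns_ref)


def cap_angle_removing(motor: Motor, n_remove: int) -> float:
    """Cap half-angle that removes exactly ``n_remove`` E2 beads.

    Returns the midpoint between the ``n_remove``-th and the next E2 polar
    angle (from theta=0), so :func:`open_polar_cap` at this angle removes
    exactly that many beads.
    """
    u = motor.axis
    inner = (motor.species == E0) | (motor.species == E1)
    center = motor.positions[inner].mean(axis=0)
    rel = motor.positions[motor.species == E2] - center
    r = np.linalg.norm(rel, axis=1)
    theta = np.sort(np.arccos(np.clip(rel @ (-u) / r, -1.0, 1.0)))
    if n_remove <= 0:
        return 0.0
    if n_remove >= len(theta):
        return math.pi / 2.0
    return float(0.5 * (theta[n_remove - 1] + theta[n_remove]))
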