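"""Simulation parameters for the enzyme-cascade Janus motor model.

All quantities are in reduced units: lengths in MPC cell sizes ``a0``,
masses in solvent masses ``ms``, energies in the LJ energy unit (kB = 1),
times in ``a0 * sqrt(ms / energy)``.

The defaults describe a Janus colloid whose inner shell (radius ``R1``)
carries an inert hemisphere (E0 beads) and a catalytic hemisphere
(E1 beads, fuel conversion A -> I), surrounded by an outer hemispherical
shell (radius ``R2``) of secondary-enzyme beads (E2, I -> B) covering an
area fraction ``phi`` of that layer.  The solvent is a point-particle MPC
fluid of number density ``ns`` at temperature ``T``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import yaml

logger = logging.getLogger("janusmpc")

#: solvent species codes
SPECIES_A, SPECIES_I, SPECIES_B = 0, 1, 2
SOLVENT_SPECIES = ("A", "I", "B")

#: motor particle codes (0 is reserved for internal mass particles)
INTERNAL, E0, E1, E2 = 0, 1, 2, 3
BEAD_SPECIES = ("E0", "E1", "E2")

#: WCA cutoff factor 2**(1/6)
RC_FACTOR = 2.0 ** (1.0 / 6.0)


class ConfigError(ValueError):
    """Invalid or inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    # --- box and solvent ---
    Lx: float = 30.0          # box edge [a0]
    Ly: float = 30.0
    Lz: float = 30.0
    ns: float = 20.0          # solvent number density [a0^-3]
    ms: float = 1.0           # solvent particle mass
    T: float = 1.0 / 6.0      # temperature (kB = 1)

    # --- MPC solvent dynamics ---
    a0: float = 1.0           # collision cell size
    t_mpc: float = 0.5        # collision time interval
    rotation_angle: float = math.pi / 2.0  # SRD rotation angle

    # --- MD integration ---
    t_md: float = 0.005       # MD interval (reaction cadence)
    md_steps_per_mpc: float = 100  # MD intervals between collisions
    md_inner_substeps: int = 4  # Verlet substeps per MD interval
    ks: float = 60.0          # spring constant [energy / a0^2]

    # --- motor geometry ---
    R1: float = 2.9           # inner bead-shell radius
    sigma1: float = 0.3       # E0/E1 bead LJ size parameter
    NE0: int = 500            # inert beads on one hemisphere
    NE1: int = 500            # catalytic beads on the other
    Nin: int = 2681           # internal mass-carrying particles
    m_in: float = 0.44        # internal particle mass
    m_out: float = 1.50       # E0/E1 bead mass
    m2: float = 0.64          # E2 bead mass
    R2: float = 4.2           # outer E2 shell radius
    sigma2: float = 0.2       # E2 bead LJ size parameter
    phi: float = 0.8          # E2 area coverage fraction of the outer layer

    # --- solvent-bead interaction well depths eps[alpha][beta] ---
    eps_A_E0: float = 0.2
    eps_A_E1: float = 0.2
    eps_A_E2: float = 5.0
    eps_I_E0: float = 5.0
    eps_I_E1: float = 5.0
    eps_I_E2: float = 5.0
    eps_B_E0: float = 5.0
    eps_B_E1: float = 5.0
    eps_B_E2: float = 0.1

    # --- reactions ---
    kb_I: float = 0.001       # bulk regeneration rate I -> A
    kb_B: float = 0.001       # bulk regeneration rate B -> A
    surface_reaction_prob: float = 1.0
    reaction_shell: float = 0.05   # zero-potential trigger shell beyond rc
    regen_exclusion_radius: float | None = None  # default R2+sigma2+rc1
    solvent_internal_coupling: bool = False  # internal particles see no solvent

    # --- run control ---
    seed: int = 0
    total_time: float = 50.0
    burn_in_frac: float = 0.2
    snapshot_stride: int = 0     # frames every N MPC cycles; 0 = off
    max_energy_drift: float = 0.01  # abort threshold, relative

    # ------------------------------------------------------------------
    def epsilon_matrix(self) -> np.ndarray:
        """Interaction well depths as a (solvent species, bead species) array."""
        return np.array(
            [
                [self.eps_A_E0, self.eps_A_E1, self.eps_A_E2],
                [self.eps_I_E0, self.eps_I_E1, self.eps_I_E2],
                [self.eps_B_E0, self.eps_B_E1, self.eps_B_E2],
            ]
        )

    @property
    def box(self) -> np.ndarray:
        return np.array([self.Lx, self.Ly, self.Lz])

    @property
    def rc1(self) -> float:
        """WCA cutoff for E0/E1 beads."""
        return RC_FACTOR * self.sigma1

    @property
    def rc2(self) -> float:
        """WCA cutoff for E2 beads."""
        return RC_FACTOR * self.sigma2

    @property
    def max_cutoff(self) -> float:
        return max(self.rc1, self.rc2)

    @property
    def exclusion_radius(self) -> float:
        """Bulk-regeneration exclusion radius from the motor center."""
        if self.regen_exclusion_radius is not None:
            return self.regen_exclusion_radius
        return self.R2 + self.sigma2 + self.rc1

    @property
    def n_solvent(self) -> int:
        return int(round(self.ns * self.Lx * self.Ly * self.Lz))

    @property
    def n_mpc_cycles(self) -> int:
        return int(round(self.total_time / self.t_mpc))

    # ------------------------------------------------------------------
    def validate(self) -> "SimulationConfig":
        """Check all invariants; raise :class:`ConfigError` on violation."""
        positive = [
            "Lx", "Ly", "Lz", "ns", "ms", "T", "a0", "t_mpc", "t_md",
            "ks", "R1", "sigma1", "m_in", "m_out", "m2", "R2", "sigma2",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ["NE0", "NE1", "Nin", "md_steps_per_mpc"]:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.md_inner_substeps < 1:
            raise ConfigError("md_inner_substeps must be >= 1")
        if not 0.0 <= self.phi <= 1.0:
            raise ConfigError(f"phi must be in [0, 1], got {self.phi}")
        if not 0.0 <= self.surface_reaction_prob <= 1.0:
            raise ConfigError("surface_reaction_prob must be in [0, 1]")
        if self.kb_I < 0 or self.kb_B < 0:
            raise ConfigError("bulk regeneration rates must be >= 0")
        if self.R2 <= self.R1 + self.sigma1 + self.sigma2:
            raise ConfigError(
                f"outer shell R2={self.R2} interpenetrates the inner shell "
                f"(need R2 > R1 + sigma1 + sigma2 = "
                f"{self.R1 + self.sigma1 + self.sigma2})"
            )
        for L, name in [(self.Lx, "Lx"), (self.Ly, "Ly"), (self.Lz, "Lz")]:
            ncell = L / self.a0
            if abs(ncell - round(ncell)) > 1e-9:
                raise ConfigError(f"a0={self.a0} must divide box length {name}={L}")
        reach = self.R2 + self.sigma2
        hard = 2.0 * (reach + self.max_cutoff)
        soft = 4.0 * reach
        Lmin = min(self.Lx, self.Ly, self.Lz)
        if Lmin < hard:
            raise ConfigError(
                f"box edge {Lmin} too small for minimum-image motor interactions "
                f"(need >= {hard:.2f})"
            )
        if Lmin < soft:
            logger.warning(
                "box edge %.3g below 4x the motor reach (%.3g); concentration "
                "fields around the motor will feel periodic images", Lmin, soft
            )
        if not (0 < self.rotation_angle < 2 * math.pi):
            raise ConfigError("rotation_angle must be in (0, 2*pi)")
        return self

    # ------------------------------------------------------------------
    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# janusmpc simulation configuration (reduced units)\n")
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data).validate()
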