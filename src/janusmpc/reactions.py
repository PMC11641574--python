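"""The enzyme cascade and bulk fuel regeneration.

Surface rules (irreversible, catalytic beads unchanged):

    A + E1 -> I + E1        fuel converted at the catalytic hemisphere
    I + E2 -> B + E2        intermediate converted at the outer layer

A species flip changes only the particle's label, never its position,
velocity or the particle count.  To keep the microcanonical dynamics
exactly energy conserving, a flip fires only while the particle sits in a
thin reaction shell just outside the WCA cutoff of a catalytic bead
*and* outside the cutoff of every bead, where its total pair energy is
exactly zero for both the old and the new species.  Because no rule's
product is its own reactant, "flip once per encounter" is automatic.

Bulk regeneration (I -> A at rate kb_I, B -> A at rate kb_B) mimics a
sustained fuel supply.  It acts once per MPC step, only on particles
beyond an exclusion radius from the motor center, where all pair
potentials vanish - again preserving energy exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import SPECIES_A, SPECIES_B, SPECIES_I, SimulationConfig
from .md import Forces, SystemState


@dataclass
class ReactionRules:
    """Cascade stoichiometry and rates resolved from the configuration."""

    p_react: float = 1.0          # flip probability on encounter
    kb_I: float = 0.001           # bulk I -> A rate
    kb_B: float = 0.001           # bulk B -> A rate
    exclusion_radius: float = 4.74  # no regeneration closer to the motor

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "ReactionRules":
        return cls(p_react=config.surface_reaction_prob,
                   kb_I=config.kb_I, kb_B=config.kb_B,
                   exclusion_radius=config.exclusion_radius)


@dataclass
class ReactionCounters:
    n_surface_1: int = 0   # A -> I events
    n_surface_2: int = 0   # I -> B events
    n_regen: int = 0       # bulk regenerations


def surface_reaction_step(state: SystemState, forces: Forces,
                          rules: ReactionRules,
                          rng: np.random.Generator | None,
                          counters: ReactionCounters) -> None:
    """Apply the two surface rules for the current MD step, in place.

    ``forces`` carries the per-candidate zone flags from the force pass.
    The E1 rule is evaluated first, then the E2 rule on the updated
    species, so a particle genuinely crossing both reaction zones in one
    step would cascade A -> I -> B (geometrically impossible at the
    default shell separation, but well defined).
    """
    if rules.p_react <= 0.0:
        return
    cand = forces.candidates
    free = forces.in_cutoff == 0   # zero total pair energy: flip is allowed
    sp = state.sspecies[cand]
    fire1 = (sp == SPECIES_A) & (forces.zone1 == 1) & free
    if rules.p_react < 1.0 and rng is not None:
        fire1 &= rng.random(len(cand)) < rules.p_react
    if np.any(fire1):
        state.sspecies[cand[fire1]] = SPECIES_I
        counters.n_surface_1 += int(np.sum(fire1))
        sp = state.sspecies[cand]
    fire2 = (sp == SPECIES_I) & (forces.zone2 == 1) & free
    if rules.p_react < 1.0 and rng is not None:
        fire2 &= rng.random(len(cand)) < rules.p_react
    if np.any(fire2):
        state.sspecies[cand[fire2]] = SPECIES_B
        counters.n_surface_2 += int(np.sum(fire2))


def bulk_regeneration_step(state: SystemState, rules: ReactionRules,
                           dt: float, rng: np.random.Generator,
                           counters: ReactionCounters) -> None:
    """Convert far-field I and B particles back to fuel A, in place.

    Each eligible particle converts independently with probability
    1 - exp(-k dt), the exact Poisson first-event probability for the
    interval.  Particles within the exclusion radius of the motor center
    (minimum image) are never touched.
    """
    if rules.kb_I <= 0.0 and rules.kb_B <= 0.0:
        return
    center = state.motor_center_wrapped
    d = state.spos - center
    d -= np.round(d / state.box) * state.box
    far = np.sum(d * d, axis=1) > rules.exclusion_radius ** 2
    for sp, rate in ((SPECIES_I, rules.kb_I), (SPECIES_B, rules.kb_B)):
        if rate <= 0.0:
            continue
        eligible = np.flatnonzero((state.sspecies == sp) & far)
        if len(eligible) == 0:
            continue
        p = 1.0 - math.exp(-rate * dt)
        hit = eligible[rng.random(len(eligible)) < p]
        state.sspecies[hit] = SPECIES_A
        counters.n_regen += len(hit)


def species_census(state: SystemState) -> dict:
    """Current solvent species counts (their sum is invariant)."""
    return {
        "N_A": int(np.sum(state.sspecies == SPECIES_A)),
        "N_I": int(np.sum(state.sspecies == SPECIES_I)),
        "N_B": int(np.sum(state.sspecies == SPECIES_B)),
    }


def cascade_fires_simultaneously(state: SystemState, forces: Forces) -> bool:
    """Whether any particle is in both reaction zones this step (logged
    by the driver when it happens; requires overlapping shells)."""
    return bool(np.any((forces.zone1 == 1) & (forces.zone2 == 1)))
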