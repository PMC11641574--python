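# Methods

`janusmpc` simulates a chemically powered Janus colloid in a mesoscale
solvent and measures the observables that characterize its
self-propulsion. This note records the model, the numerical choices, and
what the desk-scale fixtures do and do not demonstrate.

## Model

**Motor.** A bead-spring body: `NE0` inert beads (E0) on one hemisphere
and `NE1` catalytic beads (E1) on the other, both on a shell of radius
`R1` with bead size parameter `sigma1`; a second, partial hemispherical
layer of `NE2` secondary-enzyme beads (E2, size `sigma2`) at radius `R2`
over the catalytic side; and `Nin` internal point particles that carry
mass and moment of inertia but do not interact with the solvent (the
dense bead shell shields them, and they exist to set the body's inertia).
The coverage fraction of the outer layer is

    phi = NE2 * (2^(1/6) * sigma2)^2 / (2 * R2^2),

so `phi = 1` corresponds to `NE2 = 700` at the default `sigma2 = 0.2`,
`R2 = 4.2`. The body axis `u` points from the catalytic-hemisphere
center of mass to the inert one; propulsion along `+u` means the inert
side leads.

**Solvent.** Point particles of mass `ms` at number density `ns`,
evolved by multi-particle collision dynamics (stochastic rotation
variant): free streaming plus, every `t_mpc`, a per-cell rotation of
velocities relative to the cell center of mass by a fixed angle
(default pi/2) about an independent random axis, on a unit lattice
shifted uniformly each step to restore Galilean invariance. The rule
conserves each cell's mass, momentum and kinetic energy exactly, so
hydrodynamics and thermal fluctuations emerge with no thermostat. The
kinetic-theory self-diffusion coefficient

    D = (kB T t_mpc / 2 ms) * [ 3 ns / ((ns - 1 + e^-ns)(1 - cos phi_rot)) - 1 ]

evaluates to 0.0899 at the production parameters (kB = 1, T = 1/6,
t_mpc = 0.5, ms = 1, ns = 20, phi_rot = pi/2). Note the temperature:
a reduced temperature of 1/6 reproduces this transport value; 16 does
not. The package therefore uses T = 1/6 everywhere.

**Coupling.** Solvent species alpha in {A, I, B} interact with beads of
type beta in {E0, E1, E2} through the purely repulsive shifted-truncated
Lennard-Jones (WCA) potential with well depth `eps[alpha][beta]`, size
parameter `sigma_beta` and cutoff `2^(1/6) sigma_beta`. The defaults
(`eps_A_E0 = eps_A_E1 = 0.2`; all I pairs, B at E0/E1, and A at E2 equal
5.0; `eps_B_E2 = 0.1`) create the interaction contrast that converts
self-generated concentration gradients into motion. Solvent-solvent
forces are absent (the MPC collisions carry the solvent's own momentum
transport), as are bead-bead excluded-volume forces (springs maintain
the geometry).

**Reactions.** The cascade is A + E1 -> I + E1 and I + E2 -> B + E2:
a reactant particle flips species on encountering a catalytic bead, with
position, velocity and particle count untouched. To keep the
microcanonical dynamics exactly energy conserving under discrete time,
the flip fires while the particle is inside a thin shell just outside
the bead's WCA cutoff (width `reaction_shell`, default 0.05, about
fifteen times the per-step displacement) *and* outside every bead's
cutoff, i.e. at exactly zero pair energy for both the old and the new
species. Because no rule's product is its own reactant, this state-based
rule is equivalent to "react once on first crossing". Bulk regeneration
(I -> A at `kb_I`, B -> A at `kb_B`, both 0.001 by default) acts once
per MPC step on particles beyond an exclusion radius
(`R2 + sigma2 + rc`) from the motor center, again at zero pair energy,
with the exact first-event probability `1 - exp(-k t_mpc)`.

**Spring network.** Every motor particle is tied to its 6 nearest
neighbours (union over both endpoints); every bead additionally to its
16 nearest internal particles; every E2 bead to its 8 nearest
inner-shell beads. Rest lengths equal the build-time separations, so
the network is initially stress-free. Local springs alone leave the
bead shells an order of magnitude too floppy at `ks = 60` (soft
collective bending modes reach radial RMS ~0.17 on the tiny fixture);
the radial struts bring the RMS radial bead fluctuation to ~0.012,
below 5% of `sigma1`, while keeping the network O(N). The printed
component masses (`m_in = 0.44`, `m_out = 1.50`, `m2 = 0.64`) are used
verbatim; the neutral-buoyancy relation M = (4/3) pi ns R^3 is reported
as a diagnostic (`Motor.buoyancy_report()`, effective R = R1 + sigma1),
not enforced, since the printed masses and the formula are not exactly
mutually consistent.

**Geometry determinism.** Bead lattices are deterministic: the full
sphere uses a Fibonacci lattice; hemispheres use an R2 (Roberts)
low-discrepancy sequence mapped to an area-uniform colatitude and
anchored at the pole, so every prefix of the lattice is itself
near-uniform — partial E2 coverage takes the first `NE2` points of the
same sequence and stays uniform, and opening a polar cap
(`open_polar_cap`) reproduces the "removed a portion near theta = 0"
construction. A 2% equatorial margin keeps every bead strictly on its
hemisphere under the slight axis tilt of a finite lattice. Internal
particles use a fixed placement seed, so the motor geometry never
depends on the run seed.

## Integration

The loop is: 100 MD intervals of `t_md = 0.005` (each followed by the
surface-reaction pass), then one MPC collision plus bulk regeneration.
Each MD interval is integrated with 4 inner velocity-Verlet substeps
(`md_inner_substeps`): at a single step of 0.005 the stiffest encounters
(eps = 5 on sigma = 0.2 beads) have dt*omega ~ 0.7 and heat the system
by ~2e-3 relative energy per 10^4 intervals; with 4 substeps the drift
falls to ~1e-5, comfortably inside the 1e-4 conservation target, while
the reaction cadence and collision cadence stay at their defined
intervals.

Forces are evaluated with a bead cell grid plus a candidate -> bead
Verlet neighbor list rebuilt once per MD interval; the list skin (0.08)
and the candidate bounding-sphere margin (0.35) exceed any possible
displacement within an interval by more than an order of magnitude.
The cell/neighbor path is verified against a brute-force O(N^2)
evaluation to 1e-12 on small states, and the fused multi-substep kernel
against the single-step reference integrator. Total momentum is
conserved to accumulation roundoff; per-cell MPC momentum and kinetic
energy to ~1e-15 relative.

Checkpoints store the full loop state including the RNG stream states
and the cached force arrays, making save -> load -> continue bit-identical
to an uninterrupted run. Three named RNG streams (initialization, MPC,
reactions) spawn from one master seed.

## Observables

`Vu(t)` is the motor COM velocity projected on `u(t)`; means are taken
after a burn-in (default: first 20% of the run) with blocked standard
errors. Concentration profiles are computed in the co-moving motor
frame with minimum-image displacements: radial profiles normalize
counts by shell-sector volumes (the catalytic sector is theta < pi/2
measured from `-u`); angular profiles use bins uniform in cos(theta)
(equal solid angle, so a uniform gas is flat by construction) within a
spherical shell, with a Spearman monotonicity diagnostic. The flow map
averages solvent velocities relative to the motor, azimuthally, onto an
(r, theta) grid as (axial, radial) components; empty cells are reported
as missing, never zero. `fit_power_law` fits Vu = A phi^4 + Vu0 by
fixed-exponent least squares and, separately, recovers a free exponent
with `scipy.optimize.curve_fit`; `fit_amplitude_vs_R2` fits the
amplitude line A(R2) = a - b R2 by OLS.

## Desk-scale fixtures and what they show

Production scale (box 30^3, ~5e5 solvent particles, 20 realizations per
point) exceeds a desktop budget, so the test suite runs three smaller
scenarios that keep every physical constant and shrink only the box and
particle counts:

| scale | box  | ns | NE0=NE1 | Nin | solvent |
|-------|------|----|---------|-----|---------|
| micro | 10^3 | 3  | 40      | 60  | 3,000   |
| tiny  | 12^3 | 5  | 80      | 200 | 8,640   |
| small | 16^3 | 10 | 300     | 500 | 40,960  |

The small fixture's bead count (300 per hemisphere) is chosen so the
inner shell stays impermeable to solvent (the three-bead gap barrier is
several kBT); the tiny fixture's sparser shell leaks and is used only
for conservation, determinism and rigidity checks, where leakage is
immaterial. Propulsion controls run on the small fixture with three
seeds per point and 280 MPC cycles per run (140 time units), the
longest runs that fit the suite's time budget. Because the motor
velocity decorrelates slowly (tau ~ M/gamma ~ 15-30 time units),
single-run error estimates from short-lag autocorrelations or small
blocks are biased low; all control tests therefore take their standard
errors from the seed-to-seed scatter of independent replicas, which is
~0.001-0.003 for the pooled means at these run lengths.

What passing desk-scale tests show: the conservation laws, the solvent's
transport and equilibrium physics, the sign and origin of propulsion
(interaction contrast on, inert side leading; contrast off, no drift),
and the fit machinery. What they do not show: the production-scale
magnitudes of Vu or the clean phi^4 scaling, both of which require far
larger boxes and longer averaging than a desktop run — at this scale
the phi-contrast in mean Vu is comparable to the reachable noise floor,
and the periodic images at box edge 16 (below 4x the motor reach) bias
the phoretic mobility. The coverage-trend test reports the honest
pooled measurement at fixed seeds either way.

## Known limitations

- The solvent is an ideal point-particle gas between collisions;
  solvent-solvent structure and solvent compressibility effects are
  those of MPC, not of a molecular liquid.
- No rotational observables (the motor's rotational diffusion is
  present physically but not measured).
- Surface reactions are irreversible with probability 1 per encounter;
  no Michaelis-Menten saturation or enzyme deactivation.
- The box must be cubic-commensurate with the MPC cell; the force grid
  assumes (near-)cubic boxes.
- Reported propulsion numbers at desk scale are finite-size biased;
  only their sign and ordering carry physical meaning there.
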