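"""Measurements on motor trajectories.

Everything the propulsion analysis needs: the axial velocity
Vu = V_com . u and its distribution, radial and angular concentration
profiles of the solvent species in the co-moving motor frame, the
azimuthally averaged flow field, and the coverage power law
Vu = A(R2) phi^4 + Vu0 with its amplitude line A(R2) = a - b R2.

Conventions: u points from the catalytic (E1) hemisphere to the inert
(E0) hemisphere; the polar angle theta of a solvent particle is measured
from -u, so theta = 0 is the outward pole over the catalytic side where
the outer enzyme layer sits.  Theta bins are uniform in cos(theta)
(equal solid angle), so a uniform gas yields a flat angular profile by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import SOLVENT_SPECIES


class InsufficientDataError(ValueError):
    """Not enough samples for the requested measurement."""


# ----------------------------------------------------------------------
# trajectory containers
# ----------------------------------------------------------------------
@dataclass
class Frame:
    """One stored snapshot of the solvent in the motor's reference data."""

    time: float
    positions: np.ndarray      # (Ns, 3) wrapped solvent positions
    velocities: np.ndarray     # (Ns, 3)
    species: np.ndarray        # (Ns,) A/I/B codes
    center: np.ndarray         # (3,) motor center (wrapped)
    axis: np.ndarray           # (3,) unit vector u
    motor_velocity: np.ndarray  # (3,) motor COM velocity
    box: np.ndarray            # (3,)


@dataclass
class ObservableSeries:
    """Motor time series: COM velocity and body axis versus time."""

    times: np.ndarray          # strictly increasing
    v_com: np.ndarray          # (n, 3)
    axis: np.ndarray           # (n, 3), unit vectors

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.v_com = np.asarray(self.v_com, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        norms = np.linalg.norm(self.axis, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("axis vectors must be unit length")

    @classmethod
    def from_log(cls, log: pd.DataFrame) -> "ObservableSeries":
        return cls(times=log["t"].to_numpy(),
                   v_com=log[["vcom_x", "vcom_y", "vcom_z"]].to_numpy(),
                   axis=log[["u_x", "u_y", "u_z"]].to_numpy())

    @property
    def vu(self) -> np.ndarray:
        """Instantaneous axial velocity Vu(t) = V(t) . u(t)."""
        return np.sum(self.v_com * self.axis, axis=1)


# ----------------------------------------------------------------------
# axial velocity statistics
# ----------------------------------------------------------------------
def blocked_standard_error(x: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error of the mean from block averages (correlated data).

    Valid only when the block length well exceeds the correlation time;
    prefer :func:`autocorrelated_standard_error` when the correlation
    time is unknown.
    """
    n_blocks = max(2, min(n_blocks, len(x) // 2)) if len(x) >= 4 else 2
    blocks = np.array_split(np.asarray(x, dtype=float), n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / math.sqrt(len(means)))


def integrated_autocorrelation_time(x: np.ndarray, c: float = 5.0) -> float:
    """Integrated autocorrelation time tau = 1 + 2 sum rho_k, with the
    self-consistent window of Sokal (stop at the first W >= c * tau)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        return 1.0
    y = x - x.mean()
    var = float(y @ y) / n
    if var == 0.0:
        return 1.0
    acf = np.correlate(y, y, "full")[n - 1:] / (n * var)
    tau = 1.0
    for w in range(1, n // 3 + 1):
        tau = 1.0 + 2.0 * float(acf[1:w + 1].sum())
        if w >= c * tau:
            break
    return max(tau, 1.0)


def autocorrelated_standard_error(x: np.ndarray) -> float:
    """Standard error of the mean of a stationary correlated series,
    sd * sqrt(tau / N) with tau the integrated autocorrelation time."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return float("inf")
    tau = integrated_autocorrelation_time(x)
    return float(x.std(ddof=1) * math.sqrt(tau / len(x)))


@dataclass
class VelocityStats:
    mean: float
    se: float
    n_samples: int
    hist_edges: np.ndarray
    hist_density: np.ndarray


def axial_velocity_stats(series: ObservableSeries,
                         burn_in_frac: float = 0.2,
                         bin_width: float | None = None) -> VelocityStats:
    """Mean axial velocity and its normalized distribution after burn-in."""
    t0 = series.times[0] + burn_in_frac * (series.times[-1] - series.times[0])
    keep = series.times >= t0
    vu = series.vu[keep]
    if len(vu) == 0:
        raise InsufficientDataError("no samples after the burn-in window")
    if bin_width is None:
        spread = np.ptp(vu)
        bin_width = spread / 30.0 if spread > 0 else 1.0
    lo = math.floor(vu.min() / bin_width) * bin_width
    hi = math.ceil(vu.max() / bin_width) * bin_width + 0.5 * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo - 0.5 * bin_width, lo + 0.5 * bin_width])
    density, edges = np.histogram(vu, bins=edges, density=True)
    return VelocityStats(mean=float(vu.mean()),
                         se=blocked_standard_error(vu),
                         n_samples=len(vu),
                         hist_edges=edges, hist_density=density)


# ----------------------------------------------------------------------
# concentration and flow fields
# ----------------------------------------------------------------------
def _relative_coords(frame: Frame):
    d = frame.positions - frame.center
    d -= np.round(d / frame.box) * frame.box
    r = np.linalg.norm(d, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.where(r > 0, d @ (-frame.axis) / np.where(r > 0, r, 1.0),
                             1.0)
    return d, r, np.clip(cos_theta, -1.0, 1.0)


@dataclass
class FieldGrid:
    """Binned field in the motor frame, as a tidy table."""

    table: pd.DataFrame
    n_frames: int
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def radial_concentration_profile(frames: list[Frame], species: str,
                                 bin_edges: np.ndarray,
                                 sector: str = "catalytic") -> FieldGrid:
    """Radial number density C(r) of one species around the motor.

    ``sector`` restricts the angular window: ``"catalytic"`` keeps
    theta < pi/2 (the hemisphere over the catalytic side, where the
    cascade happens), ``"inert"`` the opposite one, ``"full"`` everything.
    Densities are counts / (frames x sector shell volume); far-field bins
    of a non-reacting uniform gas recover the bulk density.
    """
    if len(frames) == 0:
        raise InsufficientDataError("no frames")
    code = SOLVENT_SPECIES.index(species)
    edges = np.asarray(bin_edges, dtype=float)
    counts = np.zeros(len(edges) - 1)
    r_inner_flagged = []
    for frame in frames:
        _, r, cos_theta = _relative_coords(frame)
        mask = frame.species == code
        if sector == "catalytic":
            mask &= cos_theta > 0
        elif sector == "inert":
            mask &= cos_theta < 0
        elif sector != "full":
            raise ValueError(f"unknown sector {sector!r}")
        counts += np.histogram(r[mask], bins=edges)[0]
    frac = 1.0 if sector == "full" else 0.5
    volumes = frac * 4.0 * math.pi / 3.0 * np.diff(edges ** 3)
    density = counts / (len(frames) * volumes)
    table = pd.DataFrame({
        "r_lo": edges[:-1], "r_hi": edges[1:],
        "r_mid": 0.5 * (edges[:-1] + edges[1:]),
        "species": species, "counts": counts, "density": density,
    })
    return FieldGrid(table=table, n_frames=len(frames),
                     meta={"sector": sector, "species": species})


def angular_concentration_profile(frames: list[Frame], species: str,
                                  r_lo: float, r_hi: float,
                                  n_bins: int = 18) -> FieldGrid:
    """Angular number density C(theta) within a spherical shell.

    Bins are uniform in cos(theta) over [-1, 1] (equal solid angle).
    Also reports a Spearman rank correlation of density against theta as
    a monotonicity diagnostic.
    """
    if len(frames) == 0:
        raise InsufficientDataError("no frames")
    if r_hi <= r_lo:
        raise ValueError("need r_hi > r_lo")
    code = SOLVENT_SPECIES.index(species)
    cos_edges = np.linspace(-1.0, 1.0, n_bins + 1)
    counts = np.zeros(n_bins)
    total_in_shell = 0
    for frame in frames:
        _, r, cos_theta = _relative_coords(frame)
        mask = (frame.species == code) & (r > r_lo) & (r < r_hi)
        total_in_shell += int(np.sum((r > r_lo) & (r < r_hi)))
        counts += np.histogram(cos_theta[mask], bins=cos_edges)[0]
    if total_in_shell == 0:
        raise InsufficientDataError(
            f"no solvent particles in the shell ({r_lo}, {r_hi})")
    shell_vol = (r_hi ** 3 - r_lo ** 3) / 3.0
    bin_vol = 2.0 * math.pi * np.diff(cos_edges) * shell_vol
    density = counts / (len(frames) * bin_vol)
    # theta decreases as cos(theta) increases: order bins by theta
    theta_mid = np.arccos(0.5 * (cos_edges[:-1] + cos_edges[1:]))[::-1]
    density_by_theta = density[::-1]
    counts_by_theta = counts[::-1]
    if np.any(counts > 0) and len(np.unique(density_by_theta)) > 1:
        rho = float(stats.spearmanr(theta_mid, density_by_theta).statistic)
    else:
        rho = float("nan")
    table = pd.DataFrame({
        "theta_mid": theta_mid,
        "cos_theta_lo": cos_edges[::-1][1:], "cos_theta_hi": cos_edges[::-1][:-1],
        "species": species, "counts": counts_by_theta,
        "density": density_by_theta,
    })
    return FieldGrid(table=table, n_frames=len(frames),
                     meta={"species": species, "r_lo": r_lo, "r_hi": r_hi,
                           "spearman_theta": rho})


def flow_field_map(frames: list[Frame], r_edges: np.ndarray,
                   theta_edges: np.ndarray) -> FieldGrid:
    """Mean solvent velocity on an (r, theta) grid in the motor frame.

    Velocities are taken relative to the motor COM velocity and
    azimuthally averaged into (axial, radial) components in the plane
    spanned by the motor axis: axial = v_rel . u, radial = v_rel . rho_hat
    with rho_hat the outward in-plane direction perpendicular to u.
    Cells that collect no samples are reported with NaN means (missing),
    not zero.
    """
    if len(frames) == 0:
        raise InsufficientDataError("no frames")
    r_edges = np.asarray(r_edges, dtype=float)
    theta_edges = np.asarray(theta_edges, dtype=float)
    nr, nt = len(r_edges) - 1, len(theta_edges) - 1
    sum_ax = np.zeros((nr, nt))
    sum_rad = np.zeros((nr, nt))
    n = np.zeros((nr, nt))
    for frame in frames:
        d, r, cos_theta = _relative_coords(frame)
        theta = np.arccos(cos_theta)
        v_rel = frame.velocities - frame.motor_velocity
        u = frame.axis
        ax_pos = d @ u
        perp = d - np.outer(ax_pos, u)
        perp_norm = np.linalg.norm(perp, axis=1)
        safe = perp_norm > 1e-12
        rho_hat = np.zeros_like(perp)
        rho_hat[safe] = perp[safe] / perp_norm[safe, None]
        v_ax = v_rel @ u
        v_rad = np.sum(v_rel * rho_hat, axis=1)
        ir = np.digitize(r, r_edges) - 1
        it = np.digitize(theta, theta_edges) - 1
        ok = (ir >= 0) & (ir < nr) & (it >= 0) & (it < nt)
        np.add.at(sum_ax, (ir[ok], it[ok]), v_ax[ok])
        np.add.at(sum_rad, (ir[ok], it[ok]), v_rad[ok])
        np.add.at(n, (ir[ok], it[ok]), 1)
    with np.errstate(invalid="ignore"):
        mean_ax = np.where(n > 0, sum_ax / np.where(n > 0, n, 1), np.nan)
        mean_rad = np.where(n > 0, sum_rad / np.where(n > 0, n, 1), np.nan)
    rr, tt = np.meshgrid(0.5 * (r_edges[:-1] + r_edges[1:]),
                         0.5 * (theta_edges[:-1] + theta_edges[1:]),
                         indexing="ij")
    table = pd.DataFrame({
        "r_mid": rr.ravel(), "theta_mid": tt.ravel(),
        "v_axial": mean_ax.ravel(), "v_radial": mean_rad.ravel(),
        "n_samples": n.ravel().astype(int),
    })
    return FieldGrid(table=table, n_frames=len(frames))


# ----------------------------------------------------------------------
# power-law fits
# ----------------------------------------------------------------------
@dataclass
class PowerLawFit:
    """Result of fitting Vu = A phi^p + Vu0 to a coverage sweep.

    ``amplitude``/``baseline`` come from the fixed-exponent (p = 4) least
    squares; the free-exponent fit reports ``exponent`` (with its own
    amplitude/baseline) as an exponent-recovery diagnostic.
    """

    amplitude: float
    baseline: float
    amplitude_se: float
    baseline_se: float
    exponent: float
    exponent_se: float
    amplitude_free: float
    baseline_free: float
    residuals: np.ndarray
    r_squared: float
    fixed_exponent: float = 4.0

    def summary(self) -> str:
        return (
            f"Vu = A phi^{self.fixed_exponent:g} + Vu0 :\n"
            f"  A   = {self.amplitude:.6g} +/- {self.amplitude_se:.2g}\n"
            f"  Vu0 = {self.baseline:.6g} +/- {self.baseline_se:.2g}\n"
            f"  free exponent = {self.exponent:.4g} +/- {self.exponent_se:.2g}\n"
            f"  R^2 = {self.r_squared:.5f}"
        )


def fit_power_law(phi: np.ndarray, vu: np.ndarray,
                  fixed_exponent: float = 4.0) -> PowerLawFit:
    """Fit the coverage power law; see :class:`PowerLawFit`."""
    phi = np.asarray(phi, dtype=float)
    vu = np.asarray(vu, dtype=float)
    if len(np.unique(phi)) < 4:
        raise ValueError("need at least 4 distinct coverage values")
    x = phi ** fixed_exponent
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, vu, rcond=None)
    resid = vu - design @ coef
    dof = max(1, len(vu) - 2)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(design.T @ design)
    ss_tot = float(np.sum((vu - vu.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0

    def model(p, a, c, e):
        return a * p ** e + c

    try:
        p0 = [coef[0] if abs(coef[0]) > 1e-300 else 1e-6, coef[1],
              fixed_exponent]
        popt, pcov = optimize.curve_fit(model, phi, vu, p0=p0, maxfev=20000)
        exp_se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else float("nan")
        a_free, c_free, e_free = (float(v) for v in popt)
    except Exception:
        a_free, c_free, e_free, exp_se = (float("nan"),) * 4
    return PowerLawFit(
        amplitude=float(coef[0]), baseline=float(coef[1]),
        amplitude_se=float(np.sqrt(cov[0, 0])),
        baseline_se=float(np.sqrt(cov[1, 1])),
        exponent=e_free, exponent_se=exp_se,
        amplitude_free=a_free, baseline_free=c_free,
        residuals=resid, r_squared=r2, fixed_exponent=fixed_exponent)


@dataclass
class AmplitudeLineFit:
    """OLS line A(R2) = a - b R2 through the per-R2 amplitudes."""

    a: float
    b: float
    a_se: float
    b_se: float
    r_squared: float

    def summary(self) -> str:
        return (f"A(R2) = a - b R2 : a = {self.a:.6g} +/- {self.a_se:.2g}, "
                f"b = {self.b:.6g} +/- {self.b_se:.2g}, R^2 = {self.r_squared:.5f}")


def fit_amplitude_vs_R2(r2_values: np.ndarray,
                        amplitudes: np.ndarray) -> AmplitudeLineFit:
    """Fit the amplitude line; the slope is reported as +b for A = a - b R2."""
    r2v = np.asarray(r2_values, dtype=float)
    amp = np.asarray(amplitudes, dtype=float)
    if len(np.unique(r2v)) < 2:
        raise ValueError("need at least 2 distinct R2 values")
    res = stats.linregress(r2v, amp)
    return AmplitudeLineFit(a=float(res.intercept), b=float(-res.slope),
                            a_se=float(res.intercept_stderr),
                            b_se=float(res.stderr),
                            r_squared=float(res.rvalue ** 2))


def make_synthetic_sweep(phi: np.ndarray, amplitude: float, baseline: float,
                         exponent: float = 4.0, noise_frac: float = 0.0,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Synthetic coverage-sweep velocities for fit-recovery studies.

    Multiplicative Gaussian noise: vu * (1 + noise_frac * N(0, 1)).
    """
    phi = np.asarray(phi, dtype=float)
    vu = amplitude * phi ** exponent + baseline
    if noise_frac > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        vu = vu * (1.0 + noise_frac * rng.normal(size=len(phi)))
    return vu
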