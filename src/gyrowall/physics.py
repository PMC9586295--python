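"""Closed-form physics used for interpretation and diagnostics.

Contains the gyrotactic reorientation rate, the far-field image-force-dipole
prediction for the wall-induced angular velocity of a swimmer near a plane
wall, the wall-induced-velocity diagnostic used to test that prediction
against binned speed fields, and the exponential (Peclet) fit of vertical
concentration profiles.  None of these enter the simulator; they are the
comparison layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import BinnedField, ConcentrationProfile

__all__ = [
    "GyrotaxisParams",
    "DipoleParams",
    "gyro_omega",
    "gyro_omega_3d_theta_component",
    "dipole_wall_omega",
    "dipole_sign_change_angles",
    "WallVelocityDiagnostic",
    "wall_induced_velocity_diagnostic",
    "fit_exponential_profile",
    "stationary_orientation_pdf",
]


@dataclass
class GyrotaxisParams:
    """B is the reorientation timescale set by the gravitational torque
    against viscous resistance (seconds)."""

    B: float

    def __post_init__(self):
        if self.B <= 0:
            raise ValueError("B must be positive")


@dataclass
class DipoleParams:
    """Far-field image-dipole parameters.

    p_strength < 0 for a puller; mu is the dynamic viscosity (Pa s);
    Gamma = (r^2 - 1)/(r^2 + 1) is the shape factor of a spheroid of aspect
    ratio r (Gamma ~ 0 for a nearly spherical cell).
    """

    p_strength: float
    mu: float
    Gamma: float = 0.0

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if not -1.0 <= self.Gamma <= 1.0:
            raise ValueError("Gamma must lie in [-1, 1]")

    @classmethod
    def from_aspect_ratio(cls, p_strength, mu, r):
        return cls(p_strength, mu, (r ** 2 - 1.0) / (r ** 2 + 1.0))


def gyro_omega(theta, params: GyrotaxisParams | float):
    """Gyrotactic angular velocity -cos(theta)/(2B) in the vertical plane.

    theta is measured clockwise below the horizontal, so theta = -pi/2 (up
    swimming) is the stable orientation.  Accepts scalars or arrays.
    """
    B = params.B if isinstance(params, GyrotaxisParams) else float(params)
    if B <= 0:
        raise ValueError("B must be positive")
    return -np.cos(theta) / (2.0 * B)


def gyro_omega_3d_theta_component(theta, B: float):
    """theta-component of the 3-D reorientation rate [k - (k.p)p]/(2B).

    With p = (cos theta, -sin theta) in the vertical plane and k the unit
    upward vector, dp/dt = [k - (k.p)p]/(2B) projected on dp/dtheta gives
    dtheta/dt; this reduces exactly to -cos(theta)/(2B) and is kept as an
    independent consistency route.
    """
    theta = np.asarray(theta, float)
    p = np.stack([np.cos(theta), -np.sin(theta)], axis=-1)
    k = np.array([0.0, 1.0])
    rate = (k - (p @ k)[..., None] * p) / (2.0 * B)
    dp_dtheta = np.stack([-np.sin(theta), -np.cos(theta)], axis=-1)
    # dp/dt = dp/dtheta * dtheta/dt and |dp/dtheta| = 1.
    return np.sum(rate * dp_dtheta, axis=-1)


def dipole_wall_omega(h, phi, params: DipoleParams):
    """Far-field image-dipole angular velocity at wall distance h (um).

    omega(h, phi) = p/(8 pi mu) * 3 sin(2 phi) / (16 h^3)
                    * [1 + (Gamma/2) (1 + sin^2 phi)]

    Odd in phi and decaying exactly as h^-3; used only as a diagnostic
    reference, never inside the simulator.
    """
    h = np.asarray(h, float)
    if np.any(h <= 0):
        raise ValueError("h must be positive")
    phi = np.asarray(phi, float)
    bracket = 1.0 + 0.5 * params.Gamma * (1.0 + np.sin(phi) ** 2)
    out = (params.p_strength / (8.0 * np.pi * params.mu)
           * 3.0 * np.sin(2.0 * phi) / (16.0 * h ** 3) * bracket)
    if out.ndim == 0:
        return float(out)
    return out


def dipole_sign_change_angles():
    """Orientations where the far-field wall-induced velocity changes between
    attraction and repulsion: phi = +-pi/2 +- arccos(1/3)."""
    a = np.arccos(1.0 / 3.0)
    return np.sort(np.array([np.pi / 2 + a, np.pi / 2 - a,
                             -np.pi / 2 + a, -np.pi / 2 - a]))


@dataclass
class WallVelocityDiagnostic:
    table: pd.DataFrame          # columns h, phi, u  (u = -(V_s - V_sb) sin phi)
    exponents: pd.DataFrame      # per-phi power-law exponent of |u| vs h
    sign_changes: np.ndarray     # phi values where u(phi) crosses zero at h_ref
    h_ref: float


def wall_induced_velocity_diagnostic(field: BinnedField, V_sb: float,
                                     wall: str = "lower",
                                     h_range: tuple = (20.0, 200.0),
                                     h_ref: float | None = None):
    """Test the binned speed field against the image-dipole expectation.

    Computes u(h, phi) = -(V_s - V_sb) sin(phi), the wall-induced velocity a
    tilted image dipole would produce, from the defined bins of a speed
    field; fits log|u| against log h per orientation over ``h_range`` to
    report the apparent power-law exponent (the far-field theory predicts
    -2); and locates the sign changes of u(phi) at the reference distance
    ``h_ref`` (default: innermost h bin in range).
    """
    if field.mean_speed is None:
        raise ValueError("field has no speed estimates; run estimate_drift_diffusion")
    yc = field.position_centers
    W = field.position_edges[-1]
    h = yc if wall == "lower" else W - yc
    phi = field.orientation_centers
    Hh, Pp = np.meshgrid(h, phi, indexing="ij")
    u = -(field.mean_speed - V_sb) * np.sin(Pp)
    tab = pd.DataFrame({"h": Hh.ravel(), "phi": Pp.ravel(), "u": u.ravel()})
    tab = tab.dropna(subset=["u"])

    lo, hi = h_range
    rows = []
    for j, p in enumerate(phi):
        col = u[:, j]
        sel = (h >= lo) & (h <= hi) & np.isfinite(col) & (np.abs(col) > 0)
        hh, uu = h[sel], np.abs(col[sel])
        if sel.sum() >= 3 and np.all(np.sign(col[sel]) == np.sign(col[sel][0])):
            slope = np.polyfit(np.log(hh), np.log(uu), 1)[0]
        else:
            slope = np.nan  # insufficient or sign-mixed bins: undefined
        rows.append({"phi": p, "exponent": slope, "n_bins": int(sel.sum())})
    exponents = pd.DataFrame(rows)

    if h_ref is None:
        in_range = np.where((h >= lo) & (h <= hi))[0]
        iref = in_range[np.argmin(h[in_range])] if len(in_range) else int(np.argmin(h))
    else:
        iref = int(np.argmin(np.abs(h - h_ref)))
    row = u[iref]
    crossings = []
    # sign changes between consecutive nonzero defined bins (exact zeros,
    # e.g. a flat diagnostic, produce no crossing)
    idx = np.where(np.isfinite(row) & (row != 0.0))[0]
    for a, b in zip(idx[:-1], idx[1:]):
        ua, ub = row[a], row[b]
        if ua * ub < 0:
            # linear interpolation between bin centers
            crossings.append(phi[a] + (phi[b] - phi[a]) * (-ua) / (ub - ua))
    return WallVelocityDiagnostic(
        table=tab,
        exponents=exponents,
        sign_changes=np.asarray(crossings),
        h_ref=float(h[iref]),
    )


def fit_exponential_profile(profile: ConcentrationProfile, H: float,
                            fit_range: tuple | None = None):
    """Least-squares fit of N(z) = N0 exp(sigma z / H) on log N.

    ``fit_range`` is a (z_lo, z_hi) interval in um; the default excludes
    5 L_c = H/10 from each wall, where wall effects invalidate the bulk
    exponential.  Returns (N0, sigma).  Requires >= 3 strictly positive bins
    in range.
    """
    z = profile.position_centers
    if fit_range is None:
        fit_range = (0.1 * H, 0.9 * H)
    lo, hi = fit_range
    sel = (z >= lo) & (z <= hi)
    if np.any(profile.N[sel] <= 0):
        raise ValueError("nonpositive concentration inside the fit range")
    if sel.sum() < 3:
        raise ValueError("need at least 3 bins inside the fit range")
    slope, intercept = np.polyfit(z[sel] / H, np.log(profile.N[sel]), 1)
    return float(np.exp(intercept)), float(slope)


def fit_gyrotactic_timescale(grid: BinnedField, position_rows=slice(5, 46),
                             min_count: int = 30) -> float:
    """Fit the bulk angular-velocity map to omega(theta) = -cos(theta)/(2B).

    Uses the orientation dependence of the binned omega estimates over the
    given bulk position rows (default: everything further than ~5 bins from
    each wall), weighted by bin occupancy.  Returns the fitted B (seconds).
    """
    if grid.omega is None:
        raise ValueError("grid has no omega estimates")
    w = grid.omega[position_rows]
    n = grid.count[position_rows].astype(float)
    theta = np.broadcast_to(grid.orientation_centers, w.shape)
    ok = np.isfinite(w) & (n >= min_count)
    if ok.sum() < 10:
        raise ValueError("too few defined bulk bins for the gyrotaxis fit")
    X = -np.cos(theta[ok])
    amp = float(np.sum(n[ok] * X * w[ok]) / np.sum(n[ok] * X * X))
    if amp <= 0:
        raise ValueError("fitted gyrotactic amplitude is not positive")
    return 1.0 / (2.0 * amp)


def stationary_orientation_pdf(theta, B: float, D_r: float):
    """Stationary density of dtheta = -cos(theta)/(2B) dt + sqrt(2 D_r) dW.

    A von Mises density centered on up-swimming:
    f(theta) = exp(-sin(theta)/(2 B D_r)) / (2 pi I0(kappa)),
    kappa = 1/(2 B D_r).
    """
    from scipy.special import i0
    kappa = 1.0 / (2.0 * B * D_r)
    return np.exp(-kappa * np.sin(theta)) / (2.0 * np.pi * i0(kappa))
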