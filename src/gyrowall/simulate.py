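"""Individual-based Langevin model of a gyrotactic swimmer near plane walls.

State is (wall-normal position, heading) per walker:

    dy     = -V_s(y, phi) sin(phi) dt
    dphi   =  omega(y, phi) dt + sqrt(2 D_r(y, phi)) dW      (Ito)

where omega is the sum of a wall-induced part omega_w and (in the vertical
plane) the gyrotactic part omega_g = -cos(theta)/(2B).  Time marching is
forward Euler with dimensionless step dtau (tau = t V_sb / H, default
2e-4); coefficients are evaluated at the pre-step state.  Walls reflect
specularly (position mirrored, heading sign flipped) and the heading is
periodic on (-pi, pi].

Model variants switch terms on and off:

=======  ==========  ===========  =========  ==========
variant  wall V_s    wall torque  gyrotaxis  wall D_r
=======  ==========  ===========  =========  ==========
I        yes         yes          no         no (D_rb)
II       yes         yes          no         yes
III      no (V_sb)   no           yes        no (D_rb)
IV       yes         yes          yes        no (D_rb)
V        yes         yes          yes        yes
=======  ==========  ===========  =========  ==========

With constant coefficient fields, variant I reduces to the uniform control
(V_s = V_sb, omega = 0, D_r = D_rb) whose stationary density is uniform in
both position and heading.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .tracks import Trajectory, wrap_angle
from .fields import BinnedField, ConcentrationProfile, make_grid, \
    estimate_pdf_and_concentration

__all__ = [
    "VARIANTS",
    "WallFields",
    "GriddedField2D",
    "SimConfig",
    "total_omega",
    "euler_maruyama_step",
    "apply_boundaries",
    "run_ensemble",
    "EnsembleResult",
    "run_unbounded",
    "measure_drift_diffusivity",
]

#: variant -> (wall speed, wall torque, gyrotaxis, wall diffusivity)
VARIANTS = {
    "I": (True, True, False, False),
    "II": (True, True, False, True),
    "III": (False, False, True, False),
    "IV": (True, True, True, False),
    "V": (True, True, True, True),
}


class GriddedField2D:
    """Bilinear interpolation of a (position x heading) grid layer.

    Periodic in the heading axis; position queries are clamped to the range
    of bin centers (constant extrapolation into the half-bin margins).
    Undefined (NaN) bins are filled from the nearest defined bin before
    interpolation; the number of filled bins is recorded in ``n_filled``.
    """

    def __init__(self, position_centers, orientation_centers, values):
        vals = np.array(values, dtype=float)
        self.n_filled = 0
        if np.isnan(vals).any():
            vals = self._fill_nearest(vals)
        self.yc = np.asarray(position_centers, float)
        self.pc = np.asarray(orientation_centers, float)
        self.vals = vals
        self.dy = self.yc[1] - self.yc[0]
        self.dp = self.pc[1] - self.pc[0]

    def _fill_nearest(self, vals):
        from scipy.ndimage import distance_transform_edt
        nan = np.isnan(vals)
        self.n_filled = int(nan.sum())
        if nan.all():
            raise ValueError("field grid has no defined bins")
        # nearest defined neighbor, with the heading axis wrapped
        stacked = np.concatenate([vals, vals, vals], axis=1)
        nan3 = np.isnan(stacked)
        _, idx = distance_transform_edt(nan3, return_indices=True)
        filled = stacked[idx[0], idx[1]]
        n = vals.shape[1]
        return filled[:, n:2 * n]

    @classmethod
    def from_binned(cls, grid: BinnedField, layer: str):
        return cls(grid.position_centers, grid.orientation_centers,
                   getattr(grid, layer))

    def __call__(self, y, phi):
        y = np.asarray(y, float)
        phi = np.asarray(phi, float)
        ny, nphi = self.vals.shape
        fy = np.clip((y - self.yc[0]) / self.dy, 0.0, ny - 1.0)
        iy0 = np.minimum(fy.astype(int), ny - 2)
        wy = fy - iy0
        fp = (phi - self.pc[0]) / self.dp
        ip0 = np.floor(fp).astype(int)
        wp = fp - ip0
        ip0 = np.mod(ip0, nphi)
        ip1 = np.mod(ip0 + 1, nphi)
        v = self.vals
        out = ((1 - wy) * (1 - wp) * v[iy0, ip0]
               + (1 - wy) * wp * v[iy0, ip1]
               + wy * (1 - wp) * v[iy0 + 1, ip0]
               + wy * wp * v[iy0 + 1, ip1])
        return out


@dataclass
class WallFields:
    """Coefficient fields V_s, omega_w, D_r as callables of (y, phi).

    Each callable must be numpy-vectorized over its arguments.  Values must
    be defined on [0, W] x (-pi, pi] with V_s >= 0, D_r >= 0 and periodic
    continuity in the heading.
    """

    V_s: callable
    omega_w: callable
    D_r: callable

    @classmethod
    def constant(cls, V_sb: float, D_rb: float):
        return cls(
            V_s=lambda y, phi: np.broadcast_to(float(V_sb), np.shape(y)),
            omega_w=lambda y, phi: np.zeros(np.shape(y)),
            D_r=lambda y, phi: np.broadcast_to(float(D_rb), np.shape(y)),
        )

    @classmethod
    def from_binned(cls, grid: BinnedField):
        """Bilinear interpolants of an estimated field grid (measured-field
        mode, the analogue of driving the model with experimental maps)."""
        return cls(
            V_s=GriddedField2D.from_binned(grid, "mean_speed"),
            omega_w=GriddedField2D.from_binned(grid, "omega"),
            D_r=GriddedField2D.from_binned(grid, "D_r"),
        )


@dataclass
class SimConfig:
    """Full specification of a simulation run."""

    variant: str = "I"
    W: float = 1000.0          # channel width/height, um
    L_c: float = 20.0          # characteristic cell length, um
    V_sb: float = 80.0         # bulk speed, um/s (sets the tau scale)
    D_rb: float = 0.025        # bulk rotational diffusivity, rad^2/s
    B: float | None = None     # gyrotactic timescale, s (variants III-V)
    dtau: float = 2e-4         # dimensionless time step, tau = t V_sb / W
    n_traj: int = 100_000
    tau_end: float = 10.0
    burn_in_tau: float = 5.0   # accumulate the PDF only after this time
    seed: int = 0
    initial: str = "mid"       # "mid" (y = W/2) or "uniform"
    sample_stride: int = 25    # accumulate every this many steps
    reflect: bool = True       # False: unbounded domain (control runs)
    n_position_bins: int = 51
    n_orientation_bins: int = 80

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.dtau <= 0 or self.tau_end <= 0:
            raise ValueError("dtau and tau_end must be positive")
        if VARIANTS[self.variant][2] and self.B is None:
            raise ValueError(f"variant {self.variant} requires B")

    @property
    def dt(self):
        """Physical time step in seconds."""
        return self.dtau * self.W / self.V_sb

    def flags(self):
        return VARIANTS[self.variant]


def _coefficients(y, phi, fields: WallFields, config: SimConfig):
    """Variant-resolved (V_s, omega, D_r) at the pre-step state."""
    use_vs, use_tw, use_gyro, use_dr = config.flags()
    V = fields.V_s(y, phi) if use_vs else np.broadcast_to(config.V_sb, y.shape)
    omega = fields.omega_w(y, phi) if use_tw else np.zeros(y.shape)
    if use_gyro:
        if config.B is None:
            raise ValueError("gyrotactic term requires B")
        omega = omega + (-np.cos(phi) / (2.0 * config.B))
    D = fields.D_r(y, phi) if use_dr else np.broadcast_to(config.D_rb, y.shape)
    return V, omega, D


def total_omega(y, phi, fields: WallFields, config: SimConfig):
    """Variant-dependent deterministic angular velocity at (y, phi)."""
    y = np.atleast_1d(np.asarray(y, float))
    phi = np.atleast_1d(np.asarray(phi, float))
    _, omega, _ = _coefficients(y, phi, fields, config)
    return omega if omega.size > 1 else float(omega[0])


def euler_maruyama_step(y, phi, fields: WallFields, config: SimConfig, noise):
    """One forward-Euler step (no boundary application).

    ``noise`` is a standard-normal draw per walker; coefficients are
    evaluated at the pre-step state (Ito convention).
    """
    y = np.asarray(y, float)
    phi = np.asarray(phi, float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(phi))):
        raise ValueError("non-finite state")
    dt = config.dt
    V, omega, D = _coefficients(y, phi, fields, config)
    y_new = y - V * np.sin(phi) * dt
    phi_new = wrap_angle(phi + omega * dt + np.sqrt(2.0 * D * dt) * noise)
    return y_new, phi_new


def apply_boundaries(y, phi, W: float):
    """Specular reflection at y = 0 and y = W; heading wrapped.

    Mirror the position and flip the heading sign, which flips the
    wall-normal velocity component (sin(-phi) = -sin(phi)) and preserves
    speed.  Overshoot beyond one reflection is a step-size failure.
    """
    y = np.asarray(y, float)
    phi = np.asarray(phi, float)
    if np.any(y < -W) or np.any(y > 2 * W):
        raise RuntimeError("walker overshot beyond one reflection; reduce the step")
    below = y < 0
    above = y > W
    flip = below | above
    y = np.where(below, -y, y)
    y = np.where(above, 2 * W - y, y)
    phi = np.where(flip, wrap_angle(-phi), phi)
    return y, phi


@dataclass
class EnsembleResult:
    grid: BinnedField
    P: np.ndarray
    concentration: ConcentrationProfile
    final_y: np.ndarray
    final_phi: np.ndarray
    n_samples: int
    tracks: list = field(default_factory=list)


def run_ensemble(config: SimConfig, fields: WallFields | None = None,
                 dump_tracks: int = 0, dump_stride: int | None = None
                 ) -> EnsembleResult:
    """Simulate ``n_traj`` independent walkers and accumulate the late-time
    (position x heading) histogram.

    States are accumulated every ``sample_stride`` steps once tau exceeds
    ``burn_in_tau``.  Fully reproducible from ``config.seed``.  If
    ``dump_tracks`` > 0, that many walkers are also recorded as 2-D tracks
    (streamwise coordinate integrated as V_s cos(phi)) every ``dump_stride``
    steps, closing the loop with the track-analysis pipeline.
    """
    if fields is None:
        fields = WallFields.constant(config.V_sb, config.D_rb)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2024]))
    n = int(config.n_traj)
    if config.initial == "mid":
        y = np.full(n, config.W / 2.0)
    elif config.initial == "uniform":
        y = rng.uniform(0.0, config.W, n)
    else:
        raise ValueError("initial must be 'mid' or 'uniform'")
    phi = rng.uniform(-np.pi, np.pi, n)

    n_steps = int(round(config.tau_end / config.dtau))
    burn_steps = int(round(config.burn_in_tau / config.dtau))
    grid = make_grid(config.W, config.n_position_bins, config.n_orientation_bins)
    counts = np.zeros(grid.shape, dtype=np.int64)
    size = grid.shape[0] * grid.shape[1]
    n_samples = 0

    do_dump = dump_tracks > 0
    if do_dump:
        dump_stride = dump_stride or max(1, int(round(0.1 / config.dt)))
        x_dump = np.zeros(min(dump_tracks, n))
        y_hist, x_hist, t_hist = [], [], []

    dt = config.dt
    for step in range(n_steps):
        noise = rng.standard_normal(n)
        V, omega, D = _coefficients(y, phi, fields, config)
        if do_dump:
            m = len(x_dump)
            if step % dump_stride == 0:
                t_hist.append(step * dt)
                x_hist.append(x_dump.copy())
                y_hist.append(y[:m].copy())
            x_dump += V[:m] * np.cos(phi[:m]) * dt
        y = y - V * np.sin(phi) * dt
        phi = wrap_angle(phi + omega * dt + np.sqrt(2.0 * D * dt) * noise)
        if config.reflect:
            y, phi = apply_boundaries(y, phi, config.W)
        if step >= burn_steps and (step - burn_steps) % config.sample_stride == 0:
            if config.reflect:
                iy = np.minimum((y / config.W * grid.shape[0]).astype(int),
                                grid.shape[0] - 1)
                ip = np.minimum(((phi + np.pi) / (2 * np.pi)
                                 * grid.shape[1]).astype(int), grid.shape[1] - 1)
                counts += np.bincount(iy * grid.shape[1] + ip,
                                      minlength=size).reshape(grid.shape)
                n_samples += n
    grid.count = counts
    if config.reflect and counts.sum() > 0:
        P, conc = estimate_pdf_and_concentration(grid)
    else:
        P, conc = None, None

    tracks = []
    if do_dump and len(t_hist) > 1:
        times = np.asarray(t_hist)
        xs = np.asarray(x_hist)
        ys = np.asarray(y_hist)
        for j in range(len(x_dump)):
            tracks.append(Trajectory(
                track_id=j, times=times,
                positions=np.column_stack([xs[:, j], ys[:, j]]),
                frame_interval=float(times[1] - times[0])))
    return EnsembleResult(grid=grid, P=P, concentration=conc,
                          final_y=y, final_phi=phi, n_samples=n_samples,
                          tracks=tracks)


def run_unbounded(config: SimConfig, record_every: int = 1):
    """Unbounded control run (no walls): returns (times, z, theta) arrays.

    z has shape (n_recorded_times, n_traj).  Used to measure the bulk
    vertical drift and translational diffusivity of the free swimmer, and
    for closed-form orientation-law checks.
    """
    cfg = replace(config, reflect=False)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4091]))
    n = int(cfg.n_traj)
    z = np.zeros(n)
    theta = rng.uniform(-np.pi, np.pi, n)
    fields = WallFields.constant(cfg.V_sb, cfg.D_rb)
    n_steps = int(round(cfg.tau_end / cfg.dtau))
    dt = cfg.dt
    times, zs, thetas = [], [], []
    for step in range(n_steps):
        noise = rng.standard_normal(n)
        V, omega, D = _coefficients(z, theta, fields, cfg)
        z = z - V * np.sin(theta) * dt
        theta = wrap_angle(theta + omega * dt + np.sqrt(2.0 * D * dt) * noise)
        if (step + 1) % record_every == 0:
            times.append((step + 1) * dt)
            zs.append(z.copy())
            thetas.append(theta.copy())
    return np.asarray(times), np.asarray(zs), np.asarray(thetas)


def measure_drift_diffusivity(times, z, discard: float = 0.0):
    """Bulk vertical drift V_z and translational diffusivity D_T.

    V_z is the slope of the ensemble-mean z(t); D_T is half the slope of the
    ensemble variance of z(t); both from least squares over t > ``discard``
    (to skip the initial orientation transient).  Sign convention: V_z > 0
    means net upward motion.
    """
    times = np.asarray(times)
    sel = times > discard
    if sel.sum() < 3:
        raise ValueError("not enough recorded times after the discard window")
    mean_z = z[sel].mean(axis=1)
    var_z = z[sel].var(axis=1)
    V_z = float(np.polyfit(times[sel], mean_z, 1)[0])
    D_T = float(np.polyfit(times[sel], var_z, 1)[0] / 2.0)
    return V_z, D_T
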