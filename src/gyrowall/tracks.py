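"""Planar cell trajectories and their kinematics.

Tracks are uniformly sampled 2-D positions (streamwise x, wall-normal y, in
micrometres) at a fixed frame interval (0.1 s for the micro-PIV recordings this
package targets). The analysis convention follows the laboratory frame of the
experiments: walls sit at y = 0 and y = W, the heading angle phi lies in
(-pi, pi], and 0 < phi < pi means the cell moves toward the wall at y = 0
(dy/dt = -V_s sin phi).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "Kinematics",
    "wrap_angle",
    "smooth_trajectory",
    "compute_kinematics",
    "filter_tracks",
    "read_track_table",
    "write_track_table",
]

#: Uniform-sampling tolerance on |t[i+1] - t[i] - dt|, seconds.
_TIME_TOL = 1e-6


def wrap_angle(a):
    """Wrap angle(s) ``a`` (rad) into the interval (-pi, pi].

    Accepts scalars or arrays; the result is congruent to ``a`` modulo 2*pi.
    """
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("wrap_angle requires finite input")
    w = np.mod(a, 2.0 * np.pi)  # [0, 2*pi)
    w = np.where(w > np.pi, w - 2.0 * np.pi, w)
    if w.ndim == 0:
        return float(w)
    return w


@dataclass
class Trajectory:
    """One cell's uniformly sampled planar track.

    Parameters
    ----------
    track_id : hashable identifier.
    times : (n,) sample times in seconds, strictly increasing, uniform.
    positions : (n, 2) positions in micrometres, columns (x, y) =
        (streamwise, wall-normal).
    frame_interval : sampling interval dt in seconds.
    """

    track_id: object
    times: np.ndarray
    positions: np.ndarray
    frame_interval: float = 0.1

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if self.positions.shape != (len(self.times), 2):
            raise ValueError("positions must be (n, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.abs(dt - self.frame_interval) > _TIME_TOL):
            raise ValueError(
                f"track {self.track_id!r}: sampling is not uniform at "
                f"dt={self.frame_interval}"
            )

    def __len__(self):
        return len(self.times)

    @property
    def x(self):
        return self.positions[:, 0]

    @property
    def y(self):
        """Wall-normal coordinate (walls at 0 and W)."""
        return self.positions[:, 1]


@dataclass
class Kinematics:
    """Per-sample speed, heading and angular velocity for one trajectory.

    ``heading`` follows the sign convention above; samples where the velocity
    vanished carry the previous defined heading and are marked in
    ``undefined_heading``.
    """

    track_id: object
    speed: np.ndarray            # um/s, >= 0
    heading: np.ndarray          # rad, in (-pi, pi]
    angular_velocity: np.ndarray  # rad/s
    frame_interval: float
    undefined_heading: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.speed)
        if not (len(self.heading) == len(self.angular_velocity) == n):
            raise ValueError("kinematics arrays must have equal length")
        if self.undefined_heading is None:
            self.undefined_heading = np.zeros(n, dtype=bool)

    def __len__(self):
        return len(self.speed)

    @property
    def mean_speed(self):
        return float(np.mean(self.speed))


def _window_kernel(window: int) -> np.ndarray:
    """Centered smoothing kernel for one pass.

    Odd windows are plain centered means.  Even windows use the symmetric
    (window+1)-tap kernel with half-weight end taps (the average of the two
    possible off-center placements), which keeps the filter zero-phase: linear
    ramps pass through unchanged away from the track ends.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 1:
        return np.full(window, 1.0 / window)
    k = np.ones(window + 1)
    k[0] = k[-1] = 0.5
    return k / window


def smooth_trajectory(t: Trajectory, window: int = 10, passes: int = 5) -> Trajectory:
    """Smooth positions with repeated centered moving averages.

    Defaults (10-point window, 5 passes) match the de-zigzagging applied to
    the experimental tracks before any kinematic quantity is computed. The
    window is truncated (and renormalized) at the track ends.
    """
    if passes < 0:
        raise ValueError("passes must be >= 0")
    kernel = _window_kernel(window)
    pos = t.positions.copy()
    n = len(pos)
    if passes and n > 1:
        # Weight renormalization at the ends == convolving the all-ones track.
        ones = np.ones(n)
        norm = np.convolve(ones, kernel, mode="same")[:, None]
        for _ in range(passes):
            sm = np.empty_like(pos)
            for c in range(2):
                sm[:, c] = np.convolve(pos[:, c], kernel, mode="same")
            pos = sm / norm
    return Trajectory(t.track_id, t.times.copy(), pos, t.frame_interval)


def compute_kinematics(t: Trajectory) -> Kinematics:
    """Convert positions to speed, heading and angular velocity.

    Velocities use central differences, with one-sided differences at the
    first and last samples.  Heading is phi = atan2(-v_y, v_x) so that
    0 < phi < pi means the wall-normal velocity component is negative
    (motion toward the wall at y = 0).  Angular velocity uses minimally
    wrapped heading increments over 2*dt (dt at the ends), which prevents
    2*pi jumps from masquerading as sharp turns.
    """
    dt = t.frame_interval
    pos = t.positions
    v = np.empty_like(pos)
    v[1:-1] = (pos[2:] - pos[:-2]) / (2.0 * dt)
    v[0] = (pos[1] - pos[0]) / dt
    v[-1] = (pos[-1] - pos[-2]) / dt

    speed = np.hypot(v[:, 0], v[:, 1])
    undefined = speed == 0.0
    heading = np.arctan2(-v[:, 1], v[:, 0])
    # atan2 returns [-pi, pi]; fold -pi onto +pi for the (-pi, pi] convention.
    heading[heading == -np.pi] = np.pi
    if undefined.any():
        # Carry the last defined heading forward (then backward at the start).
        idx = np.where(~undefined, np.arange(len(heading)), -1)
        np.maximum.accumulate(idx, out=idx)
        first = np.argmax(~undefined) if (~undefined).any() else None
        if first is None:
            heading[:] = 0.0
        else:
            idx[idx < 0] = first
            heading = heading[idx]

    omega = np.empty_like(heading)
    omega[1:-1] = wrap_angle(heading[2:] - heading[:-2]) / (2.0 * dt)
    omega[0] = wrap_angle(heading[1] - heading[0]) / dt
    omega[-1] = wrap_angle(heading[-1] - heading[-2]) / dt

    return Kinematics(
        track_id=t.track_id,
        speed=speed,
        heading=heading,
        angular_velocity=omega,
        frame_interval=dt,
        undefined_heading=undefined,
    )


def filter_tracks(tracks, min_mean_speed: float = 5.0):
    """Keep tracks whose mean per-sample speed strictly exceeds the threshold.

    The 5 um/s default reproduces the screening applied to the experimental
    track sets before any population statistic.
    """
    kept = []
    for t in tracks:
        k = compute_kinematics(t)
        if k.mean_speed > min_mean_speed:
            kept.append(t)
    return kept


# ---------------------------------------------------------------------------
# Track-table I/O (the column set of common particle-tracking exports)
# ---------------------------------------------------------------------------

_COLUMNS = ["TRACK_ID", "POSITION_T", "POSITION_X", "POSITION_Y"]


def read_track_table(path_or_buf, frame_interval: float = 0.1):
    """Read a delimited track table into a list of :class:`Trajectory`.

    Requires columns TRACK_ID, POSITION_T (s), POSITION_X, POSITION_Y (um);
    tolerates extra columns and either comma or tab delimiters. Tracks with
    fewer than 2 samples are skipped (reported via the second return value).

    Returns
    -------
    (tracks, n_skipped)
    """
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    header = text.split("\n", 1)[0]
    sep = "\t" if "\t" in header else ","
    # float_precision='round_trip' makes read(write(tracks)) bit-exact
    df = pd.read_csv(io.StringIO(text), sep=sep, comment="#",
                     float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    tracks, n_skipped = [], 0
    for tid, g in df.groupby("TRACK_ID", sort=True):
        g = g.sort_values("POSITION_T")
        if len(g) < 2:
            n_skipped += 1
            continue
        tracks.append(
            Trajectory(
                track_id=tid,
                times=g["POSITION_T"].to_numpy(float),
                positions=g[["POSITION_X", "POSITION_Y"]].to_numpy(float),
                frame_interval=frame_interval,
            )
        )
    return tracks, n_skipped


def write_track_table(tracks, path_or_buf, sep: str = "\t"):
    """Write trajectories as a delimited track table (units: s and um).

    Floats are written with shortest-round-trip repr, so read/write
    round-trips are bit-exact.
    """
    frames = []
    for t in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "TRACK_ID": t.track_id,
                    "POSITION_T": t.times,
                    "POSITION_X": t.positions[:, 0],
                    "POSITION_Y": t.positions[:, 1],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    out = io.StringIO()
    out.write(sep.join(_COLUMNS) + "\n")
    for row in df.itertuples(index=False):
        out.write(
            sep.join(
                [str(row.TRACK_ID), repr(row.POSITION_T), repr(row.POSITION_X),
                 repr(row.POSITION_Y)]
            )
            + "\n"
        )
    data = out.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(data)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(data)
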