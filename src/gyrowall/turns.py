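"""Sharp-turn detection and event statistics.

A sharp turn is an episode in which the magnitude of a cell's angular
velocity exceeds a critical value omega_ct (pi/8 rad/s in the horizontal
plane, pi/2 rad/s in the vertical plane, where the gyrotactic background is
larger).  An event is the maximal contiguous run of samples with
|omega| >= omega_ct; t0 is the in-run sample of maximum |omega|.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .tracks import Trajectory, Kinematics

__all__ = [
    "OMEGA_CRIT_HORIZONTAL",
    "OMEGA_CRIT_VERTICAL",
    "SharpTurnEvent",
    "detect_sharp_turns",
    "events_table",
    "turn_statistics",
    "aligned_profiles",
    "default_regions",
]

OMEGA_CRIT_HORIZONTAL = np.pi / 8  # rad/s
OMEGA_CRIT_VERTICAL = np.pi / 2    # rad/s


@dataclass
class SharpTurnEvent:
    track_id: object
    start_index: int          # inclusive
    end_index: int            # inclusive
    t0_index: int             # argmax |omega| within the event (earliest tie)
    duration: float           # (end-start+1)*dt, s
    peak_abs_omega: float     # rad/s
    mean_speed_during: float  # um/s
    mean_abs_omega_during: float  # rad/s
    location: float           # wall-normal coordinate at t0, um


def detect_sharp_turns(k: Kinematics, omega_crit: float,
                       trajectory: Trajectory | None = None):
    """Detect sharp-turn events on one track.

    Parameters
    ----------
    k : kinematics of the track.
    omega_crit : positive threshold on |omega| (rad/s).
    trajectory : optional source track; if given, each event's ``location``
        is the wall-normal coordinate at t0 (otherwise NaN).

    Returns an ordered list of disjoint :class:`SharpTurnEvent`.
    """
    if omega_crit <= 0:
        raise ValueError("omega_crit must be positive")
    absw = np.abs(k.angular_velocity)
    above = absw >= omega_crit
    if not above.any():
        return []
    # Run boundaries of the boolean mask.
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(above) - 1]
    events = []
    dt = k.frame_interval
    for s, e in zip(starts, ends):
        seg = absw[s:e + 1]
        t0 = s + int(np.argmax(seg))  # argmax takes the earliest tie
        loc = float(trajectory.y[t0]) if trajectory is not None else float("nan")
        events.append(
            SharpTurnEvent(
                track_id=k.track_id,
                start_index=int(s),
                end_index=int(e),
                t0_index=t0,
                duration=(e - s + 1) * dt,
                peak_abs_omega=float(seg.max()),
                mean_speed_during=float(np.mean(k.speed[s:e + 1])),
                mean_abs_omega_during=float(np.mean(seg)),
                location=loc,
            )
        )
    return events


def events_table(events) -> pd.DataFrame:
    """One row per event, columns as in :class:`SharpTurnEvent`."""
    return pd.DataFrame([asdict(e) for e in events])


def turn_statistics(events, tracks, channel_width: float = 1000.0,
                    bin_width: float = 50.0) -> pd.DataFrame:
    """Per-position-bin sharp-turn statistics across the channel.

    For each wall-normal bin of width ``bin_width`` (default 2.5 L_c = 50 um)
    reports N_t (events whose t0 falls in the bin), N_traj (tracks that visit
    the bin), their ratio — the per-track sharp-turn probability profile —
    and the mean event duration.  Bins visited by no track carry NaN ratios.
    """
    edges = np.arange(0.0, channel_width + 0.5 * bin_width, bin_width)
    edges[-1] = channel_width
    nbins = len(edges) - 1

    def _bin(y):
        i = np.digitize(y, edges) - 1
        return np.clip(i, 0, nbins - 1)

    n_traj = np.zeros(nbins, dtype=int)
    for t in tracks:
        inside = (t.y >= 0) & (t.y <= channel_width)
        visited = np.unique(_bin(t.y[inside]))
        n_traj[visited] += 1

    n_t = np.zeros(nbins, dtype=int)
    dur_sum = np.zeros(nbins)
    for ev in events:
        if not np.isfinite(ev.location):
            continue
        if 0 <= ev.location <= channel_width:
            b = int(_bin(np.array([ev.location]))[0])
            n_t[b] += 1
            dur_sum[b] += ev.duration

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(n_traj > 0, n_t / np.maximum(n_traj, 1), np.nan)
        mean_dur = np.where(n_t > 0, dur_sum / np.maximum(n_t, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "bin_center": 0.5 * (edges[:-1] + edges[1:]),
            "n_turns": n_t,
            "n_tracks": n_traj,
            "turns_per_track": ratio,
            "mean_duration": mean_dur,
        }
    )


def default_regions(channel_width: float = 1000.0, L_c: float = 20.0):
    """Named wall and bulk regions: RW1/RW2 within 2.5 L_c of either wall,
    RB the mid-channel band 23.75-26.25 L_c."""
    return {
        "RW1": (0.0, 2.5 * L_c),
        "RW2": (channel_width - 2.5 * L_c, channel_width),
        "RB": (23.75 * L_c, 26.25 * L_c),
    }


def aligned_profiles(events, kinematics_by_id, regions=None, max_lag: int = 20,
                     channel_width: float = 1000.0, L_c: float = 20.0):
    """Time-aligned ensembles of V_s and |omega| around each event's t0.

    For every named region (keyed by the event location), averages speed and
    |omega| over events at each lag t - t0 on the grid
    ``lag in [-max_lag, +max_lag]`` frames (truncated at track ends).

    Returns a DataFrame with columns region, lag_s, mean_speed,
    mean_abs_omega, n_events.
    """
    if regions is None:
        regions = default_regions(channel_width, L_c)
    lags = np.arange(-max_lag, max_lag + 1)
    rows = []
    for name, (lo, hi) in regions.items():
        sel = [e for e in events
               if np.isfinite(e.location) and lo <= e.location <= hi]
        speed_sum = np.zeros(len(lags))
        omega_sum = np.zeros(len(lags))
        count = np.zeros(len(lags), dtype=int)
        for e in sel:
            k = kinematics_by_id[e.track_id]
            idx = e.t0_index + lags
            ok = (idx >= 0) & (idx < len(k))
            speed_sum[ok] += k.speed[idx[ok]]
            omega_sum[ok] += np.abs(k.angular_velocity[idx[ok]])
            count[ok] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            ms = np.where(count > 0, speed_sum / np.maximum(count, 1), np.nan)
            mo = np.where(count > 0, omega_sum / np.maximum(count, 1), np.nan)
        dt = next(iter(kinematics_by_id.values())).frame_interval if kinematics_by_id else 0.1
        for i, lag in enumerate(lags):
            rows.append(
                {"region": name, "lag_s": lag * dt, "mean_speed": ms[i],
                 "mean_abs_omega": mo[i], "n_events": count[i]}
            )
    return pd.DataFrame(rows)
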