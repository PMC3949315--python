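"""Reach-trajectory metrics.

Per-trial measures of perturbation and adaptation: maximum perpendicular
error from the straight start→target line, signed angular error at peak
speed, path length normalized by the 10-cm reach distance, correlation with
the matched baseline reach over position+velocity channels, and ρ — a
running windowed inner product of the trial's velocity against the average
baseline velocity trace, normalized so a trial identical to its baseline
scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .kinematics import Trajectory

__all__ = [
    "AlignedTrial",
    "align_trial",
    "estimate_velocity",
    "mpe",
    "signed_mpe",
    "angular_error",
    "normalized_path_length",
    "trajectory_correlation",
    "rho",
]

REACH_DISTANCE = 0.10  # m
ONSET_SPEED_EXP2 = 0.1  # m/s, alignment threshold
CORRELATION_WINDOW = (-0.125, 0.750)  # s around the alignment point
RHO_WINDOW = 0.100  # s, sliding-window length for ρ


def estimate_velocity(pos: np.ndarray, dt: float, cutoff_hz: float = 20.0) -> np.ndarray:
    """Velocity from position: central differences then 3rd-order 20-Hz low-pass."""
    vel = np.gradient(pos, dt, axis=0)
    nyq = 0.5 / dt
    if cutoff_hz < nyq:
        b, a = butter(3, cutoff_hz / nyq)
        padlen = min(3 * max(len(a), len(b)), pos.shape[0] - 1)
        vel = filtfilt(b, a, vel, axis=0, padlen=padlen)
    return vel


@dataclass
class AlignedTrial:
    """Trajectory translated to the origin and time-aligned to onset.

    The alignment sample is the first at which speed reaches ``threshold``;
    position is re-expressed relative to that sample and time relative to
    the alignment instant.
    """

    t: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    onset_index: int
    trial_id: int | None = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def align_trial(traj: Trajectory, threshold: float = ONSET_SPEED_EXP2) -> AlignedTrial:
    speed = traj.speed
    above = np.nonzero(speed >= threshold)[0]
    if len(above) == 0:
        raise ValueError(f"speed never reaches the {threshold} m/s alignment threshold")
    i0 = int(above[0])
    return AlignedTrial(
        t=traj.t - traj.t[i0],
        pos=traj.pos - traj.pos[i0],
        vel=traj.vel.copy(),
        onset_index=i0,
        trial_id=traj.trial_id,
    )


def _line_frame(start: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    d = np.asarray(target, float) - np.asarray(start, float)
    length = float(np.linalg.norm(d))
    if length == 0:
        raise ValueError("start and target coincide; perpendicular error undefined")
    u = d / length
    n = np.array([-u[1], u[0]])
    return u, n, length


def signed_mpe(traj: Trajectory, start, target) -> float:
    """Perpendicular error of largest magnitude, keeping its side (sign)."""
    _, n, _ = _line_frame(start, target)
    lateral = (traj.pos - np.asarray(start, float)) @ n
    return float(lateral[np.argmax(np.abs(lateral))])


def mpe(traj: Trajectory, start, target) -> float:
    """Maximum unsigned perpendicular distance from the start→target line, meters."""
    return abs(signed_mpe(traj, start, target))


def angular_error(traj: Trajectory, start, target) -> float:
    """Signed angle (degrees) between the target ray and the peak-speed ray.

    Both rays emanate from the start position; the second passes through
    the path point where speed is maximal (first sample on ties).
    Positive = counterclockwise of the target ray.
    """
    start = np.asarray(start, float)
    i_peak = int(np.argmax(traj.speed))
    p = traj.pos[i_peak] - start
    if np.linalg.norm(p) == 0:
        raise ValueError("peak-speed point coincides with the start position")
    d = np.asarray(target, float) - start
    ang = np.arctan2(p[1], p[0]) - np.arctan2(d[1], d[0])
    ang = (ang + np.pi) % (2 * np.pi) - np.pi
    return float(np.rad2deg(ang))


def normalized_path_length(traj: Trajectory, reach_distance: float = REACH_DISTANCE) -> float:
    """Discretely integrated path length divided by the reach distance."""
    seg = np.linalg.norm(np.diff(traj.pos, axis=0), axis=1)
    return float(seg.sum() / reach_distance)


def _window_slice(trial: AlignedTrial, window: tuple[float, float]) -> slice:
    lo = trial.onset_index + int(round(window[0] / trial.dt))
    hi = trial.onset_index + int(round(window[1] / trial.dt))
    if lo < 0 or hi >= len(trial.t):
        raise ValueError(
            f"trial covers [{trial.t[0]:.3f}, {trial.t[-1]:.3f}] s around onset; "
            f"window {window} not fully covered"
        )
    return slice(lo, hi + 1)


def trajectory_correlation(
    trial: AlignedTrial,
    baseline: AlignedTrial,
    window: tuple[float, float] = CORRELATION_WINDOW,
) -> float:
    """Correlation of trial vs baseline over concatenated position and velocity.

    Both traces are restricted to the window around their own alignment
    points; the Pearson coefficient is computed on the stacked
    (x, y, vx, vy) samples.
    """
    st, sb = _window_slice(trial, window), _window_slice(baseline, window)
    a = np.concatenate([trial.pos[st].ravel(), trial.vel[st].ravel()])
    b = np.concatenate([baseline.pos[sb].ravel(), baseline.vel[sb].ravel()])
    if len(a) != len(b):
        raise ValueError("trial and baseline sampling rates differ")
    return float(np.corrcoef(a, b)[0, 1])


def rho(
    trial: AlignedTrial,
    baseline: AlignedTrial,
    window_s: float = RHO_WINDOW,
    data_window: tuple[float, float] = CORRELATION_WINDOW,
) -> float:
    """Running windowed inner product of velocities, baseline-normalized.

    Over sliding windows of ``window_s`` within the analysis window, the
    mean inner product ⟨v_trial · v_baseline⟩ is averaged and divided by
    the identical statistic of the baseline with itself, so
    rho(baseline, baseline) = 1 exactly.
    """
    st, sb = _window_slice(trial, data_window), _window_slice(baseline, data_window)
    v1, v2 = trial.vel[st], baseline.vel[sb]
    if len(v1) != len(v2):
        raise ValueError("trial and baseline sampling rates differ")
    w = int(round(window_s / trial.dt))
    if w < 1 or w > len(v1):
        raise ValueError(f"window of {w} samples invalid for trace of {len(v1)}")

    def windowed_mean_inner(a, b):
        inner = np.sum(a * b, axis=1)
        kernel = np.ones(w) / w
        means = np.convolve(inner, kernel, mode="valid")
        return float(np.mean(means))

    denom = windowed_mean_inner(v2, v2)
    if denom == 0:
        raise ValueError("baseline velocity is identically zero in the window")
    return windowed_mean_inner(v1, v2) / denom
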