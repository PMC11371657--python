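"""Per-track kinematics, motility classification and reversal detection.

Trajectories are pose tables (one row per frame, time strictly
increasing).  The motility classification mirrors the tracking filters
used for twitching cells: mean speed below 0.038 µm/min is stationary;
faster tracks are motile unless their net-to-gross displacement ratio
(NGDR) falls below 0.04 (jostling in place) or their smoothed body angle
turns faster than 0.073 rad/min for more than 2 contiguous minutes
(surface-tethered rotation).  Orientation series are axial (mod pi),
unwrapped to a continuous signal and smoothed with a first-order
Savitzky-Golay filter over a 20 min window before differentiation.

Reversal detection is a documented stand-in (the original detector is
external): a reversal is logged where the dominant displacement direction
over the preceding and following persistence windows differ by more than
150 degrees, with consecutive detections merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .inference_stats import RateEstimate, poisson_rate_ci

logger = logging.getLogger(__name__)

STATIONARY = "stationary"
MOTILE = "motile"
EXCLUDED_ROTATING = "excluded_rotating"
EXCLUDED_JOSTLING = "excluded_jostling"


@dataclass
class KinematicsParams:
    """Motility-classification thresholds (units: µm, min, rad)."""

    v_stationary: float = 0.038     # µm/min
    ngdr_min: float = 0.04
    omega_max: float = 0.073        # rad/min
    omega_duration: float = 2.0     # min
    smoothing_window: float = 20.0  # min
    smoothing_order: int = 1
    reversal_angle_deg: float = 150.0
    reversal_persistence: int = 2   # frames


def _check_times(t: np.ndarray) -> None:
    if len(t) >= 2 and np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")


def compute_speed(traj: pd.DataFrame) -> np.ndarray:
    """Instantaneous speeds (µm/min) between consecutive frames."""
    if len(traj) < 2:
        raise ValueError("need at least two frames")
    t = traj.t_min.to_numpy(dtype=float)
    _check_times(t)
    dx = np.diff(traj.x_um.to_numpy(dtype=float))
    dy = np.diff(traj.y_um.to_numpy(dtype=float))
    return np.hypot(dx, dy) / np.diff(t)


def compute_ngdr(traj: pd.DataFrame) -> float:
    """Net-to-gross displacement ratio; 0 when the gross path length is 0."""
    x = traj.x_um.to_numpy(dtype=float)
    y = traj.y_um.to_numpy(dtype=float)
    steps = np.hypot(np.diff(x), np.diff(y))
    gross = steps.sum()
    if gross == 0:
        return 0.0
    net = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    return net / gross


def unwrap_axial(theta: np.ndarray) -> np.ndarray:
    """Unwrap an axial (mod pi) angle series into a continuous signal."""
    return np.unwrap(2.0 * np.asarray(theta, dtype=float)) / 2.0


def smooth_orientation(theta: np.ndarray, times: np.ndarray,
                       window: float = 20.0, order: int = 1) -> np.ndarray:
    """Savitzky-Golay smoothing of an (unwrapped) axial angle series.

    ``window`` is in minutes and converted to an odd frame count from the
    sampling interval; a window longer than the series passes the input
    through with a warning.  An order-1 filter is an exact local
    least-squares line fit, so linear ramps are preserved.
    """
    theta = unwrap_axial(theta)
    times = np.asarray(times, dtype=float)
    if len(theta) < 3:
        return theta
    dt = float(np.median(np.diff(times)))
    wl = int(round(window / dt))
    wl = wl + 1 if wl % 2 == 0 else wl
    wl = max(wl, order + 2 + ((order + 2) % 2 == 0))
    if wl > len(theta):
        logger.warning("smoothing window (%d frames) exceeds series length "
                       "(%d); passthrough", wl, len(theta))
        return theta
    return savgol_filter(theta, wl, order)


def angular_velocity(theta_smooth: np.ndarray,
                     times: np.ndarray) -> np.ndarray:
    """Central-difference angular velocity (rad/min) of a smoothed series."""
    if len(theta_smooth) < 2:
        return np.zeros(len(theta_smooth))
    return np.gradient(np.asarray(theta_smooth, dtype=float),
                       np.asarray(times, dtype=float))


def _has_contiguous_excursion(flags: np.ndarray, times: np.ndarray,
                              min_duration: float) -> bool:
    run_start = None
    for i, f in enumerate(flags):
        if f and run_start is None:
            run_start = i
        elif not f and run_start is not None:
            if times[i - 1] - times[run_start] > min_duration:
                return True
            run_start = None
    return run_start is not None and times[len(flags) - 1] - \
        times[run_start] > min_duration


def classify_motility(traj: pd.DataFrame,
                      params: KinematicsParams | None = None) -> str:
    """Assign one of stationary / motile / excluded_rotating /
    excluded_jostling to a track.

    Mean speed decides stationary vs candidate motile; candidates are then
    excluded for low NGDR (jostling) or sustained fast body rotation.
    Degenerate single-frame tracks are stationary.
    """
    params = params or KinematicsParams()
    if len(traj) < 2:
        return STATIONARY
    speeds = compute_speed(traj)
    if speeds.mean() < params.v_stationary:
        return STATIONARY
    if compute_ngdr(traj) < params.ngdr_min:
        return EXCLUDED_JOSTLING
    times = traj.t_min.to_numpy(dtype=float)
    theta_s = smooth_orientation(traj.orientation_rad.to_numpy(), times,
                                 params.smoothing_window,
                                 params.smoothing_order)
    omega = angular_velocity(theta_s, times)
    if _has_contiguous_excursion(np.abs(omega) > params.omega_max, times,
                                 params.omega_duration):
        return EXCLUDED_ROTATING
    return MOTILE


def detect_reversals(traj: pd.DataFrame, angle_threshold_deg: float = 150.0,
                     persistence: int = 2) -> list:
    """Reversal frames of a motile track.

    At frame k the dominant displacement direction is summed over the
    ``persistence`` steps before and after k; an angle between the two
    vectors above the threshold marks a reversal.  Detections within
    ``persistence`` frames of each other merge into one event (first
    frame reported).  Frames are the track's ``frame`` values.
    """
    x = traj.x_um.to_numpy(dtype=float)
    y = traj.y_um.to_numpy(dtype=float)
    frames = traj.frame.to_numpy()
    n = len(x)
    if n < 2 * persistence + 1:
        return []
    steps = np.column_stack([np.diff(x), np.diff(y)])
    cos_thr = np.cos(np.deg2rad(angle_threshold_deg))
    candidates = []
    for k in range(persistence, n - persistence):
        v_before = steps[k - persistence:k].sum(axis=0)
        v_after = steps[k:k + persistence].sum(axis=0)
        nb, na = np.linalg.norm(v_before), np.linalg.norm(v_after)
        if nb == 0 or na == 0:
            continue
        if np.dot(v_before, v_after) / (nb * na) < cos_thr:
            candidates.append(k)
    events = []
    for k in candidates:
        if events and k - events[-1][-1] <= persistence:
            events[-1].append(k)
        else:
            events.append([k])
    return [int(frames[grp[0]]) for grp in events]


def leading_pole_series(traj: pd.DataFrame,
                        v_stationary: float = 0.038) -> np.ndarray:
    """Leading pole (1 or 2) per frame from the instantaneous velocity.

    Pole 1 is the +axis endpoint (axis angle in [0, pi)).  The pole with
    the larger positive projection on the velocity leads; frames with
    speed below ``v_stationary`` are undefined (0).
    """
    t = traj.t_min.to_numpy(dtype=float)
    x = traj.x_um.to_numpy(dtype=float)
    y = traj.y_um.to_numpy(dtype=float)
    theta = traj.orientation_rad.to_numpy(dtype=float)
    n = len(t)
    out = np.zeros(n, dtype=int)
    if n < 2:
        return out
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    speed = np.hypot(vx, vy)
    proj = vx * np.cos(theta) + vy * np.sin(theta)
    defined = speed >= v_stationary
    out[defined & (proj > 0)] = 1
    out[defined & (proj <= 0)] = 2
    return out


def reversal_rate_series(reversal_times, point_times, boundaries,
                         conf: float = 0.95) -> pd.DataFrame:
    """Per-interval reversal counts, exposures and Poisson rate CIs.

    ``reversal_times`` are event times (min), ``point_times`` the times of
    every trajectory point counted as exposure, ``boundaries`` a sequence
    of half-open interval edges [b0, b1, ..., bk] defining k disjoint
    intervals [b_i, b_{i+1}).  The rate is events per trajectory point;
    intervals without exposure report NaN.
    """
    reversal_times = np.asarray(reversal_times, dtype=float)
    point_times = np.asarray(point_times, dtype=float)
    boundaries = np.asarray(boundaries, dtype=float)
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError("interval boundaries must be increasing")
    rows = []
    for i in range(len(boundaries) - 1):
        lo, hi = boundaries[i], boundaries[i + 1]
        n_r = int(np.sum((reversal_times >= lo) & (reversal_times < hi)))
        n_t = int(np.sum((point_times >= lo) & (point_times < hi)))
        if n_t == 0:
            rows.append({"interval": i, "t_start": lo, "t_end": hi,
                         "n_r": n_r, "n_t": 0, "rate": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        est: RateEstimate = poisson_rate_ci(n_r, n_t, conf)
        rows.append({"interval": i, "t_start": lo, "t_end": hi,
                     "n_r": n_r, "n_t": n_t, "rate": est.rate,
                     "ci_low": est.ci_low, "ci_high": est.ci_high})
    return pd.DataFrame(rows)


def annotate_tracks(poses: pd.DataFrame,
                    params: KinematicsParams | None = None) -> tuple:
    """Add per-frame kinematics columns and per-track classes.

    Returns ``(poses_with_columns, per_track_table)``.  Added columns:
    speed_um_min (NaN on the first frame of each track), ngdr,
    omega_rad_min, motility_class, is_reversal.
    """
    params = params or KinematicsParams()
    poses = poses.sort_values(["cell_id", "frame"]).reset_index(drop=True)
    speed_col = np.full(len(poses), np.nan)
    omega_col = np.full(len(poses), np.nan)
    rev_col = np.zeros(len(poses), dtype=bool)
    track_rows = []
    ngdr_col = np.full(len(poses), np.nan)
    class_col = np.empty(len(poses), dtype=object)
    for cid, idx in poses.groupby("cell_id").groups.items():
        idx = np.asarray(idx)
        traj = poses.loc[idx]
        mclass = classify_motility(traj, params)
        ngdr = compute_ngdr(traj) if len(traj) >= 2 else 0.0
        class_col[idx] = mclass
        ngdr_col[idx] = ngdr
        if len(traj) >= 2:
            speed_col[idx[1:]] = compute_speed(traj)
            times = traj.t_min.to_numpy(dtype=float)
            theta_s = smooth_orientation(traj.orientation_rad.to_numpy(),
                                         times, params.smoothing_window,
                                         params.smoothing_order)
            omega_col[idx] = angular_velocity(theta_s, times)
        rev_frames = detect_reversals(traj, params.reversal_angle_deg,
                                      params.reversal_persistence) \
            if mclass == MOTILE else []
        rev_col[idx[np.isin(traj.frame.to_numpy(), rev_frames)]] = True
        track_rows.append({"cell_id": cid, "n_frames": len(traj),
                           "motility_class": mclass, "ngdr": ngdr,
                           "mean_speed": np.nanmean(speed_col[idx])
                           if len(traj) >= 2 else 0.0,
                           "n_reversals": len(rev_frames)})
    out = poses.copy()
    out["speed_um_min"] = speed_col
    out["ngdr"] = ngdr_col
    out["omega_rad_min"] = omega_col
    out["motility_class"] = class_col
    out["is_reversal"] = rev_col
    return out, pd.DataFrame(track_rows)
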