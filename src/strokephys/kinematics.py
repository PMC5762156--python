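"""Skilled-reaching trajectory extraction and kinematic metrics.

A mouse reaches through a slot for a food pellet; the preferred paw, painted
with a green dye, is filmed from the side at 120 frames/s.  The paw is
tracked by colour contrast (green dominance over the red and blue channels),
yielding a 2-D sagittal-plane trajectory, from which four scalar metrics are
computed: ArcLen (total path length), AUC (area enclosed by the
reach-and-retract loop), Mean Speed (average tangential speed) and
Smoothness (number of peaks in the tangential speed profile; more peaks mean
a more fragmented, less smooth movement).  Only successful (correct) trials
enter the kinematic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "ReachTrajectory",
    "SpeedProfile",
    "KinematicMetrics",
    "TrackingError",
    "track_paw",
    "speed_profile",
    "kinematic_metrics",
    "baseline_normalize",
]


class TrackingError(ValueError):
    """Raised when a trial cannot be tracked reliably."""


@dataclass
class ReachTrajectory:
    """2-D paw path in the sagittal plane (x toward the slot, y upward), mm."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float
    trial_id: str | int | None = None
    outcome: str = "correct"
    interpolated: np.ndarray | None = None  # frames filled in by interpolation

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have matching shapes")
        if self.t.size < 5:
            raise ValueError("a trajectory needs at least 5 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.frame_rate, rtol=1e-6):
            raise ValueError("t must be strictly increasing and uniform at 1/frame_rate")
        if self.outcome not in ("correct", "incorrect"):
            raise ValueError("outcome must be 'correct' or 'incorrect'")

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class SpeedProfile:
    """Tangential speed of the paw, mm/s."""

    t: np.ndarray
    v: np.ndarray
    smoothing_window: int


@dataclass
class KinematicMetrics:
    arc_len: float      # mm
    auc: float          # mm^2
    mean_speed: float   # mm/s
    smoothness: int     # count of speed peaks


# ---------------------------------------------------------------------------
# colour-contrast tracking
# ---------------------------------------------------------------------------

def track_paw(
    frames: np.ndarray,
    mm_per_px: float,
    frame_rate: float,
    green_threshold: float = 40.0,
    max_missing_frac: float = 0.25,
    trial_id: str | int | None = None,
    outcome: str = "correct",
) -> ReachTrajectory:
    """Track the green-painted paw across a frame stack.

    Per frame, the binary mask is the set of pixels whose green dominance
    ``G - max(R, B)`` exceeds ``green_threshold`` (8-bit channels); the paw
    position is the dominance-weighted centroid of the largest connected
    component (weighting by the colour contrast gives sub-pixel accuracy on
    the anti-aliased dye edge).  Frames with
    an empty mask are filled by linear interpolation and flagged in
    ``interpolated``; if more than ``max_missing_frac`` of frames are empty
    the trial is rejected.

    ``frames`` is ``(n_frames, height, width, 3)`` RGB; output coordinates
    are millimetres with x along image columns and y upward (image rows
    flipped).
    """
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError("frames must be (n_frames, height, width, 3) RGB")
    n_frames, height = frames.shape[0], frames.shape[1]
    f = frames.astype(float)
    dominance = f[..., 1] - np.maximum(f[..., 0], f[..., 2])

    cols = np.full(n_frames, np.nan)
    rows = np.full(n_frames, np.nan)
    for i in range(n_frames):
        mask = dominance[i] > green_threshold
        if not mask.any():
            continue
        labels, n_comp = ndimage.label(mask)
        if n_comp > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
            keep = int(np.argmax(sizes)) + 1
            mask = labels == keep
        weights = np.where(mask, np.maximum(dominance[i], 0.0), 0.0)
        r, c = ndimage.center_of_mass(weights)
        rows[i], cols[i] = r, c

    missing = np.isnan(cols)
    if missing.mean() > max_missing_frac:
        raise TrackingError(
            f"{missing.mean():.0%} of frames had no trackable paw "
            f"(limit {max_missing_frac:.0%}); trial rejected"
        )
    if missing.any():
        idx = np.arange(n_frames)
        good = ~missing
        cols = np.interp(idx, idx[good], cols[good])
        rows = np.interp(idx, idx[good], rows[good])

    x = cols * mm_per_px
    y = (height - 1 - rows) * mm_per_px
    t = np.arange(n_frames) / frame_rate
    return ReachTrajectory(t=t, x=x, y=y, frame_rate=frame_rate, trial_id=trial_id,
                           outcome=outcome, interpolated=missing)


# ---------------------------------------------------------------------------
# speed profile and scalar metrics
# ---------------------------------------------------------------------------

def speed_profile(traj: ReachTrajectory, smoothing_window: int = 5) -> SpeedProfile:
    """Tangential speed via central differences plus moving-average smoothing.

    ``smoothing_window`` must be odd (1 disables smoothing).  Endpoints use
    one-sided differences.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be odd and >= 1")
    if traj.t.size < smoothing_window:
        raise ValueError("trajectory shorter than the smoothing window")
    dx = np.gradient(traj.x, traj.t)
    dy = np.gradient(traj.y, traj.t)
    v = np.hypot(dx, dy)
    if smoothing_window > 1:
        v = ndimage.uniform_filter1d(v, size=smoothing_window, mode="nearest")
    return SpeedProfile(t=traj.t.copy(), v=v, smoothing_window=smoothing_window)


def kinematic_metrics(
    traj: ReachTrajectory,
    speed: SpeedProfile | None = None,
    peak_prominence_frac: float = 0.1,
) -> KinematicMetrics:
    """The four reaching metrics: ArcLen, AUC, Mean Speed, Smoothness.

    ArcLen is the summed Euclidean segment length of the path.  AUC is the
    absolute shoelace area of the polygon formed by the path closed by the
    chord from its last back to its first point.  Mean Speed averages the
    tangential speed profile over the whole reach-and-retract movement.
    Smoothness counts local maxima of the speed profile with prominence at
    least ``peak_prominence_frac`` times the maximum speed; a moving
    trajectory whose profile is monotone (single extremum at the boundary)
    counts as one peak.
    """
    pts = traj.points
    if np.unique(pts, axis=0).shape[0] < 2:
        raise ValueError("degenerate trajectory: fewer than 2 distinct points")
    seg = np.diff(pts, axis=0)
    arc_len = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    x, y = traj.x, traj.y
    auc = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))

    if speed is None:
        speed = speed_profile(traj)
    v = speed.v
    mean_speed = float(v.mean())
    vmax = v.max()
    if vmax <= 0:
        smoothness = 0
    else:
        peaks, _ = signal.find_peaks(v, prominence=peak_prominence_frac * vmax)
        smoothness = max(int(peaks.size), 1)
    return KinematicMetrics(arc_len=arc_len, auc=auc, mean_speed=mean_speed,
                            smoothness=smoothness)


# ---------------------------------------------------------------------------
# session normalization
# ---------------------------------------------------------------------------

def baseline_normalize(
    df: pd.DataFrame,
    value_cols: list[str],
    baseline_sessions: list,
    session_col: str = "session",
    animal_col: str = "animal",
) -> pd.DataFrame:
    """Subtract each animal's mean over baseline sessions, per metric.

    Returns a copy of ``df`` with ``value_cols`` replaced by their
    baseline-subtracted values.  Every animal must have at least one baseline
    session.
    """
    out = df.copy()
    base = df[df[session_col].isin(baseline_sessions)]
    if base.empty:
        raise ValueError("no rows match the baseline sessions")
    means = base.groupby(animal_col)[value_cols].mean()
    missing = set(df[animal_col]) - set(means.index)
    if missing:
        raise ValueError(f"animals without baseline sessions: {sorted(missing)}")
    for col in value_cols:
        out[col] = df[col] - df[animal_col].map(means[col])
    return out
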