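"""Open-field behavioral measures: per-fly kinematics, group activity,
and the one-way ANOVA + Tukey HSD used to compare genotypes.

Trajectories are planar position series (mm) sampled at a fixed frame rate
(33 frames/s in the source assay).  Kinematic features are computed on a
centered-moving-average-smoothed track:

* pathlength   = Σ ‖p_{t+1} − p_t‖                       [mm]
* velocity_t   = ‖p_{t+1} − p_t‖ · fps, averaged         [mm/s]
* ang. vel._t  = |Δheading| · fps with headings from atan2 of the steps,
  wrapped to (−180°, 180°], averaged over frames whose adjacent steps are
  both nonzero                                           [deg/s]

Group activity is the per-frame count of flies whose step exceeds a movement
threshold, averaged within fixed-width time bins (10 s by default) and then
across replicate arenas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Trajectory",
    "KinematicFeatures",
    "GroupActivitySeries",
    "AnovaResult",
    "kinematic_features",
    "group_activity",
    "one_way_anova",
]


@dataclass
class Trajectory:
    """Per-fly planar track: positions (n, 2) in mm at fixed frame rate."""

    fly_id: str
    positions: np.ndarray
    fps: float = 33.0
    genotype: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n_frames, 2)")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions must be finite")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


@dataclass
class KinematicFeatures:
    pathlength: float         # mm
    mean_velocity: float      # mm/s
    mean_angular_velocity: float  # deg/s
    smoothing_window: int = 1
    n_heading_frames: int = 0  # frames that entered the angular mean


@dataclass
class GroupActivitySeries:
    genotype: str
    bin_width: float                 # s
    activity: np.ndarray             # per-bin mean moving-fly count, replicate-averaged
    n_replicates: int
    move_threshold: float            # mm/frame; must accompany every series

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if (self.activity < 0).any():
            raise ValueError("activity counts must be >= 0")


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    tukey: list[tuple[str, str, float, float]]  # (group_a, group_b, mean diff, adj p)


def _smooth(positions: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return positions
    kernel = np.ones(window) / window
    # valid-mode convolution: trims (window-1)//2 frames at each end so the
    # interior is an exact centered average, with no edge-padding artifacts
    return np.column_stack([
        np.convolve(positions[:, 0], kernel, mode="valid"),
        np.convolve(positions[:, 1], kernel, mode="valid"),
    ])


def kinematic_features(traj: Trajectory, smoothing_window: int = 5) -> KinematicFeatures:
    """Pathlength, mean velocity and mean angular velocity of one fly."""
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be odd and >= 1")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    pos = _smooth(traj.positions, smoothing_window)
    if pos.shape[0] < 2:
        raise ValueError("trajectory too short for this smoothing window")
    steps = np.diff(pos, axis=0)
    step_len = np.hypot(steps[:, 0], steps[:, 1])
    pathlength = float(step_len.sum())
    mean_velocity = float(step_len.mean() * traj.fps)

    moving = step_len > 0
    heading = np.degrees(np.arctan2(steps[:, 1], steps[:, 0]))
    # angular velocity defined only where both adjacent steps are nonzero
    valid = moving[:-1] & moving[1:]
    if valid.any():
        dh = heading[1:][valid] - heading[:-1][valid]
        dh = -((180.0 - dh) % 360.0 - 180.0)  # wrap to (-180, 180]
        mean_ang = float(np.abs(dh).mean() * traj.fps)
        n_heading = int(valid.sum())
    else:
        mean_ang = 0.0
        n_heading = 0
    return KinematicFeatures(
        pathlength=pathlength,
        mean_velocity=mean_velocity,
        mean_angular_velocity=mean_ang,
        smoothing_window=smoothing_window,
        n_heading_frames=n_heading,
    )


def group_activity(
    replicates: list[list[Trajectory]],
    move_threshold: float = 0.05,
    bin_width: float = 10.0,
    genotype: str = "",
) -> GroupActivitySeries:
    """Replicate-averaged binned count of moving flies.

    ``replicates`` is a list of arenas, each a list of fly trajectories
    sharing fps and duration.  ``move_threshold`` is in mm/frame (default
    0.05 mm/frame ≈ 1.7 mm/s at 33 fps).
    """
    if not replicates or not replicates[0]:
        raise ValueError("need at least one replicate with at least one fly")
    fps = replicates[0][0].fps
    n_frames = replicates[0][0].n_frames
    for rep in replicates:
        for t in rep:
            if t.fps != fps or t.n_frames != n_frames:
                raise ValueError("all trajectories must share fps and duration")
    frames_per_bin = int(round(bin_width * fps))
    if frames_per_bin < 1:
        raise ValueError("bin_width shorter than one frame")
    n_bins = (n_frames - 1) // frames_per_bin
    if n_bins < 1:
        raise ValueError("recording shorter than one bin")

    per_rep = np.empty((len(replicates), n_bins))
    for i, rep in enumerate(replicates):
        steps = np.stack([
            np.hypot(*np.diff(t.positions, axis=0).T) for t in rep
        ])  # (n_flies, n_frames-1)
        active = (steps > move_threshold).sum(axis=0).astype(float)
        trimmed = active[: n_bins * frames_per_bin]
        per_rep[i] = trimmed.reshape(n_bins, frames_per_bin).mean(axis=1)
    return GroupActivitySeries(
        genotype=genotype,
        bin_width=bin_width,
        activity=per_rep.mean(axis=0),
        n_replicates=len(replicates),
        move_threshold=move_threshold,
    )


def one_way_anova(
    groups: dict[str, np.ndarray] | list[np.ndarray],
) -> AnovaResult:
    """One-way fixed-effects ANOVA with Tukey HSD post hoc.

    F is the ratio of between- to within-group mean squares; if the
    within-group variance is exactly zero with unequal means, F is +inf and
    p is 0.  All values identical is degenerate and rejected.
    """
    if isinstance(groups, dict):
        names = list(groups)
        samples = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        samples = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i}" for i in range(len(samples))]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least 2 values")

    k = len(samples)
    n_total = sum(len(s) for s in samples)
    grand = np.concatenate(samples).mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_between, df_within = k - 1, n_total - k

    if ss_within == 0.0:
        if ss_between == 0.0:
            raise ValueError("all values identical: ANOVA is degenerate")
        F, p = math.inf, 0.0
    else:
        F = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(F, df_between, df_within))

    tukey: list[tuple[str, str, float, float]] = []
    if ss_within > 0.0:
        res = stats.tukey_hsd(*samples)
        for i in range(k):
            for j in range(i + 1, k):
                tukey.append((names[i], names[j],
                              float(samples[i].mean() - samples[j].mean()),
                              float(res.pvalue[i, j])))
    else:
        for i in range(k):
            for j in range(i + 1, k):
                diff = float(samples[i].mean() - samples[j].mean())
                tukey.append((names[i], names[j], diff, 0.0 if diff else 1.0))
    return AnovaResult(F=float(F), df_between=df_between, df_within=df_within,
                       p=p, tukey=tukey)
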