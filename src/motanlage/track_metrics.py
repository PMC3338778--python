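"""Per-track and per-group motility statistics.

A :class:`Track` is one cell's time-ordered sequence of 2-D positions sampled
at a uniform interval.  The module computes, per track, the total path length
``T``, the net start-to-end displacement ``D``, the directionality ratio
``D/T``, a moving/paused segmentation with its time budget, mean velocity and
direction-change counts; and per group, mean +/- SEM summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Track",
    "TrackStats",
    "GroupMotilitySummary",
    "MetricSummary",
    "path_length",
    "net_displacement",
    "directionality_ratio",
    "relative_directionality",
    "segment_motion",
    "time_budget",
    "mean_velocity",
    "count_direction_changes",
    "compute_track_stats",
    "summarize_group",
    "DEFAULT_PAUSE_THRESHOLD_UM",
    "DEFAULT_ANGLE_THRESHOLD_DEG",
]

#: Interval displacement below this (um per interval) counts as paused.
DEFAULT_PAUSE_THRESHOLD_UM = 1.0

#: Heading change above this (degrees) counts as a direction change.
DEFAULT_ANGLE_THRESHOLD_DEG = 45.0


@dataclass(frozen=True)
class Track:
    """One cell's time-ordered 2-D positions with uniform sampling interval.

    Parameters
    ----------
    track_id : str
        Identifier of the cell/track.
    positions : (n, 2) ndarray
        Positions in micrometers, one row per frame.
    dt_min : float
        Sampling interval in minutes (must be positive).
    """

    track_id: str
    positions: np.ndarray
    dt_min: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if pos.shape[0] < 1:
            raise ValueError("a track needs at least one point")
        if not self.dt_min > 0:
            raise ValueError(f"dt_min must be positive, got {self.dt_min}")
        object.__setattr__(self, "positions", pos)

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_min(self) -> float:
        """Total observation time, (n_points - 1) * dt_min."""
        return (self.n_points - 1) * self.dt_min

    def step_vectors(self) -> np.ndarray:
        """(n-1, 2) array of consecutive displacement vectors."""
        return np.diff(self.positions, axis=0)

    def step_lengths(self) -> np.ndarray:
        """(n-1,) array of consecutive step lengths in micrometers."""
        return np.linalg.norm(self.step_vectors(), axis=1)


@dataclass(frozen=True)
class TrackStats:
    """Scalar motility statistics of a single track."""

    track_id: str
    T_um: float
    D_um: float
    dt_ratio: float  # nan when T == 0 (undefined)
    velocity_um_min: float
    time_moving_min: float
    time_paused_min: float
    n_dir_changes: int


@dataclass(frozen=True)
class MetricSummary:
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class GroupMotilitySummary:
    group_label: str
    metrics: Mapping[str, MetricSummary]
    n_tracks: int
    n_undefined_dt_excluded: int = 0


def _require_points(track: Track, minimum: int) -> None:
    if track.n_points < minimum:
        raise ValueError(
            f"track {track.track_id!r} has {track.n_points} points; "
            f"at least {minimum} required"
        )


def path_length(track: Track) -> float:
    """Total pathway distance traveled T: sum of consecutive step lengths."""
    _require_points(track, 1)
    if track.n_points == 1:
        return 0.0
    return float(track.step_lengths().sum())


def net_displacement(track: Track) -> float:
    """Net start-to-end distance D."""
    _require_points(track, 1)
    return float(np.linalg.norm(track.positions[-1] - track.positions[0]))


def directionality_ratio(track: Track) -> float:
    """D/T in [0, 1]; NaN (undefined) for a track that never moved (T = 0)."""
    _require_points(track, 2)
    T = path_length(track)
    if T == 0.0:
        return float("nan")
    return net_displacement(track) / T


def relative_directionality(
    groups: Mapping[str, Sequence[float]], control: str
) -> dict[str, float]:
    """Group mean D/T expressed as percent of the control group's mean.

    NaN ratios (tracks with T = 0) are dropped before averaging.  The control
    group itself maps to 100.0 by construction.
    """
    if control not in groups:
        raise KeyError(f"control group {control!r} not present")
    means: dict[str, float] = {}
    for label, ratios in groups.items():
        arr = np.asarray(list(ratios), dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            raise ValueError(f"group {label!r} has no defined ratios")
        means[label] = float(arr.mean())
    if means[control] <= 0:
        raise ValueError("control group mean ratio must be positive")
    return {label: 100.0 * m / means[control] for label, m in means.items()}


def segment_motion(
    track: Track, pause_threshold_um: float = DEFAULT_PAUSE_THRESHOLD_UM
) -> np.ndarray:
    """Label each interval moving (True) or paused (False).

    An interval is moving iff its displacement is >= ``pause_threshold_um``.
    """
    _require_points(track, 2)
    if not pause_threshold_um > 0:
        raise ValueError(
            f"pause_threshold_um must be positive, got {pause_threshold_um}"
        )
    return track.step_lengths() >= pause_threshold_um


def time_budget(labels: np.ndarray, dt_min: float) -> tuple[float, float]:
    """(time_moving, time_paused) in minutes; sums exactly to n_intervals*dt."""
    labels = np.asarray(labels, dtype=bool)
    if labels.size == 0:
        raise ValueError("cannot compute a time budget from zero intervals")
    n_moving = int(labels.sum())
    return n_moving * dt_min, (labels.size - n_moving) * dt_min


def mean_velocity(
    track: Track,
    mode: str = "observation",
    pause_threshold_um: float = DEFAULT_PAUSE_THRESHOLD_UM,
) -> float:
    """Mean velocity in um/min.

    mode="observation" (default): T divided by total observation time.
    mode="moving": T divided by time spent moving; NaN if never moving.
    """
    _require_points(track, 2)
    T = path_length(track)
    if mode == "observation":
        return T / track.duration_min
    if mode == "moving":
        labels = segment_motion(track, pause_threshold_um)
        moving, _ = time_budget(labels, track.dt_min)
        if moving == 0:
            return float("nan")
        return T / moving
    raise ValueError(f"unknown velocity mode {mode!r}")


def count_direction_changes(
    track: Track, angle_threshold_deg: float = DEFAULT_ANGLE_THRESHOLD_DEG
) -> int:
    """Count consecutive step pairs whose heading change exceeds the threshold.

    Only pairs of steps that both have nonzero length contribute (a heading is
    undefined for a zero step).
    """
    _require_points(track, 3)
    vecs = track.step_vectors()
    lengths = np.linalg.norm(vecs, axis=1)
    headings = np.arctan2(vecs[:, 1], vecs[:, 0])
    dtheta = np.diff(headings)
    # wrap to (-pi, pi]
    dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi
    valid = (lengths[:-1] > 0) & (lengths[1:] > 0)
    thresh = np.deg2rad(angle_threshold_deg)
    return int(np.count_nonzero(valid & (np.abs(dtheta) > thresh)))


def compute_track_stats(
    track: Track,
    pause_threshold_um: float = DEFAULT_PAUSE_THRESHOLD_UM,
    velocity_mode: str = "observation",
    angle_threshold_deg: float = DEFAULT_ANGLE_THRESHOLD_DEG,
) -> TrackStats:
    """All scalar statistics of one track in a single pass."""
    _require_points(track, 2)
    labels = segment_motion(track, pause_threshold_um)
    moving, paused = time_budget(labels, track.dt_min)
    n_changes = (
        count_direction_changes(track, angle_threshold_deg)
        if track.n_points >= 3
        else 0
    )
    return TrackStats(
        track_id=track.track_id,
        T_um=path_length(track),
        D_um=net_displacement(track),
        dt_ratio=directionality_ratio(track),
        velocity_um_min=mean_velocity(track, velocity_mode, pause_threshold_um),
        time_moving_min=moving,
        time_paused_min=paused,
        n_dir_changes=n_changes,
    )


_SUMMARY_FIELDS = (
    "T_um",
    "D_um",
    "dt_ratio",
    "velocity_um_min",
    "time_moving_min",
    "time_paused_min",
    "n_dir_changes",
)


def summarize_group(
    tracks: Sequence[Track],
    group_label: str = "group",
    pause_threshold_um: float = DEFAULT_PAUSE_THRESHOLD_UM,
    velocity_mode: str = "observation",
    angle_threshold_deg: float = DEFAULT_ANGLE_THRESHOLD_DEG,
) -> GroupMotilitySummary:
    """Mean and SEM (sd/sqrt(n)) of every metric over a group of tracks.

    Undefined directionality ratios (T = 0) are excluded from the D/T summary
    and their count is reported in ``n_undefined_dt_excluded``.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks to summarize a group")
    stats = [
        compute_track_stats(
            t, pause_threshold_um, velocity_mode, angle_threshold_deg
        )
        for t in tracks
    ]
    metrics: dict[str, MetricSummary] = {}
    n_excluded = 0
    for name in _SUMMARY_FIELDS:
        values = np.array([getattr(s, name) for s in stats], dtype=float)
        if name == "dt_ratio":
            defined = values[~np.isnan(values)]
            n_excluded = values.size - defined.size
            values = defined
        if values.size == 0:
            metrics[name] = MetricSummary(0, float("nan"), float("nan"))
            continue
        mean = float(values.mean())
        sem = (
            float(values.std(ddof=1) / np.sqrt(values.size))
            if values.size > 1
            else float("nan")
        )
        metrics[name] = MetricSummary(int(values.size), mean, sem)
    return GroupMotilitySummary(
        group_label=group_label,
        metrics=metrics,
        n_tracks=len(tracks),
        n_undefined_dt_excluded=n_excluded,
    )
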