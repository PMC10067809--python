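"""CASA velocity metrics from tracked sperm-head coordinates.

Implements the two classic computer-assisted sperm analysis (CASA) speed
measures used for externally fertilizing fish sperm:

* **VCL** (curvilinear velocity): time-averaged speed of the sperm head along
  its actual, point-to-point path.
* **VAP** (average-path velocity): time-averaged speed along a smoothed
  ("average") version of the path, obtained here by a centered moving average
  of the head positions. VAP <= VCL always.

Both are expressed in µm/s. Tracks are planar (x, y) coordinates in µm at a
known frame rate; frame numbers may skip (dropped frames), in which case
elapsed time uses the frame difference divided by the frame rate.

Male-level traits follow the subsampling design of the study this package
models: speeds are measured on several subsamples per male and the male trait
is the unweighted mean of subsample means, not the pooled per-track mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "SubsampleSummary",
    "MaleSpermTraits",
    "DegenerateTrackError",
    "vcl",
    "vap",
    "smooth_path",
    "summarize_subsample",
    "summarize_male",
    "read_trajectories",
]

DEFAULT_VAP_WINDOW = 5
DEFAULT_MIN_POINTS = 30


class DegenerateTrackError(ValueError):
    """Raised for tracks with fewer than two points."""


@dataclass(frozen=True)
class Trajectory:
    """One sperm head's tracked path at fixed frame rate.

    Parameters
    ----------
    track_id : str
        Identifier within a recording.
    frames : ndarray of int
        Strictly increasing frame indices (gaps allowed).
    x, y : ndarray of float
        Head coordinates in µm.
    fps : float
        Recording speed in frames per second (> 0).
    """

    track_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if frames.size < 2:
            raise DegenerateTrackError(
                f"track {self.track_id!r} has {frames.size} point(s); need >= 2"
            )
        if not (frames.size == x.size == y.size):
            raise ValueError("frames, x and y must have equal length")
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"track {self.track_id!r}: frames must be strictly increasing")
        if not self.fps > 0:
            raise ValueError("fps must be > 0")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return int(self.frames.size)

    @property
    def elapsed_s(self) -> float:
        """Elapsed time of the track in seconds (frame span / fps)."""
        return float(self.frames[-1] - self.frames[0]) / self.fps


@dataclass(frozen=True)
class SubsampleSummary:
    mean_vcl: float
    mean_vap: float
    n_tracks: int


@dataclass(frozen=True)
class MaleSpermTraits:
    """Male-level sperm traits: mean-of-subsample-means speeds plus concentration."""

    male_id: str
    ecotype: str  # "LF" or "LP"
    vcl_mean: float
    vap_mean: float
    concentration: float  # sperm / mL
    n_tracks_per_subsample: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.ecotype not in ("LF", "LP"):
            raise ValueError(f"ecotype must be 'LF' or 'LP', got {self.ecotype!r}")
        if self.vap_mean > self.vcl_mean * (1 + 1e-12):
            raise ValueError("vap_mean cannot exceed vcl_mean")
        if not self.concentration > 0:
            raise ValueError("concentration must be > 0")


def _path_length(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.hypot(np.diff(x), np.diff(y)).sum())


def vcl(traj: Trajectory) -> float:
    """Curvilinear velocity in µm/s.

    Sum of Euclidean distances between successive tracked positions divided by
    the elapsed time of the track.
    """
    return _path_length(traj.x, traj.y) / traj.elapsed_s


def smooth_path(x: np.ndarray, y: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average of positions with shrinking windows at the edges.

    Interior points are averaged over ``window`` positions; near the track ends
    the window shrinks symmetrically so no positions are fabricated and the
    smoothed track keeps the original length.
    """
    n = x.size
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if window > n:
        raise ValueError(f"window ({window}) exceeds track length ({n})")
    radius = (window - 1) // 2
    cx = np.concatenate(([0.0], np.cumsum(x)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    i = np.arange(n)
    r = np.minimum(np.minimum(i, n - 1 - i), radius)
    lo, hi = i - r, i + r + 1
    w = (hi - lo).astype(float)
    return (cx[hi] - cx[lo]) / w, (cy[hi] - cy[lo]) / w


def vap(traj: Trajectory, window: int = DEFAULT_VAP_WINDOW) -> float:
    """Average-path velocity in µm/s.

    Path length of the moving-average-smoothed positions divided by the same
    elapsed time as :func:`vcl`. Since each smoothed displacement is a convex
    combination of raw steps, ``vap(t, w) <= vcl(t)`` for every window.
    """
    sx, sy = smooth_path(traj.x, traj.y, window)
    return _path_length(sx, sy) / traj.elapsed_s


def summarize_subsample(
    trajs: Iterable[Trajectory],
    window: int = DEFAULT_VAP_WINDOW,
    min_points: int = DEFAULT_MIN_POINTS,
) -> SubsampleSummary:
    """Unweighted mean VCL and VAP over the tracks of one subsample.

    Tracks shorter than ``min_points`` positions are excluded (short tracks
    carry mostly noise); the count of retained tracks is reported.
    """
    kept = [t for t in trajs if len(t) >= min_points]
    if not kept:
        raise ValueError("no tracks of sufficient length in subsample")
    vcls = np.array([vcl(t) for t in kept])
    vaps = np.array([vap(t, window) for t in kept])
    return SubsampleSummary(float(vcls.mean()), float(vaps.mean()), len(kept))


def summarize_male(
    subsamples: Sequence[SubsampleSummary],
    male_id: str,
    ecotype: str,
    concentration: float,
) -> MaleSpermTraits:
    """Male-level traits as the unweighted mean of subsample means.

    This deliberately differs from pooling all tracks: subsamples with more
    tracks do not get more weight.
    """
    if not subsamples:
        raise ValueError("need at least one subsample summary")
    return MaleSpermTraits(
        male_id=male_id,
        ecotype=ecotype,
        vcl_mean=float(np.mean([s.mean_vcl for s in subsamples])),
        vap_mean=float(np.mean([s.mean_vap for s in subsamples])),
        concentration=concentration,
        n_tracks_per_subsample=tuple(s.n_tracks for s in subsamples),
    )


def read_trajectories(path: str | Path, fps: float = 60.0) -> list[Trajectory]:
    """Read a trajectory CSV (columns track, frame, x_um, y_um) into tracks."""
    df = pd.read_csv(path)
    required = {"track", "frame", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for track_id, g in df.groupby("track", sort=True):
        g = g.sort_values("frame")
        out.append(
            Trajectory(
                track_id=str(track_id),
                frames=g["frame"].to_numpy(),
                x=g["x_um"].to_numpy(float),
                y=g["y_um"].to_numpy(float),
                fps=fps,
            )
        )
    return out
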