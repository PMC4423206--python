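"""Summary statistics of individual movement paths.

Tracked paths (e.g. of swimming ciliates filmed at 25 frames per second)
are reduced to two movement descriptors:

* **velocity** — the mean per-step displacement divided by the frame
  interval (units follow the coordinate units, e.g. um/s);
* **circular s.d. of turning angles** — sqrt(-2 ln R) where R is the mean
  resultant length of the signed heading changes between consecutive
  steps; 0 for straight motion, large for tortuous motion.

Short tracks are unreliable, so a minimum-duration filter (4 s by
default in the analyses here) is applied before summarising.  Summaries
are typically averaged per sample (population level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MovementPath",
    "filter_paths",
    "path_velocity",
    "net_displacement",
    "turning_angles",
    "turning_angle_circular_sd",
    "summarize_paths",
    "read_paths_csv",
]

DEFAULT_FPS = 25.0
_RBAR_FLOOR = 1e-12


@dataclass
class MovementPath:
    """A single track: x/y positions at uniformly spaced frames."""

    x: np.ndarray
    y: np.ndarray
    frame_interval: float = 1.0 / DEFAULT_FPS
    path_id: int | str | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1 or self.x.size < 2:
            raise ValueError("x and y must be equal-length 1-D arrays with >= 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.x.size

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval


def filter_paths(paths, min_duration: float = 4.0):
    """Keep only paths observed for at least ``min_duration`` seconds."""
    if min_duration < 0:
        raise ValueError("min_duration must be >= 0")
    return [p for p in paths if p.duration >= min_duration]


def path_velocity(path: MovementPath) -> float:
    """Mean step speed: mean per-frame displacement over the frame interval."""
    steps = np.hypot(np.diff(path.x), np.diff(path.y))
    return float(steps.mean() / path.frame_interval)


def net_displacement(path: MovementPath) -> float:
    """Straight-line distance between the first and last position."""
    return float(np.hypot(path.x[-1] - path.x[0], path.y[-1] - path.y[0]))


def turning_angles(path: MovementPath) -> np.ndarray:
    """Signed heading changes between consecutive non-zero steps, in
    (-pi, pi].  Zero-length steps have no heading and are skipped."""
    dx, dy = np.diff(path.x), np.diff(path.y)
    nonzero = (dx != 0) | (dy != 0)
    headings = np.arctan2(dy[nonzero], dx[nonzero])
    ang = np.diff(headings)
    return np.mod(ang + np.pi, 2 * np.pi) - np.pi


def turning_angle_circular_sd(path: MovementPath) -> float:
    """Circular standard deviation sqrt(-2 ln R) of the turning angles.

    R is floored at 1e-12, so a uniform angle distribution yields a large
    finite value rather than infinity.  Returns NaN when fewer than two
    turning angles are defined.
    """
    ang = turning_angles(path)
    if ang.size < 2:
        return float("nan")
    rbar = np.abs(np.mean(np.exp(1j * ang)))
    return float(np.sqrt(-2.0 * np.log(max(rbar, _RBAR_FLOOR))))


def summarize_paths(paths, min_duration: float = 4.0) -> pd.DataFrame:
    """Per-path summary table after the duration filter."""
    kept = filter_paths(paths, min_duration)
    rows = [
        {
            "id": p.path_id if p.path_id is not None else i,
            "n_frames": p.n_frames,
            "duration_s": p.duration,
            "velocity": path_velocity(p),
            "circ_sd": turning_angle_circular_sd(p),
            "net_displacement": net_displacement(p),
        }
        for i, p in enumerate(kept)
    ]
    return pd.DataFrame(
        rows,
        columns=["id", "n_frames", "duration_s", "velocity", "circ_sd", "net_displacement"],
    )


def read_paths_csv(path, fps: float = DEFAULT_FPS) -> list[MovementPath]:
    """Read tracks from a CSV with columns id, frame, x, y."""
    df = pd.read_csv(path)
    for col in ("id", "frame", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    out = []
    for pid, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            MovementPath(
                grp["x"].to_numpy(), grp["y"].to_numpy(),
                frame_interval=1.0 / fps, path_id=pid,
            )
        )
    return out


def write_paths_csv(paths, out) -> None:
    """Write tracks to a CSV with columns id, frame, x, y."""
    frames = []
    for i, p in enumerate(paths):
        pid = p.path_id if p.path_id is not None else i
        frames.append(
            pd.DataFrame(
                {"id": pid, "frame": np.arange(p.n_frames), "x": p.x, "y": p.y}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
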