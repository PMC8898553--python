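"""Time-stamped 2-D object trajectories and their CSV representation.

A :class:`Trajectory` is the common currency of the package: the motion
analysis segments it, the stimulus simulators produce it, and the design
builder references sets of them.  Samples are uniformly spaced in time
(the frame grid of a video or simulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "read_trajectories_csv", "write_trajectories_csv"]

_UNIFORM_TOL = 1e-6  # s; allowed deviation of inter-sample spacing


@dataclass
class Trajectory:
    """One object's path: strictly increasing, uniformly spaced samples.

    Parameters
    ----------
    object_id
        Identifier of the object within its scene.
    t
        Sample times in seconds, strictly increasing, uniform spacing
        within 1e-6 s.
    x, y
        Positions in pixels; must be finite.
    frame_rate
        Sampling rate in Hz.  If omitted it is inferred from ``t``.
    """

    object_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.ptp(dt) > _UNIFORM_TOL:
            raise ValueError("sample times must be uniformly spaced")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("positions must be finite")
        if self.frame_rate is None:
            self.frame_rate = 1.0 / float(np.mean(dt))

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Total time span in seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) position array."""
        return np.column_stack([self.x, self.y])


def read_trajectories_csv(path) -> list[Trajectory]:
    """Read trajectories from a scene CSV with columns object_id,frame,t,x,y."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"object_id", "frame", "t", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    out = []
    for oid, grp in df.groupby("object_id", sort=False):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                object_id=str(oid),
                t=grp["t"].to_numpy(),
                x=grp["x"].to_numpy(),
                y=grp["y"].to_numpy(),
            )
        )
    return out


def write_trajectories_csv(trajs: list[Trajectory], path) -> None:
    """Write trajectories in the scene CSV format (one file per scene)."""
    frames = []
    for traj in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "object_id": traj.object_id,
                    "frame": np.arange(len(traj)),
                    "t": traj.t,
                    "x": traj.x,
                    "y": traj.y,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
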