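"""Frame-to-frame linking of foci into trajectories.

Minimum-cost bipartite matching per frame pair (which subsumes greedy
nearest-neighbour linking and resolves ambiguous assignments globally),
with a hard displacement gate and gap closing.  Sign convention:
negative velocity means motion toward the 5' tether (lower column
index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["Trajectory", "link_foci", "trajectory_velocity", "trajectories_to_frame"]

_BIG = 1e9


@dataclass
class Trajectory:
    traj_id: int
    frames: np.ndarray
    positions_px: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("trajectory frames must be strictly increasing")

    def __len__(self) -> int:
        return self.frames.size

    def duration_s(self, frame_interval_s: float) -> float:
        return (self.frames[-1] - self.frames[0]) * frame_interval_s

    def displacement_nt(self, nt_per_px: float) -> float:
        return (self.positions_px[-1] - self.positions_px[0]) * nt_per_px


def link_foci(
    foci_by_frame,
    max_disp_px: float,
    max_gap_frames: int = 1,
) -> list[Trajectory]:
    """Link per-frame focus positions into trajectories.

    Each frame's detections are matched to open tracks by global
    minimum-cost assignment on absolute displacement; links longer than
    ``max_disp_px`` per elapsed frame are rejected.  Tracks may skip up
    to ``max_gap_frames`` frames.  Unlinked detections open new tracks
    (length-1 trajectories are legitimate output).
    """
    tracks: list[dict] = []
    open_tracks: list[dict] = []
    for frame, positions in enumerate(foci_by_frame):
        positions = np.atleast_1d(np.asarray(positions, dtype=float))
        open_tracks = [t for t in open_tracks if frame - t["frames"][-1] <= max_gap_frames + 1]
        if positions.size and open_tracks:
            cost = np.empty((len(open_tracks), positions.size))
            for i, t in enumerate(open_tracks):
                gap = frame - t["frames"][-1]
                d = np.abs(positions - t["positions"][-1])
                cost[i] = np.where(d <= max_disp_px * gap, d, _BIG)
            rows, cols = linear_sum_assignment(cost)
            matched_cols = set()
            for i, j in zip(rows, cols):
                if cost[i, j] < _BIG:
                    open_tracks[i]["frames"].append(frame)
                    open_tracks[i]["positions"].append(float(positions[j]))
                    matched_cols.add(j)
            new = [j for j in range(positions.size) if j not in matched_cols]
        else:
            new = list(range(positions.size))
        for j in new:
            t = {"frames": [frame], "positions": [float(positions[j])]}
            tracks.append(t)
            open_tracks.append(t)
    return [
        Trajectory(i, t["frames"], t["positions"]) for i, t in enumerate(tracks)
    ]


def trajectory_velocity(
    traj: Trajectory, nt_per_px: float, frame_interval_s: float
) -> float:
    """Signed velocity in nt/s from a least-squares position-time fit."""
    if len(traj) < 3:
        raise ValueError("trajectory too short for a velocity fit (need >= 3 points)")
    t = traj.frames * frame_interval_s
    slope = float(np.polyfit(t, traj.positions_px, 1)[0])
    return slope * nt_per_px


def trajectories_to_frame(
    trajectories: list[Trajectory], nt_per_px: float
) -> pd.DataFrame:
    rows = []
    for t in trajectories:
        for f, p in zip(t.frames, t.positions_px):
            rows.append(
                {
                    "traj_id": t.traj_id,
                    "frame": int(f),
                    "position_px": float(p),
                    "position_nt": float(p) * nt_per_px,
                }
            )
    return pd.DataFrame(rows)
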