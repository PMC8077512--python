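"""Translation-site tracking across time-lapse frames.

Sites tethered at the plasma membrane are nearly stationary, so linking is
nearest-neighbour with gap closing rather than a motion model: detections in
consecutive frames are assigned greedily by ascending distance under a
travel cap (default 6 µm), and a track whose site goes undetected stays
alive for up to ``max_gap`` frames (default 5) before it is terminated.
Traces are background-corrected by subtracting the per-frame mean of
equal-volume background spots, sites are linked to their nearest nucleus per
frame, and series are aligned to the onset of a reference nuclear cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import spot_xyz


@dataclass
class TrackingParams:
    max_link_distance: float = 6.0  # µm
    max_gap: int = 5  # frames

    def __post_init__(self) -> None:
        if self.max_link_distance <= 0:
            raise ValueError("max_link_distance must be positive")
        if self.max_gap < 0:
            raise ValueError("max_gap cannot be negative")


def link_tracks(detections: pd.DataFrame, params: TrackingParams | None = None) -> pd.DataFrame:
    """Assign a ``track_id`` to every detection.

    ``detections`` needs columns id, frame, x_um, y_um, z_um (intensity
    passes through).  Output tracks satisfy the linking contract: no
    consecutive displacement above the cap, no gap above ``max_gap``.
    """
    params = params or TrackingParams()
    det = detections.sort_values(["frame", "id"]).reset_index(drop=True)
    track_of = np.full(len(det), -1, dtype=int)
    next_track = 0
    # open track ends: list of [track_id, last_frame, xyz]
    open_pos: list[np.ndarray] = []
    open_meta: list[list] = []  # [track_id, last_frame]

    for frame, group in det.groupby("frame", sort=True):
        idx = group.index.to_numpy()
        pts = spot_xyz(group)
        # retire tracks whose gap budget is exhausted
        alive = [
            k for k, (tid, last) in enumerate(open_meta)
            if frame - last - 1 <= params.max_gap
        ]
        open_pos = [open_pos[k] for k in alive]
        open_meta = [open_meta[k] for k in alive]

        assigned = np.zeros(len(idx), dtype=bool)
        if open_pos and len(idx):
            prev = np.vstack(open_pos)
            dists = np.linalg.norm(prev[:, None, :] - pts[None, :, :], axis=2)
            cand = np.argwhere(dists <= params.max_link_distance)
            order = np.argsort(dists[cand[:, 0], cand[:, 1]], kind="stable")
            used_track = np.zeros(len(open_pos), dtype=bool)
            for t_i, d_i in cand[order]:
                if not used_track[t_i] and not assigned[d_i]:
                    used_track[t_i] = True
                    assigned[d_i] = True
                    track_of[idx[d_i]] = open_meta[t_i][0]
                    open_meta[t_i][1] = frame
                    open_pos[t_i] = pts[d_i]
        for d_i in np.flatnonzero(~assigned):
            track_of[idx[d_i]] = next_track
            open_meta.append([next_track, frame])
            open_pos.append(pts[d_i])
            next_track += 1

    out = det.copy()
    out["track_id"] = track_of
    return out


def validate_tracks(tracks: pd.DataFrame, params: TrackingParams | None = None) -> None:
    """Assert the linking contract on a tracked table; raises on violation."""
    params = params or TrackingParams()
    for tid, g in tracks.groupby("track_id"):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        if np.any(np.diff(frames) < 1):
            raise AssertionError(f"track {tid}: frames not strictly increasing")
        if np.any(np.diff(frames) - 1 > params.max_gap):
            raise AssertionError(f"track {tid}: gap exceeds {params.max_gap} frames")
        xyz = spot_xyz(g)
        step = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        if np.any(step > params.max_link_distance + 1e-9):
            raise AssertionError(f"track {tid}: displacement exceeds the link cap")


def background_correct(trace: pd.DataFrame, background_spots: pd.DataFrame) -> pd.DataFrame:
    """Subtract per-frame mean background intensity from a site trace.

    ``trace`` has columns frame, intensity; ``background_spots`` the same
    (several spots per frame allowed).  Frames without background fall back
    to the nearest background frame and are flagged.
    """
    bg = background_spots.groupby("frame")["intensity"].mean()
    out = trace.copy()
    if not len(bg):
        raise ValueError("no background spots supplied")
    bg_frames = bg.index.to_numpy()
    frames = out["frame"].to_numpy()
    nearest = bg_frames[np.abs(bg_frames[None, :] - frames[:, None]).argmin(axis=1)]
    out["background"] = bg.loc[nearest].to_numpy()
    out["bg_fallback"] = nearest != frames
    out["corrected"] = out["intensity"] - out["background"]
    return out


def link_sites_to_nuclei(tracks: pd.DataFrame, nuclei: pd.DataFrame) -> pd.DataFrame:
    """Attach the nearest-nucleus id per frame (ties to the lowest id)."""
    out = tracks.copy()
    out["nucleus_id"] = -1
    for frame, g in tracks.groupby("frame"):
        nuc = nuclei[nuclei["frame"] == frame]
        if not len(nuc):
            raise ValueError(f"frame {frame} has no nuclei to link against")
        nxyz = spot_xyz(nuc)
        nid = nuc["id"].to_numpy()
        tree = cKDTree(nxyz)
        sxyz = spot_xyz(g)
        dist, idx = tree.query(sxyz)
        assigned = nid[idx]
        balls = tree.query_ball_point(sxyz, dist + 1e-9)
        for row, cand in enumerate(balls):
            if len(cand) > 1:
                d2 = np.linalg.norm(nxyz[cand] - sxyz[row], axis=1)
                near = [c for c, dd in zip(cand, d2) if dd <= dist[row] + 1e-9]
                assigned[row] = nid[near].min()
        out.loc[g.index, "nucleus_id"] = assigned
    return out


def align_to_onset(
    frames: np.ndarray, onset_frame: int, frame_interval_s: float
) -> np.ndarray:
    """Convert frame indices to minutes with t = 0 at the cycle-onset frame."""
    frames = np.asarray(frames)
    if frames.size == 0:
        return np.zeros(0)
    if onset_frame < frames.min() or onset_frame > frames.max():
        raise ValueError("onset frame lies outside the series")
    return (frames - onset_frame) * frame_interval_s / 60.0


def detect_cycle_onset(nuclei_counts: pd.Series) -> int:
    """Change-point helper: frame of the largest relative jump in nuclei count.

    Mitotic cycles roughly double the nuclear count; the onset is the frame
    right after the largest proportional increase.  Intended as a convenience
    for series where the onset is not annotated manually.
    """
    counts = nuclei_counts.sort_index()
    vals = counts.to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least two frames to detect an onset")
    ratio = vals[1:] / np.clip(vals[:-1], 1e-9, None)
    return int(counts.index[int(np.argmax(ratio)) + 1])


def count_sites_over_time(
    detections: pd.DataFrame,
    ap_um: np.ndarray | None = None,
    bin_um: float = 20.0,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Per-frame site counts, and per-frame AP-binned counts when positions
    along the axis are supplied (same row order as ``detections``)."""
    totals = detections.groupby("frame").size()
    if ap_um is None:
        return totals, None
    df = detections.assign(_bin=np.floor(np.asarray(ap_um) / bin_um).astype(int))
    binned = df.groupby(["frame", "_bin"]).size().unstack(fill_value=0)
    binned.columns.name = "ap_bin"
    return totals, binned
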