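"""Embryo AP-axis estimation and nearest-nucleus territory assignment.

Only part of the embryo is imaged and its orientation in the frame varies, so
the anterior-posterior axis must be recovered from the nuclear point cloud
itself.  The procedure mirrors the midline-from-edge-nuclei approach used for
blastoderm embryos:

1. discard nuclei within ``k`` internuclear distances of the frame edge
   (default 1.5), where the internuclear distance is the median xy
   nearest-neighbour spacing;
2. extract the boundary nuclei of the 2D point cloud (alpha-shape) and split
   them into two arcs on opposite sides of the preliminary principal axis,
   excluding the extreme ends and any boundary produced by the frame crop
   rather than the embryo outline;
3. take the midpoints of all cross pairs between the two arcs and fit a
   total-least-squares line through them: the midline;
4. orient the axis by nuclear counts in bins along it — the sparser end
   (the elliptical anterior cap) is the anterior;
5. AP position of any point is its orthogonal projection on the axis,
   measured from the anterior-most nuclear projection, with %EL computed
   against a conventional 500 µm egg length.

All axis work is done in the xy projection: the blastoderm is a surface
monolayer and z carries no AP information.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

from .io import spot_xyz


@dataclass
class EmbryoAxis:
    """Fitted midline: anchor + unit direction (posterior-pointing once oriented)."""

    anchor: np.ndarray  # (3,) µm; z is the mean nuclear z
    direction: np.ndarray  # (3,) unit vector, z-component 0
    anterior_origin: float = 0.0  # axis offset of the anterior-most nucleus
    embryo_length_el: float = 500.0
    oriented: bool = False

    def project(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points[:, :2] - self.anchor[:2]) @ self.direction[:2]


def frame_bounds_of(nuclei: pd.DataFrame, frame_size=None) -> tuple[float, float, float, float]:
    """(xmin, xmax, ymin, ymax) of the acquisition frame; falls back to the
    bounding box of the nuclei when no frame metadata is supplied."""
    if frame_size is not None:
        return (0.0, float(frame_size[0]), 0.0, float(frame_size[1]))
    x = nuclei["x_um"]
    y = nuclei["y_um"]
    return (float(x.min()), float(x.max()), float(y.min()), float(y.max()))


def internuclear_distance(nuclei: pd.DataFrame) -> float:
    """Median nearest-neighbour distance between nucleus centroids (2D xy)."""
    if len(nuclei) < 2:
        raise ValueError("internuclear distance needs at least 2 nuclei")
    xy = nuclei[["x_um", "y_um"]].to_numpy(dtype=float)
    d, _ = cKDTree(xy).query(xy, k=2)
    return float(np.median(d[:, 1]))


def trim_frame_edge_nuclei(
    nuclei: pd.DataFrame,
    frame_bounds: tuple[float, float, float, float],
    k: float = 1.5,
) -> pd.DataFrame:
    """Remove nuclei within ``k`` internuclear distances of any frame edge."""
    d = internuclear_distance(nuclei)
    xmin, xmax, ymin, ymax = frame_bounds
    margin = k * d
    x = nuclei["x_um"].to_numpy(dtype=float)
    y = nuclei["y_um"].to_numpy(dtype=float)
    keep = (
        (x - xmin >= margin) & (xmax - x >= margin) & (y - ymin >= margin) & (ymax - y >= margin)
    )
    if not keep.any():
        raise ValueError("edge trimming removed every nucleus")
    return nuclei[keep].reset_index(drop=True)


def _alpha_shape_boundary(xy: np.ndarray, alpha: float) -> np.ndarray:
    """Indices of boundary points of a 2D cloud via an alpha-complex.

    Keeps Delaunay triangles with circumradius < ``alpha``; boundary points
    are the endpoints of edges used by exactly one kept triangle.
    """
    tri = Delaunay(xy)
    pts = xy[tri.simplices]
    a = np.linalg.norm(pts[:, 0] - pts[:, 1], axis=1)
    b = np.linalg.norm(pts[:, 1] - pts[:, 2], axis=1)
    c = np.linalg.norm(pts[:, 2] - pts[:, 0], axis=1)
    s = (a + b + c) / 2.0
    area = np.sqrt(np.clip(s * (s - a) * (s - b) * (s - c), 1e-12, None))
    circum_r = a * b * c / (4.0 * area)
    kept = tri.simplices[circum_r < alpha]
    if not len(kept):
        raise ValueError("alpha-shape kept no triangles; increase alpha")
    edges: dict[tuple[int, int], int] = {}
    for simplex in kept:
        for i, j in ((0, 1), (1, 2), (2, 0)):
            e = (min(simplex[i], simplex[j]), max(simplex[i], simplex[j]))
            edges[e] = edges.get(e, 0) + 1
    boundary = {v for e, count in edges.items() if count == 1 for v in e}
    return np.array(sorted(boundary), dtype=int)


def find_opposing_edges(
    nuclei: pd.DataFrame,
    frame_bounds: tuple[float, float, float, float] | None = None,
    alpha_factor: float = 2.0,
    end_margin_factor: float = 1.0,
    frame_margin_factor: float = 2.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the cloud's boundary nuclei into two lateral embryo-edge arcs.

    Boundary nuclei are found with an alpha-shape (alpha = ``alpha_factor`` x
    internuclear distance).  Points whose boundary status is an artefact of
    the frame crop (within ``frame_margin_factor`` internuclear distances of
    a frame edge) and points at the extreme ends of the preliminary principal
    axis are assigned to neither side.
    """
    if len(nuclei) < 6:
        raise ValueError("opposing-edge detection needs at least 6 nuclei")
    xy = nuclei[["x_um", "y_um"]].to_numpy(dtype=float)
    d = internuclear_distance(nuclei)
    centred = xy - xy.mean(axis=0)
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise ValueError("degenerate (collinear) nuclear cloud")
    axis_dir = vt[0]
    perp = vt[1]

    boundary_idx = _alpha_shape_boundary(xy, alpha_factor * d)
    bxy = xy[boundary_idx]

    if frame_bounds is not None:
        xmin, xmax, ymin, ymax = frame_bounds
        m = frame_margin_factor * d
        not_frame = (
            (bxy[:, 0] - xmin >= m)
            & (xmax - bxy[:, 0] >= m)
            & (bxy[:, 1] - ymin >= m)
            & (ymax - bxy[:, 1] >= m)
        )
        # only apply the frame filter when it leaves both sides usable
        if not_frame.sum() >= 6:
            boundary_idx = boundary_idx[not_frame]
            bxy = bxy[not_frame]

    proj = (bxy - xy.mean(axis=0)) @ axis_dir
    lo, hi = proj.min(), proj.max()
    inner = (proj > lo + end_margin_factor * d) & (proj < hi - end_margin_factor * d)
    side = (bxy - xy.mean(axis=0)) @ perp
    side_a = boundary_idx[inner & (side > 0)]
    side_b = boundary_idx[inner & (side <= 0)]
    if not len(side_a) or not len(side_b):
        raise ValueError("could not find two opposing embryo edges")
    return nuclei.iloc[side_a].reset_index(drop=True), nuclei.iloc[side_b].reset_index(drop=True)


def fit_midline(side_a: pd.DataFrame, side_b: pd.DataFrame) -> EmbryoAxis:
    """Total-least-squares midline through midpoints of all cross pairs."""
    if not len(side_a) or not len(side_b):
        raise ValueError("both edge sets must be non-empty")
    a = side_a[["x_um", "y_um"]].to_numpy(dtype=float)
    b = side_b[["x_um", "y_um"]].to_numpy(dtype=float)
    mids = (a[:, None, :] + b[None, :, :]).reshape(-1, 2) / 2.0
    anchor_xy = mids.mean(axis=0)
    centred = mids - anchor_xy
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    if len(mids) < 2 or svals[0] < 1e-9:
        raise ValueError("midline direction is ill-defined (single midpoint)")
    direction = vt[0]
    z = float(np.concatenate([side_a["z_um"], side_b["z_um"]]).mean())
    return EmbryoAxis(
        anchor=np.array([anchor_xy[0], anchor_xy[1], z]),
        direction=np.array([direction[0], direction[1], 0.0]),
    )


def orient_anterior(
    axis: EmbryoAxis,
    nuclei: pd.DataFrame,
    bin_width: float = 20.0,
    end_window_bins: int = 3,
) -> EmbryoAxis:
    """Point the axis posterior; the end with fewer nuclei in its end bins is anterior.

    Counts are compared in windows of ``end_window_bins`` x ``bin_width``
    measured inward from each end of the axis.  The window spans several bins
    because the anterior signal — the elliptical cap narrowing — extends over
    tens of µm, whereas a partially-cropped frame corner only depletes the
    outermost sliver; a multi-bin window keeps the crop artefact from
    masquerading as the anterior.  Raises on an exact tie rather than guessing.
    """
    proj = axis.project(nuclei[["x_um", "y_um"]].to_numpy(dtype=float))
    lo, hi = proj.min(), proj.max()
    window = end_window_bins * bin_width
    if hi - lo < 2 * window:
        raise ValueError("axis extent shorter than the two end windows; cannot orient")
    first = int(np.sum(proj <= lo + window))
    last = int(np.sum(proj >= hi - window))
    if first == last:
        raise ValueError(
            "anterior detection tie: end bins hold equal nuclei; orient manually"
        )
    direction = axis.direction if first < last else -axis.direction
    proj_oriented = (nuclei[["x_um", "y_um"]].to_numpy(dtype=float)[:, :2] - axis.anchor[:2]) @ direction[:2]
    return replace(
        axis,
        direction=direction,
        anterior_origin=float(proj_oriented.min()),
        oriented=True,
    )


def ap_position(points: np.ndarray, axis: EmbryoAxis) -> tuple[np.ndarray, np.ndarray]:
    """AP coordinate (µm from the anterior-most nucleus) and %EL of points."""
    if not axis.oriented:
        raise ValueError("axis must be oriented before computing AP positions")
    ap = axis.project(points) - axis.anterior_origin
    return ap, 100.0 * ap / axis.embryo_length_el


def estimate_axis(
    nuclei: pd.DataFrame,
    frame_size=None,
    trim_k: float = 1.5,
    bin_width: float = 20.0,
    embryo_length_el: float = 500.0,
) -> tuple[EmbryoAxis, pd.DataFrame]:
    """Full axis pipeline: trim -> opposing edges -> midline -> orientation.

    Returns the oriented axis and the edge-trimmed nucleus table used to
    anchor AP = 0 at the anterior-most retained nucleus.
    """
    bounds = frame_bounds_of(nuclei, frame_size)
    retained = trim_frame_edge_nuclei(nuclei, bounds, k=trim_k)
    side_a, side_b = find_opposing_edges(retained, frame_bounds=bounds)
    axis = fit_midline(side_a, side_b)
    axis = orient_anterior(axis, retained, bin_width=bin_width)
    axis.embryo_length_el = embryo_length_el
    return axis, retained


def assign_territories(spots: pd.DataFrame, nuclei: pd.DataFrame) -> pd.DataFrame:
    """Map each spot to its nearest nucleus (3D); ties go to the lowest id.

    Returns a copy of ``spots`` with a ``nucleus_id`` column.
    """
    if not len(nuclei):
        raise ValueError("territory assignment needs at least one nucleus")
    nxyz = spot_xyz(nuclei)
    nid = nuclei["id"].to_numpy()
    tree = cKDTree(nxyz)
    sxyz = spot_xyz(spots)
    out = spots.copy()
    if not len(spots):
        out["nucleus_id"] = pd.Series(dtype=nid.dtype)
        return out
    dist, idx = tree.query(sxyz)
    assigned = nid[idx]
    # deterministic tie-break: among equally-near nuclei pick the lowest id
    ties = tree.query_ball_point(sxyz, dist + 1e-9)
    for row, cand in enumerate(ties):
        if len(cand) > 1:
            d2 = np.linalg.norm(nxyz[cand] - sxyz[row], axis=1)
            near = [c for c, dd in zip(cand, d2) if dd <= dist[row] + 1e-9]
            assigned[row] = nid[near].min()
    out["nucleus_id"] = assigned
    return out
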