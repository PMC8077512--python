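"""Cytoplasmic masking, colocalization and translation-efficiency profiles.

An mRNA counts as translated when a nascent-protein punctum lies within the
translation radius (default 0.6 µm, strict inequality) of its centroid;
matching is one-to-one, greedily by ascending distance.  Counts are tallied
per nuclear territory, positioned in µm along the AP axis and %EL, and binned
in 20 µm AP bins for cross-embryo aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import EmbryoAxis, ap_position
from .io import spot_xyz


@dataclass
class ColocParams:
    """Distance thresholds for spot colocalization (µm, strict '<')."""

    translation_radius: float = 0.6
    compaction_radius: float = 0.3

    def __post_init__(self) -> None:
        # zero is legal and matches nothing (strict '<'): a useful degenerate
        if self.translation_radius < 0 or self.compaction_radius < 0:
            raise ValueError("colocalization radii cannot be negative")


def mask_nuclear_spots(spots: pd.DataFrame, nuclei: pd.DataFrame) -> pd.DataFrame:
    """Drop spots inside any nucleus sphere, then deduplicate.

    Duplicate records (identical channel and centroid to 1e-6 µm) collapse to
    one survivor.  Only removes rows — never edits coordinates.
    """
    out = spots
    if len(nuclei) and len(spots):
        nxyz = spot_xyz(nuclei)
        radii = nuclei["radius_um"].to_numpy(dtype=float)
        tree = cKDTree(nxyz)
        sxyz = spot_xyz(spots)
        rmax = float(radii.max())
        inside = np.zeros(len(spots), dtype=bool)
        for row, cand in enumerate(tree.query_ball_point(sxyz, rmax)):
            if cand:
                d = np.linalg.norm(nxyz[cand] - sxyz[row], axis=1)
                inside[row] = bool(np.any(d <= radii[cand]))
        out = spots[~inside]
    if not len(out):
        return out.copy()
    key = out.assign(
        _x=np.round(out["x_um"] / 1e-6).astype(np.int64),
        _y=np.round(out["y_um"] / 1e-6).astype(np.int64),
        _z=np.round(out["z_um"] / 1e-6).astype(np.int64),
    )
    keep = ~key.duplicated(subset=["channel", "_x", "_y", "_z"])
    return out[keep.to_numpy()].reset_index(drop=True)


@dataclass
class PairResult:
    pairs: pd.DataFrame  # columns: id_a, id_b, distance_um
    unmatched_a: np.ndarray
    unmatched_b: np.ndarray


def greedy_pair(
    xyz_a: np.ndarray,
    xyz_b: np.ndarray,
    ids_a: np.ndarray,
    ids_b: np.ndarray,
    radius: float,
) -> PairResult:
    """One-to-one matching: candidates strictly under ``radius``, accepted in
    ascending distance, each point used at most once."""
    pairs_rows = []
    used_a = np.zeros(len(xyz_a), dtype=bool)
    used_b = np.zeros(len(xyz_b), dtype=bool)
    if len(xyz_a) and len(xyz_b):
        tree_b = cKDTree(xyz_b)
        cand = tree_b.query_ball_point(xyz_a, radius)
        ia, ib, dd = [], [], []
        for i, neigh in enumerate(cand):
            if neigh:
                d = np.linalg.norm(xyz_b[neigh] - xyz_a[i], axis=1)
                ok = d < radius  # strict: boundary equality excluded
                ia.extend([i] * int(ok.sum()))
                ib.extend([n for n, o in zip(neigh, ok) if o])
                dd.extend(d[ok])
        if dd:
            ia = np.asarray(ia)
            ib = np.asarray(ib)
            dd = np.asarray(dd)
            # stable ordering: distance, then ids, so ties are deterministic
            order = np.lexsort((ids_b[ib], ids_a[ia], dd))
            for k in order:
                i, j = ia[k], ib[k]
                if not used_a[i] and not used_b[j]:
                    used_a[i] = used_b[j] = True
                    pairs_rows.append((ids_a[i], ids_b[j], dd[k]))
    pairs = pd.DataFrame(pairs_rows, columns=["id_a", "id_b", "distance_um"])
    return PairResult(
        pairs=pairs,
        unmatched_a=np.asarray(ids_a)[~used_a],
        unmatched_b=np.asarray(ids_b)[~used_b],
    )


def pair_spots(
    mrna_spots: pd.DataFrame,
    protein_spots: pd.DataFrame,
    params: ColocParams | None = None,
) -> PairResult:
    """Match mRNA to nascent-protein spots within the translation radius."""
    params = params or ColocParams()
    res = greedy_pair(
        spot_xyz(mrna_spots),
        spot_xyz(protein_spots),
        mrna_spots["id"].to_numpy(),
        protein_spots["id"].to_numpy(),
        params.translation_radius,
    )
    res.pairs = res.pairs.rename(columns={"id_a": "mrna_id", "id_b": "protein_id"})
    return res


def territory_table(
    mrna_assigned: pd.DataFrame,
    pairs: pd.DataFrame,
    nuclei: pd.DataFrame,
    axis: EmbryoAxis,
) -> pd.DataFrame:
    """Per-nucleus counts of total/translated cytoplasmic mRNAs with AP position.

    ``mrna_assigned`` must carry ``nucleus_id`` (see ``assign_territories``).
    Territories with zero mRNAs keep ``pct_translated`` as NaN (flagged, not 0).
    """
    translated_ids = set(pairs["mrna_id"].tolist())
    df = mrna_assigned.assign(_tr=mrna_assigned["id"].isin(translated_ids))
    per = df.groupby("nucleus_id").agg(n_total=("id", "size"), n_translated=("_tr", "sum"))
    out = nuclei[["id"]].rename(columns={"id": "nucleus_id"}).set_index("nucleus_id")
    out = out.join(per).fillna(0).astype(int)
    ap, el = ap_position(spot_xyz(nuclei), axis)
    out["ap_um"] = ap
    out["pct_el"] = el
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pct_translated"] = np.where(
            out["n_total"] > 0, 100.0 * out["n_translated"] / out["n_total"], np.nan
        )
    return out.reset_index()


def binned_profile(territories: pd.DataFrame, bin_um: float = 20.0) -> pd.DataFrame:
    """Mean per-territory quantities in half-open AP bins [0,20), [20,40), ...

    Bin percent-translated is computed from the summed counts (mRNA-weighted),
    matching a per-bin pooled estimate; per-territory means of the counts are
    also reported.
    """
    if bin_um <= 0:
        raise ValueError("bin width must be positive")
    t = territories[territories["ap_um"] >= 0].copy()
    t["bin"] = np.floor(t["ap_um"] / bin_um).astype(int)
    g = t.groupby("bin")
    out = pd.DataFrame(
        {
            "n_territories": g.size(),
            "total_mrna": g["n_total"].sum(),
            "translated_mrna": g["n_translated"].sum(),
            "mean_total": g["n_total"].mean(),
            "mean_translated": g["n_translated"].mean(),
        }
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pct_translated"] = np.where(
            out["total_mrna"] > 0, 100.0 * out["translated_mrna"] / out["total_mrna"], np.nan
        )
    out = out.reset_index()
    out["ap_mid_um"] = (out["bin"] + 0.5) * bin_um
    out["pct_el_mid"] = 100.0 * out["ap_mid_um"] / 500.0
    return out


def aggregate_embryos(profiles: list[pd.DataFrame], column: str = "pct_translated") -> pd.DataFrame:
    """Across-embryo mean ± s.d. of a binned quantity (bins aligned by index)."""
    merged = pd.concat(
        [p.set_index("bin")[column].rename(i) for i, p in enumerate(profiles)], axis=1
    )
    out = pd.DataFrame(
        {
            "mean": merged.mean(axis=1),
            "sd": merged.std(axis=1, ddof=1),
            "n_embryos": merged.notna().sum(axis=1),
        }
    ).reset_index()
    out["ap_mid_um"] = (out["bin"] + 0.5) * 20.0
    return out


def nuclear_concentration(
    nucleus_sum_intensity: float,
    nucleus_area: float,
    bg_sum: float = 0.0,
    bg_area: float = 1.0,
) -> float:
    """Background-corrected mean nuclear intensity per unit area.

    sum/area of the nucleus minus sum/area of cytoplasmic background spots.
    Negative results are legal (over-subtraction) and left to the caller to flag.
    """
    if nucleus_area <= 0 or bg_area <= 0:
        raise ValueError("areas must be strictly positive")
    return nucleus_sum_intensity / nucleus_area - bg_sum / bg_area
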