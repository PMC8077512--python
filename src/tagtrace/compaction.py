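"""mRNA 5'-3' end separation (compaction) for translating vs silent mRNAs.

Two probe sets hybridize to opposite ends of the transcript; an mRNA's
compaction is the 3D distance between its 5' and 3' probe centroids.  Foci
are taken to come from the same molecule when less than 0.3 µm apart
(strict), matched one-to-one greedily by ascending distance; an mRNA is
classified translating when the nearest nascent-protein centroid lies within
0.3 µm of its 5' spot.  Unmatched 3' spots (e.g. probes bound to untagged
endogenous transcripts) are dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .io import spot_xyz
from .quantify import greedy_pair
from .ribosomes import bootstrap_median_ci


def match_probe_pairs(
    five_spots: pd.DataFrame,
    three_spots: pd.DataFrame,
    radius: float = 0.3,
) -> pd.DataFrame:
    """Pair 5' and 3' probe spots within ``radius`` (µm, strict, 3D, one-to-one).

    The 5' channel is the reference: translating classification is defined on
    the 5' spot. Returns columns five_id, three_id, distance_um.
    """
    res = greedy_pair(
        spot_xyz(five_spots),
        spot_xyz(three_spots),
        five_spots["id"].to_numpy(),
        three_spots["id"].to_numpy(),
        radius,
    )
    return res.pairs.rename(columns={"id_a": "five_id", "id_b": "three_id"})


def classify_translating(
    pairs: pd.DataFrame,
    five_spots: pd.DataFrame,
    protein_spots: pd.DataFrame,
    radius: float = 0.3,
) -> pd.DataFrame:
    """Flag each pair translating iff a protein centroid is < radius from its 5' spot."""
    out = pairs.copy()
    if not len(pairs):
        out["translating"] = pd.Series(dtype=bool)
        return out
    five = five_spots.set_index("id")
    pxyz = five.loc[out["five_id"], ["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if len(protein_spots):
        d, _ = cKDTree(spot_xyz(protein_spots)).query(pxyz)
        out["translating"] = d < radius
    else:
        out["translating"] = False
    return out


def compaction_summary(per_embryo_pairs: dict, seed: int = 0) -> dict:
    """Per-embryo medians for translating/non-translating mRNAs + paired t-test.

    ``per_embryo_pairs`` maps embryo id -> classified pair table.  Embryos
    missing one class are excluded (with a warning entry in the report).  The
    paired two-sided t-test runs across embryo-level medians.
    """
    rows = []
    excluded = []
    for embryo, pairs in per_embryo_pairs.items():
        tr = pairs.loc[pairs["translating"], "distance_um"].to_numpy(dtype=float)
        nt = pairs.loc[~pairs["translating"], "distance_um"].to_numpy(dtype=float)
        if not len(tr) or not len(nt):
            excluded.append(embryo)
            continue
        rows.append(
            {
                "embryo": embryo,
                "median_translating": float(np.median(tr)),
                "median_nontranslating": float(np.median(nt)),
                "n_translating": len(tr),
                "n_nontranslating": len(nt),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise ValueError("paired comparison needs >= 2 embryos with both classes")
    diffs = (table["median_translating"] - table["median_nontranslating"]).to_numpy()
    if np.allclose(diffs, 0.0):
        t_stat, p_value = 0.0, 1.0  # identical classes: no paired evidence
    else:
        t_stat, p_value = stats.ttest_rel(
            table["median_translating"], table["median_nontranslating"]
        )
    all_tr = np.concatenate(
        [
            per_embryo_pairs[e].loc[per_embryo_pairs[e]["translating"], "distance_um"].to_numpy()
            for e in table["embryo"]
        ]
    )
    all_nt = np.concatenate(
        [
            per_embryo_pairs[e].loc[~per_embryo_pairs[e]["translating"], "distance_um"].to_numpy()
            for e in table["embryo"]
        ]
    )
    med_tr = bootstrap_median_ci(all_tr, seed=seed)
    med_nt = bootstrap_median_ci(all_nt, seed=seed + 1)
    return {
        "per_embryo": table,
        "excluded_embryos": excluded,
        "paired_t": float(t_stat),
        "paired_p": float(p_value),
        "pooled_median_translating": {"median": med_tr[0], "ci_low": med_tr[1], "ci_high": med_tr[2]},
        "pooled_median_nontranslating": {"median": med_nt[0], "ci_low": med_nt[1], "ci_high": med_nt[2]},
    }
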