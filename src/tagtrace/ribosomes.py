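"""Ribosome-number estimation from translation-site intensities.

A translation site's summed fluorescence is the product of the number of
ribosomes on the mRNA, the brightness of one completed nascent-chain
reporter, and a correction for ribosomes that have synthesized only part of
the epitope array.  With the epitope cassette (length ``L_sun`` nt) at the 5'
end of a downstream CDS (``L_hb`` nt), a ribosome carries on average half the
epitopes while inside the cassette and all of them after, so the expected
per-ribosome signal fraction is

    c = (0.5 * L_sun + L_hb) / (L_sun + L_hb),

bounded in [0.5, 1].  The single-protein unit brightness is the median
intensity of the non-colocalized protein-spot pool (per embryo, as imaging
gain varies between acquisitions), after excluding rare bright aggregates.
Estimated counts at or below ``min_confident`` (default 5) are flagged
low-confidence and excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def correction_factor(length_suntag_nt: float, length_hb_nt: float) -> float:
    """Partial-epitope correction c = (0.5*L_sun + L_hb)/(L_sun + L_hb)."""
    if length_suntag_nt < 0 or length_hb_nt < 0:
        raise ValueError("segment lengths cannot be negative")
    total = length_suntag_nt + length_hb_nt
    if total <= 0:
        raise ValueError("total transcript length must be positive")
    return (0.5 * length_suntag_nt + length_hb_nt) / total


@dataclass
class RibosomeModel:
    """Calibrated intensity-to-ribosome conversion."""

    i_single: float  # median single-protein intensity
    length_suntag_nt: float
    length_hb_nt: float
    min_confident: int = 5

    def __post_init__(self) -> None:
        if self.i_single <= 0:
            raise ValueError("single-protein intensity must be positive")
        self.c = correction_factor(self.length_suntag_nt, self.length_hb_nt)


def classify_protein_spots(
    protein_spots: pd.DataFrame,
    matched_protein_ids,
    aggregate_factor: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split the protein channel into translation sites and single proteins.

    Spots matched to an mRNA are translation sites.  Unmatched spots form the
    single-protein calibration pool after one pass of aggregate exclusion:
    spots brighter than ``aggregate_factor`` x the pool median are dropped
    and the median recomputed once.

    Returns (sites, singles, aggregates).
    """
    if not len(protein_spots):
        raise ValueError("protein channel is empty")
    matched = protein_spots["id"].isin(set(np.asarray(matched_protein_ids).tolist()))
    sites = protein_spots[matched].reset_index(drop=True)
    pool = protein_spots[~matched].reset_index(drop=True)
    if not len(pool):
        raise ValueError(
            "no unmatched protein spots: single-protein calibration impossible"
        )
    med0 = float(pool["intensity"].median())
    agg = pool["intensity"] > aggregate_factor * med0
    singles = pool[~agg].reset_index(drop=True)
    aggregates = pool[agg].reset_index(drop=True)
    return sites, singles, aggregates


def calibrate(
    singles: pd.DataFrame,
    length_suntag_nt: float,
    length_hb_nt: float,
    min_confident: int = 5,
) -> RibosomeModel:
    """Build a RibosomeModel from the single-protein pool of one embryo."""
    if not len(singles):
        raise ValueError("empty single-protein pool")
    return RibosomeModel(
        i_single=float(singles["intensity"].median()),
        length_suntag_nt=length_suntag_nt,
        length_hb_nt=length_hb_nt,
        min_confident=min_confident,
    )


def ribosome_count(site_intensity, model: RibosomeModel) -> pd.DataFrame:
    """Estimate ribosomes per site: n = intensity / (I_single * c).

    Returns the continuous estimate, a rounded count, and a ``confident``
    flag (strictly greater than ``min_confident``); summaries should use the
    continuous value on confident sites.
    """
    intensity = np.atleast_1d(np.asarray(site_intensity, dtype=float))
    n_hat = intensity / (model.i_single * model.c)
    return pd.DataFrame(
        {
            "intensity": intensity,
            "n_ribosomes": n_hat,
            "n_rounded": np.rint(n_hat).astype(int),
            "confident": n_hat > model.min_confident,
        }
    )


def interribosomal_distance(n_ribosomes, transcript_length_nt: float):
    """Average spacing between ribosomes: transcript length / count (nt)."""
    n = np.asarray(n_ribosomes, dtype=float)
    if np.any(n < 1):
        raise ValueError("inter-ribosomal distance needs at least one ribosome")
    if transcript_length_nt <= 0:
        raise ValueError("transcript length must be positive")
    out = transcript_length_nt / n
    return float(out) if out.ndim == 0 else out


def bootstrap_median_ci(
    values, n_boot: int = 10000, alpha: float = 0.05, seed: int = 0
) -> tuple[float, float, float]:
    """Median with percentile bootstrap CI (seeded, 10k resamples)."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    meds = np.median(values[idx], axis=1)
    return (
        float(np.median(values)),
        float(np.quantile(meds, alpha / 2)),
        float(np.quantile(meds, 1 - alpha / 2)),
    )


def compare_regions(groups: dict[str, np.ndarray], seed: int = 0) -> dict:
    """One-way ANOVA with Tukey HSD across groups of ribosome counts.

    Also reports each group's median with a seeded bootstrap 95% CI, matching
    how site-level distributions are usually summarized.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    f_stat, p_value = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(tukey.pvalue[i, j]),
                }
            )
    medians = {}
    for k, (name, vals) in enumerate(zip(names, arrays)):
        med, lo, hi = bootstrap_median_ci(vals, seed=seed + k)
        medians[name] = {"median": med, "ci_low": lo, "ci_high": hi}
    return {
        "anova_F": float(f_stat),
        "anova_p": float(p_value),
        "tukey": pairwise,
        "medians": medians,
    }
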