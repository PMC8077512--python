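"""Delimited-text table formats shared by every pipeline stage.

Spot tables hold one detected (or simulated) fluorescent punctum per row:
``id, channel, x_um, y_um, z_um, intensity, frame``.  Nucleus tables hold one
nucleus per row: ``id, x_um, y_um, z_um, radius_um, frame``.  All coordinates
are in micrometres, with the frame origin at a corner of the imaged volume.
Tables are written as tab-separated text so that every intermediate of a run
can be inspected or re-imported without binary readers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

SPOT_COLUMNS = ["id", "channel", "x_um", "y_um", "z_um", "intensity", "frame"]
NUCLEUS_COLUMNS = ["id", "x_um", "y_um", "z_um", "radius_um", "frame"]


def _validated(df: pd.DataFrame, columns: list[str], what: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns {missing}")
    return df.loc[:, columns].copy()


def make_spot_table(
    positions: np.ndarray,
    intensity: np.ndarray,
    channel: str,
    ids: np.ndarray | None = None,
    frame: np.ndarray | int = 0,
) -> pd.DataFrame:
    """Assemble a spot table from an (n, 3) array of xyz positions in µm."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    if positions.shape != (n, 3):
        raise ValueError("positions must be an (n, 3) array")
    if ids is None:
        ids = np.arange(n)
    return pd.DataFrame(
        {
            "id": np.asarray(ids),
            "channel": channel,
            "x_um": positions[:, 0],
            "y_um": positions[:, 1],
            "z_um": positions[:, 2],
            "intensity": np.broadcast_to(np.asarray(intensity, dtype=float), (n,)).copy(),
            "frame": np.broadcast_to(np.asarray(frame), (n,)).copy(),
        }
    )


def spot_xyz(spots: pd.DataFrame) -> np.ndarray:
    """Return the (n, 3) coordinate array of a spot or nucleus table."""
    return spots[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)


def write_spots(spots: pd.DataFrame, path: str | Path) -> None:
    _validated(spots, SPOT_COLUMNS, "spot").to_csv(path, sep="\t", index=False)


def read_spots(path: str | Path) -> pd.DataFrame:
    return _validated(pd.read_csv(path, sep="\t"), SPOT_COLUMNS, "spot")


def write_nuclei(nuclei: pd.DataFrame, path: str | Path) -> None:
    _validated(nuclei, NUCLEUS_COLUMNS, "nucleus").to_csv(path, sep="\t", index=False)


def read_nuclei(path: str | Path) -> pd.DataFrame:
    return _validated(pd.read_csv(path, sep="\t"), NUCLEUS_COLUMNS, "nucleus")
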