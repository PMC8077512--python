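import numpy as np
import pandas as pd
import pytest

from tagtrace.config import ConstantProfile, EmbryoConfig
from tagtrace import simulate


@pytest.fixture(scope="session")
def small_embryo():
    """One deterministic mid-size nc12 embryo shared by read-only tests."""
    cfg = EmbryoConfig(rng_seed=11, orientation_deg=6.0, midline_offset_um=4.0)
    return simulate.generate_embryo(cfg)


@pytest.fixture()
def nucleus_table():
    def make(xyz, radius=3.0, ids=None):
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return pd.DataFrame(
            {
                "id": np.arange(len(xyz)) if ids is None else np.asarray(ids),
                "x_um": xyz[:, 0],
                "y_um": xyz[:, 1],
                "z_um": xyz[:, 2],
                "radius_um": radius,
                "frame": 0,
            }
        )

    return make


@pytest.fixture()
def spot_table():
    from tagtrace.io import make_spot_table

    def make(xyz, intensity=100.0, channel="mrna", ids=None):
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        return make_spot_table(xyz, intensity, channel, ids=ids)

    return make
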