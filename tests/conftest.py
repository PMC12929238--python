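import numpy as np
import pandas as pd
import pytest

import vwplat as v


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_gaze():
    """Hand-written 2-participant gaze table covering both groups."""
    rows = []
    for g, p in (("baseline", "p1"), ("shifted", "p2")):
        for t in (250.0, 300.0, 350.0, 400.0):
            rows.append((p, g, "c1", "t1", t, "target"))
    return pd.DataFrame(
        rows, columns=["participant", "group", "condition", "trial", "time_ms", "aoi"]
    )


@pytest.fixture
def default_binning():
    return v.BinningConfig()  # 0-2000 ms window, 50 ms bins, 200 ms offset


def make_counts(binning, s_base, n_base, s_shift, n_shift):
    """Build a BinnedCounts container directly from group-level count vectors.

    Each group gets a single pseudo-participant holding the pooled counts,
    which is all the pooled per-bin tests look at.
    """
    from vwplat.data_model import BinnedCounts, GroupCounts

    def grp(name, s, n):
        return GroupCounts(
            participants=np.asarray([f"{name}_p0"], dtype=object),
            conditions=np.asarray(["c1"], dtype=object),
            S=np.asarray([s], dtype=float),
            N=np.asarray([n], dtype=float),
        )

    return BinnedCounts(
        binning=binning,
        groups={"baseline": grp("b", s_base, n_base), "shifted": grp("s", s_shift, n_shift)},
    )
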