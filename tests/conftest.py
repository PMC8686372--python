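"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ctg_interpret.ctg_data import CTG_FEATURES, CTGDataset


def make_dataset(n: int | None = None, **columns) -> CTGDataset:
    """Build a valid CTGDataset; unspecified features default to zero.

    The zero default satisfies every record invariant (Width = Max - Min,
    Mode/Median inside [Min, Max], Tendency in {-1, 0, 1}, NSP = 1).
    """
    if n is None:
        lengths = {len(np.atleast_1d(v)) for v in columns.values()}
        if len(lengths) != 1:
            raise ValueError("give n or equal-length columns")
        n = lengths.pop()
    data = {f: np.zeros(n, float) for f in CTG_FEATURES}
    data["NSP"] = np.ones(n, int)
    for name, vals in columns.items():
        data[name] = np.broadcast_to(np.atleast_1d(vals), (n,)).copy()
    return CTGDataset(pd.DataFrame(data))


def random_dataset(rng: np.random.Generator, n: int,
                   features: list[str], levels: int = 10) -> CTGDataset:
    """Random integer-valued dataset (ties guaranteed) over given features."""
    cols = {f: rng.integers(0, levels, size=n).astype(float) for f in features}
    nsp = rng.integers(1, 4, size=n)
    return make_dataset(n, NSP=nsp, **cols)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Ten records, two informative features, all three classes."""
    return make_dataset(
        ASTV=[10, 20, 30, 40, 50, 60, 70, 80, 90, 95],
        MSTV=[3.0, 2.5, 2.0, 1.8, 1.5, 1.0, 0.8, 0.6, 0.5, 0.4],
        NSP=[1, 1, 1, 1, 1, 2, 2, 3, 3, 3],
    )
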