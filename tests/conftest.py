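import numpy as np
import pytest

import dnabubbles as db


@pytest.fixture(scope="session")
def base_mech():
    return db.default_base_mechanics()


@pytest.fixture(scope="session")
def toy_duplex():
    """24-bp synthetic duplex with the three-region composition layout."""
    spec = db.SyntheticSpec(
        n=24, at_fractions={"I": 0.551, "II": 0.530, "III": 0.709}, seed=7
    )
    duplex, partition = db.generate_sequence(spec)
    return duplex, partition


@pytest.fixture(scope="session")
def packaged():
    return db.load_packaged_tables()


def brute_force_runs(mask):
    """Independent left-to-right scan for maximal broken runs."""
    runs = []
    start = None
    for i, broken in enumerate(list(mask) + [False]):
        if broken and start is None:
            start = i
        elif not broken and start is not None:
            runs.append((start + 1, i - start))
            start = None
    return runs


def brute_force_group_fractions(mask):
    """Independent occupancy computation from the brute-force runs."""
    bounds = {"OS": (1, 1), "group1": (2, 4), "group2": (5, 10),
              "group3": (11, 30), "group4": (31, 10**9)}
    n = len(mask)
    out = dict.fromkeys(bounds, 0.0)
    for _, length in brute_force_runs(mask):
        for g, (lo, hi) in bounds.items():
            if lo <= length <= hi:
                out[g] += length / n
    return out
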