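"""Synthetic inputs: random duplexes with controlled composition and
prescribed bond-state trajectories.

These generators define the test conditions for every stage that does not
need the physical integrator: sequences mimic the three-region layout of a
real gene (per-region A–T fractions), and mask series provide trajectories
with known run-length statistics.  Everything is a pure function of its
arguments; randomized generation requires an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .duplex import DEFAULT_REGIONS, GeneDuplex, RegionPartition
from .dynamics import BondTrajectory

__all__ = ["SyntheticSpec", "generate_sequence", "generate_mask_series"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Sequence recipe: length, per-region A–T target fractions, seed."""

    n: int
    at_fractions: dict[str, float]
    seed: int
    partition: RegionPartition | None = None  # defaults to the I/II/III layout

    def __post_init__(self) -> None:
        for name, f in self.at_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"A–T fraction for region {name!r} outside [0, 1]: {f}")


def _partition_for(spec: SyntheticSpec) -> RegionPartition:
    if spec.partition is not None:
        if spec.partition.n != spec.n:
            raise ValueError("partition does not cover n")
        return spec.partition
    if spec.n == DEFAULT_REGIONS.n:
        return DEFAULT_REGIONS
    # Scale the default three-region layout proportionally to n.
    b1 = max(1, round(spec.n * 49 / 980))
    b2 = max(b1 + 1, round(spec.n * 619 / 980))
    if b2 >= spec.n:
        b2 = spec.n - 1
    return RegionPartition.from_bounds(
        [("I", 1, b1), ("II", b1 + 1, b2), ("III", b2 + 1, spec.n)]
    )


def generate_sequence(spec: SyntheticSpec) -> tuple[GeneDuplex, RegionPartition]:
    """Random duplex whose per-region A–T fraction hits the target within
    one pair of quantization.  Reproducible given the seed."""
    partition = _partition_for(spec)
    missing = set(partition.names) - set(spec.at_fractions)
    if missing:
        raise ValueError(f"no A–T fraction given for regions {sorted(missing)}")
    rng = np.random.default_rng(spec.seed)
    letters = []
    for region in partition.regions:
        size = region.size
        n_at = int(round(spec.at_fractions[region.name] * size))
        kinds = np.array(["W"] * n_at + ["S"] * (size - n_at))
        rng.shuffle(kinds)
        for k in kinds:
            if k == "W":
                letters.append(rng.choice(["A", "T"]))
            else:
                letters.append(rng.choice(["G", "C"]))
    return GeneDuplex("".join(letters)), partition


def generate_mask_series(
    n: int,
    m: int,
    law: str = "random",
    p: float = 0.5,
    seed: int | None = None,
    tau: float = 1.0,
) -> BondTrajectory:
    """Prescribed broken-mask trajectories for exercising bubble statistics.

    Laws: ``intact`` (never broken), ``broken`` (always), ``alternating``
    (odd positions broken on odd samples, even on even), ``random``
    (i.i.d. Bernoulli(p) per position and sample; seed required).
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    times = tau * np.arange(1, m + 1)
    if law == "intact":
        broken = np.zeros((m, n), dtype=bool)
    elif law == "broken":
        broken = np.ones((m, n), dtype=bool)
    elif law == "alternating":
        pos = np.arange(n)
        broken = np.stack([(pos + j) % 2 == 0 for j in range(m)])
    elif law == "random":
        if seed is None:
            raise ValueError("random law requires a seed")
        if not 0.0 <= p <= 1.0:
            raise ValueError("p outside [0, 1]")
        rng = np.random.default_rng(seed)
        broken = rng.random((m, n)) < p
    else:
        raise ValueError(f"unknown mask law {law!r}")
    return BondTrajectory(times=times, broken=broken)
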