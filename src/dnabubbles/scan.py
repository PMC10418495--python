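"""Single-substitution scanning across a critical-energy grid.

For every grid energy Ecr, one baseline simulation (all-protium, position
key 0) and one simulation per substitution position are run; each yields
the bubble occurrence probability P for every size group.  The substituted
pair uses k12_D = kD * k12_H and Ecr_D = kD * Ecr_H; every other pair keeps
the protium values.  The sweep applies a single Ecr to all pairs at each
grid point.

Energies are carried as exact decimal strings (e.g. "0.250", in units of
1e-22 N·m) in all tables and files to avoid float-key drift; SI values are
used only inside the dynamics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bubbles import GROUP_ORDER, occupancy_probabilities
from .duplex import GeneDuplex
from .dynamics import ForcingSpec, IntegrationSpec, ModelOptions, simulate
from .mechanics import BaseMechanics, IsotopeSpec, build_pair_mechanics

__all__ = ["EnergyGrid", "BubbleProfile", "baseline_profile", "scan_positions", "extrema"]

PROFILE_COLUMNS = ["energy", "group", "position", "P"]


@dataclass(frozen=True)
class EnergyGrid:
    """Ordered critical energies, quoted in units of ``scale`` N·m.

    The default grid is 0.250 to 0.600 in steps of 0.050 (×1e-22 N·m).
    """

    values: tuple[float, ...] = (0.250, 0.300, 0.350, 0.400, 0.450, 0.500, 0.550, 0.600)
    scale: float = 1.0e-22

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError("energy grid is empty")
        if np.any(np.diff(v) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("energies must be positive")

    @property
    def keys(self) -> list[str]:
        """Exact-decimal labels, e.g. '0.250'."""
        return [f"{v:.3f}" for v in self.values]

    def si(self, key_or_value: str | float) -> float:
        return float(key_or_value) * self.scale

    @classmethod
    def from_spec(cls, spec: str, scale: float = 1.0e-22) -> "EnergyGrid":
        """Parse 'start:stop:step' (inclusive) or a comma list of values."""
        if ":" in spec:
            start, stop, step = (float(x) for x in spec.split(":"))
            k = int(round((stop - start) / step))
            vals = tuple(round(start + i * step, 6) for i in range(k + 1))
        else:
            vals = tuple(float(x) for x in spec.split(","))
        return cls(values=vals, scale=scale)


@dataclass
class BubbleProfile:
    """Long-format table of P values: columns energy, group, position, P.

    ``position == 0`` marks the all-protium baseline P0; positions 1..n are
    single-substitution runs.  ``n`` is the duplex length.
    """

    table: pd.DataFrame
    n: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(PROFILE_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"profile table missing columns {sorted(missing)}")

    @property
    def energies(self) -> list[str]:
        return sorted(self.table["energy"].unique())

    def _select(self, energy: str, group: str) -> pd.DataFrame:
        sel = self.table[(self.table["energy"] == energy) & (self.table["group"] == group)]
        if sel.empty:
            raise KeyError(f"no profile rows for energy {energy!r}, group {group!r}")
        return sel

    def p0(self, energy: str, group: str) -> float:
        sel = self._select(energy, group)
        base = sel[sel["position"] == 0]
        if base.empty:
            raise KeyError(f"no baseline row for energy {energy!r}, group {group!r}")
        return float(base["P"].iloc[0])

    def pi_vector(self, energy: str, group: str) -> np.ndarray:
        """P_i for positions 1..n as an array (index i-1 = position i)."""
        sel = self._select(energy, group)
        sub = sel[sel["position"] > 0].sort_values("position")
        if len(sub) != self.n:
            raise KeyError(
                f"profile incomplete for energy {energy!r}, group {group!r}: "
                f"{len(sub)} of {self.n} positions"
            )
        return sub["P"].to_numpy(dtype=float)

    def is_complete(self, grid_keys: list[str] | None = None) -> bool:
        keys = grid_keys or self.energies
        try:
            for e in keys:
                for g in GROUP_ORDER:
                    self.p0(e, g)
                    self.pi_vector(e, g)
        except KeyError:
            return False
        return True


def _profile_rows(energy_key: str, position: int, probs: dict[str, float]) -> list[dict]:
    return [
        {"energy": energy_key, "group": g, "position": position, "P": probs[g]}
        for g in GROUP_ORDER
    ]


def _run_once(
    duplex: GeneDuplex,
    base_mech: BaseMechanics,
    forcing: ForcingSpec,
    integ: IntegrationSpec,
    options: ModelOptions,
    iso: IsotopeSpec | None,
) -> dict[str, float]:
    mech = build_pair_mechanics(duplex, base_mech, iso)
    traj = simulate(mech, forcing, integ, options)
    return occupancy_probabilities(traj)


def baseline_profile(
    duplex: GeneDuplex,
    base_mech: BaseMechanics,
    forcing: ForcingSpec,
    integ: IntegrationSpec,
    grid: EnergyGrid,
    options: ModelOptions = ModelOptions(),
) -> pd.DataFrame:
    """All-protium P0 per (energy, group): one simulation per grid energy."""
    rows: list[dict] = []
    for key in grid.keys:
        bm = base_mech.with_uniform_ecr(grid.si(key))
        probs = _run_once(duplex, bm, forcing, integ, options, None)
        rows.extend(_profile_rows(key, 0, probs))
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def scan_positions(
    duplex: GeneDuplex,
    base_mech: BaseMechanics,
    forcing: ForcingSpec,
    integ: IntegrationSpec,
    grid: EnergyGrid,
    kD: float = 1.05,
    options: ModelOptions = ModelOptions(),
    checkpoint: str | os.PathLike | None = None,
    progress: bool = False,
) -> BubbleProfile:
    """Baseline plus one substitution run per (energy, position).

    With *checkpoint* set, completed (energy, position) rows are appended to
    a TSV as they finish and a rerun resumes from it; the final table is
    identical to an uninterrupted scan.  The computation is deterministic.
    """
    if not kD > 0:
        raise ValueError("kD must be strictly positive")
    done: set[tuple[str, int]] = set()
    rows: list[dict] = []
    if checkpoint is not None and os.path.exists(checkpoint):
        prev = pd.read_csv(checkpoint, sep="\t", dtype={"energy": str})
        missing = set(PROFILE_COLUMNS) - set(prev.columns)
        if missing:
            raise ValueError(f"corrupt checkpoint {checkpoint}: missing {sorted(missing)}")
        rows = prev.to_dict("records")
        done = set(zip(prev["energy"], prev["position"].astype(int)))

    def emit(key: str, position: int, probs: dict[str, float]) -> None:
        new = _profile_rows(key, position, probs)
        rows.extend(new)
        if checkpoint is not None:
            header = not os.path.exists(checkpoint)
            pd.DataFrame(new, columns=PROFILE_COLUMNS).to_csv(
                checkpoint, sep="\t", index=False, mode="a", header=header
            )

    for key in grid.keys:
        bm = base_mech.with_uniform_ecr(grid.si(key))
        if (key, 0) not in done:
            emit(key, 0, _run_once(duplex, bm, forcing, integ, options, None))
        for i in range(1, duplex.n + 1):
            if (key, i) in done:
                continue
            if progress:  # pragma: no cover - console feedback only
                print(f"energy {key} position {i}/{duplex.n}", flush=True)
            emit(key, i, _run_once(duplex, bm, forcing, integ, options, IsotopeSpec(i, kD)))

    table = (
        pd.DataFrame(rows, columns=PROFILE_COLUMNS)
        .drop_duplicates(subset=["energy", "group", "position"])
        .sort_values(["energy", "group", "position"])
        .reset_index(drop=True)
    )
    return BubbleProfile(table=table, n=duplex.n, meta={"kD": kD, "grid": grid.keys})


def extrema(
    profile: BubbleProfile, energy: str, group: str
) -> tuple[float, float, set[int], set[int]]:
    """(Pimax, Pimin, argmax positions, argmin positions) with ties preserved."""
    pi = profile.pi_vector(energy, group)
    pmax = float(pi.max())
    pmin = float(pi.min())
    argmax = {int(i) + 1 for i in np.flatnonzero(pi == pmax)}
    argmin = {int(i) + 1 for i in np.flatnonzero(pi == pmin)}
    return pmax, pmin, argmax, argmin
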