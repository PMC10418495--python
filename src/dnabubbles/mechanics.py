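"""Mechanical parameters of the torsional pendulum-chain duplex model.

Each nitrogen base is a rigid pendulum of rotational inertia ``I`` hanging
off its sugar–phosphate backbone at distance ``R``; neighbouring bases on a
chain are coupled through the backbone torsional constant ``K``; the two
bases of a pair interact through an elastic hydrogen-bond constant ``k12``
whose potential energy, measured against the closed (equilibrium) pair, is
compared with a critical energy ``Ecr`` to decide bond breaking.  Replacing
one protium by deuterium at a single pair stiffens that bond: both ``k12``
and ``Ecr`` at the substituted pair are multiplied by ``kD`` (default 1.05,
a 5% stronger bond); inertia and dissipation are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .duplex import GeneDuplex

__all__ = [
    "BaseMechanics",
    "IsotopeSpec",
    "PairMechanics",
    "default_base_mechanics",
    "base_mechanics_from_dict",
    "build_pair_mechanics",
]

_LETTERS = ("A", "T", "G", "C")
_KINDS = ("AT", "GC")


def _check_letter_map(
    name: str, m: Mapping[str, float], allow_zero: bool = False
) -> dict[str, float]:
    out = {}
    for letter in _LETTERS:
        if letter not in m:
            raise ValueError(f"mechanics table missing {name} entry for base {letter}")
        v = float(m[letter])
        if v < 0 or (v == 0 and not allow_zero):
            raise ValueError(f"{name}[{letter}] must be strictly positive, got {v}")
        out[letter] = v
    return out


def _check_kind_map(name: str, m: Mapping[str, float]) -> dict[str, float]:
    out = {}
    for kind in _KINDS:
        if kind not in m:
            raise ValueError(f"mechanics table missing {name} entry for pair {kind}")
        v = float(m[kind])
        if not v > 0:
            raise ValueError(f"{name}[{kind}] must be strictly positive, got {v}")
        out[kind] = v
    return out


@dataclass(frozen=True)
class BaseMechanics:
    """Per-letter and per-pair-kind mechanical coefficients (SI units).

    inertia
        rotational inertia I per base letter, kg·m².
    radius
        distance R from the base's centre of inertia to the backbone, m.
    torsion
        backbone torsional constant K per base letter, N·m (uniform by
        default; per-letter values allowed).
    dissipation
        environmental drag coefficient beta per base letter, N·m·s.
    bond
        hydrogen-bond elastic constant k12 per pair kind (AT covers A–T and
        T–A, GC covers G–C and C–G), N/m.
    ecr
        protium critical energy Ecr^H per pair kind, N·m.
    """

    inertia: dict[str, float]
    radius: dict[str, float]
    torsion: dict[str, float]
    dissipation: dict[str, float]
    bond: dict[str, float]
    ecr: dict[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "inertia", _check_letter_map("inertia", self.inertia))
        object.__setattr__(self, "radius", _check_letter_map("radius", self.radius))
        object.__setattr__(self, "torsion", _check_letter_map("torsion", self.torsion))
        object.__setattr__(
            self,
            "dissipation",
            # beta = 0 is the undamped (conservative) limit, used in energy
            # audits; every other coefficient must be strictly positive.
            _check_letter_map("dissipation", self.dissipation, allow_zero=True),
        )
        object.__setattr__(self, "bond", _check_kind_map("bond", self.bond))
        object.__setattr__(self, "ecr", _check_kind_map("ecr", self.ecr))

    def with_uniform_ecr(self, ecr: float) -> "BaseMechanics":
        """Copy with the same critical energy for both pair kinds.

        Used by the energy scan, which sweeps a single Ecr applied to every
        pair regardless of kind.
        """
        if not ecr > 0:
            raise ValueError("ecr must be strictly positive")
        return replace(self, ecr={"AT": float(ecr), "GC": float(ecr)})


@dataclass(frozen=True)
class IsotopeSpec:
    """A single ²H-for-¹H substitution at one pair (or none).

    ``kD`` multiplies k12 and Ecr at the substituted pair only.
    """

    substituted_position: int | None = None  # 1-based
    kD: float = 1.05

    def __post_init__(self) -> None:
        if not self.kD > 0:
            raise ValueError("kD must be strictly positive")
        if self.substituted_position is not None and self.substituted_position < 1:
            raise ValueError("substituted_position is 1-based and must be >= 1")


@dataclass(frozen=True)
class PairMechanics:
    """Length-n coefficient arrays; chain 1 is the input strand."""

    I1: np.ndarray
    I2: np.ndarray
    R1: np.ndarray
    R2: np.ndarray
    K1: np.ndarray
    K2: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    k12: np.ndarray
    Ecr: np.ndarray

    @property
    def n(self) -> int:
        return self.I1.shape[0]


def base_mechanics_from_dict(cfg: Mapping) -> BaseMechanics:
    """Build a :class:`BaseMechanics` from a parsed config mapping.

    ``units.energy_scale`` (default 1.0) multiplies the ``ecr`` entries so
    tables may quote critical energies in the conventional 10⁻²² N·m units.
    ``torsion`` accepts either a single ``K`` applied to every letter or a
    per-letter map.
    """
    scale = float(cfg.get("units", {}).get("energy_scale", 1.0))
    torsion = cfg["torsion"]
    if "K" in torsion and not set(torsion) & set(_LETTERS):
        torsion = {letter: torsion["K"] for letter in _LETTERS}
    ecr = {k: float(v) * scale for k, v in cfg["ecr"].items()}
    return BaseMechanics(
        inertia=dict(cfg["inertia"]),
        radius=dict(cfg["radius"]),
        torsion=dict(torsion),
        dissipation=dict(cfg["dissipation"]),
        bond=dict(cfg["bond"]),
        ecr=ecr,
    )


def default_base_mechanics() -> BaseMechanics:
    """The packaged default coefficient table.

    Values are representative of published torsional (Yakushevich-family)
    DNA models; see the notes inside ``data/base_mechanics.yaml``.  For
    quantitative work on a specific gene, override them via config.
    """
    text = resources.files("dnabubbles.data").joinpath("base_mechanics.yaml").read_text()
    return base_mechanics_from_dict(yaml.safe_load(text))


def build_pair_mechanics(
    duplex: GeneDuplex,
    base_mech: BaseMechanics,
    iso: IsotopeSpec | None = None,
) -> PairMechanics:
    """Assemble per-pair coefficient arrays, applying the isotope scaling.

    The substituted position's ``k12`` and ``Ecr`` are multiplied by ``kD``;
    every other entry is determined by the sequence alone.
    """
    iso = iso or IsotopeSpec(None)
    n = duplex.n
    if iso.substituted_position is not None and iso.substituted_position > n:
        raise ValueError(
            f"substituted_position {iso.substituted_position} exceeds n={n}"
        )
    b1 = duplex.bases
    b2 = duplex.complement_strand()

    def per_base(table: Mapping[str, float], strand: str) -> np.ndarray:
        return np.array([table[b] for b in strand], dtype=float)

    kinds = ["AT" if b in "AT" else "GC" for b in b1]
    k12 = np.array([base_mech.bond[k] for k in kinds], dtype=float)
    ecr = np.array([base_mech.ecr[k] for k in kinds], dtype=float)
    if iso.substituted_position is not None:
        j = iso.substituted_position - 1
        k12[j] *= iso.kD
        ecr[j] *= iso.kD
    return PairMechanics(
        I1=per_base(base_mech.inertia, b1),
        I2=per_base(base_mech.inertia, b2),
        R1=per_base(base_mech.radius, b1),
        R2=per_base(base_mech.radius, b2),
        K1=per_base(base_mech.torsion, b1),
        K2=per_base(base_mech.torsion, b2),
        beta1=per_base(base_mech.dissipation, b1),
        beta2=per_base(base_mech.dissipation, b2),
        k12=k12,
        Ecr=ecr,
    )
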