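"""Coupled angular dynamics of the duplex with threshold bond breaking.

Each base is a damped, periodically driven torsional pendulum.  Writing
``phi1[i]``, ``phi2[i]`` for the angular deflections of pair *i*'s bases on
the two chains, the torque on a base has three parts:

* backbone coupling ``K * (phi[i-1] - 2 phi[i] + phi[i+1])`` (one-neighbour
  forms at the chain ends),
* the hydrogen-bond interaction with the complementary base, gated by the
  bond indicator ``delta[i]``,
* the external term ``-beta * dphi/dt + F0 * cos(omega * t)``.

The closed duplex is at ``phi1 = 0``, ``phi2 = pi``.  The bond-stretch
energy of pair *i*, ``E_i = k12 R1 R2 (1 + cos(phi1 - phi2))``, vanishes
there and grows as the pair twists out of register; when ``E_i`` exceeds the
critical energy ``Ecr_i`` the bond breaks (``delta = 0``) and when a broken
pair's energy falls back below ``Ecr_i`` it reforms (``delta = 1``).  Ties
leave ``delta`` unchanged.

Two coupling conventions are provided.  The default ``conservative`` mode
derives both chains' hydrogen-bond torques from the explicit potential

    V_i = g_i k12 [ (R1+R2)(R1(1-cos phi1) + R2(1+cos phi2))
                    + R1 R2 (1 + cos(phi1 - phi2)) ]

(with ``g_i`` the delta gating) so the closed state is a true energy
minimum and, with ``beta = F0 = 0``, total mechanical energy is conserved
up to integrator truncation error.  ``literal`` mode flips the sign of the
relative-rotation torque on chain 2, reproducing a common printed form of
the equations that is not derivable from a single potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mechanics import PairMechanics

__all__ = [
    "DynamicState",
    "ForcingSpec",
    "IntegrationSpec",
    "ModelOptions",
    "BondTrajectory",
    "equilibrium_state",
    "rhs",
    "pair_energies",
    "pair_potential_energy",
    "update_bonds",
    "rk4_step",
    "total_energy",
    "simulate",
]


@dataclass
class DynamicState:
    """Angles (rad), angular velocities (rad/s), bond indicators, time (s)."""

    phi1: np.ndarray
    phi2: np.ndarray
    om1: np.ndarray
    om2: np.ndarray
    delta: np.ndarray  # 1 = intact, 0 = broken
    t: float = 0.0

    @property
    def n(self) -> int:
        return self.phi1.shape[0]

    def copy(self) -> "DynamicState":
        return DynamicState(
            self.phi1.copy(),
            self.phi2.copy(),
            self.om1.copy(),
            self.om2.copy(),
            self.delta.copy(),
            self.t,
        )


@dataclass(frozen=True)
class ForcingSpec:
    """External periodic torque ``F0 * cos(omega * t)`` applied to every base.

    Defaults: F0 = 0.526e-22 N·m, omega = 0.4e12 s^-1.
    """

    F0: float = 0.526e-22
    omega: float = 0.4e12

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError("omega must be positive")


@dataclass(frozen=True)
class IntegrationSpec:
    """Fixed-step integration horizon T, step tau, and recording stride.

    Defaults: T = 3.0e-10 s, tau = 1.0e-14 s (30,000 steps), every step
    recorded, so samples sit at t_j = j*tau, j = 1..m.
    """

    T: float = 3.0e-10
    tau: float = 1.0e-14
    record_stride: int = 1

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.m < 1:
            raise ValueError("horizon shorter than one step")

    @property
    def m(self) -> int:
        return int(round(self.T / self.tau))


@dataclass(frozen=True)
class ModelOptions:
    """Coupling convention flags; see the module docstring."""

    mode: str = "conservative"  # or "literal"
    delta_gates_both: bool = True
    break_energy: str = "relative"  # or "full"

    def __post_init__(self) -> None:
        if self.mode not in ("conservative", "literal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.break_energy not in ("relative", "full"):
            raise ValueError(f"unknown break_energy {self.break_energy!r}")


@dataclass
class BondTrajectory:
    """Sampled bond states: ``broken[j, i]`` is True when pair i+1 is open
    at sample time ``times[j]``."""

    times: np.ndarray
    broken: np.ndarray  # shape (samples, n), bool
    angles: np.ndarray | None = None  # optional (samples, 2, n) phi snapshots

    @property
    def n(self) -> int:
        return self.broken.shape[1]

    @property
    def samples(self) -> int:
        return self.broken.shape[0]


def equilibrium_state(n: int) -> DynamicState:
    """Closed-duplex rest state: phi1 = 0, phi2 = pi, no motion, all bonds intact."""
    if n < 2:
        raise ValueError("the chain equations need n >= 2 (distinct ends)")
    return DynamicState(
        phi1=np.zeros(n),
        phi2=np.full(n, np.pi),
        om1=np.zeros(n),
        om2=np.zeros(n),
        delta=np.ones(n, dtype=np.int8),
        t=0.0,
    )


def _backbone_torque(phi: np.ndarray, K: np.ndarray) -> np.ndarray:
    lap = np.empty_like(phi)
    lap[1:-1] = phi[:-2] - 2.0 * phi[1:-1] + phi[2:]
    lap[0] = phi[1] - phi[0]
    lap[-1] = phi[-2] - phi[-1]
    return K * lap


def _accelerations(
    phi1: np.ndarray,
    phi2: np.ndarray,
    om1: np.ndarray,
    om2: np.ndarray,
    delta: np.ndarray,
    t: float,
    mech: PairMechanics,
    forcing: ForcingSpec,
    options: ModelOptions,
) -> tuple[np.ndarray, np.ndarray]:
    gA = delta.astype(float)
    gB = gA if options.delta_gates_both else 1.0
    k = mech.k12
    R1, R2 = mech.R1, mech.R2
    rel = np.sin(phi1 - phi2)
    drive = forcing.F0 * np.cos(forcing.omega * t)

    tq1 = (
        _backbone_torque(phi1, mech.K1)
        - gA * k * R1 * (R1 + R2) * np.sin(phi1)
        + gB * k * R1 * R2 * rel
        - mech.beta1 * om1
        + drive
    )
    s2 = 1.0 if options.mode == "literal" else -1.0
    tq2 = (
        _backbone_torque(phi2, mech.K2)
        + gA * k * R2 * (R1 + R2) * np.sin(phi2)
        + s2 * gB * k * R1 * R2 * rel
        - mech.beta2 * om2
        + drive
    )
    return tq1 / mech.I1, tq2 / mech.I2


def rhs(
    state: DynamicState,
    mech: PairMechanics,
    forcing: ForcingSpec,
    t: float | None = None,
    options: ModelOptions = ModelOptions(),
) -> tuple[np.ndarray, np.ndarray]:
    """Angular accelerations of both chains at time *t* (defaults to state.t)."""
    if not (
        np.all(np.isfinite(state.phi1))
        and np.all(np.isfinite(state.phi2))
        and np.all(np.isfinite(state.om1))
        and np.all(np.isfinite(state.om2))
    ):
        raise ValueError("non-finite dynamic state")
    return _accelerations(
        state.phi1,
        state.phi2,
        state.om1,
        state.om2,
        state.delta,
        state.t if t is None else t,
        mech,
        forcing,
        options,
    )


def pair_energies(
    state: DynamicState,
    mech: PairMechanics,
    options: ModelOptions = ModelOptions(),
) -> np.ndarray:
    """Bond-stretch energy per pair, N·m; 0 at the closed state.

    The break test uses the relative-rotation term
    ``k12 R1 R2 (1 + cos(phi1 - phi2))`` by default; ``break_energy='full'``
    adds the backbone-referenced parts of the pair potential.
    """
    e = mech.k12 * mech.R1 * mech.R2 * (1.0 + np.cos(state.phi1 - state.phi2))
    if options.break_energy == "full":
        e = e + mech.k12 * (mech.R1 + mech.R2) * (
            mech.R1 * (1.0 - np.cos(state.phi1))
            + mech.R2 * (1.0 + np.cos(state.phi2))
        )
    return e


def pair_potential_energy(
    state: DynamicState,
    mech: PairMechanics,
    i: int,
    options: ModelOptions = ModelOptions(),
) -> float:
    """Bond-stretch energy of the pair at 1-based position *i* (ignores delta)."""
    if not 1 <= i <= state.n:
        raise ValueError(f"position {i} outside 1..{state.n}")
    return float(pair_energies(state, mech, options)[i - 1])


def update_bonds(
    state: DynamicState,
    mech: PairMechanics,
    options: ModelOptions = ModelOptions(),
) -> DynamicState:
    """Apply the threshold break/restore rule (strict inequalities; in place)."""
    e = pair_energies(state, mech, options)
    breaking = (state.delta == 1) & (e > mech.Ecr)
    restoring = (state.delta == 0) & (e < mech.Ecr)
    state.delta[breaking] = 0
    state.delta[restoring] = 1
    return state


def rk4_step(
    state: DynamicState,
    mech: PairMechanics,
    forcing: ForcingSpec,
    tau: float,
    options: ModelOptions = ModelOptions(),
) -> DynamicState:
    """One classic Runge–Kutta 4 step of size tau; delta held fixed."""
    p1, p2, v1, v2 = state.phi1, state.phi2, state.om1, state.om2
    d, t = state.delta, state.t

    def acc(p1_, p2_, v1_, v2_, t_):
        return _accelerations(p1_, p2_, v1_, v2_, d, t_, mech, forcing, options)

    a1, a2 = acc(p1, p2, v1, v2, t)
    k1 = (v1, v2, a1, a2)

    h = 0.5 * tau
    b1, b2 = acc(p1 + h * k1[0], p2 + h * k1[1], v1 + h * k1[2], v2 + h * k1[3], t + h)
    k2 = (v1 + h * k1[2], v2 + h * k1[3], b1, b2)

    c1, c2 = acc(p1 + h * k2[0], p2 + h * k2[1], v1 + h * k2[2], v2 + h * k2[3], t + h)
    k3 = (v1 + h * k2[2], v2 + h * k2[3], c1, c2)

    d1, d2 = acc(
        p1 + tau * k3[0], p2 + tau * k3[1], v1 + tau * k3[2], v2 + tau * k3[3], t + tau
    )
    k4 = (v1 + tau * k3[2], v2 + tau * k3[3], d1, d2)

    w = tau / 6.0
    new = DynamicState(
        phi1=p1 + w * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]),
        phi2=p2 + w * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]),
        om1=v1 + w * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]),
        om2=v2 + w * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]),
        delta=d,
        t=t + tau,
    )
    for name, arr in (("phi1", new.phi1), ("phi2", new.phi2), ("om1", new.om1), ("om2", new.om2)):
        if not np.all(np.isfinite(arr)):
            pos = int(np.flatnonzero(~np.isfinite(arr))[0]) + 1
            raise FloatingPointError(
                f"non-finite {name} at t={new.t:.3e} s, position {pos}; "
                "reduce tau or check parameters"
            )
    return new


def total_energy(
    state: DynamicState,
    mech: PairMechanics,
    options: ModelOptions = ModelOptions(),
) -> float:
    """Total mechanical energy in conservative mode (uniform K assumed).

    Kinetic + hydrogen-bond potential (with the configured delta gating)
    + backbone elastic energy.  Exactly conserved dynamics require
    ``mode='conservative'``, ``beta = 0``, ``F0 = 0`` and no bond events.
    """
    kin = 0.5 * np.sum(mech.I1 * state.om1**2 + mech.I2 * state.om2**2)
    g = state.delta.astype(float)
    gA = g
    gB = g if options.delta_gates_both else 1.0
    k, R1, R2 = mech.k12, mech.R1, mech.R2
    vpair = np.sum(
        gA * k * (R1 + R2) * (R1 * (1.0 - np.cos(state.phi1)) + R2 * (1.0 + np.cos(state.phi2)))
        + gB * k * R1 * R2 * (1.0 + np.cos(state.phi1 - state.phi2))
    )
    d1 = np.diff(state.phi1)
    d2 = np.diff(state.phi2)
    vchain = 0.5 * np.sum(mech.K1[:-1] * d1**2) + 0.5 * np.sum(mech.K2[:-1] * d2**2)
    return float(kin + vpair + vchain)


def simulate_energies(
    mech: PairMechanics,
    forcing: ForcingSpec,
    integ: IntegrationSpec,
    options: ModelOptions = ModelOptions(),
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate with bonds held intact and record pair energies per sample.

    Returns ``(times, energies)`` with energies of shape (samples, n).  The
    recorded energies can be re-thresholded at any critical energy to study
    how the threshold shapes bubble statistics on one fixed trajectory.
    """
    state = equilibrium_state(mech.n)
    m = integ.m
    stride = integ.record_stride
    nrec = m // stride
    times = np.empty(nrec)
    energies = np.empty((nrec, mech.n))
    r = 0
    for j in range(1, m + 1):
        state = rk4_step(state, mech, forcing, integ.tau, options)
        if j % stride == 0:
            times[r] = state.t
            energies[r] = pair_energies(state, mech, options)
            r += 1
    return times, energies


def rethreshold_masks(energies: np.ndarray, ecr: float) -> np.ndarray:
    """Broken-pair masks from recorded energies at one critical energy."""
    return np.asarray(energies) > ecr


def simulate(
    mech: PairMechanics,
    forcing: ForcingSpec,
    integ: IntegrationSpec,
    options: ModelOptions = ModelOptions(),
    initial: DynamicState | None = None,
    store_angles: bool = False,
) -> BondTrajectory:
    """Integrate from the closed equilibrium and record broken-bond masks.

    Each step is one RK4 update (delta frozen within the step) followed by
    the threshold break/restore rule; the mask is recorded every
    ``record_stride`` completed steps, so with the default stride the
    samples are exactly the t_j = j*tau grid.  Fully deterministic.
    """
    n = mech.n
    state = initial.copy() if initial is not None else equilibrium_state(n)
    m = integ.m
    stride = integ.record_stride
    nrec = m // stride
    times = np.empty(nrec)
    broken = np.empty((nrec, n), dtype=bool)
    angles = np.empty((nrec, 2, n)) if store_angles else None
    r = 0
    for j in range(1, m + 1):
        state = rk4_step(state, mech, forcing, integ.tau, options)
        update_bonds(state, mech, options)
        if j % stride == 0:
            times[r] = state.t
            broken[r] = state.delta == 0
            if store_angles:
                angles[r, 0] = state.phi1
                angles[r, 1] = state.phi2
            r += 1
    return BondTrajectory(times=times, broken=broken, angles=angles)
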