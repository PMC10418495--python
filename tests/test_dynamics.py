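"""Integrator and bond-rule tests: equilibrium, gradients, convergence,
energy accounting, hysteresis, determinism."""

import numpy as np
import pytest

import dnabubbles as db
from dnabubbles.dynamics import ModelOptions, pair_energies

CONS = ModelOptions(mode="conservative", delta_gates_both=True)


def make_mech(seq="ATGCA", base_mech=None, beta=None, ecr=None):
    bm = base_mech or db.default_base_mechanics()
    if beta is not None:
        bm = db.BaseMechanics(
            inertia=bm.inertia, radius=bm.radius, torsion=bm.torsion,
            dissipation={b: beta for b in "ATGC"}, bond=bm.bond, ecr=bm.ecr,
        )
    if ecr is not None:
        bm = bm.with_uniform_ecr(ecr)
    return db.build_pair_mechanics(db.duplex_from_string(seq), bm)


def potential(phi1, phi2, delta, mech, gates_both=True):
    """Independent scalar potential for the conservative convention."""
    g = delta.astype(float)
    gB = g if gates_both else np.ones_like(g)
    k, R1, R2 = mech.k12, mech.R1, mech.R2
    vpair = np.sum(
        g * k * (R1 + R2) * (R1 * (1 - np.cos(phi1)) + R2 * (1 + np.cos(phi2)))
        + gB * k * R1 * R2 * (1 + np.cos(phi1 - phi2))
    )
    vchain = 0.5 * np.sum(mech.K1[:-1] * np.diff(phi1) ** 2)
    vchain += 0.5 * np.sum(mech.K2[:-1] * np.diff(phi2) ** 2)
    return vpair + vchain


class TestEquilibrium:
    def test_state_layout(self):
        st = db.equilibrium_state(4)
        assert np.array_equal(st.phi2, np.full(4, np.pi))
        assert np.all(st.delta == 1) and st.t == 0.0

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            db.equilibrium_state(1)

    def test_zero_acceleration_without_forcing(self):
        mech = make_mech("ATGCATGC")
        st = db.equilibrium_state(8)
        a1, a2 = db.rhs(st, mech, db.ForcingSpec(F0=0.0), options=CONS)
        scale = float(np.max(mech.k12 * mech.R1 * (mech.R1 + mech.R2) / mech.I1))
        assert np.abs(a1).max() < 1e-10 * scale
        assert np.abs(a2).max() < 1e-10 * scale

    def test_non_finite_state_rejected(self):
        mech = make_mech("ATGC")
        st = db.equilibrium_state(4)
        st.phi1[2] = np.nan
        with pytest.raises(ValueError):
            db.rhs(st, mech, db.ForcingSpec())


class TestTorqueGradient:
    @pytest.mark.parametrize("gates_both", [True, False])
    @pytest.mark.parametrize("with_breaks", [False, True])
    def test_torques_equal_minus_numeric_gradient(self, gates_both, with_breaks):
        """Conservative-mode torques match -dV/dphi by central differences."""
        mech = make_mech("ATGCA", beta=0.0)
        opts = ModelOptions(mode="conservative", delta_gates_both=gates_both)
        rng = np.random.default_rng(5)
        st = db.equilibrium_state(5)
        st.phi1 = rng.uniform(-0.4, 0.4, 5)
        st.phi2 = np.pi + rng.uniform(-0.4, 0.4, 5)
        if with_breaks:
            st.delta = np.array([1, 0, 1, 1, 0], dtype=np.int8)
        a1, a2 = db.rhs(st, mech, db.ForcingSpec(F0=0.0), options=opts)
        tq1, tq2 = a1 * mech.I1, a2 * mech.I2
        h = 1e-7
        for i in range(5):
            for phi, tq in ((st.phi1, tq1), (st.phi2, tq2)):
                orig = phi[i]
                phi[i] = orig + h
                vp = potential(st.phi1, st.phi2, st.delta, mech, gates_both)
                phi[i] = orig - h
                vm = potential(st.phi1, st.phi2, st.delta, mech, gates_both)
                phi[i] = orig
                grad = (vp - vm) / (2 * h)
                assert tq[i] == pytest.approx(-grad, rel=1e-6, abs=1e-32)

    def test_mirrored_perturbation_gives_mirrored_accelerations(self):
        """Uniform chain: reversing the perturbation reverses the response."""
        mech = make_mech("AAAAAA", beta=0.0)
        pert = np.array([0.3, -0.1, 0.05, 0.2, -0.25, 0.15])
        st = db.equilibrium_state(6)
        st.phi1 = pert.copy()
        st.phi2 = np.pi + 0.5 * pert
        a1, a2 = db.rhs(st, mech, db.ForcingSpec(F0=0.0), options=CONS)
        st2 = db.equilibrium_state(6)
        st2.phi1 = pert[::-1].copy()
        st2.phi2 = np.pi + 0.5 * pert[::-1]
        b1, b2 = db.rhs(st2, mech, db.ForcingSpec(F0=0.0), options=CONS)
        np.testing.assert_allclose(b1, a1[::-1], rtol=1e-12)
        np.testing.assert_allclose(b2, a2[::-1], rtol=1e-12)


class TestPairEnergy:
    def test_zero_at_equilibrium_and_max_at_alignment(self):
        mech = make_mech("ATGC")
        st = db.equilibrium_state(4)
        assert db.pair_potential_energy(st, mech, 1) == pytest.approx(0.0, abs=1e-40)
        st.phi2 = np.zeros(4)  # aligned: phi1 - phi2 = 0
        for i in range(1, 5):
            expect = 2 * mech.k12[i - 1] * mech.R1[i - 1] * mech.R2[i - 1]
            assert db.pair_potential_energy(st, mech, i) == pytest.approx(expect)

    def test_strictly_increasing_with_stretch(self):
        mech = make_mech("ATGC")
        st = db.equilibrium_state(4)
        energies = []
        for eps in np.linspace(0.0, np.pi - 1e-6, 50):
            st.phi1 = np.full(4, eps)  # phi1 - phi2 = -pi + eps
            energies.append(db.pair_potential_energy(st, mech, 2))
        assert np.all(np.diff(energies) > 0)

    def test_evaluated_regardless_of_delta(self):
        mech = make_mech("ATGC")
        st = db.equilibrium_state(4)
        st.phi1[:] = 0.5
        st.delta[:] = 0
        assert db.pair_potential_energy(st, mech, 1) > 0


class TestBondUpdate:
    def test_untouched_at_rest(self):
        mech = make_mech("ATGC")
        st = db.equilibrium_state(4)
        db.update_bonds(st, mech)
        assert np.all(st.delta == 1)

    def test_break_one_pair(self):
        mech = make_mech("ATGC", ecr=1e-25)
        st = db.equilibrium_state(4)
        st.phi1[2] = 2.0  # drive pair 3 past threshold
        db.update_bonds(st, mech)
        assert list(st.delta) == [1, 1, 0, 1]

    def test_restore_after_relaxation(self):
        mech = make_mech("ATGC", ecr=1e-25)
        st = db.equilibrium_state(4)
        st.delta[:] = 0
        db.update_bonds(st, mech)  # energy 0 < Ecr everywhere
        assert np.all(st.delta == 1)

    def test_tie_leaves_delta_unchanged(self):
        mech = make_mech("ATGC")
        st = db.equilibrium_state(4)
        e = pair_energies(st, mech)
        mech2 = db.PairMechanics(
            **{f: getattr(mech, f) for f in
               ("I1", "I2", "R1", "R2", "K1", "K2", "beta1", "beta2", "k12")},
            Ecr=e.copy(),
        )
        st.delta = np.array([1, 0, 1, 0], dtype=np.int8)
        db.update_bonds(st, mech2)
        assert list(st.delta) == [1, 0, 1, 0]


class TestIntegrator:
    def test_equilibrium_is_fixed_point(self):
        mech = make_mech("ATGCAT")
        st = db.equilibrium_state(6)
        out = db.rk4_step(st, mech, db.ForcingSpec(F0=0.0), 1e-14, CONS)
        np.testing.assert_allclose(out.phi1, st.phi1, atol=1e-18)
        np.testing.assert_allclose(out.phi2, st.phi2, rtol=1e-15)
        # velocity noise floor: sin(pi) rounding ~1e-16 feeds accel ~1e8
        # rad/s^2; against the ~1e12 rad/s natural scale this is negligible
        np.testing.assert_allclose(out.om1, 0.0, atol=1e-4)

    def test_fourth_order_convergence(self):
        """Richardson: global error ratio ~ 2^4 across tau, tau/2, tau/4."""
        mech = make_mech("AT", beta=0.0)
        horizon = 512e-14

        def run(tau):
            st = db.equilibrium_state(2)
            st.phi1 = np.array([0.05, -0.03])
            st.phi2 = np.pi + np.array([-0.02, 0.04])
            for _ in range(int(round(horizon / tau))):
                st = db.rk4_step(st, mech, db.ForcingSpec(F0=0.0), tau, CONS)
            return np.concatenate([st.phi1, st.phi2])

        ref = run(1e-15)
        errs = [np.max(np.abs(run(tau) - ref)) for tau in (16e-15, 8e-15, 4e-15)]
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(np.abs(orders - 4.0) < 0.2)

    def test_energy_conserved_without_damping(self):
        mech = make_mech("ATGCAT", beta=0.0)
        st = db.equilibrium_state(6)
        st.phi1 += 0.05
        e0 = db.total_energy(st, mech, CONS)
        drifts = {}
        for tau in (2e-14, 1e-14):
            s = st.copy()
            for _ in range(int(2e-11 / tau)):
                s = db.rk4_step(s, mech, db.ForcingSpec(F0=0.0), tau, CONS)
            drifts[tau] = abs(db.total_energy(s, mech, CONS) - e0) / e0
        assert drifts[1e-14] < 1e-6
        # RK4 truncation: halving tau should cut the drift by roughly 2^4
        assert drifts[2e-14] / drifts[1e-14] > 8

    def test_energy_non_increasing_with_damping(self):
        mech = make_mech("ATGCAT", beta=1e-34)
        st = db.equilibrium_state(6)
        st.phi1 += 0.05
        prev = db.total_energy(st, mech, CONS)
        for _ in range(400):
            st = db.rk4_step(st, mech, db.ForcingSpec(F0=0.0), 1e-14, CONS)
            cur = db.total_energy(st, mech, CONS)
            assert cur <= prev * (1 + 1e-12)
            prev = cur


class TestSimulate:
    def test_unreachable_threshold_keeps_bonds_intact(self, toy_duplex, base_mech):
        duplex, _ = toy_duplex
        mech = db.build_pair_mechanics(duplex, base_mech.with_uniform_ecr(1.0))
        traj = db.simulate(mech, db.ForcingSpec(), db.IntegrationSpec(T=1e-12, tau=1e-14))
        assert not traj.broken.any()
        assert all(v == 0.0 for v in db.occupancy_probabilities(traj).values())

    def test_vanishing_threshold_saturates(self, toy_duplex, base_mech):
        duplex, _ = toy_duplex
        mech = db.build_pair_mechanics(duplex, base_mech.with_uniform_ecr(1e-40))
        traj = db.simulate(mech, db.ForcingSpec(), db.IntegrationSpec(T=1e-12, tau=1e-14))
        assert traj.broken[-1].all()

    def test_bit_identical_reruns(self, toy_duplex, base_mech):
        duplex, _ = toy_duplex
        mech = db.build_pair_mechanics(duplex, base_mech.with_uniform_ecr(0.25e-22))
        opts = ModelOptions(mode="literal")
        integ = db.IntegrationSpec(T=5e-12, tau=1e-13)
        t1 = db.simulate(mech, db.ForcingSpec(), integ, opts)
        t2 = db.simulate(mech, db.ForcingSpec(), integ, opts)
        assert np.array_equal(t1.broken, t2.broken)
        assert np.array_equal(t1.times, t2.times)

    def test_record_stride_subsamples_t_grid(self, base_mech):
        mech = make_mech("ATGCAT", base_mech=base_mech)
        integ = db.IntegrationSpec(T=1e-13, tau=1e-14, record_stride=2)
        traj = db.simulate(mech, db.ForcingSpec(), integ)
        assert traj.samples == 5
        np.testing.assert_allclose(traj.times, np.arange(1, 6) * 2e-14, rtol=1e-12)
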