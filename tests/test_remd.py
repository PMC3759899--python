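"""Reference selection, flat-bottom restraint, Langevin sampling and
replica exchange."""

import numpy as np
import pytest

from actionpath import (DoubleWell1D, HarmonicWell, LadderConfig,
                        MolecularSystem, ReferenceSet, ZeroPotential,
                        exchange_probability, langevin_step, run_remd,
                        select_references)
from actionpath.constants import KB, KCAL_PER_AMU_A2_FS2
from actionpath.potentials import LJCluster
from actionpath.potentials import finite_difference_forces
from actionpath.remd import ReplicaState, maxwell_boltzmann_velocities


class TestSelectReferences:
    def test_full_scale_selection(self):
        idx = select_references(300, 9)
        assert len(idx) == 34
        assert list(idx[:3]) == [0, 9, 18]
        assert list(idx[-3:]) == [279, 288, 300]

    def test_stride_equal_p_gives_endpoints(self):
        assert list(select_references(40, 40)) == [0, 40]

    def test_small_case_by_hand(self):
        # multiples of 9 up to 30 − 9 = 21, then P appended
        assert list(select_references(30, 9)) == [0, 9, 18, 30]

    def test_bad_stride(self):
        with pytest.raises(ValueError):
            select_references(30, 0)


def _toy_refs_1d(n=5, spacing=1.0, radius=0.4, k=2.24):
    xs = np.arange(n) * spacing
    return ReferenceSet(xs[:, None, None], np.arange(n) * 10,
                        radius=radius, force_constant=k, superpose=False)


class TestRestraint:
    def test_on_a_reference_is_zero(self):
        refs = _toy_refs_1d()
        v, idx, rmsd, forces = refs.restraint(np.array([[2.0]]))
        assert (v, idx, rmsd) == (0.0, 2, 0.0)
        assert np.all(forces == 0.0)

    def test_inside_flat_bottom_is_zero(self):
        refs = ReferenceSet(np.zeros((1, 1, 1)), [0], radius=2.0,
                            superpose=False)
        v, _, rmsd, forces = refs.restraint(np.array([[1.5]]))
        assert v == 0.0 and rmsd == pytest.approx(1.5)
        assert np.all(forces == 0.0)

    def test_outside_matches_direct_harmonic_sum(self):
        refs = ReferenceSet(np.zeros((1, 2, 1)), [0], radius=2.0,
                            force_constant=2.24, superpose=False)
        coords = np.array([[3.0], [4.0]])
        v, _, rmsd, forces = refs.restraint(coords)
        assert v == pytest.approx(0.5 * 2.24 * (9.0 + 16.0), rel=1e-10)
        assert forces == pytest.approx(-2.24 * coords, rel=1e-12)

    def test_superposed_restraint_force_finite_difference(self, rng):
        """3D restraint with alignment: the envelope theorem makes the
        analytic force −k·(q − q_aligned); check against central FD."""
        ref = rng.normal(size=(5, 3))
        refs = ReferenceSet(ref[None], [0], radius=0.05,
                            force_constant=2.24, superpose=True)
        coords = ref + 0.5 * rng.normal(size=(5, 3))

        class _Wrap:
            n_atoms, dim = 5, 3
            def energy(self, q):
                return refs.restraint(q)[0]
        v, _, rmsd, forces = refs.restraint(coords)
        assert rmsd > refs.radius and v > 0
        fd = finite_difference_forces(_Wrap(), coords, step=1e-6)
        assert forces == pytest.approx(fd, abs=1e-5)

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            ReferenceSet(np.zeros((0, 1, 1)), [])


class TestExchangeProbability:
    def test_equal_energies_always_accepted(self):
        assert exchange_probability(-5.0, -5.0, 275.0, 300.0) == 1.0

    def test_equal_temperatures_always_accepted(self):
        assert exchange_probability(-5.0, 3.0, 300.0, 300.0) == 1.0

    def test_closed_form_value(self):
        beta_i = 1.0 / (KB * 275.0)
        beta_j = 1.0 / (KB * 300.0)
        expected = np.exp((beta_i - beta_j) * (-1.0))
        assert exchange_probability(0.0, 1.0, 275.0, 300.0) == \
            pytest.approx(expected, rel=1e-12)

    def test_bad_temperature(self):
        with pytest.raises(ValueError):
            exchange_probability(0.0, 0.0, -1.0, 300.0)

    def test_swap_move_preserves_product_boltzmann(self):
        """Exact stationarity on a 2-level surrogate: the swap kernel built
        from the Metropolis probability leaves the product of Boltzmann
        distributions invariant."""
        energies = np.array([0.0, 1.3])
        t_lo, t_hi = 280.0, 400.0

        def boltz(t):
            w = np.exp(-energies / (KB * t))
            return w / w.sum()

        pi = np.outer(boltz(t_lo), boltz(t_hi)).ravel()  # joint (s_lo, s_hi)
        kernel = np.zeros((4, 4))
        for a in range(2):
            for b in range(2):
                i = 2 * a + b
                p_swap = exchange_probability(energies[a], energies[b],
                                              t_lo, t_hi)
                kernel[i, 2 * b + a] += p_swap
                kernel[i, i] += 1.0 - p_swap
        assert pi @ kernel == pytest.approx(pi, abs=1e-14)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=50)
@given(vi=st.floats(-50, 50), vj=st.floats(-50, 50),
       ti=st.floats(100, 1000), tj=st.floats(100, 1000))
def test_exchange_probability_is_a_probability(vi, vj, ti, tj):
    p = exchange_probability(vi, vj, ti, tj)
    assert 0.0 <= p <= 1.0
    # when the colder replica holds the higher energy the swap is
    # downhill and never rejected
    if (vi - vj) * (ti - tj) <= 0:
        assert p == 1.0


class TestLangevinStep:
    def test_ballistic_limit(self):
        pot = ZeroPotential(1, 1)
        sys_ = MolecularSystem.uniform(1, 1.0, dim=1)
        state = ReplicaState(np.zeros((1, 1)), np.full((1, 1), 0.3), 0, 0,
                             np.random.default_rng(0))
        for _ in range(10):
            langevin_step(state, pot, None, temperature=0.0, timestep=1.0,
                          damping=0.0, system=sys_)
        assert state.coords[0, 0] == pytest.approx(3.0, rel=1e-12)

    def test_determinism(self):
        pot = HarmonicWell(1, 1, 4.0)
        sys_ = MolecularSystem.uniform(1, 2.0, dim=1)

        def run():
            state = ReplicaState(np.ones((1, 1)), np.zeros((1, 1)), 0, 0,
                                 np.random.default_rng(99))
            force = None
            for _ in range(200):
                force = langevin_step(state, pot, None, 300.0, 1.0, 0.091,
                                      sys_, force)
            return state.coords.copy()

        assert np.array_equal(run(), run())

    def test_equipartition_position_variance(self):
        """Long harmonic-well run: Var(x) ≈ k_B·T/k within 3 SE (SE from
        ten block averages)."""
        k, temp = 5.0, 300.0
        pot = HarmonicWell(1, 1, k)
        sys_ = MolecularSystem.uniform(1, 2.0, dim=1)
        state = ReplicaState(
            np.zeros((1, 1)),
            maxwell_boltzmann_velocities(sys_, temp,
                                         np.random.default_rng(1)),
            0, 0, np.random.default_rng(2))
        xs = []
        force = None
        for step in range(120000):
            force = langevin_step(state, pot, None, temp, 1.0, 0.091, sys_,
                                  force)
            if step >= 20000 and step % 5 == 0:
                xs.append(state.coords[0, 0])
        xs = np.array(xs)
        block_vars = np.array([b.var() for b in np.array_split(xs, 10)])
        se = block_vars.std(ddof=1) / np.sqrt(10)
        assert abs(xs.var() - KB * temp / k) < 3 * se

    def test_restraint_neutrality_bit_identical(self):
        """Inside the flat bottom the restrained trajectory equals the
        unrestrained one bit for bit under the same random stream."""
        pot = HarmonicWell(1, 1, 5.0)
        sys_ = MolecularSystem.uniform(1, 2.0, dim=1)
        refs = ReferenceSet(np.zeros((1, 1, 1)), [0], radius=5.0,
                            superpose=False)

        def run(active_refs):
            state = ReplicaState(np.zeros((1, 1)), np.zeros((1, 1)), 0, 0,
                                 np.random.default_rng(42))
            force = None
            traj = []
            for _ in range(500):
                force = langevin_step(state, pot, active_refs, 300.0, 1.0,
                                      0.091, sys_, force)
                traj.append(state.coords[0, 0])
            return np.array(traj)

        assert np.array_equal(run(refs), run(None))


class TestRunRemd:
    def _double_well_setup(self):
        pot = DoubleWell1D(2.5, 1.0)
        sys_ = MolecularSystem.uniform(1, 1.0, dim=1)
        idx = select_references(60, 6)
        xs = -1.0 + 2.0 * idx / 60
        refs = ReferenceSet(xs[:, None, None], idx, radius=2.0,
                            force_constant=2.24, superpose=False)
        return pot, sys_, refs

    def test_single_temperature_no_exchange(self):
        pot, sys_, refs = self._double_well_setup()
        cfg = LadderConfig(temperatures=(300.0,), n_ladders=1,
                           total_steps=500, exchange_interval=100,
                           snapshot_interval=10, seed=3)
        store = run_remd(pot, sys_, refs, cfg, store_coords=False)
        assert store.n_samples == 50
        assert store.exchange_attempts == {}

    def test_flat_potential_exchange_acceptance_is_one(self):
        pot = ZeroPotential(1, 1)
        sys_ = MolecularSystem.uniform(1, 1.0, dim=1)
        refs = ReferenceSet(np.zeros((1, 1, 1)), [0], radius=50.0,
                            superpose=False)
        cfg = LadderConfig(temperatures=(300.0, 350.0), n_ladders=1,
                           total_steps=1000, exchange_interval=100,
                           snapshot_interval=100, seed=4)
        store = run_remd(pot, sys_, refs, cfg, store_coords=False)
        rates = store.acceptance_rates()
        assert rates[(0, 1)] == 1.0

    def test_determinism(self):
        pot, sys_, refs = self._double_well_setup()
        cfg = LadderConfig(total_steps=500, exchange_interval=100,
                           snapshot_interval=20, n_ladders=2, seed=7)
        s1 = run_remd(pot, sys_, refs, cfg, store_coords=True)
        s2 = run_remd(pot, sys_, refs, cfg, store_coords=True)
        assert np.array_equal(s1.coords, s2.coords)
        assert np.array_equal(s1.state_index, s2.state_index)

    def test_double_well_populations_match_boltzmann(self):
        """4-temperature ladder on the double well: basin populations at
        the lowest temperature agree with the Boltzmann ratio from
        numerical quadrature within 3 MC standard errors."""
        from scipy.integrate import quad
        pot, sys_, refs = self._double_well_setup()
        cfg = LadderConfig(temperatures=(300.0, 350.0, 400.0, 450.0),
                           n_ladders=4, total_steps=12000,
                           exchange_interval=200, snapshot_interval=10,
                           seed=5)
        store = run_remd(pot, sys_, refs, cfg, store_coords=True)
        temp = 300.0
        mask = store.at_temperature(temp) & \
            (store.step > 0.1 * store.step.max())
        x = store.coords[mask][:, 0, 0] if store.coords is not None else None
        p_right_sim = float(np.mean(x > 0))
        beta = 1.0 / (KB * temp)
        z_right, _ = quad(lambda y: np.exp(-beta * pot.energy(
            np.array([[y]]))), 0, 6, limit=200)
        z_total, _ = quad(lambda y: np.exp(-beta * pot.energy(
            np.array([[y]]))), -6, 6, limit=200)
        p_right_exact = z_right / z_total
        blocks = [float(np.mean(b > 0)) for b in np.array_split(x, 10)]
        se = np.std(blocks, ddof=1) / np.sqrt(10)
        assert abs(p_right_sim - p_right_exact) < 3 * max(se, 1e-3)

    def test_temperature_ordering_of_energy(self):
        """Mean potential energy is non-decreasing in temperature."""
        pot, sys_, refs = self._double_well_setup()
        cfg = LadderConfig(temperatures=(275.0, 350.0, 450.0), n_ladders=2,
                           total_steps=6000, exchange_interval=200,
                           snapshot_interval=10, seed=6)
        store = run_remd(pot, sys_, refs, cfg, store_coords=False)
        keep = store.step > 0.1 * store.step.max()
        means = [store.potential_energy[keep
                                        & store.at_temperature(t)].mean()
                 for t in cfg.temperatures]
        assert means[0] < means[1] < means[2]

    def test_diverged_replica_recorded_not_fatal(self):
        pot = LJCluster(2)
        sys_ = MolecularSystem.uniform(2, 1.0, dim=3)
        # overlapping atoms overflow the 12-6 core: the run must survive
        close = np.zeros((2, 3))
        close[1] = 1e-30
        refs = ReferenceSet(close[None], [0], radius=100.0, superpose=False)
        cfg = LadderConfig(temperatures=(300.0,), n_ladders=1,
                           total_steps=200, exchange_interval=100,
                           snapshot_interval=10, seed=8)
        store = run_remd(pot, sys_, refs, cfg,
                         initial_coords=close[None, None],
                         store_coords=False)
        assert store.n_samples < 20  # replica died early, run completed
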