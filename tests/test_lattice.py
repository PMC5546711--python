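"""Core simulator: neighbor fractions, flip probabilities, synchronous
stepping, ensembles and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psdsim import (
    KineticParams,
    LatticeState,
    NeighborSpec,
    binding_probability,
    neighbor_fraction,
    simulate_ensemble,
    simulate_lattice,
    step_synchronous,
    unbinding_probability,
)
from psdsim.lattice import neighbor_fraction_grid, synapse_rng

EDGE_ADJUSTED = NeighborSpec(full_denominator=False)


class TestNeighborFraction:
    def test_empty_lattice_everywhere_zero(self):
        state = LatticeState.empty(5, 5)
        assert neighbor_fraction(state, 2, 2) == 0.0
        assert neighbor_fraction(state, 0, 0) == 0.0

    def test_full_lattice_interior_one(self):
        state = LatticeState.full(5, 5)
        assert neighbor_fraction(state, 2, 2) == 1.0
        assert neighbor_fraction(state, 2, 2, NeighborSpec(mode="vonneumann4")) == 1.0

    def test_corner_edge_adjusted(self):
        # corner has 3 Moore neighbors; one occupied -> 1/3
        state = LatticeState.empty(4, 4)
        state.occupancy[0, 1] = True
        assert neighbor_fraction(state, 0, 0, EDGE_ADJUSTED) == pytest.approx(1 / 3)

    def test_corner_maximal_denominator(self):
        # same configuration under the always-8 convention -> 1/8
        state = LatticeState.empty(4, 4)
        state.occupancy[0, 1] = True
        assert neighbor_fraction(state, 0, 0) == pytest.approx(1 / 8)

    def test_out_of_bounds_raises(self):
        state = LatticeState.empty(3, 3)
        with pytest.raises(IndexError):
            neighbor_fraction(state, 3, 0)

    def test_grid_matches_per_site(self):
        rng = np.random.default_rng(0)
        state = LatticeState(rng.random((6, 7)) < 0.4)
        for spec in (NeighborSpec(), EDGE_ADJUSTED, NeighborSpec(mode="vonneumann4")):
            grid = neighbor_fraction_grid(state.occupancy, spec)
            for r in range(6):
                for c in range(7):
                    assert grid[r, c] == pytest.approx(
                        neighbor_fraction(state, r, c, spec)
                    )

    def test_global_mode_is_occupancy_fraction(self):
        state = LatticeState.empty(4, 5)
        state.occupancy[:2] = True
        assert neighbor_fraction(state, 0, 0, NeighborSpec(mode="global")) == 0.5


class TestFlipProbabilities:
    def test_bidirectional_binding_extremes(self):
        p = KineticParams()
        assert binding_probability(p, 0.0) == pytest.approx(0.0007)
        assert binding_probability(p, 1.0) == pytest.approx(0.4937)

    def test_langmuir_binding_constant_in_chi(self):
        p = KineticParams(model="langmuir", alpha=0.3, beta=0.5)
        for chi in (0.0, 0.3, 1.0):
            assert binding_probability(p, chi) == pytest.approx(0.3)

    def test_bidirectional_unbinding(self):
        p = KineticParams()
        assert unbinding_probability(p, 1.0) == 0.0  # fully surrounded, beta=0
        assert unbinding_probability(p, 0.0) == pytest.approx(0.5)

    def test_contact_unbinding_constant(self):
        p = KineticParams(model="contact", lambda_on=0.4, alpha=0.01, beta=0.5)
        for chi in (0.0, 0.7, 1.0):
            assert unbinding_probability(p, chi) == pytest.approx(0.5)

    def test_probability_clipped_to_unit_interval(self):
        p = KineticParams(model="langmuir", alpha=3.0, beta=0.1, dt=1.0)
        assert binding_probability(p, 0.0) == 1.0

    def test_exponential_waiting_rule(self):
        p = KineticParams(model="langmuir", alpha=0.3, beta=0.5,
                          prob_rule="exponential")
        assert binding_probability(p, 0.5) == pytest.approx(1 - np.exp(-0.3))

    def test_negative_chi_rejected(self):
        with pytest.raises(ValueError):
            binding_probability(KineticParams(), -0.1)
        with pytest.raises(ValueError):
            unbinding_probability(KineticParams(), 1.5)


class TestStepSynchronous:
    def test_zero_rates_leave_state_unchanged(self):
        p = KineticParams(model="langmuir", alpha=0.0, beta=0.0)
        rng = np.random.default_rng(1)
        state = LatticeState(rng.random((8, 8)) < 0.5)
        new = step_synchronous(state, p, rng=rng)
        assert np.array_equal(new.occupancy, state.occupancy)

    def test_certain_binding_fills_lattice(self):
        p = KineticParams(model="langmuir", alpha=1.5, beta=0.0)
        new = step_synchronous(LatticeState.empty(6, 6), p,
                               rng=np.random.default_rng(0))
        assert new.size == 36

    def test_input_state_untouched(self):
        state = LatticeState.full(4, 4)
        p = KineticParams(model="langmuir", alpha=0.0, beta=1.5)
        step_synchronous(state, p, rng=np.random.default_rng(0))
        assert state.size == 16

    def test_chi_from_pre_step_state(self):
        # contact model, alpha=0: only neighbors of the seed can bind this
        # step, even with uniforms forced to 0 (synchronous update)
        p = KineticParams(model="contact", lambda_on=8.0, alpha=0.0, beta=0.0)
        state = LatticeState.empty(7, 7)
        state.occupancy[3, 3] = True
        new = step_synchronous(state, p, uniforms=np.zeros((7, 7)))
        grown = new.occupancy & ~state.occupancy
        assert new.occupancy[3, 3]
        assert grown.sum() == 8  # exactly the Moore shell of the seed
        assert not new.occupancy[3, 5]  # two sites away: chi was 0

    def test_bidirectional_full_lattice_is_fixed(self):
        # with edge-adjusted chi every site of a full lattice has chi = 1,
        # so k_off = 0 at beta = 0 and the configuration cannot change
        state = LatticeState.full(6, 6)
        new = step_synchronous(state, KineticParams(), EDGE_ADJUSTED,
                               rng=np.random.default_rng(3))
        assert new.size == 36
        # under the maximal-denominator default only boundary sites see
        # chi < 1, so the interior remains fixed
        new = step_synchronous(state, KineticParams(),
                               rng=np.random.default_rng(3))
        assert new.occupancy[1:-1, 1:-1].all()

    def test_langmuir_long_run_occupancy(self):
        # two-state Markov chain per site: stationary occupancy alpha/(alpha+beta)
        p = KineticParams(model="langmuir", alpha=0.3, beta=0.5)
        sizes, _ = simulate_lattice(p, rows=20, cols=20, n_steps=2000,
                                    rng=np.random.default_rng(12))
        frac = sizes[200:].mean() / 400
        assert frac == pytest.approx(0.375, abs=0.01)


class TestEnsemble:
    def test_reproducible_from_master_seed(self):
        p = KineticParams()
        a = simulate_ensemble(p, rows=10, cols=10, n_synapses=4, n_steps=50,
                              master_seed=42)
        b = simulate_ensemble(p, rows=10, cols=10, n_synapses=4, n_steps=50,
                              master_seed=42)
        assert np.array_equal(a.sizes, b.sizes)

    def test_row_regenerable_in_isolation(self):
        p = KineticParams()
        ens = simulate_ensemble(p, rows=10, cols=10, n_synapses=5, n_steps=60,
                                master_seed=9)
        sizes, _ = simulate_lattice(p, rows=10, cols=10, n_steps=60,
                                    rng=synapse_rng(9, 3))
        assert np.array_equal(ens.sizes[3], sizes)

    def test_snapshot_time_validation(self):
        with pytest.raises(ValueError):
            simulate_ensemble(KineticParams(), rows=5, cols=5, n_synapses=1,
                              n_steps=10, snapshot_times=(11,))

    def test_contact_empty_state_absorbing(self):
        p = KineticParams(model="contact", lambda_on=0.4, alpha=0.0, beta=0.5)
        ens = simulate_ensemble(p, rows=10, cols=10, n_synapses=20, n_steps=300,
                                master_seed=3, initial=0.5)
        for row in ens.sizes:
            hit = np.flatnonzero(row == 0)
            if hit.size:
                assert np.all(row[hit[0]:] == 0)

    def test_dt_halving_preserves_stationary_mean(self):
        # halving dt while doubling steps leaves the stationary mean intact
        base = KineticParams()
        a = simulate_ensemble(base, rows=20, cols=20, n_synapses=80,
                              n_steps=1500, master_seed=21)
        b = simulate_ensemble(base.replace(dt=0.5), rows=20, cols=20,
                              n_synapses=80, n_steps=3000, master_seed=22)
        ma = a.sizes[:, 1200:].mean(axis=1)
        mb = b.sizes[:, 2400:].mean(axis=1)
        se = np.hypot(ma.std() / np.sqrt(len(ma)), mb.std() / np.sqrt(len(mb)))
        assert abs(ma.mean() - mb.mean()) < 3 * se

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(
        st.sampled_from(["langmuir", "contact", "bidirectional"]),
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
        st.floats(0.0, 0.05),
        st.floats(0.0, 0.3),
        st.integers(0, 10_000),
    )
    def test_sizes_bounded_and_deterministic(self, model, lam_on, lam_off,
                                             alpha, beta, seed):
        p = KineticParams(model=model, lambda_on=lam_on, lambda_off=lam_off,
                          alpha=alpha, beta=beta)
        a = simulate_ensemble(p, rows=6, cols=6, n_synapses=2, n_steps=30,
                              master_seed=seed, initial=0.3)
        b = simulate_ensemble(p, rows=6, cols=6, n_synapses=2, n_steps=30,
                              master_seed=seed, initial=0.3)
        assert np.array_equal(a.sizes, b.sizes)
        assert a.sizes.min() >= 0 and a.sizes.max() <= 36
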