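"""Cell-based rules: probit division switch, softmax site selection,
single-sweep contracts and trajectory-level behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from explantca import (
    GdnfField,
    LatticeState,
    ModelParams,
    division_probability,
    simulate,
    site_selection_probs,
    step,
)


def phi_oracle(x):
    """Standard normal CDF via the complementary error function."""
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


class TestDivisionProbability:
    def test_half_at_switch_midpoint(self):
        """At g = -c1/c2 a cell with free space divides with probability 0.5."""
        assert division_probability(25.0 / 120.0, c1=-25.0, c2=120.0) == pytest.approx(0.5, abs=1e-12)

    def test_flat_switch_gives_half(self):
        assert division_probability(0.7, c1=0.0, c2=0.0) == 0.5

    def test_no_division_without_gdnf(self):
        """c1 < 0: at g = 0 the lower probit tail shuts division off."""
        assert division_probability(0.0, c1=-25.0, c2=120.0) < 1e-100

    def test_matches_error_function_oracle(self):
        assert division_probability(0.1, c1=-25.0, c2=400.0) == pytest.approx(phi_oracle(15.0), abs=1e-12)

    @given(st.floats(0, 1), st.floats(-50, 0), st.floats(0, 500))
    @settings(max_examples=50, deadline=None)
    def test_is_a_probability_and_increasing_in_g(self, g, c1, c2):
        p = division_probability(g, c1, c2)
        assert 0.0 <= p <= 1.0
        assert division_probability(min(g + 0.1, 1.0), c1, c2) >= p


class TestSiteSelection:
    def test_equal_gdnf_is_uniform(self):
        np.testing.assert_allclose(site_selection_probs([0.3] * 4, beta=7.0), [0.25] * 4)

    def test_zero_beta_is_uniform(self):
        np.testing.assert_allclose(site_selection_probs([0.9, 0.1, 0.5], beta=0.0), [1 / 3] * 3)

    def test_two_site_softmax_value(self):
        e = math.e
        np.testing.assert_allclose(
            site_selection_probs([1.0, 0.0], beta=1.0), [e / (1 + e), 1 / (1 + e)], atol=1e-12
        )

    def test_large_beta_concentrates_on_argmax(self):
        p = site_selection_probs([0.2, 0.5, 0.21, 0.49], beta=1e3)
        assert np.argmax(p) == 1
        assert p[1] > 0.999

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            site_selection_probs([], beta=1.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=4), st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_probability_vector_invariants(self, g, beta):
        p = site_selection_probs(g, beta)
        assert p.shape == (len(g),)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)


def _uniform_field(n, value=1.0):
    return GdnfField(values=np.full((n, n), value), residual=0.0)


class TestStep:
    def test_moves_conserve_cell_count(self):
        rng = np.random.default_rng(0)
        occ = np.zeros((15, 15), dtype=bool)
        occ[4:10, 4:10] = rng.random((6, 6)) < 0.5
        params = ModelParams(grid_size=15, p_move=1.0)
        state = LatticeState(occupancy=occ, rng=np.random.default_rng(1))
        for _ in range(5):
            state = step(state, _uniform_field(15, 0.5), params)
            assert state.occupancy.sum() == occ.sum()

    def test_no_empty_neighbours_means_no_change(self):
        """Fully occupied interior (boundary ring unavailable): nothing moves."""
        occ = np.zeros((4, 4), dtype=bool)
        occ[1:3, 1:3] = True
        params = ModelParams(grid_size=4, p_move=0.5)
        state = LatticeState(occupancy=occ, rng=np.random.default_rng(2))
        out = step(state, _uniform_field(4), params)
        np.testing.assert_array_equal(out.occupancy, occ)

    def test_certain_division_places_daughter_adjacent(self):
        """Phi(c1 + c2 g) = Phi(100) ~ 1 forces the single cell to divide."""
        occ = np.zeros((7, 7), dtype=bool)
        occ[3, 3] = True
        params = ModelParams(grid_size=7, p_move=0.0, c1=0.0, c2=100.0)
        state = LatticeState(occupancy=occ, rng=np.random.default_rng(3))
        out = step(state, _uniform_field(7), params)
        assert out.occupancy.sum() == 2
        daughters = np.argwhere(out.occupancy & ~occ)
        assert len(daughters) == 1
        assert abs(daughters[0][0] - 3) + abs(daughters[0][1] - 3) == 1

    def test_shape_mismatch_rejected(self):
        occ = np.zeros((7, 7), dtype=bool)
        occ[3, 3] = True
        state = LatticeState(occupancy=occ)
        with pytest.raises(ValueError):
            step(state, _uniform_field(9), ModelParams(grid_size=7))

    def test_attachment_rule_blocks_detaching_moves(self):
        """A lone pair: the mover's only neighbour is its partner, so any
        move destination lacks support and the move is rejected."""
        occ = np.zeros((9, 9), dtype=bool)
        occ[4, 4] = occ[4, 5] = True
        params = ModelParams(grid_size=9, p_move=1.0, attachment_rule=True, chemotaxis=False)
        state = LatticeState(occupancy=occ, rng=np.random.default_rng(5))
        for _ in range(10):
            state = step(state, _uniform_field(9, 0.5), params)
        # cells may swap along the pair axis but can never detach
        assert state.occupancy.sum() == 2
        cells = np.argwhere(state.occupancy)
        assert abs(cells[0] - cells[1]).sum() == 1


class TestSimulate:
    def test_time_zero_only_returns_initial_mask(self, small_mask, small_params):
        traj = simulate(small_mask, small_params, [0.0], seed=0)
        assert len(traj) == 1
        np.testing.assert_array_equal(traj.snapshots[0], small_mask)

    def test_identical_seeds_give_identical_trajectories(self, small_mask, small_params):
        t1 = simulate(small_mask, small_params, [0, 3, 6], seed=99)
        t2 = simulate(small_mask, small_params, [0, 3, 6], seed=99)
        for a, b in zip(t1.snapshots, t2.snapshots):
            np.testing.assert_array_equal(a, b)

    def test_cell_count_never_decreases(self, small_mask, small_params):
        traj = simulate(small_mask, small_params, [0, 2, 4, 6, 8], seed=4)
        counts = [s.sum() for s in traj.snapshots]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_mask_on_boundary_ring_rejected(self, small_params):
        occ = np.zeros((small_params.grid_size,) * 2, dtype=bool)
        occ[0, 5] = True
        occ[20, 20] = True
        with pytest.raises(ValueError):
            simulate(occ, small_params, [0, 1], seed=0)

    def test_recorded_fields_match_occupancy_shape(self, small_mask, small_params):
        traj = simulate(small_mask, small_params, [0, 2], seed=1, record_fields=True)
        assert len(traj.fields) == len(traj.snapshots)
        for f, s in zip(traj.fields, traj.snapshots):
            assert f.values.shape == s.shape
            assert f.values.max() <= 1.0
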