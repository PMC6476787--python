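import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tundradiv import (
    BRIMModularity,
    MatrixOrdering,
    altitude_constrained_modularity,
    altitude_ordering,
    barber_q,
    brim_optimize,
    nodf,
    optimal_nestedness_ordering,
    reciprocal_averaging,
    render_incidence,
)
from tundradiv.metacom import band_partition, reciprocal_averaging_ordering
from conftest import make_community_matrix


def exhaustive_best_q(A, max_modules=3):
    """Exact maximum Q over all bipartitions into <= max_modules modules.

    Columns are optimized greedily per row assignment, which is exact:
    given the row partition, each column's best module is independent.
    """
    A = np.asarray(A, dtype=float)
    m = A.sum()
    k, d = A.sum(1), A.sum(0)
    Bt = A - np.outer(k, d) / m
    best = -np.inf
    for rows in itertools.product(range(max_modules), repeat=A.shape[0]):
        R = np.zeros((A.shape[0], max_modules))
        R[np.arange(A.shape[0]), rows] = 1
        scores = Bt.T @ R
        best = max(best, scores.max(axis=1).sum() / m)
    return best


class TestNODF:
    def test_perfect_staircase_is_100(self, staircase):
        assert nodf(staircase).nodf == pytest.approx(100.0)

    def test_checkerboard_is_0(self):
        assert nodf(np.array([[1, 0], [0, 1]])).nodf == 0.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            nodf(np.zeros((3, 3), dtype=int))

    def test_zero_fill_rows_contribute_nothing(self):
        A = np.array([[1, 1], [0, 0], [1, 0]])
        res = nodf(A)
        assert 0.0 <= res.nodf <= 100.0

    def test_components_weighted_by_pair_counts(self, staircase):
        res = nodf(staircase)
        r, c = staircase.shape
        pooled = (res.nodf_rows * r * (r - 1) / 2 + res.nodf_cols * c * (c - 1) / 2)
        pooled /= r * (r - 1) / 2 + c * (c - 1) / 2
        assert res.nodf == pytest.approx(pooled)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_optimal_ordering_maximizes_nodf(self, seed):
        rng = np.random.default_rng(seed)
        A = (rng.random((6, 7)) < 0.5).astype(int)
        if A.sum() == 0:
            return
        opt = nodf(A).nodf
        assert 0.0 <= opt <= 100.0
        shuffled = MatrixOrdering(
            rng.permutation(6), rng.permutation(7)
        )
        assert nodf(A, shuffled).nodf <= opt + 1e-9


class TestOrderings:
    def test_sorted_matrix_gives_identity(self, staircase):
        o = optimal_nestedness_ordering(staircase)
        assert np.array_equal(o.row_order, np.arange(4))
        assert np.array_equal(o.col_order, np.arange(4))

    def test_reversed_staircase_reverses(self, staircase):
        o = optimal_nestedness_ordering(staircase[::-1])
        assert np.array_equal(o.row_order, np.arange(4)[::-1])

    def test_richness_ties_keep_input_order(self):
        A = np.array([[1, 0], [0, 1], [1, 1]])
        o = optimal_nestedness_ordering(A)
        assert o.row_order.tolist() == [2, 0, 1]

    def test_altitude_ordering_ascending_and_band_contiguous(self, default_matrix):
        from tundradiv.survey import band_label

        o = altitude_ordering(default_matrix)
        alts = default_matrix.row_meta["altitude_m"].to_numpy()[o.row_order]
        assert (np.diff(alts) >= 0).all()
        bands = [band_label(a) for a in alts]
        seen, prev = set(), None
        for b in bands:
            if b != prev:
                assert b not in seen
                seen.add(b)
            prev = b

    def test_within_mountain_concatenates_ascending_runs(self, default_matrix):
        o = altitude_ordering(default_matrix, within_mountain=True)
        meta = default_matrix.row_meta.iloc[o.row_order]
        for _, grp in meta.groupby("mountain", sort=False):
            assert (np.diff(grp["altitude_m"].to_numpy()) >= 0).all()

    def test_missing_altitude_rejected(self, default_matrix):
        bad = default_matrix.row_meta.copy()
        bad.loc[0, "altitude_m"] = np.nan
        from tundradiv import CommunityMatrix

        mat = CommunityMatrix(default_matrix.incidence, bad, default_matrix.species)
        with pytest.raises(ValueError):
            altitude_ordering(mat)


class TestReciprocalAveraging:
    def test_disjoint_blocks_separated(self):
        A = np.zeros((6, 6), dtype=int)
        A[:3, :3] = 1
        A[3:, 3:] = 1
        with pytest.warns(RuntimeWarning, match="disconnected"):
            u, v = reciprocal_averaging(A)
        assert u[:3].max() < u[3:].min()
        assert v[:3].max() < v[3:].min()

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        A = (rng.random((8, 10)) < 0.5).astype(int)
        A[A.sum(1) == 0, 0] = 1
        A[:, A.sum(0) == 0] = 0
        A = A[:, A.sum(0) > 0]
        u, v = reciprocal_averaging(A)
        perm = rng.permutation(A.shape[0])
        up, vp = reciprocal_averaging(A[perm])
        sign = np.sign(np.dot(up, u[perm])) or 1.0
        assert np.allclose(sign * up, u[perm], atol=1e-8)
        assert np.allclose(sign * vp, v, atol=1e-8)

    def test_matches_power_iteration_oracle(self):
        A = np.array(
            [[1, 1, 0, 0],
             [1, 1, 1, 0],
             [0, 1, 1, 1],
             [0, 0, 1, 1]], dtype=float
        )
        u, v = reciprocal_averaging(A)
        # independent oracle: iterated mutual averaging with weighted
        # standardization of the row scores each round
        r = A.sum(1)
        c = A.sum(0)
        w = r / r.sum()
        x = np.linspace(-1, 1, A.shape[0])
        for _ in range(2000):
            y = (A.T @ x) / c
            x = (A @ y) / r
            x = x - (w * x).sum()
            x = x / np.sqrt((w * x * x).sum())
        sign = np.sign(np.dot(x, u)) or 1.0
        assert np.allclose(sign * x, u, atol=1e-6)

    def test_highest_altitude_plot_nonnegative(self, default_matrix):
        u, _ = reciprocal_averaging(default_matrix)
        ref = int(np.argmax(default_matrix.row_meta["altitude_m"].to_numpy()))
        assert u[ref] >= 0


class TestBarberQ:
    def test_single_module_zero(self, two_block):
        assert barber_q(two_block, np.zeros(4, int), np.zeros(4, int)) == pytest.approx(0.0)

    def test_two_block_hand_value(self, two_block):
        rows = np.array([0, 0, 1, 1])
        cols = np.array([0, 0, 1, 1])
        assert barber_q(two_block, rows, cols) == pytest.approx(0.5)

    def test_invariant_to_matrix_permutation(self, two_block):
        rng = np.random.default_rng(0)
        rows = np.array([0, 0, 1, 1])
        cols = np.array([0, 0, 1, 1])
        rp, cp = rng.permutation(4), rng.permutation(4)
        q = barber_q(two_block[np.ix_(rp, cp)], rows[rp], cols[cp])
        assert q == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            barber_q(np.zeros((2, 2), int), np.zeros(2, int), np.zeros(2, int))


class TestBRIM:
    def test_recovers_two_blocks(self, two_block):
        res = brim_optimize(two_block, n_restarts=5, seed=0)
        assert res.Q == pytest.approx(0.5)
        assert res.n_modules == 2
        assert res.plot_modules[0] == res.plot_modules[1]
        assert res.plot_modules[0] != res.plot_modules[2]

    def test_sweeps_never_decrease_q(self):
        from tundradiv.metacom import _brim_sweeps

        rng = np.random.default_rng(5)
        A = (rng.random((10, 12)) < 0.4).astype(float)
        A[A.sum(1) == 0, 0] = 1
        m = A.sum()
        Bt = A - np.outer(A.sum(1), A.sum(0)) / m
        for _ in range(10):
            start = rng.integers(0, 3, size=10)
            R = np.zeros((10, 3))
            R[np.arange(10), start] = 1
            greedy_cols = np.argmax(Bt.T @ R, axis=1)
            q0 = barber_q(A, start, greedy_cols)
            q, _, _ = _brim_sweeps(Bt, start.copy(), 3, m)
            assert q >= q0 - 1e-12

    def test_q_bounded_by_one(self, default_matrix):
        res = brim_optimize(default_matrix, n_restarts=3, seed=1)
        assert res.Q <= 1.0

    def test_exhaustive_oracle_small_matrices(self):
        """BRIM matches the exact <=3-module optimum on >=90% of 20 5x5s."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            A = (rng.random((5, 5)) < 0.5).astype(int)
            if A.sum() == 0:
                hits += 1
                continue
            best = exhaustive_best_q(A, max_modules=3)
            got = brim_optimize(A, n_restarts=20, seed=seed, max_modules=3).Q
            assert got <= best + 1e-9
            hits += abs(got - best) < 1e-9
        assert hits >= 18

    def test_deterministic_under_seed(self, two_block):
        a = brim_optimize(two_block, n_restarts=4, seed=9)
        b = brim_optimize(two_block, n_restarts=4, seed=9)
        assert a.Q == b.Q
        assert np.array_equal(a.plot_modules, b.plot_modules)

    def test_estimator_interface(self, two_block):
        est = BRIMModularity(n_restarts=5, seed=0).fit(two_block)
        assert est.modularity_ == pytest.approx(0.5)
        assert est.labels_.shape == (4,)
        assert est.get_params()["n_restarts"] == 5
        est.set_params(seed=3)
        assert est.seed == 3


class TestAltitudeConstrainedModularity:
    def test_unconstrained_at_least_band_partition(self, default_matrix):
        rows, cols = band_partition(default_matrix)
        q_band = barber_q(default_matrix, rows, cols)
        res = brim_optimize(default_matrix, n_restarts=5, seed=0)
        assert res.Q >= q_band - 1e-12

    def test_constrained_close_to_unconstrained_when_modular(self):
        from tundradiv import SimulationConfig, simulate_survey

        sim = simulate_survey(
            SimulationConfig(seed=13, turnover_strength=6.0, core_fraction=0.0)
        )
        mat = sim.matrix()
        free = brim_optimize(mat, n_restarts=10, seed=0).Q
        cons = altitude_constrained_modularity(mat, n_restarts=10, seed=0).Q
        assert abs(free - cons) < 0.01


class TestRenderIncidence:
    def test_checkerboard_blocks(self, tmp_path):
        A = np.array([[1, 0], [0, 1]])
        px = render_incidence(A, path=tmp_path / "c.png", cell=2)
        assert px.shape == (4, 4)
        assert (px[:2, :2] == 0).all() and (px[:2, 2:] == 255).all()

    def test_pixel_count_round_trip(self, tmp_path, default_matrix):
        from PIL import Image

        path = tmp_path / "m.png"
        o = optimal_nestedness_ordering(default_matrix)
        render_incidence(default_matrix, o, path, cell=1)
        px = np.asarray(Image.open(path))
        assert (px == 0).sum() == default_matrix.incidence.sum()

    def test_staircase_renders_its_own_triangle(self, staircase):
        px = render_incidence(
            staircase, optimal_nestedness_ordering(staircase), cell=1
        )
        assert ((px == 0) == staircase.astype(bool)).all()
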