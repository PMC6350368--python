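import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rwbrmda import (
    SimilarityMatrix,
    WalkParams,
    all_walks,
    initial_distribution,
    stationary_solve,
    transition_matrix,
    walk_to_stationary,
)
from rwbrmda.random_walk import profiles_to_matrix, write_profiles

from conftest import random_prob_vector, random_stochastic


def sim_from(S):
    S = np.asarray(S, dtype=float)
    return SimilarityMatrix([f"m{i}" for i in range(S.shape[0])], S, role="SM")


class TestTransitionMatrix:
    def test_uniform_similarity(self):
        T = transition_matrix(sim_from([[1, 1], [1, 1]]))
        assert np.allclose(T, 0.5)

    def test_hand_normalization(self):
        T = transition_matrix(sim_from([[1, 0.5], [0.5, 1]]))
        assert np.allclose(T, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]])

    def test_stochastic_input_unchanged(self):
        # symmetric doubly-stochastic mix of I, the uniform matrix and the
        # reversal permutation: a valid similarity whose columns already sum to 1
        rng = np.random.default_rng(0)
        n = 6
        w = rng.dirichlet(np.ones(3))
        T0 = w[0] * np.eye(n) + w[1] * np.full((n, n), 1 / n) + w[2] * np.eye(n)[::-1]
        assert np.allclose(transition_matrix(sim_from(T0)), T0)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(1)
        S = rng.random((7, 7))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        assert np.allclose(transition_matrix(sim_from(S)).sum(axis=0), 1.0)

    def test_zero_column_names_the_mirna(self):
        with pytest.raises(ValueError, match="m1"):
            transition_matrix(sim_from([[1, 0], [0, 0]]))


class TestInitialDistribution:
    def test_hand_normalization(self):
        sm = sim_from([[1, 0.5, 0.5], [0.5, 1, 0], [0.5, 0, 1]])
        assert np.allclose(initial_distribution(sm, 0), [0.5, 0.25, 0.25])

    def test_one_hot_row(self):
        sm = sim_from([[1, 0], [0, 1]])
        assert np.allclose(initial_distribution(sm, 0), [1, 0])

    def test_uniform_row(self):
        sm = sim_from(np.full((4, 4), 0.3))
        assert np.allclose(initial_distribution(sm, 2), 0.25)


class TestWalkToStationary:
    def test_identity_transition_fixes_p0(self):
        p0 = np.array([0.2, 0.3, 0.5])
        prof = walk_to_stationary(np.eye(3), p0, WalkParams(restart=0.4))
        assert np.allclose(prof.p_inf, p0)
        assert prof.converged

    def test_hand_example_matches_closed_form(self):
        T = np.full((2, 2), 0.5)
        prof = walk_to_stationary(T, np.array([1.0, 0.0]), WalkParams(restart=0.4))
        assert np.allclose(prof.p_inf, [0.7, 0.3], atol=1e-5)

    def test_mass_conserved(self):
        rng = np.random.default_rng(2)
        T = random_stochastic(rng, 10)
        prof = walk_to_stationary(T, random_prob_vector(rng, 10), WalkParams())
        assert prof.p_inf.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("restart", [0.1, 0.5, 0.9])
    def test_matches_linear_solve_oracle(self, restart):
        rng = np.random.default_rng(3)
        params = WalkParams(restart=restart)
        for _ in range(10):
            n = int(rng.integers(2, 21))
            T = random_stochastic(rng, n)
            p0 = random_prob_vector(rng, n)
            prof = walk_to_stationary(T, p0, params)
            exact = stationary_solve(T, p0, restart)
            assert np.abs(prof.p_inf - exact).sum() < 1e-5

    def test_restart_limit_returns_p0(self):
        rng = np.random.default_rng(4)
        T = random_stochastic(rng, 8)
        p0 = random_prob_vector(rng, 8)
        prof = walk_to_stationary(T, p0, WalkParams(restart=0.999))
        assert np.abs(prof.p_inf - p0).sum() < 2e-3

    def test_max_iter_flagged(self):
        rng = np.random.default_rng(5)
        T = random_stochastic(rng, 5)
        prof = walk_to_stationary(
            T, random_prob_vector(rng, 5), WalkParams(restart=0.1, max_iter=2)
        )
        assert not prof.converged
        assert prof.iterations == 2

    def test_invalid_restart_rejected(self):
        for r in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                WalkParams(restart=r)


class TestAllWalks:
    def test_one_profile_per_mirna_in_order(self, small_fixture, small_profiles):
        assoc, _, _ = small_fixture
        _, profiles = small_profiles
        assert len(profiles) == assoc.n_mirna
        assert [p.seed_index for p in profiles] == list(range(assoc.n_mirna))
        assert all(p.converged for p in profiles)

    def test_batched_engine_matches_per_seed_iteration(self):
        rng = np.random.default_rng(6)
        S = rng.random((12, 12))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        sm = sim_from(S)
        params = WalkParams()
        T = transition_matrix(sm)
        for prof in all_walks(sm, params):
            single = walk_to_stationary(
                T, initial_distribution(sm, prof.seed_index), params
            )
            assert np.allclose(prof.p_inf, single.p_inf, atol=1e-12, rtol=0)
            assert prof.iterations == single.iterations

    def test_structurally_identical_nodes_have_permuted_profiles(self):
        # nodes 0 and 1 are exchangeable by construction
        S = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.2], [0.2, 0.2, 1.0]])
        p0, p1 = all_walks(sim_from(S), WalkParams())[:2]
        swap = np.array([1, 0, 2])
        assert np.allclose(p0.p_inf, p1.p_inf[swap], atol=1e-6)

    def test_profile_matrix_export_round_trips(self, small_fixture, small_profiles, tmp_path):
        import pandas as pd

        assoc, _, _ = small_fixture
        _, profiles = small_profiles
        path = tmp_path / "profiles.tsv"
        write_profiles(profiles, assoc.mirna_ids, path)
        back = pd.read_csv(path, sep="\t", index_col=0)
        assert list(back.index) == assoc.mirna_ids
        assert np.allclose(back.to_numpy(), profiles_to_matrix(profiles), rtol=1e-10)

    def test_block_structure_concentrates_stationary_mass(self, small_fixture, small_profiles):
        _, _, blocks = small_fixture
        _, profiles = small_profiles
        for prof in profiles:
            mine = blocks == blocks[prof.seed_index]
            within = prof.p_inf[mine].sum() - prof.p_inf[prof.seed_index]
            assert within > prof.p_inf[~mine].sum() * (mine.sum() - 1) / (~mine).sum()


class TestWalkProperties:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        n=st.integers(min_value=2, max_value=15),
        restart=st.floats(min_value=0.05, max_value=0.95),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_stationary_vector_is_probability_and_solves_fixed_point(
        self, n, restart, seed
    ):
        rng = np.random.default_rng(seed)
        T = random_stochastic(rng, n)
        p0 = random_prob_vector(rng, n)
        params = WalkParams(restart=restart)
        prof = walk_to_stationary(T, p0, params)
        assert (prof.p_inf >= 0).all()
        assert prof.p_inf.sum() == pytest.approx(1.0, abs=1e-9)
        exact = stationary_solve(T, p0, restart)
        assert np.abs(prof.p_inf - exact).sum() < 10 * params.cutoff


class TestContraction:
    def test_iteration_count_within_contraction_bound(self):
        rng = np.random.default_rng(7)
        for restart in (0.1, 0.3, 0.5, 0.7, 0.9):
            params = WalkParams(restart=restart)
            bound = np.log(params.cutoff) / np.log(1 - restart) + 2
            for _ in range(5):
                n = int(rng.integers(3, 21))
                prof = walk_to_stationary(
                    random_stochastic(rng, n), random_prob_vector(rng, n), params
                )
                assert prof.iterations <= bound
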