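"""Non-backtracking walk: sampler, Monte Carlo model and exact oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maturewalk import (ScalarMap, WalkConfig, WalkState,
                        expected_scores_exact, run_model, sample_walk,
                        scores_vs_scalar, step_distribution)
from maturewalk.walk import WalkError

from conftest import make_connectome, random_connectome


def path_graph():
    return make_connectome(["TER"] * 3, [(0, 1, 1), (1, 2, 1)])


def triangle(w=(1.0, 1.0, 1.0)):
    return make_connectome(["TER"] * 3,
                           [(0, 1, w[0]), (1, 2, w[1]), (0, 2, w[2])])


class TestStepDistribution:
    def test_excludes_previous_and_normalizes_by_weight(self):
        c = make_connectome(["TER"] * 4,
                            [(0, 1, 1.0), (0, 2, 3.0), (0, 3, 6.0)])
        dist = step_distribution(c, WalkState(current=0, previous=3))
        assert dist == pytest.approx({1: 0.25, 2: 0.75})

    def test_forced_move(self):
        dist = step_distribution(path_graph(), WalkState(current=1, previous=0))
        assert dist == {2: 1.0}

    def test_seed_state_uses_all_neighbors(self):
        c = make_connectome(["TER"] * 3, [(0, 1, 2.0), (0, 2, 2.0)])
        dist = step_distribution(c, WalkState(current=0, previous=None))
        assert dist == pytest.approx({1: 0.5, 2: 0.5})

    def test_dead_end_returns_empty(self):
        dist = step_distribution(path_graph(), WalkState(current=2, previous=1))
        assert dist == {}

    def test_isolated_region_raises(self):
        c = make_connectome(["TER"] * 3, [(0, 1, 1)])
        with pytest.raises(WalkError):
            step_distribution(c, WalkState(current=2))


class TestSampleWalk:
    def test_path_graph_terminates_at_dead_end(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert sample_walk(path_graph(), 0, 5, rng) == [0, 1, 2]

    def test_path_graph_backtrack_policy_oscillates(self):
        rng = np.random.default_rng(0)
        path = sample_walk(path_graph(), 0, 5, rng,
                           dead_end_policy="allow_backtrack")
        # dead end at 2 bounces back; the no-back rule then forces 1 -> 0
        assert path == [0, 1, 2, 1, 0, 1]

    def test_triangle_forced_around_cycle(self):
        """After the first step the no-back rule forces the walk to circle."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            path = sample_walk(triangle(), 0, 6, rng)
            assert len(path) == 7
            if path[1] == 1:
                assert path == [0, 1, 2, 0, 1, 2, 0]
            else:
                assert path == [0, 2, 1, 0, 2, 1, 0]

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_never_backtracks(self, seed):
        rng = np.random.default_rng(seed)
        c = random_connectome(12, 4.0, rng)
        path = sample_walk(c, int(rng.integers(12)), 15, rng)
        for a, b, cnode in zip(path, path[1:], path[2:]):
            assert a != cnode


class TestRunModel:
    def test_deterministic_path_counts(self):
        scores = run_model(path_graph(),
                           WalkConfig(seeds=[0], n_steps=4, n_reps=1))
        # arrivals: node 1 at t=1, node 2 at t=2, dead end afterwards
        assert scores.node_per_step[1].tolist() == [1, 0, 0, 0]
        assert scores.node_per_step[2].tolist() == [0, 1, 0, 0]
        assert scores.alive.tolist() == [1, 1, 0, 0]
        assert scores.seed_occupancy.tolist() == [1, 0, 0]

    def test_per_step_counts_sum_to_alive(self):
        rng = np.random.default_rng(2)
        c = random_connectome(15, 4.0, rng)
        scores = run_model(c, WalkConfig(seeds=[0, 3], n_steps=8, n_reps=200,
                                         rng_seed=9))
        assert scores.node_per_step.sum(axis=0) == pytest.approx(scores.alive)
        assert scores.edge_per_step.sum(axis=0) == pytest.approx(scores.alive)

    def test_cumulative_monotone(self):
        rng = np.random.default_rng(3)
        c = random_connectome(15, 4.0, rng)
        scores = run_model(c, WalkConfig(seeds=[1], n_steps=6, n_reps=100,
                                         rng_seed=4))
        assert (np.diff(scores.node_cumulative(), axis=1) >= 0).all()
        assert (np.diff(scores.edge_cumulative(), axis=1) >= 0).all()

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(5)
        c = random_connectome(20, 5.0, rng)
        cfg = WalkConfig(seeds=[0, 5], n_steps=10, n_reps=300, rng_seed=77)
        s1, s2 = run_model(c, cfg), run_model(c, cfg)
        assert np.array_equal(s1.node_per_step, s2.node_per_step)
        assert np.array_equal(s1.edge_per_step, s2.edge_per_step)

    def test_invariant_to_global_weight_rescaling(self):
        """Normalizing streamline counts by their total leaves every
        transition probability, hence the whole model output, unchanged."""
        rng = np.random.default_rng(6)
        c = random_connectome(15, 4.0, rng)
        from maturewalk import Connectome, Edge
        scaled = Connectome(
            parcellation=c.parcellation,
            edges=[Edge(e.i, e.j, e.weight * 1e-4, e.length_mm,
                        e.presence_count) for e in c.edges])
        cfg = WalkConfig(seeds=[2], n_steps=8, n_reps=200, rng_seed=8)
        assert np.array_equal(run_model(c, cfg).node_per_step,
                              run_model(scaled, cfg).node_per_step)

    def test_seed_absent_raises(self):
        with pytest.raises(WalkError):
            run_model(path_graph(), WalkConfig(seeds=[9], n_reps=1))

    def test_seed_occupancy_flag_adds_to_cumulative(self):
        cfg = WalkConfig(seeds=[0], n_steps=3, n_reps=5,
                         count_seed_occupancy=True)
        scores = run_model(path_graph(), cfg)
        assert scores.node_cumulative()[0, 0] == 5  # seed occupancy at t=0


class TestExactOracle:
    def test_forced_chain(self):
        exp = expected_scores_exact(path_graph(), 0, 4)
        assert exp.node_mass[1].tolist() == [1, 0, 0, 0]
        assert exp.node_mass[2].tolist() == [0, 1, 0, 0]
        assert exp.alive.tolist() == [1, 1, 0, 0]

    def test_triangle_hand_enumerated(self):
        """Equal-weight triangle from seed 0: mass 1/2 per branch, then the
        cycle is deterministic per branch; node transit masses alternate."""
        exp = expected_scores_exact(triangle(), 0, 6)
        # t=1: arrive at 1 or 2 with mass 1/2 each
        assert exp.node_mass[:, 0].tolist() == [0, 0.5, 0.5]
        # t=2: branch 0->1 forced to 2, branch 0->2 forced to 1
        assert exp.node_mass[:, 1].tolist() == [0, 0.5, 0.5]
        # t=3: both branches forced back to 0
        assert exp.node_mass[:, 2].tolist() == [1, 0, 0]
        assert exp.alive.tolist() == [1.0] * 6

    def test_mass_conservation(self):
        rng = np.random.default_rng(7)
        c = random_connectome(18, 4.0, rng)
        exp = expected_scores_exact(c, 0, 10)
        assert exp.node_mass.sum(axis=0) == pytest.approx(exp.alive)
        assert (exp.alive <= 1 + 1e-12).all()
        assert (np.diff(exp.alive) <= 1e-12).all()

    def test_state_cap_enforced(self):
        rng = np.random.default_rng(8)
        c = random_connectome(10, 3.0, rng)
        with pytest.raises(WalkError):
            expected_scores_exact(c, 0, 3, state_cap=2)

    def test_monte_carlo_matches_exact_on_four_cycle(self):
        """4-cycle, equal weights: per-step node frequencies within 3
        binomial SEs of the exact oracle."""
        c = make_connectome(["TER"] * 4,
                            [(0, 1, 1), (1, 2, 1), (2, 3, 1), (0, 3, 1)])
        n_reps = 100_000
        scores = run_model(c, WalkConfig(seeds=[0], n_steps=3, n_reps=n_reps,
                                         rng_seed=13))
        exp = expected_scores_exact(c, 0, 3)
        freq = scores.node_per_step / n_reps
        se = np.sqrt(exp.node_mass * (1 - exp.node_mass) / n_reps)
        assert (np.abs(freq - exp.node_mass) <= 3 * se + 1e-12).all()


class TestScoresVsScalar:
    def test_perfect_anti_rank_gives_minus_one(self):
        rng = np.random.default_rng(9)
        c = random_connectome(12, 4.0, rng)
        cfg = WalkConfig(seeds=[0], n_steps=4, n_reps=500, rng_seed=3)
        scores = run_model(c, cfg)
        t_star = 2
        s = ScalarMap(modality="ADC")
        cum = scores.node_cumulative()
        s.node_values = {r: -float(cum[r, t_star - 1]) for r in range(12)}
        s.edge_values = {(e.i, e.j): float(rng.normal()) for e in c.edges}
        curves = scores_vs_scalar(scores, s, c)
        assert curves["node"][t_star - 1].r == pytest.approx(-1.0)

    def test_excludes_subcortical_regions(self):
        groups = ["SUB", "SUB"] + ["TER"] * 6
        edges = [(i, j, 1.0) for i in range(8) for j in range(i + 1, 8)]
        c = make_connectome(groups, edges)
        scores = run_model(c, WalkConfig(seeds=[2], n_steps=3, n_reps=50,
                                         rng_seed=1))
        s = ScalarMap(modality="ADC")
        rng = np.random.default_rng(10)
        s.node_values = {r: float(rng.normal()) for r in range(8)}
        s.edge_values = {(e.i, e.j): float(rng.normal()) for e in c.edges}
        curves = scores_vs_scalar(scores, s, c)
        assert curves["node"][0].n == 6  # SUB regions left out
        # edge side: only edges between included regions
        n_incl_edges = sum(1 for e in c.edges if e.i >= 2 and e.j >= 2)
        assert curves["edge"][0].n == n_incl_edges

    def test_permuted_scalar_uncorrelated(self):
        """With scalars permuted at random, r stays small on average."""
        rng = np.random.default_rng(11)
        c = random_connectome(30, 5.0, rng)
        scores = run_model(c, WalkConfig(seeds=[0, 1], n_steps=5, n_reps=500,
                                         rng_seed=2))
        cum = scores.node_cumulative()
        rs = []
        for _ in range(200):
            s = ScalarMap(modality="ADC")
            perm = rng.permutation(cum[:, 2])
            s.node_values = {r: float(perm[r]) for r in range(30)}
            s.edge_values = {(e.i, e.j): float(rng.normal()) for e in c.edges}
            curves = scores_vs_scalar(scores, s, c)
            rs.append(curves["node"][2].r)
        assert abs(np.mean(rs)) < 0.1
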