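"""JT trend test, correlation battery and descriptive network tables."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from maturewalk import (ScalarMap, connected_vs_unconnected, correlate,
                        group_edge_counts, jt_test, length_summary,
                        pairmean_vs_tract, region_vs_incident)
from maturewalk.stats import StatsError, n_distinct_assignments

from conftest import make_connectome


def jt_u_brute(groups_of_values):
    """Independent JT statistic: direct double loop over ordered group pairs."""
    u = 0.0
    for a in range(len(groups_of_values)):
        for b in range(a + 1, len(groups_of_values)):
            for x in groups_of_values[a]:
                for y in groups_of_values[b]:
                    if x < y:
                        u += 1.0
                    elif x == y:
                        u += 0.5
    return u


class TestJT:
    def test_worked_example_statistic_and_moments(self):
        """Maximally ordered groups [1,2],[3,4],[5,6]: U = 12 (every cross
        pair ascending), null mean 6, variance 456/72, z ~ 2.384."""
        res = jt_test([1, 2, 3, 4, 5, 6], [0, 0, 1, 1, 2, 2], exact=True)
        assert res.U == 12.0
        assert res.z == pytest.approx(6 / np.sqrt(456 / 72), abs=1e-4)
        assert res.z == pytest.approx(2.384, abs=1e-3)

    def test_worked_example_exact_p_matches_enumeration(self):
        """Exact p equals exhaustive enumeration over all 90 distinct label
        permutations (independent itertools oracle)."""
        values = [1, 2, 3, 4, 5, 6]
        sizes = [2, 2, 2]
        assert n_distinct_assignments(sizes) == 90
        u_obs = jt_u_brute([[1, 2], [3, 4], [5, 6]])
        count = total = 0
        seen = set()
        for perm in itertools.permutations(range(6)):
            key = (frozenset(perm[:2]), frozenset(perm[2:4]), frozenset(perm[4:]))
            if key in seen:
                continue
            seen.add(key)
            total += 1
            grouped = [[values[i] for i in perm[:2]],
                       [values[i] for i in perm[2:4]],
                       [values[i] for i in perm[4:]]]
            if jt_u_brute(grouped) >= u_obs:
                count += 1
        assert total == 90
        res = jt_test(values, [0, 0, 1, 1, 2, 2], exact=True)
        assert res.p_perm == pytest.approx(count / total)
        assert res.p_perm == pytest.approx(1 / 90)

    def test_complete_ties_give_null_center(self):
        res = jt_test([7.0] * 9, [0, 0, 0, 1, 1, 1, 2, 2, 2], n_perm=999)
        sizes = np.array([3, 3, 3])
        mu = (81 - (sizes**2).sum()) / 4
        assert res.U == mu
        assert res.z == 0.0

    def test_two_groups_reduce_to_mann_whitney(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=8)
        y = rng.normal(loc=0.5, size=11)
        res = jt_test(np.concatenate([x, y]), [0] * 8 + [1] * 11, n_perm=999)
        # U counts pairs with first-group value below second-group value,
        # i.e. the Mann-Whitney U of y over x
        assert res.U == sps.mannwhitneyu(y, x).statistic

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=20)
        grp = rng.integers(0, 4, size=20)
        while len(set(grp.tolist())) < 4:
            grp = rng.integers(0, 4, size=20)
        res = jt_test(vals, grp, n_perm=999)
        grouped = [vals[grp == g].tolist() for g in range(4)]
        assert res.U == pytest.approx(jt_u_brute(grouped))

    def test_monotone_power(self):
        """An added ordered shift strictly increases the mean z."""
        rng = np.random.default_rng(0)
        sizes = [12, 12, 34, 32]
        grp = np.repeat(np.arange(4), sizes)
        z0, z1 = [], []
        for _ in range(30):
            base = rng.normal(size=90)
            z0.append(jt_test(base, grp, n_perm=999, rng_seed=1).z)
            z1.append(jt_test(base + 0.5 * grp, grp, n_perm=999, rng_seed=1).z)
        assert np.mean(z1) > np.mean(z0) + 1

    def test_input_validation(self):
        with pytest.raises(StatsError):
            jt_test([1, 2], [0, 0], n_perm=999)  # single group
        with pytest.raises(StatsError):
            jt_test([1, 2, 3], [0, 0, 1], n_perm=5)  # too few permutations

    def test_dict_input_accepted(self):
        res = jt_test({0: 1.0, 1: 2.0, 2: 3.0, 3: 4.0},
                      {0: "PRIM", 1: "PRIM", 2: "TER", 3: "TER"}, n_perm=999)
        assert res.U == 4.0


class TestCorrelate:
    def test_perfect_linear_pearson(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1, "pearson").r == pytest.approx(1.0)

    def test_monotone_nonlinear_spearman(self):
        x = np.linspace(-2, 2, 15)
        res = correlate(x, x**3, "spearman")
        assert res.r == pytest.approx(1.0)
        assert correlate(x, x**3, "pearson").r < 1.0

    def test_matches_from_definition_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=10)
        y = 0.3 * x + rng.normal(size=10)
        r_def = (np.sum((x - x.mean()) * (y - y.mean())) /
                 np.sqrt(np.sum((x - x.mean())**2) * np.sum((y - y.mean())**2)))
        assert correlate(x, y, "pearson").r == pytest.approx(r_def, abs=1e-12)

    def test_zero_variance_names_side(self):
        with pytest.raises(StatsError, match="x"):
            correlate([1, 1, 1], [1, 2, 3])
        with pytest.raises(StatsError, match="y"):
            correlate([1, 2, 3], [1, 1, 1])


def _degree_map(c):
    s = ScalarMap(modality="ADC")
    deg = c.degrees()
    s.node_values = {r: float(deg[r]) for r in range(c.n_regions)}
    s.edge_values = {(e.i, e.j): 0.5 * (deg[e.i] + deg[e.j]) for e in c.edges}
    return s


class TestNetworkCorrelations:
    def test_region_vs_incident_brute_force(self):
        """Node value = degree, edge value = mean endpoint degree, on a fixed
        6-node graph; r recomputed by hand from the adjacency lists."""
        c = make_connectome(["TER"] * 6,
                            [(0, 1, 1), (0, 2, 1), (1, 2, 1), (2, 3, 1),
                             (3, 4, 1), (3, 5, 1)])
        s = _degree_map(c)
        res = region_vs_incident(c, s)
        adj = c.neighbors()
        x, y = [], []
        for r in range(6):
            if not adj[r]:
                continue
            x.append(s.node_values[r])
            y.append(np.mean([s.edge_values[tuple(sorted((r, k)))]
                              for k, _ in adj[r]]))
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
        assert res.n == 6

    def test_pairmean_vs_tract_strata_split_at_mean_length(self):
        rng = np.random.default_rng(5)
        edges = [(0, 1, 1, 10.0), (1, 2, 1, 20.0), (2, 3, 1, 30.0),
                 (3, 4, 1, 100.0)]  # mean length 40 -> long = {100}, 3 short
        c = make_connectome(["TER"] * 5, edges)
        s = ScalarMap(modality="ADC")
        s.node_values = {r: float(rng.uniform(1000, 2000)) for r in range(5)}
        s.edge_values = {(e.i, e.j): float(rng.uniform(1000, 2000))
                         for e in c.edges}
        assert pairmean_vs_tract(c, s, "all").n == 4
        assert pairmean_vs_tract(c, s, "short").n == 3
        with pytest.raises(StatsError):  # only one long edge -> n < 3
            pairmean_vs_tract(c, s, "long")

    def test_pairmean_ties_at_mean_go_short(self):
        edges = [(0, 1, 1, 10.0), (1, 2, 1, 10.0), (2, 3, 1, 10.0),
                 (3, 4, 1, 10.0)]  # all lengths equal the mean
        c = make_connectome(["TER"] * 5, edges)
        rng = np.random.default_rng(6)
        s = ScalarMap(modality="ADC")
        s.node_values = {r: float(rng.normal()) for r in range(5)}
        s.edge_values = {(e.i, e.j): float(rng.normal()) for e in c.edges}
        assert pairmean_vs_tract(c, s, "short").n == 4

    def test_constant_edge_values_raise(self):
        c = make_connectome(["TER"] * 4, [(0, 1, 1), (1, 2, 1), (2, 3, 1)])
        s = ScalarMap(modality="ADC")
        s.node_values = {r: float(r) for r in range(4)}
        s.edge_values = {(e.i, e.j): 5.0 for e in c.edges}
        with pytest.raises(StatsError):
            pairmean_vs_tract(c, s)

    def test_connected_vs_unconnected_order_invariant(self, bundle):
        """The duplicated-orderings estimate is symmetric in i and j by
        construction; check the connected-pair r against a direct
        computation with both orderings stacked."""
        c = bundle.consensus
        s = bundle.scalar_maps["ADC"]
        conn, unconn = connected_vs_unconnected(c, s, n_perm=999, rng_seed=0)
        a = [s.node_values[e.i] for e in c.edges]
        b = [s.node_values[e.j] for e in c.edges]
        r_direct = np.corrcoef(a + b, b + a)[0, 1]
        assert conn.r == pytest.approx(r_direct, abs=1e-12)
        assert conn.n == c.n_edges
        assert unconn.n == 4005 - c.n_edges

    def test_connected_exceeds_unconnected_on_forward_model(self):
        """Connected region pairs share more scalar variance than
        unconnected ones — a generator property, checked across seeds."""
        from maturewalk import GeneratorConfig, generate_study
        diffs = []
        for seed in range(1, 9):
            b = generate_study(GeneratorConfig(rng_seed=seed))
            conn, unconn = connected_vs_unconnected(
                b.consensus, b.scalar_maps["ADC"], n_perm=999, rng_seed=0)
            diffs.append(conn.r - unconn.r)
        assert sum(d > 0 for d in diffs) >= 7
        assert np.mean(diffs) > 0.05


class TestDescriptives:
    def test_single_cross_group_edge_counted_once(self):
        c = make_connectome(["PRIM", "SEC"], [(0, 1, 1)])
        t = group_edge_counts(c)
        assert t.loc["PRIM", "SEC"] == 1
        assert t.to_numpy().sum() == 1

    def test_complete_graph_two_sub_two_ter(self):
        edges = [(i, j, 1) for i in range(4) for j in range(i + 1, 4)]
        c = make_connectome(["SUB", "SUB", "TER", "TER"], edges)
        t = group_edge_counts(c)
        assert t.loc["SUB", "SUB"] == 1
        assert t.loc["TER", "TER"] == 1
        assert t.loc["SUB", "TER"] == 4
        assert t.to_numpy().sum() == 6

    def test_empty_connectome_zero_table(self):
        c = make_connectome(["SUB", "TER"], [])
        assert group_edge_counts(c).to_numpy().sum() == 0

    def test_counts_conserve_edge_total(self, bundle):
        c = bundle.consensus
        assert group_edge_counts(c).to_numpy().sum() == c.n_edges

    def test_length_summary_long_short_partition(self, bundle):
        summ = length_summary(bundle.consensus)
        assert summ["n_long"] + summ["n_short"] == summ["n_edges"]
        assert summ["n_short"] > summ["n_long"]  # right-skewed lengths
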