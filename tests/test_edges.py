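import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pggcoevo.edges import (
    apply_edge_breaking,
    breaking_probability,
    breaking_probability_table,
    dominant_nodes,
    edge_breaking_value,
    reconnect_dominant,
    reconnect_isolated,
    update_weight,
)
from pggcoevo.graph import COOPERATE, DEFECT, make_ring_lattice
from pggcoevo.params import GameParams
from pggcoevo.payoff import play_round

from conftest import FakeRng, build_graph


def poisson_cdf_bruteforce(w, lam):
    """Independent oracle: the partial factorial sum of the Poisson pmf."""
    return sum(math.exp(-lam) * lam**m / math.factorial(m) for m in range(w + 1))


class TestBreakingProbability:
    @pytest.mark.parametrize("w", range(11))
    def test_matches_factorial_sum(self, w):
        assert breaking_probability(w, 6.0) == pytest.approx(
            poisson_cdf_bruteforce(w, 6.0), abs=1e-12
        )

    def test_reference_values(self):
        assert breaking_probability(0, 6.0) == pytest.approx(math.exp(-6), abs=1e-12)
        assert breaking_probability(6, 6.0) == pytest.approx(0.6063, abs=5e-5)
        assert breaking_probability(10, 6.0) == pytest.approx(0.9574, abs=5e-5)

    def test_monotone_in_weight(self):
        table = breaking_probability_table(10, 6.0)
        assert np.all(np.diff(table) > 0)
        assert table[0] > 0 and table[-1] < 1

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            breaking_probability(-1, 6.0)
        with pytest.raises(ValueError):
            breaking_probability(3, 0.0)


class TestUpdateWeight:
    @pytest.mark.parametrize(
        "w,value,expect",
        [(0, 1.5, 0), (6, -0.2, 9), (9, -1.0, 10), (5, 0.3, 4), (10, -0.5, 10)],
    )
    def test_rule_and_clamping(self, w, value, expect):
        assert update_weight(w, value, 10) == expect

    def test_zero_value_tie_handling(self):
        # a payoff-dead edge counts as unsatisfying by default; the
        # lenient reading treats it as satisfied
        assert update_weight(4, 0.0, 10) == 7
        assert update_weight(4, 0.0, 10, zero_satisfies=True) == 3

    def test_rejects_out_of_range_weight(self):
        with pytest.raises(ValueError):
            update_weight(11, 1.0, 10)

    @given(w=st.integers(0, 10), value=st.floats(-5, 5, allow_nan=False))
    def test_stays_in_range(self, w, value):
        assert 0 <= update_weight(w, value, 10) <= 10


class TestEdgeBreakingValue:
    def test_all_defect_both_modes_zero(self):
        g = make_ring_lattice(10, 4, seed=0, init_coop_fraction=0.0)
        play_round(g, 2.0)
        for mode in ("edge_attributed", "node_total"):
            assert edge_breaking_value(g, 0, 1, 2.0, mode) == 0.0

    def test_all_cooperate_node_total(self):
        g = make_ring_lattice(10, 4, seed=0, init_coop_fraction=1.0)
        play_round(g, 2.0)
        # each endpoint earned (k0+1)(r-1) = 5
        assert edge_breaking_value(g, 0, 1, 2.0, "node_total") == pytest.approx(10.0)

    def test_edge_attributed_symmetrization(self):
        g = build_graph(
            [(0, 1), (0, 2), (1, 3)], [COOPERATE, COOPERATE, DEFECT, DEFECT]
        )
        r = 2.0
        # x-centered game: g=3, n_c=2; y-centered game: g=3, n_c=2
        expect = ((r - 1) / 3 + (r * 2 / 3 - 1)) * 2
        assert edge_breaking_value(g, 0, 1, r) == pytest.approx(expect)
        # symmetric in the endpoint order
        assert edge_breaking_value(g, 1, 0, r) == pytest.approx(expect)

    def test_missing_edge_rejected(self, star_graph):
        with pytest.raises(ValueError):
            edge_breaking_value(star_graph, 1, 2, 2.0)


class TestApplyEdgeBreaking:
    def test_stubbed_rng_updates_weights_only(self):
        g = make_ring_lattice(10, 4, seed=0, init_coop_fraction=1.0)
        play_round(g, 3.0)
        removed = apply_edge_breaking(g, GameParams(N=10, r=3.0), FakeRng(1.0))
        assert removed == set()
        assert g.number_of_edges() == 20
        # all values positive (full cooperation) so weights stay at 0
        assert all(d["weight"] == 0 for *_, d in g.edges(data=True))

    def test_negative_values_accumulate_and_cap(self):
        g = make_ring_lattice(10, 4, seed=0, init_coop_fraction=0.0)
        params = GameParams(N=10, r=2.0)  # dead edges: value 0, unsatisfying
        for expect in (3, 6, 9, 10):
            play_round(g, 2.0)
            apply_edge_breaking(g, params, FakeRng(1.0))
            assert all(d["weight"] == expect for *_, d in g.edges(data=True))

    def test_removal_frequency_at_weight_ceiling(self):
        # every edge at the ceiling should vanish at rate F(10; 6) = 0.9574
        removed = total = 0
        for seed in range(60):
            g = make_ring_lattice(20, 4, seed=seed, init_coop_fraction=0.0)
            nx.set_edge_attributes(g, 10, "weight")
            play_round(g, 2.0)
            before = g.number_of_edges()
            out = apply_edge_breaking(
                g, GameParams(N=20, r=2.0), np.random.default_rng(seed)
            )
            removed += len(out)
            total += before
        assert removed / total == pytest.approx(0.9574, abs=0.02)

    def test_baseline_removal_rate_when_satisfied(self):
        # satisfied edges at weight 0 still break at the floor rate e^-6
        removed = total = 0
        for seed in range(200):
            g = make_ring_lattice(30, 4, seed=seed, init_coop_fraction=1.0)
            play_round(g, 2.0)
            total += g.number_of_edges()
            removed += len(
                apply_edge_breaking(g, GameParams(N=30, r=2.0), np.random.default_rng(seed))
            )
        assert removed / total == pytest.approx(math.exp(-6), abs=2e-3)

    def test_reproducible_with_same_seed(self):
        for _ in range(2):
            outs = []
            for _ in range(2):
                g = make_ring_lattice(30, 4, seed=9)
                play_round(g, 2.0)
                outs.append(
                    apply_edge_breaking(g, GameParams(N=30), np.random.default_rng(4))
                )
            assert outs[0] == outs[1]


class TestDominantNodes:
    def test_all_defect_empty(self):
        g = make_ring_lattice(10, 4, seed=0, init_coop_fraction=0.0)
        play_round(g, 2.0)
        assert dominant_nodes(g) == set()

    def test_all_cooperate_connected_all_dominant(self):
        g = make_ring_lattice(10, 4, seed=0, init_coop_fraction=1.0)
        play_round(g, 2.0)
        assert dominant_nodes(g) == set(range(10))

    def test_zero_payoff_cooperator_excluded(self, two_player_cd):
        play_round(two_player_cd, 2.0)  # cooperator nets exactly 0
        assert dominant_nodes(two_player_cd) == set()

    def test_outside_largest_component_excluded(self):
        g = build_graph(
            [(0, 1), (1, 2), (3, 4)],
            [COOPERATE] * 5,
        )
        play_round(g, 4.0)
        assert dominant_nodes(g) == {0, 1, 2}


class TestReconnectIsolated:
    def _params(self, **kw):
        return GameParams(N=20, k0=2, edge_cap=kw.pop("edge_cap", 100), **kw)

    def test_isolated_defector_never_reconnects(self):
        g = build_graph([(1, 2), (2, 3)], [DEFECT, COOPERATE, COOPERATE, COOPERATE])
        added = reconnect_isolated(g, self._params(), FakeRng(0.0))
        assert added == set()
        assert g.degree(0) == 0

    def test_forced_fire_joins_largest_component(self):
        g = build_graph([(1, 2), (2, 3)], [COOPERATE] * 4)
        added = reconnect_isolated(g, self._params(), FakeRng(0.0))
        assert len(added) == 1
        assert g.degree(0) == 1
        (edge,) = added
        assert edge[0] == 0 and edge[1] in {1, 2, 3}
        assert g.edges[edge]["weight"] == 0

    def test_cooperator_targeting_prefers_cooperators(self):
        g = build_graph(
            [(1, 2), (2, 3)], [COOPERATE, DEFECT, COOPERATE, DEFECT]
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            added = reconnect_isolated(g, self._params(), rng)
            for u, v in added:
                assert g.nodes[v]["strategy"] == COOPERATE
                g.remove_edge(u, v)

    def test_any_targeting_uses_whole_component(self):
        g = build_graph([(1, 2), (2, 3)], [COOPERATE, DEFECT, DEFECT, DEFECT])
        added = reconnect_isolated(
            g, self._params(isolated_target="any"), FakeRng(0.0)
        )
        assert len(added) == 1

    def test_binomial_reconnection_rate(self):
        # ten isolated cooperators, p = 0.5: about five rejoin per step
        counts = []
        for seed in range(400):
            g = build_graph(
                [(10, 11), (11, 12)],
                [COOPERATE] * 13,
                n_nodes=13,
            )
            added = reconnect_isolated(
                g, self._params(), np.random.default_rng(seed)
            )
            counts.append(len(added))
        assert np.mean(counts) == pytest.approx(5.0, abs=0.3)

    def test_respects_edge_cap(self):
        g = build_graph([(1, 2)], [COOPERATE, COOPERATE, COOPERATE])
        params = GameParams(N=20, k0=2, edge_cap=1)
        assert reconnect_isolated(g, params, FakeRng(0.0)) == set()


class TestReconnectDominant:
    def test_no_additions_at_cap(self):
        g = make_ring_lattice(10, 4, seed=0, init_coop_fraction=1.0)
        play_round(g, 2.0)
        params = GameParams(N=10, edge_cap=g.number_of_edges())
        assert reconnect_dominant(g, params, np.random.default_rng(0)) == set()

    def test_cap_limits_additions(self):
        g = build_graph(
            [(0, 1), (1, 2), (2, 3), (3, 0)], [COOPERATE] * 4
        )
        play_round(g, 6.0)
        params = GameParams(N=20, k0=2, edge_cap=5)
        added = reconnect_dominant(g, params, np.random.default_rng(1))
        assert len(added) == 1
        assert g.number_of_edges() == 5

    def test_skips_when_no_eligible_target(self):
        # both cooperators already linked: nothing to add
        g = build_graph([(0, 1)], [COOPERATE, COOPERATE])
        play_round(g, 3.0)
        params = GameParams(N=10, k0=2, edge_cap=100)
        assert reconnect_dominant(g, params, np.random.default_rng(0)) == set()

    def test_new_edges_connect_cooperators_at_weight_zero(self):
        g = build_graph(
            [(0, 1), (1, 2), (3, 4)],
            [COOPERATE, COOPERATE, COOPERATE, COOPERATE, COOPERATE],
        )
        play_round(g, 5.0)
        params = GameParams(N=10, k0=2, edge_cap=100)
        added = reconnect_dominant(g, params, np.random.default_rng(3))
        assert added
        for u, v in added:
            assert g.nodes[v]["strategy"] == COOPERATE
            assert g.degree(v) >= 1
            assert g.edges[u, v]["weight"] == 0
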