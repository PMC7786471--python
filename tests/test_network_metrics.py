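"""Metric suite: contacts, density, reciprocity, E-I, diversity, value.

Brute-force oracles used here classify each unordered pair independently
of the package's dyad-census implementation.
"""

import itertools
import math
import random

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from collabnet import (
    RINGS_12,
    RINGS_123,
    NodeSubsetSpec,
    average_degree,
    density,
    diversity,
    dyad_census,
    ei_decomposition,
    mean_diversity,
    mean_tie_value,
    out_degree,
    reciprocity,
    value_summary,
)

from conftest import make_network


def brute_force_dyads(arcs, n):
    """Independent oracle: classify every unordered pair by membership."""
    arcs = set(arcs)
    mutual = asym = null = 0
    for i, j in itertools.combinations(range(n), 2):
        forward = (f"a{i}", f"a{j}") in arcs or (i, j) in arcs
        backward = (f"a{j}", f"a{i}") in arcs or (j, i) in arcs
        if forward and backward:
            mutual += 1
        elif forward or backward:
            asym += 1
        else:
            null += 1
    return mutual, asym, null


class TestOutDegree:
    def test_isolated_responder_is_zero(self):
        assert out_degree(make_network(2), "a0") == 0

    def test_counts_nominations(self):
        net = make_network(6, [(0, j) for j in range(1, 6)])
        assert out_degree(net, "a0") == 5

    def test_nonresponder_is_missing(self):
        net = make_network(2, [(0, 1)], rings={1: 3})
        assert out_degree(net, "a1") is None

    def test_unknown_actor_raises(self, triangle):
        with pytest.raises(KeyError):
            out_degree(triangle, "ghost")


class TestAverageDegree:
    def test_mean_of_degrees(self):
        # degrees 4 and 6 among responders a0, a1; the other five isolated
        net = make_network(
            7, [(0, j) for j in range(1, 5)] + [(1, j) for j in [0, 2, 3, 4, 5, 6]]
        )
        assert average_degree(net) == pytest.approx((4 + 6) / 7)

    def test_all_isolated_is_zero(self):
        assert average_degree(make_network(4)) == 0.0

    def test_forty_eight_arcs_over_ten_actors(self):
        # sum of out-degrees 48 over 10 responders -> 4.8
        rng = random.Random(1)
        arcs = set()
        while len(arcs) < 48:
            s, t = rng.sample(range(10), 2)
            arcs.add((s, t))
        assert average_degree(make_network(10, sorted(arcs))) == pytest.approx(4.8)

    def test_nonresponders_excluded_from_numerator_and_denominator(self):
        net = make_network(3, [(0, 1), (0, 2)], rings={2: 3})
        assert average_degree(net, RINGS_123) == pytest.approx(1.0)  # (2+0)/2

    def test_error_when_no_observed_out_degree(self):
        net = make_network(2, rings={0: 3, 1: 3})
        with pytest.raises(ValueError):
            average_degree(net, RINGS_123)


class TestDensity:
    def test_no_arcs_gives_zero(self):
        assert density(make_network(5)) == 0.0

    def test_complete_digraph_gives_one(self):
        arcs = [(i, j) for i in range(4) for j in range(4) if i != j]
        assert density(make_network(4, arcs)) == 1.0

    def test_three_node_enumeration(self, triangle):
        # arcs {a0->a1, a1->a0, a1->a2} over 3*2 ordered pairs
        assert density(triangle) == pytest.approx(3 / 6)

    def test_subset_too_small(self):
        with pytest.raises(ValueError):
            density(make_network(1))

    def test_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 15))
            g = nx.gnp_random_graph(n, 0.3, directed=True,
                                    seed=int(rng.integers(2**31)))
            net = make_network(n, list(g.edges))
            assert density(net) == pytest.approx(nx.density(g))

    @given(st.integers(2, 7), st.data())
    def test_monotone_under_arc_addition(self, n, data):
        all_pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
        k = data.draw(st.integers(0, len(all_pairs) - 1))
        arcs = all_pairs[:k]
        before = density(make_network(n, arcs))
        after = density(make_network(n, arcs + [all_pairs[k]]))
        assert after >= before


class TestReciprocity:
    def test_fully_symmetric_is_one(self):
        arcs = [(i, j) for i in range(4) for j in range(4) if i != j]
        assert reciprocity(make_network(4, arcs)) == 1.0

    def test_one_mutual_one_asymmetric(self, triangle):
        assert reciprocity(triangle) == pytest.approx(0.5)

    def test_no_mutual_arcs_is_zero(self):
        assert reciprocity(make_network(3, [(0, 1), (1, 2)])) == 0.0

    def test_no_connected_dyads_is_an_error(self):
        with pytest.raises(ValueError, match="no connected dyads"):
            reciprocity(make_network(3))

    def test_arc_variant_matches_networkx(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            g = nx.gnp_random_graph(n, 0.4, directed=True,
                                    seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            net = make_network(n, list(g.edges))
            assert reciprocity(net, method="arc") == pytest.approx(
                nx.overall_reciprocity(g)
            )

    def test_dyad_census_exhaustive_small(self):
        # every simple digraph on 3 nodes, against the pair-classification oracle
        pairs = [(i, j) for i in range(3) for j in range(3) if i != j]
        for mask in range(2 ** len(pairs)):
            arcs = {p for k, p in enumerate(pairs) if mask >> k & 1}
            named = {(f"a{s}", f"a{t}") for s, t in arcs}
            assert dyad_census(named, 3) == brute_force_dyads(arcs, 3)


class TestEIIndex:
    def test_all_internal_scores_minus_one(self):
        net = make_network(4, [(0, 1), (1, 0)], rings={0: 1, 1: 1})
        assert ei_decomposition(net, 1).ei_index == -1.0

    def test_all_external_scores_plus_one(self):
        net = make_network(4, [(0, 2), (1, 3)], rings={0: 1, 1: 1})
        assert ei_decomposition(net, 1).ei_index == 1.0

    def test_two_external_one_internal(self):
        net = make_network(4, [(0, 1), (0, 2), (1, 3)], rings={0: 1, 1: 1})
        deco = ei_decomposition(net, 1)
        assert deco.internal_contacts == 1 and deco.external_contacts == 2
        assert deco.ei_index == pytest.approx(1 / 3)

    def test_average_degrees_divide_by_group_size(self):
        net = make_network(4, [(0, 1), (0, 2), (1, 3)], rings={0: 1, 1: 1})
        deco = ei_decomposition(net, 1)
        assert deco.group_size == 2
        assert deco.internal_avg_degree == pytest.approx(0.5)
        assert deco.external_avg_degree == pytest.approx(1.0)

    def test_no_contacts_is_missing_not_zero(self):
        net = make_network(3, rings={0: 1})
        assert ei_decomposition(net, 1).ei_index is None

    def test_unknown_group_raises(self, triangle):
        with pytest.raises(ValueError, match="unknown group"):
            ei_decomposition(triangle, 9)

    def test_sign_flips_under_partition_complement(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 8
            g = nx.gnp_random_graph(n, 0.35, directed=True,
                                    seed=int(rng.integers(2**31)))
            net = make_network(n, list(g.edges))
            partition = {f"a{i}": ("in" if i < 4 else "out") for i in range(n)}
            flipped = {k: ("out" if v == "in" else "in") for k, v in partition.items()}
            a = ei_decomposition(net, "in", partition=partition).ei_index
            # complement relabel: the same nodes now form the "out" group
            b = ei_decomposition(net, "out", partition=flipped).ei_index
            if a is None:
                assert b is None
            else:
                internal_a = ei_decomposition(net, "in", partition=partition)
                internal_b = ei_decomposition(net, "out", partition=flipped)
                assert internal_a.internal_contacts == internal_b.internal_contacts
                assert a == b  # same group, same arcs, relabeled only


class TestDiversity:
    def test_worked_example_is_half(self, diversity_worked_example):
        comp = diversity(diversity_worked_example, "a0")
        assert comp.p_ir == pytest.approx(0.5)
        assert comp.d_id == pytest.approx(1.0)
        assert comp.h_i == pytest.approx(0.5)

    def test_own_discipline_only_is_zero(self):
        # a second discipline exists in the network but sends no in-ties
        net = make_network(4, [(1, 0), (2, 0)],
                           disciplines={0: "gp", 1: "gp", 2: "gp", 3: "nurse"})
        assert diversity(net, "a0").h_i == 0.0

    def test_hand_enumerated_components(self):
        # 4 in-ties: 2 own discipline, 2 from one other; 3 disciplines total
        net = make_network(
            6,
            [(1, 0), (2, 0), (3, 0), (4, 0)],
            disciplines={0: "gp", 1: "gp", 2: "gp", 3: "nurse", 4: "nurse",
                         5: "social"},
        )
        comp = diversity(net, "a0")
        assert (comp.r_i, comp.r_div_i, comp.d_i, comp.d_div_i) == (4, 2, 2, 1)
        assert comp.p_ir == pytest.approx(0.5)
        assert comp.d_id == pytest.approx(0.5)
        assert comp.h_i == pytest.approx(0.25)

    def test_in_degree_zero_is_missing(self):
        net = make_network(2, [(0, 1)], disciplines={0: "gp", 1: "nurse"})
        assert diversity(net, "a0") is None

    def test_single_discipline_network_is_an_error(self):
        net = make_network(2, [(0, 1)], disciplines={0: "gp", 1: "gp"})
        with pytest.raises(ValueError, match="diversity undefined"):
            diversity(net, "a1")


class TestMeanDiversity:
    def test_constant_values(self):
        net = make_network(
            3, [(1, 0), (0, 1)], disciplines={0: "gp", 1: "nurse", 2: "social"}
        )
        # both H_i = 1/2: single in-tie from the other discipline, 1 of 2 reached
        mean, sd = mean_diversity(net, RINGS_12)
        assert sd == 0.0

    def test_closed_form_sample_sd(self):
        net = make_network(
            4,
            [(1, 0), (2, 0), (3, 1), (2, 1)],
            disciplines={0: "gp", 1: "gp", 2: "gp", 3: "nurse"},
        )
        # a0: 2 own in-ties -> H=0; a1: in-ties from gp and nurse -> P=.5, D=1
        mean, sd = mean_diversity(net, RINGS_12)
        assert mean == pytest.approx(0.25)
        assert sd == pytest.approx(math.sqrt(((0.25) ** 2 * 2) / 1), abs=1e-9)

    def test_all_in_degree_zero_is_an_error(self):
        net = make_network(3, disciplines={0: "gp", 1: "nurse"})
        with pytest.raises(ValueError):
            mean_diversity(net, RINGS_12)


class TestTieValue:
    def test_constant_ratings(self):
        net = make_network(3, [(0, 1), (0, 2)], values={(0, 1): 8.0, (0, 2): 8.0})
        assert mean_tie_value(net, "a0") == 8.0

    def test_mean_of_ratings(self):
        net = make_network(
            4, [(0, 1), (0, 2), (0, 3)],
            values={(0, 1): 6.0, (0, 2): 7.0, (0, 3): 9.0},
        )
        assert mean_tie_value(net, "a0") == pytest.approx(22 / 3)

    def test_nonresponder_is_missing(self):
        net = make_network(2, [(0, 1)], rings={1: 3}, values={(0, 1): 5.0})
        assert mean_tie_value(net, "a1") is None

    def test_unrated_ties_are_skipped(self):
        net = make_network(3, [(0, 1), (0, 2)], values={(0, 1): 6.0})
        assert mean_tie_value(net, "a0") == 6.0

    def test_value_summary(self):
        net = make_network(
            3, [(0, 1), (1, 0)], values={(0, 1): 6.0, (1, 0): 8.0}
        )
        mean, sd = value_summary(net, RINGS_12)
        assert mean == pytest.approx(7.0)
        assert sd == pytest.approx(math.sqrt(2.0))


class TestMetricProperties:
    """Range and invariance properties on randomized networks."""

    @given(st.integers(0, 2**31 - 1))
    def test_ranges_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.05, 0.6)), directed=True,
                                seed=int(rng.integers(2**31)))
        values = {e: float(rng.uniform(1, 10)) for e in g.edges}
        disciplines = {i: f"disc{rng.integers(0, 4)}" for i in range(n)}
        net = make_network(n, list(g.edges), disciplines=disciplines, values=values)
        assert 0.0 <= density(net) <= 1.0
        try:
            assert 0.0 <= reciprocity(net) <= 1.0
        except ValueError:
            pass
        for ring in (2,):
            deco = ei_decomposition(net, ring)
            if deco.ei_index is not None:
                assert -1.0 <= deco.ei_index <= 1.0
        if len(net.disciplines()) >= 2:
            for actor_id in net.actors:
                comp = diversity(net, actor_id)
                if comp is not None:
                    assert 0.0 <= comp.h_i <= 1.0
        for actor_id in net.actors:
            v = mean_tie_value(net, actor_id)
            if v is not None:
                assert 1.0 <= v <= 10.0

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = 8
            g = nx.gnp_random_graph(n, 0.4, directed=True,
                                    seed=int(rng.integers(2**31)))
            arcs = list(g.edges)
            perm = list(rng.permutation(n))
            relabeled = [(perm[s], perm[t]) for s, t in arcs]
            disciplines = {i: f"d{i % 3}" for i in range(n)}
            disciplines_perm = {perm[i]: disciplines[i] for i in range(n)}
            a = make_network(n, arcs, disciplines=disciplines)
            b = make_network(n, relabeled, disciplines=disciplines_perm)
            assert density(a) == pytest.approx(density(b))
            assert average_degree(a) == pytest.approx(average_degree(b))
            try:
                assert reciprocity(a) == pytest.approx(reciprocity(b))
            except ValueError:
                pass
            if len(a.disciplines()) >= 2:
                assert mean_diversity(a)[0] == pytest.approx(mean_diversity(b)[0])
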