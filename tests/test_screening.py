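"""Instrument-screening tests: association strength, the three screening
strategies on the documented shared-upstream-trait geometries, path queries,
and set-monotonicity properties."""

import networkx as nx
import numpy as np
import pytest

from mrgraph.data import CorrelationStructure, SummaryPanel
from mrgraph.network import steady_state_effects
from mrgraph.screening import (
    association_strength,
    build_assignment,
    build_pools,
    has_directed_path,
    reference_graph_from_pvalues,
    screen_aug,
    screen_max,
    screen_pair,
    strength_matrix,
)

from conftest import random_admissible_graph


def panel_from_graph(G, gamma_value=0.15, n=200_000, group_sizes=(8, 7, 15)):
    """Noise-free panel whose betas are the exact total effects of
    block-exclusive SNPs; standard errors mimic GWAS at sample size n."""
    T = len(group_sizes)
    S = sum(group_sizes)
    Gamma = np.zeros((T, S))
    start = 0
    for t, size in enumerate(group_sizes):
        Gamma[t, start : start + size] = gamma_value
        start += size
    B = steady_state_effects(G, Gamma).B
    se = np.full((T, S), 1.0 / np.sqrt(0.42 * n))
    return SummaryPanel(beta=B, se=se, n=np.full(T, n))


@pytest.fixture
def acyclic_panel(acyclic_graph):
    return panel_from_graph(acyclic_graph)


@pytest.fixture
def cyclic_panel(cyclic_graph):
    return panel_from_graph(cyclic_graph, n=50_000)


class TestAssociationStrength:
    def test_zero_effect(self):
        panel = SummaryPanel(beta=[[0.0]], se=[[0.1]], n=[1000.0])
        assert association_strength(panel, 0, 0) == 0.0

    def test_formula_value(self):
        # z = 10 at n = 50000: r^2 = 100 / (100 + 49998)
        panel = SummaryPanel(beta=[[1.0]], se=[[0.1]], n=[50_000.0])
        assert association_strength(panel, 0, 0) == pytest.approx(100.0 / 50_098.0)

    def test_equal_z_larger_n_is_weaker(self):
        panel = SummaryPanel(
            beta=[[1.0], [1.0]], se=[[0.1], [0.1]], n=[50_000.0, 500_000.0]
        )
        assert association_strength(panel, 0, 1) < association_strength(panel, 0, 0)


class TestScreenPair:
    def test_single_trait_significance_assigns_to_that_trait(self, acyclic_panel):
        pools = build_pools(acyclic_panel)
        sets = screen_pair(acyclic_panel, pools)
        # SNPs 0..7 act only on Y1: instruments for exposure Y1
        assert set(range(8)) <= set(sets[(0, 1)].tolist())
        assert not set(range(8)) & set(sets[(1, 0)].tolist())

    def test_shared_upstream_snps_go_to_stronger_trait(self, acyclic_panel):
        """Y3's SNPs reach both Y1 (0.2 gamma) and Y2 (0.1 gamma); pairwise
        screening hands them to Y1 -- the documented failure mode."""
        pools = build_pools(acyclic_panel)
        sets = screen_pair(acyclic_panel, pools)
        z3 = set(range(15, 30))
        assert z3 <= set(sets[(0, 1)].tolist())
        assert not z3 & set(sets[(1, 0)].tolist())

    def test_exact_tie_breaks_to_lower_trait_index(self):
        beta = np.array([[0.1], [0.1]])
        panel = SummaryPanel(beta=beta, se=np.full((2, 1), 0.005), n=np.full(2, 1e5))
        sets = screen_pair(panel, {(0, 1): np.array([0])}, p_threshold=0.05)
        assert sets[(0, 1)].tolist() == [0]
        assert sets[(1, 0)].tolist() == []


class TestScreenMax:
    def test_shared_upstream_snps_reserved_for_their_trait(self, acyclic_panel):
        pools = build_pools(acyclic_panel)
        pair_sets = screen_pair(acyclic_panel, pools)
        sets = screen_max(acyclic_panel, pools, pair_sets)
        z3 = set(range(15, 30))
        for key in ((0, 1), (1, 0)):
            assert not z3 & set(sets[key].tolist())
        # they remain instruments for Y3 itself
        assert z3 <= set(sets[(2, 0)].tolist())

    def test_single_trait_snp_always_retained(self, acyclic_panel):
        pools = build_pools(acyclic_panel)
        pair_sets = screen_pair(acyclic_panel, pools)
        sets = screen_max(acyclic_panel, pools, pair_sets)
        assert set(range(8)) <= set(sets[(0, 1)].tolist())

    def test_conservative_in_cyclic_design(self, cyclic_panel):
        """Y3's SNPs are excluded from the Y1 -> Y2 analysis although valid
        there: the cost of global pruning."""
        pools = build_pools(cyclic_panel)
        pair_sets = screen_pair(cyclic_panel, pools)
        sets = screen_max(cyclic_panel, pools, pair_sets)
        z3 = set(range(15, 30))
        assert not z3 & set(sets[(0, 1)].tolist())

    def test_global_exposure_map_is_a_function(self, rng):
        """Under global-max screening no SNP instruments two exposures."""
        G = random_admissible_graph(rng, T=4, density=0.5, radius=0.6)
        panel = panel_from_graph(G, group_sizes=(5, 5, 5, 5))
        assignment = build_assignment(panel, "max")
        exposure_of: dict = {}
        for (j, _i), snps in assignment.sets.items():
            for k in snps:
                assert exposure_of.setdefault(k, j) == j


class TestPathQueries:
    def test_direct_edge(self):
        g = nx.DiGraph([(0, 1)])
        assert has_directed_path(g, 0, 1)

    def test_empty_graph(self):
        assert not has_directed_path(nx.DiGraph(), 0, 1)

    def test_cycle_transitive_closure_matches_matrix_powers(self):
        g = nx.DiGraph([(0, 1), (1, 2), (2, 0)])
        A = nx.to_numpy_array(g, nodelist=[0, 1, 2])
        closure = (sum(np.linalg.matrix_power(A, l) for l in range(1, 4)) > 0)
        for s in range(3):
            for t in range(3):
                if s != t:
                    assert has_directed_path(g, s, t) == bool(closure[s, t])
        assert has_directed_path(g, 0, 2)  # via the length-2 path


class TestScreenAug:
    def _sets(self, panel, reference):
        pools = build_pools(panel)
        pair_sets = screen_pair(panel, pools)
        max_sets = screen_max(panel, pools, pair_sets)
        aug = screen_aug(panel, pools, pair_sets, max_sets, reference)
        return pair_sets, max_sets, aug

    def test_not_readded_when_alternative_path_survives(self, acyclic_panel):
        """Acyclic geometry: with Y3 -> Y2 in the reference graph, removing
        Y1 still leaves Y3 a path to Y2, so Y3's SNPs stay excluded."""
        ref = nx.DiGraph([(2, 0), (2, 1)])  # Y3->Y1, Y3->Y2
        _, max_sets, aug = self._sets(acyclic_panel, ref)
        z3 = set(range(15, 30))
        assert not z3 & set(aug[(0, 1)].tolist())
        assert set(aug[(0, 1)].tolist()) == set(max_sets[(0, 1)].tolist())

    def test_readded_when_deleting_exposure_blocks_path(self, cyclic_panel):
        """Cyclic geometry: removing Y1 leaves Y3 no path to Y2, so Y3's
        SNPs come back as instruments for Y1 and power is recovered."""
        ref = nx.DiGraph([(2, 0), (0, 1), (1, 2)])  # Y3->Y1->Y2->Y3
        _, max_sets, aug = self._sets(cyclic_panel, ref)
        z3 = set(range(15, 30))
        assert z3 <= set(aug[(0, 1)].tolist())
        assert not z3 & set(max_sets[(0, 1)].tolist())

    def test_empty_reference_returns_pairwise_sets(self, acyclic_panel):
        pair_sets, _, aug = self._sets(acyclic_panel, nx.DiGraph())
        for key in pair_sets:
            assert set(aug[key].tolist()) == set(pair_sets[key].tolist())

    def test_mode_monotonicity(self, rng):
        """max subset of aug subset of pair for every ordered pair."""
        for _ in range(5):
            G = random_admissible_graph(rng, T=4, density=0.5, radius=0.7)
            panel = panel_from_graph(G, group_sizes=(6, 6, 6, 6))
            ref = reference_graph_from_pvalues(rng.uniform(0, 1, (4, 4)), 0.2)
            pools = build_pools(panel)
            pair_sets = screen_pair(panel, pools)
            max_sets = screen_max(panel, pools, pair_sets)
            aug = screen_aug(panel, pools, pair_sets, max_sets, ref)
            for key in pair_sets:
                m = set(max_sets[key].tolist())
                a = set(aug[key].tolist())
                p = set(pair_sets[key].tolist())
                assert m <= a <= p


class TestPoolsAndLd:
    def test_pool_requires_significance_for_a_pair_trait(self, acyclic_panel):
        pools = build_pools(acyclic_panel)
        # Y1/Y2 pool holds Z1, Z2 and (via pleiotropy at n=2e5) Z3 SNPs
        assert set(pools[(0, 1)].tolist()) == set(range(30))

    def test_ld_pruning_keeps_smallest_p_within_block(self):
        beta = np.array([[0.30, 0.20, 0.25], [0.0, 0.0, 0.0]])
        R = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]])
        blocks = np.array([0, 0, 1])
        panel = SummaryPanel(
            beta=beta, se=np.full((2, 3), 0.01), n=np.array([1e5, 1e5]), block_index=blocks
        )
        structure = CorrelationStructure(R, np.eye(2), block_index=blocks)
        pools = build_pools(panel, structure)
        # SNPs 0 and 1 are in LD (r=0.9): only SNP 0 (larger |z|, smaller p) survives
        assert pools[(0, 1)].tolist() == [0, 2]

    def test_reference_graph_excludes_self_edges(self):
        p = np.zeros((3, 3))
        g = reference_graph_from_pvalues(p, alpha=0.05)
        assert not any(u == v for u, v in g.edges)
        assert g.has_edge(1, 0) and g.has_edge(0, 1)
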