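"""Explanation graph, greedy weighted cover, overlap and cover significance."""

import numpy as np
import pytest

from causalflow.causal_cover import (
    ExplanationGraph,
    build_explanation_graph,
    cover_significance,
    greedy_weighted_cover,
    overlap_significance,
)
from causalflow.circuit_flow import CandidateRecord
from causalflow.core_data import CopyNumberProfile, Locus
from causalflow.eqtl_mapping import TagLocus
from causalflow.target_selection import DifferentialCallMatrix, InfeasibleCoverError
from _oracles import brute_force_weighted_cover


def _graph(weights, genes=None, cases=None):
    genes = genes or sorted({g for g, _ in weights})
    cases = cases or sorted({s for _, s in weights})
    return ExplanationGraph(causal_genes=genes, cases=cases, weights=dict(weights))


class TestBuildExplanationGraph:
    def _fixture(self):
        """Two candidates; cg1's locus L1 amplified in s1,s2; L2 neutral
        everywhere, so cg2 explains nothing."""
        loci = [Locus("L1", "chr1", 1000), Locus("L2", "chr1", 2000)]
        log2 = np.array([[2.0, 2.0, 1.0], [1.0, 1.02, 0.98]])
        cnv = CopyNumberProfile(loci=loci, samples=["s1", "s2", "s3"],
                                log2_ratios=log2,
                                locus_genes={"L1": ["cg1"], "L2": ["cg2"]})
        tags = [
            TagLocus("L1", 0, "chr1", 0, 0, region_genes=["cg1"]),
            TagLocus("L2", 1, "chr1", 1, 1, region_genes=["cg2"]),
        ]
        de = DifferentialCallMatrix(
            genes=["t1", "t2"],
            cases=["s1", "s2", "s3"],
            z=np.array([[3.0, 3.0, 0.0], [-3.0, 0.0, 0.0]]),
            calls=np.array([[True, True, False], [True, False, False]]),
            de_p=0.01,
        )
        records = [
            CandidateRecord("t1", "L1", "cg1", 0.9, 1e-4),
            CandidateRecord("t2", "L1", "cg1", 0.8, 1e-3),
            CandidateRecord("t1", "L2", "cg2", 0.7, 1e-3),
        ]
        return records, cnv, tags, de

    def test_edges_and_weights(self):
        records, cnv, tags, de = self._fixture()
        graph = build_explanation_graph(records, cnv, tags, de)
        # s1: L1 amplified, both affected targets DE -> weight 2
        assert graph.weights[("cg1", "s1")] == 2
        assert graph.edge_targets[("cg1", "s1")] == ["t1", "t2"]
        # s2: only t1 DE -> weight 1
        assert graph.weights[("cg1", "s2")] == 1
        # s3: L1 neutral -> no edge; cg2's locus never altered -> isolated
        assert ("cg1", "s3") not in graph.weights
        assert all(g != "cg2" for g, _ in graph.weights)

    def test_case_with_no_alterations_isolated(self):
        records, cnv, tags, de = self._fixture()
        graph = build_explanation_graph(records, cnv, tags, de)
        assert graph.total_weight(graph.causal_genes, "s3") == 0


class TestGreedyWeightedCover:
    def test_gamma_zero_returns_empty(self):
        graph = _graph({("g1", "s1"): 3})
        assert greedy_weighted_cover(graph, gamma=0, delta=0) == []

    def test_single_dominating_gene(self):
        graph = _graph({("g1", "s1"): 5, ("g1", "s2"): 7, ("g2", "s1"): 1})
        assert greedy_weighted_cover(graph, gamma=5, delta=0) == ["g1"]

    def test_auto_delta_counts_unreachable_cases(self):
        graph = _graph(
            {("g1", "s1"): 5, ("g2", "s2"): 5},
            cases=["s1", "s2", "s3"],  # s3 can never be explained
        )
        chosen = greedy_weighted_cover(graph, gamma=5, delta="auto")
        assert set(chosen) == {"g1", "g2"}

    def test_numeric_delta_infeasible_raises(self):
        graph = _graph({("g1", "s1"): 5}, cases=["s1", "s2", "s3"])
        with pytest.raises(InfeasibleCoverError) as err:
            greedy_weighted_cover(graph, gamma=5, delta=1)
        assert set(err.value.cases) == {"s2", "s3"}

    def test_evidence_breaks_exact_ties(self):
        """Identical explanation edges: the gene with stronger circuit
        evidence wins the tie even when lexicographically later."""
        weights = {("a_decoy", "s1"): 1, ("z_causal", "s1"): 1}
        graph = ExplanationGraph(
            causal_genes=["a_decoy", "z_causal"], cases=["s1"],
            weights=weights,
            gene_priority={"a_decoy": (0.04, -0.3), "z_causal": (1e-6, -0.9)},
        )
        assert greedy_weighted_cover(graph, gamma=1, delta=0) == ["z_causal"]

    @pytest.mark.parametrize("seed", range(40))
    def test_greedy_matches_brute_force_within_log_factor(self, seed):
        rng = np.random.default_rng(4000 + seed)
        w = rng.integers(0, 4, size=(5, 4))
        gamma = int(rng.integers(1, 4))
        weights = {
            (f"g{i}", f"s{j}"): int(w[i, j])
            for i in range(5) for j in range(4) if w[i, j] > 0
        }
        graph = ExplanationGraph(
            causal_genes=[f"g{i}" for i in range(5)],
            cases=[f"s{j}" for j in range(4)],
            weights=weights,
        )
        chosen = greedy_weighted_cover(graph, gamma=gamma, delta="auto")
        achievable = graph.achievable()
        delta = sum(1 for s in graph.cases if achievable[s] < gamma)
        opt, _ = brute_force_weighted_cover(w, gamma, delta)
        total_demand = gamma * (4 - delta)
        bound = max(1, opt) * (1 + np.log(max(total_demand, 2)))
        assert len(chosen) <= bound + 1e-9
        # certificate
        short = sum(1 for s in graph.cases if graph.total_weight(chosen, s) < gamma)
        assert short <= delta


class TestOverlapSignificance:
    def test_reference_equal_universe_forces_overlap(self):
        u = {f"g{i}" for i in range(10)}
        assert overlap_significance({"g1", "g2"}, u, u) == pytest.approx(1.0)

    def test_exact_enumeration_value(self):
        """|U|=10, |selected|=4, |reference|=5, overlap 4:
        p = C(5,4)C(5,0)/C(10,4) = 5/210."""
        universe = [f"g{i}" for i in range(10)]
        reference = universe[:5]
        selected = universe[:4]
        p = overlap_significance(selected, reference, universe)
        assert p == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_large_sets_near_one(self):
        universe = [f"g{i}" for i in range(40)]
        p = overlap_significance(universe[:10], universe[20:], universe)
        assert p > 0.99

    def test_empty_universe_rejected(self):
        with pytest.raises(Exception):
            overlap_significance(set(), set(), set())


class TestCoverSignificance:
    def test_full_set_feasible_gives_one(self):
        graph = _graph({("g1", "s1"): 5, ("g2", "s1"): 5})
        p = cover_significance(graph, selected_size=2, gamma=5, delta=0,
                               n_perm=200, seed=1)
        assert p == 1.0

    def test_unique_feasible_pair_matches_combinatorics(self):
        """6 candidates, only {g1, g2} jointly reach gamma: the chance that a
        random pair works is 1/C(6,2) = 1/15."""
        weights = {("g1", "s1"): 3, ("g2", "s1"): 3}
        genes = [f"g{i}" for i in range(1, 7)]
        graph = ExplanationGraph(causal_genes=genes, cases=["s1"],
                                 weights=weights)
        p = cover_significance(graph, selected_size=2, gamma=6, delta=0,
                               n_perm=10_000, seed=3)
        expect = 1 / 15
        se = np.sqrt(expect * (1 - expect) / 10_000)
        assert abs(p - expect) < 4 * se

    def test_equal_seeds_agree(self):
        graph = _graph({("g1", "s1"): 2, ("g2", "s1"): 2, ("g3", "s1"): 1})
        a = cover_significance(graph, 1, gamma=2, delta=0, n_perm=500, seed=9)
        b = cover_significance(graph, 1, gamma=2, delta=0, n_perm=500, seed=9)
        assert a == b
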