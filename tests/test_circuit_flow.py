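"""Circuit solver, direction heuristic, rewiring null and empirical p-values."""

import numpy as np
import pytest

from causalflow.circuit_flow import (
    CircuitInstance,
    UnsolvableInstanceError,
    build_instance,
    build_null_instance,
    degree_preserving_rewire,
    edge_conductance,
    empirical_pvalues,
    permutation_null,
    select_candidates,
    solve_circuit,
    solve_directed,
    InstanceResult,
    NullCurrents,
)
from causalflow.core_data import (
    InteractionNetwork,
    make_edge,
    PPI,
    PROTEIN_DNA,
)
from _oracles import dense_circuit_solve, random_instance, random_walk_absorption


def _instance(edge_specs, target, candidates, conductances=None):
    """edge_specs: (u, v, etype) triples."""
    edges = [make_edge(u, v, et) for u, v, et in edge_specs]
    nodes = sorted({n for e in edges for n in (e.u, e.v)})
    cond = np.ones(len(edges)) if conductances is None else np.asarray(conductances, float)
    return CircuitInstance(nodes=nodes, edges=edges, conductances=cond,
                           target=target, candidates=candidates)


class TestConductance:
    def test_perfect_correlation_gives_unit_conductance(self, toy):
        # tumor profiles of tf1 and mid1 both equal the target's exactly
        assert edge_conductance("tf1", "mid1", "t", toy.expr) == pytest.approx(1.0)

    def test_absolute_value_of_anticorrelation(self, toy):
        # c3 is exactly anti-correlated with t: |corr| = 1 on both ends
        assert edge_conductance("tf1", "c3", "t", toy.expr) == pytest.approx(1.0)

    def test_missing_gene_contributes_floor(self, toy):
        w = edge_conductance("tf1", "not_measured", "t", toy.expr)
        assert w == pytest.approx((1.0 + 1e-3) / 2)

    def test_toy_conductance_matches_direct_pearson(self, toy):
        ti = toy.expr.genes.index("t")
        fi = toy.expr.genes.index("f01")
        tumor = ~toy.expr.is_control
        c = abs(np.corrcoef(toy.expr.values[ti, tumor], toy.expr.values[fi, tumor])[0, 1])
        assert edge_conductance("t", "f01", "t", toy.expr) == pytest.approx((1 + c) / 2)


class TestBuildInstance:
    def test_only_tf_edge_survives_at_target(self, toy):
        inst = build_instance(toy.network, "t", toy.tag, toy.expr)
        target_edges = [e for e in inst.edges if "t" in (e.u, e.v)]
        assert len(target_edges) == 1
        assert target_edges[0].etype == PROTEIN_DNA and target_edges[0].u == "tf1"
        assert inst.candidates == ["c1", "c2", "c3"]

    def test_no_tf_in_edge_is_unsolvable(self, toy):
        net = InteractionNetwork(
            nodes={"a": False, "b": False, "c": False},
            edges=[make_edge("a", "b", PPI), make_edge("b", "c", PPI)],
        )
        from causalflow.eqtl_mapping import TagLocus

        tag = TagLocus(tag_id="L1", tag_index=0, chromosome="chr1",
                       start_index=0, end_index=0, region_genes=["c"])
        with pytest.raises(UnsolvableInstanceError, match="no protein-DNA"):
            build_instance(net, "a", tag)

    def test_toy_instance_counts_match_hand_enumeration(self, toy):
        # t keeps 1 edge; all 20 nodes stay connected through tf1
        inst = build_instance(toy.network, "t", toy.tag, toy.expr)
        assert len(inst.nodes) == 20
        assert len(inst.edges) == 20


class TestSolveCircuit:
    def test_series_path(self):
        inst = _instance([("tg", "a", PPI), ("a", "c", PPI)], "tg", ["c"])
        sol = solve_circuit(inst)
        v = dict(zip(inst.nodes, sol.voltages))
        assert v["tg"] == pytest.approx(2.0)
        assert v["a"] == pytest.approx(1.0)
        assert v["c"] == pytest.approx(0.0)
        assert all(abs(i) == pytest.approx(1.0) for i in sol.currents)

    def test_parallel_divider(self):
        # two branches tg-a-c and tg-b-c with conductances 1 and 3
        inst = _instance(
            [("tg", "a", PPI), ("a", "c", PPI), ("tg", "b", PPI), ("b", "c", PPI)],
            "tg", ["c"], conductances=[1, 1, 3, 3],
        )
        sol = solve_circuit(inst)
        flows = {e.key(): abs(i) for e, i in zip(inst.edges, sol.currents)}
        assert flows[("a", "tg", PPI)] == pytest.approx(0.25)
        assert flows[("b", "tg", PPI)] == pytest.approx(0.75)

    def test_toy_exit_currents_hand_computed(self, toy):
        """Series/parallel reduction of the toy gives exact eighths."""
        inst = build_instance(toy.network, "t", toy.tag, toy.expr)
        sol = solve_circuit(inst)
        assert sol.exit_currents["c3"] == pytest.approx(5 / 8)
        assert sol.exit_currents["c1"] == pytest.approx(2 / 8)
        assert sol.exit_currents["c2"] == pytest.approx(1 / 8)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_dense_solve_and_conserves(self, seed):
        rng = np.random.default_rng(3000 + seed)
        inst = random_instance(rng, n_nodes=int(rng.integers(8, 30)))
        sol = solve_circuit(inst)
        _, dense_i, dense_x = dense_circuit_solve(inst)
        np.testing.assert_allclose(sol.currents, dense_i, atol=1e-10)
        for c in inst.candidates:
            assert sol.exit_currents[c] == pytest.approx(dense_x[c], abs=1e-10)
        assert sum(sol.exit_currents.values()) == pytest.approx(1.0, abs=1e-8)
        assert sol.kirchhoff_residual() <= 1e-8
        assert all(x >= -1e-8 for x in sol.exit_currents.values())

    def test_scaling_conductances_leaves_exit_currents_unchanged(self, rng):
        inst = random_instance(rng, n_nodes=15)
        sol1 = solve_circuit(inst)
        scaled = CircuitInstance(
            nodes=inst.nodes, edges=inst.edges,
            conductances=7.5 * inst.conductances,
            target=inst.target, candidates=inst.candidates,
        )
        sol2 = solve_circuit(scaled)
        for c in inst.candidates:
            assert sol1.exit_currents[c] == pytest.approx(sol2.exit_currents[c])

    def test_removing_zero_current_edge_changes_nothing(self):
        # edge between two grounded candidates carries no current
        inst = _instance(
            [("tg", "a", PPI), ("a", "c1", PPI), ("a", "c2", PPI), ("c1", "c2", PPI)],
            "tg", ["c1", "c2"],
        )
        sol = solve_circuit(inst)
        cc = [abs(i) for e, i in zip(inst.edges, sol.currents)
              if {e.u, e.v} == {"c1", "c2"}]
        assert cc[0] == pytest.approx(0.0, abs=1e-12)
        pruned = _instance(
            [("tg", "a", PPI), ("a", "c1", PPI), ("a", "c2", PPI)],
            "tg", ["c1", "c2"],
        )
        sol2 = solve_circuit(pruned)
        for c in ("c1", "c2"):
            assert sol.exit_currents[c] == pytest.approx(sol2.exit_currents[c])


class TestSolveDirected:
    def test_undirected_instance_one_iteration(self, rng):
        specs = [("tg", "a", PPI), ("a", "c", PPI), ("a", "b", PPI), ("b", "c", PPI)]
        inst = _instance(specs, "tg", ["c"])
        sol = solve_directed(inst)
        assert sol.iterations == 1
        assert sol.wrong_direction_count == 0

    def test_reverse_oriented_edge_removed(self):
        """A protein-DNA edge a->b lying on the only detour carries current
        from its regulator toward its regulated gene (the forbidden direction
        in the reversed frame) and must be deleted, rerouting the flow."""
        specs = [
            ("tg", "a", PPI),
            ("a", "b", PROTEIN_DNA),  # regulator a -> regulated b
            ("b", "c", PPI),
            ("a", "d", PPI),
            ("d", "c", PPI),
        ]
        inst = _instance(specs, "tg", ["c"])
        first = solve_circuit(inst)
        assert first.wrong_direction_count == 1
        sol = solve_directed(inst, wrong_dir_max=0)
        assert sol.wrong_direction_count == 0
        assert sol.iterations == 2
        assert len(sol.instance.edges) == len(inst.edges) - 1
        assert sol.exit_currents["c"] == pytest.approx(1.0)

    def test_wrong_count_non_increasing(self):
        for seed in range(25):
            rng = np.random.default_rng(8800 + seed)
            inst = random_instance(rng, n_nodes=18, extra_edges=20)
            counts = []
            cur = inst
            while True:
                sol = solve_circuit(cur)
                counts.append(sol.wrong_direction_count)
                if sol.wrong_direction_count == 0:
                    break
                try:
                    sol = solve_directed(cur, wrong_dir_max=0)
                except UnsolvableInstanceError:
                    break
                counts.append(sol.wrong_direction_count)
                break
            assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestRewiring:
    def test_degree_sequence_preserved(self, small_cohort, rng):
        _, _, _, net, _ = small_cohort
        rewired = degree_preserving_rewire(net, rng)
        assert rewired.degrees() == net.degrees()
        assert rewired.n_edges == net.n_edges

    def test_type_counts_preserved(self, small_cohort, rng):
        _, _, _, net, _ = small_cohort
        rewired = degree_preserving_rewire(net, rng)
        def type_counts(n):
            out = {}
            for e in n.edges:
                out[e.etype] = out.get(e.etype, 0) + 1
            return out
        assert type_counts(rewired) == type_counts(net)

    def test_deterministic_under_seed(self, small_cohort):
        _, _, _, net, _ = small_cohort
        a = degree_preserving_rewire(net, np.random.default_rng(42))
        b = degree_preserving_rewire(net, np.random.default_rng(42))
        assert a.edge_key_set() == b.edge_key_set()

    def test_rewiring_depth(self, rng):
        """Rewired networks share well under half their edges with the
        original on a 200-edge random graph."""
        inst = random_instance(rng, n_nodes=60, extra_edges=141)
        nodes = {n: False for n in inst.nodes}
        net = InteractionNetwork(nodes=nodes, edges=inst.edges)
        jacc = []
        for k in range(5):
            rw = degree_preserving_rewire(net, np.random.default_rng(900 + k))
            a, b = net.edge_key_set(), rw.edge_key_set()
            jacc.append(len(a & b) / len(a | b))
        assert np.mean(jacc) < 0.5


class TestEmpiricalPValues:
    def _null(self, values):
        arr = np.asarray(values, float)[:, None]
        return NullCurrents(candidates=["c"], matrix=arr, nodes=["c"],
                            node_matrix=arr)

    def _sol(self, x):
        inst = _instance([("tg", "c", PPI)], "tg", ["c"])
        sol = solve_circuit(inst)
        sol.exit_currents["c"] = x
        return sol

    def test_observed_at_null_mean_gives_half(self):
        null = self._null([0.1, 0.2, 0.3, 0.4])
        assert empirical_pvalues(self._sol(0.25), null)["c"] == pytest.approx(0.5)

    def test_two_sigma_tail(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        mu, sd = vals.mean(), vals.std(ddof=1)
        null = self._null(vals)
        p = empirical_pvalues(self._sol(mu + 2 * sd), null)["c"]
        assert p == pytest.approx(0.02275, abs=1e-4)

    def test_below_mean_gives_large_p(self):
        null = self._null([0.1, 0.2, 0.3, 0.4])
        assert empirical_pvalues(self._sol(0.05), null)["c"] > 0.5

    def test_zero_sd_degenerate(self):
        # 0.25 is exactly representable, so the null sd is exactly zero
        null = self._null([0.25, 0.25, 0.25])
        assert empirical_pvalues(self._sol(0.5), null)["c"] == 0.0
        assert empirical_pvalues(self._sol(0.25), null)["c"] == 1.0


class TestPermutationNull:
    def test_reproducible_from_seed(self, small_cohort):
        _, expr, cnv, net, truth = small_cohort
        from causalflow.eqtl_mapping import select_tag_loci

        tags = select_tag_loci(cnv)
        cg, tg = truth.causal_genes[0], truth.target_genes[0]
        tag = next(t for t in tags if cg in t.region_genes)
        inst = build_instance(net, tg, tag, expr)
        null_a = permutation_null(net, inst, n_perm=3, seed=7)
        null_b = permutation_null(net, inst, n_perm=3, seed=7)
        np.testing.assert_array_equal(null_a.matrix, null_b.matrix)
        assert null_a.matrix.shape == (3, len(inst.candidates))


class TestSelectCandidates:
    def _result(self, currents, pvals):
        inst = _instance(
            [("tg", "x", PPI)] + [("x", c, PPI) for c in currents],
            "tg", sorted(currents),
        )
        sol = solve_circuit(inst)
        sol.exit_currents = dict(currents)
        return InstanceResult(target="tg", tag_id="L1", solution=sol,
                              candidate_p=pvals)

    def test_seventy_percent_rule(self):
        res = self._result(
            {"a": 1.0, "b": 0.8, "c": 0.6},
            {"a": 0.01, "b": 0.01, "c": 0.01},
        )
        kept = {r.gene for r in select_candidates([res])}
        assert kept == {"a", "b"}

    def test_single_gene_region_kept(self):
        res = self._result({"a": 0.4}, {"a": 0.04})
        assert [r.gene for r in select_candidates([res])] == ["a"]

    def test_p_filter_applies(self):
        res = self._result({"a": 1.0, "b": 0.9}, {"a": 0.04, "b": 0.2})
        assert {r.gene for r in select_candidates([res])} == {"a"}


class TestRandomWalkEquivalence:
    def test_unit_conductance_currents_are_absorption_probabilities(self):
        rng = np.random.default_rng(77)
        inst = random_instance(rng, n_nodes=16, unit_conductance=True)
        sol = solve_circuit(inst)
        probs = random_walk_absorption(inst, 200_000, rng)
        for c in inst.candidates:
            p = probs[c]
            se = max(np.sqrt(p * (1 - p) / 200_000), 1e-4)
            assert abs(sol.exit_currents[c] - p) < 4 * se
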