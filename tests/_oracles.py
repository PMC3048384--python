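"""Independent oracles used by the test suite.

Everything here is deliberately implemented by a different route than the
package: the circuit is solved as one dense block system in its raw
Ohm/Kirchhoff/ground form, absorption probabilities are estimated by actually
simulating random walks, covers are brute-forced over all subsets, and widest
paths are found by enumerating every simple path.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np

from causalflow.circuit_flow import CircuitInstance
from causalflow.core_data import Edge, make_edge, PPI, PROTEIN_DNA, PHOSPHORYLATION


# ---------------------------------------------------------------------------
# circuit oracles


def dense_circuit_solve(instance: CircuitInstance):
    """Solve the raw block system: Ohm per edge, Kirchhoff per free node,
    V=0 per grounded candidate.  Returns (voltages, currents, exit_currents)
    aligned with the instance's node/edge order."""
    nodes = instance.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    n, m = len(nodes), len(instance.edges)
    A = np.zeros((m + n, m + n))  # unknowns: I_0..I_{m-1}, V_0..V_{n-1}
    b = np.zeros(m + n)
    for k, (e, w) in enumerate(zip(instance.edges, instance.conductances)):
        A[k, k] = 1.0
        A[k, m + idx[e.u]] = -w
        A[k, m + idx[e.v]] = w
    grounded = set(instance.candidates)
    row = m
    for node in nodes:
        if node in grounded:
            A[row, m + idx[node]] = 1.0  # V = 0
        else:
            for k, e in enumerate(instance.edges):
                if e.u == node:
                    A[row, k] += 1.0  # current leaving
                elif e.v == node:
                    A[row, k] -= 1.0  # current entering
            if node == instance.target:
                b[row] = 1.0
        row += 1
    sol = np.linalg.solve(A, b)
    currents = sol[:m]
    voltages = sol[m:]
    exit_currents = {c: 0.0 for c in instance.candidates}
    for k, e in enumerate(instance.edges):
        if e.u in exit_currents:
            exit_currents[e.u] -= currents[k]
        if e.v in exit_currents:
            exit_currents[e.v] += currents[k]
    return voltages, currents, exit_currents


def random_walk_absorption(
    instance: CircuitInstance, n_walks: int, rng: np.random.Generator
):
    """Absorption probabilities of the conductance-weighted random walk from
    the target, estimated by simulating ``n_walks`` walks (propagated as
    multinomial counts, which is an exact simulation of independent walks)."""
    nodes = instance.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    weight = np.zeros((n, n))
    for e, w in zip(instance.edges, instance.conductances):
        weight[idx[e.u], idx[e.v]] += w
        weight[idx[e.v], idx[e.u]] += w
    absorbing = np.zeros(n, dtype=bool)
    for c in instance.candidates:
        absorbing[idx[c]] = True
    trans_prob = {}
    for i in range(n):
        if absorbing[i]:
            continue
        tot = weight[i].sum()
        if tot > 0:
            trans_prob[i] = weight[i] / tot
    counts = np.zeros(n, dtype=np.int64)
    counts[idx[instance.target]] = n_walks
    absorbed = np.zeros(n, dtype=np.int64)
    for _ in range(200_000):
        moving = [i for i in trans_prob if counts[i] > 0]
        if not moving:
            break
        nxt = np.zeros(n, dtype=np.int64)
        for i in moving:
            nxt += rng.multinomial(counts[i], trans_prob[i])
            counts[i] = 0
        landed_abs = nxt * absorbing
        absorbed += landed_abs
        counts = counts + nxt - landed_abs
    assert counts[~absorbing].sum() == 0, "walks failed to absorb"
    return {c: absorbed[idx[c]] / n_walks for c in instance.candidates}


def random_instance(
    rng: np.random.Generator,
    n_nodes: int = 20,
    extra_edges: int = 15,
    n_candidates: int = 4,
    unit_conductance: bool = False,
) -> CircuitInstance:
    """A connected random circuit instance with mixed edge types."""
    names = [f"n{i:02d}" for i in range(n_nodes)]
    edges: dict[tuple, Edge] = {}
    order = rng.permutation(n_nodes)
    for a, b in zip(order, order[1:]):  # random spanning tree
        e = make_edge(names[a], names[b], PPI)
        edges[e.key()] = e
    types = [PPI, PPI, PROTEIN_DNA, PHOSPHORYLATION]
    for _ in range(extra_edges):
        a, b = rng.choice(n_nodes, size=2, replace=False)
        et = types[rng.integers(len(types))]
        e = make_edge(names[a], names[b], et)
        edges.setdefault(e.key(), e)
    edge_list = list(edges.values())
    if unit_conductance:
        cond = np.ones(len(edge_list))
    else:
        cond = rng.uniform(0.05, 1.0, size=len(edge_list))
    picks = rng.choice(n_nodes, size=n_candidates + 1, replace=False)
    target = names[picks[0]]
    candidates = sorted(names[i] for i in picks[1:])
    return CircuitInstance(
        nodes=list(names),
        edges=edge_list,
        conductances=cond,
        target=target,
        candidates=candidates,
    )


# ---------------------------------------------------------------------------
# cover oracles


def brute_force_multiset_cover(incidence: np.ndarray, alpha: int, beta: int):
    """Smallest gene subset leaving at most ``beta`` cases under-covered."""
    n_genes, n_cases = incidence.shape
    for size in range(n_genes + 1):
        for subset in combinations(range(n_genes), size):
            cover = incidence[list(subset)].sum(axis=0)
            if int((cover < alpha).sum()) <= beta:
                return size, subset
    raise AssertionError("unreachable: the full set always qualifies or fails")


def brute_force_weighted_cover(weights: np.ndarray, gamma: int, delta: int):
    """Smallest gene subset leaving at most ``delta`` cases under weight gamma."""
    n_genes, n_cases = weights.shape
    for size in range(n_genes + 1):
        for subset in combinations(range(n_genes), size):
            total = weights[list(subset)].sum(axis=0)
            if int((total < gamma).sum()) <= delta:
                return size, subset
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# path oracle


def exhaustive_widest_path(graph: nx.Graph, capacity: dict, source, sink):
    """Best bottleneck (min interior capacity) over all simple paths, by
    enumeration; None when no path exists."""
    best = None
    for path in nx.all_simple_paths(graph, source, sink):
        interior = path[1:-1]
        value = min((capacity[n] for n in interior), default=np.inf)
        if best is None or value > best:
            best = value
    return best


# ---------------------------------------------------------------------------
# regression oracle


def permutation_slope_p(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Two-sided permutation p-value for the OLS slope of y on x."""
    xc = x - x.mean()
    denom = xc @ xc

    def slope(v):
        return abs(xc @ (v - v.mean())) / denom

    obs = slope(y)
    hits = sum(slope(rng.permutation(y)) >= obs for _ in range(n_perm))
    return (hits + 1) / (n_perm + 1)
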