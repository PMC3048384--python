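"""Maximum-current causal paths, causal subnetworks and pathway hubs.

For each final (causal gene, target gene) pair, the circuit solution of the
pair's most significant tag locus is turned into a *causal path*: nodes with
empirical p-value above 0.05 are removed, and among the remaining simple paths
from the target to the causal gene the one maximizing the bottleneck objective
— the minimum total current through any interior node — is extracted with a
widest-path (maximin) variant of Dijkstra's algorithm.  An alternative
objective maximizing the product of interior currents is available; since all
node throughflows are bounded by the unit injected current it reduces to a
shortest path in −log current.

The union of a causal gene's paths over its targets forms its causal
subnetwork, and genes recurring in many paths across the cohort are reported
as pathway hubs.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

from .core_data import Edge, ValidationError
from .circuit_flow import CircuitSolution

__all__ = [
    "CausalPath",
    "CausalSubnetwork",
    "max_current_path",
    "count_hubs",
    "assemble_subnetworks",
]


@dataclass
class CausalPath:
    """A simple path from a target gene to a causal gene.

    ``nodes`` runs target → … → causal gene; ``objective`` is the minimum
    interior-node throughflow (bottleneck mode) or the product of interior
    throughflows (product mode); paths with no interior have objective inf
    (bottleneck) or 1 (product).
    """

    target: str
    causal_gene: str
    nodes: tuple[str, ...]
    objective: float
    tag_id: str | None = None

    @property
    def interior(self) -> tuple[str, ...]:
        return self.nodes[1:-1]


@dataclass
class CausalSubnetwork:
    """Union of one causal gene's paths across its targets."""

    causal_gene: str
    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    targets: set[str] = field(default_factory=set)


def _filtered_adjacency(
    edges: list[Edge], keep: set[str]
) -> dict[str, list[str]]:
    adj: dict[str, list[str]] = {n: [] for n in keep}
    seen: set[tuple[str, str]] = set()
    for e in edges:
        if e.u in keep and e.v in keep:
            for a, b in ((e.u, e.v), (e.v, e.u)):
                if (a, b) not in seen:
                    seen.add((a, b))
                    adj[a].append(b)
    for n in adj:
        adj[n].sort()
    return adj


def max_current_path(
    solution: CircuitSolution,
    node_p: dict[str, float],
    target: str,
    causal_gene: str,
    p_max: float = 0.05,
    objective: str = "bottleneck",
    tag_id: str | None = None,
) -> CausalPath | None:
    """Extract the maximum-current simple path from target to causal gene.

    Nodes with empirical p-value > ``p_max`` are removed first (the two
    endpoints are always kept).  ``objective='bottleneck'`` maximizes the
    minimum interior throughflow by a maximin Dijkstra; ``'product'``
    maximizes the product of interior throughflows.  Returns None when the
    causal gene is unreachable after filtering.
    """
    if objective not in ("bottleneck", "product"):
        raise ValidationError(f"unknown objective {objective!r}")
    inst = solution.instance
    if target not in inst.nodes or causal_gene not in inst.nodes:
        return None
    flow = solution.node_throughflow()
    keep = {
        n
        for n in inst.nodes
        if n in (target, causal_gene) or node_p.get(n, 1.0) <= p_max
    }
    adj = _filtered_adjacency(inst.edges, keep)

    if objective == "bottleneck":
        nodes_path = _widest_path(adj, flow, target, causal_gene)
        if nodes_path is None:
            return None
        interior = nodes_path[1:-1]
        value = min((flow[n] for n in interior), default=math.inf)
    else:
        nodes_path = _max_product_path(adj, flow, target, causal_gene)
        if nodes_path is None:
            return None
        interior = nodes_path[1:-1]
        value = math.prod(flow[n] for n in interior) if interior else 1.0
    return CausalPath(
        target=target,
        causal_gene=causal_gene,
        nodes=tuple(nodes_path),
        objective=value,
        tag_id=tag_id,
    )


def _widest_path(adj, flow, source, sink):
    """Maximin path over interior-node capacities (endpoints uncapacitated)."""
    best: dict[str, float] = {source: math.inf}
    prev: dict[str, str] = {}
    heap = [(-math.inf, source)]
    done: set[str] = set()
    while heap:
        neg_b, n = heapq.heappop(heap)
        if n in done:
            continue
        done.add(n)
        if n == sink:
            break
        for m in adj.get(n, ()):
            if m in done:
                continue
            cap = math.inf if m == sink else flow.get(m, 0.0)
            cand = min(-neg_b, cap)
            if cand > best.get(m, -math.inf):
                best[m] = cand
                prev[m] = n
                heapq.heappush(heap, (-cand, m))
    if sink not in done:
        return None
    return _backtrack(prev, source, sink)


def _max_product_path(adj, flow, source, sink):
    """Maximize the product of interior throughflows via -log shortest path.

    Node throughflows never exceed the unit injected current, so every
    -log weight is non-negative and Dijkstra applies.
    """
    tiny = 1e-300
    best: dict[str, float] = {source: 0.0}
    prev: dict[str, str] = {}
    heap = [(0.0, source)]
    done: set[str] = set()
    while heap:
        d, n = heapq.heappop(heap)
        if n in done:
            continue
        done.add(n)
        if n == sink:
            break
        for m in adj.get(n, ()):
            if m in done:
                continue
            w = 0.0 if m == sink else -math.log(max(flow.get(m, 0.0), tiny))
            cand = d + w
            if cand < best.get(m, math.inf):
                best[m] = cand
                prev[m] = n
                heapq.heappush(heap, (cand, m))
    if sink not in done:
        return None
    return _backtrack(prev, source, sink)


def _backtrack(prev, source, sink):
    path = [sink]
    while path[-1] != source:
        path.append(prev[path[-1]])
    return path[::-1]


def count_hubs(paths: list[CausalPath], min_occurrences: int = 10) -> list[tuple[str, int]]:
    """Genes appearing as interior nodes in strictly more than
    ``min_occurrences`` causal paths, with their counts, most frequent first."""
    counts: dict[str, int] = {}
    for p in paths:
        for g in p.interior:
            counts[g] = counts.get(g, 0) + 1
    hubs = [(g, c) for g, c in counts.items() if c > min_occurrences]
    hubs.sort(key=lambda gc: (-gc[1], gc[0]))
    return hubs


def assemble_subnetworks(paths: list[CausalPath]) -> list[CausalSubnetwork]:
    """One subnetwork per causal gene: the union of its paths' nodes/edges."""
    nets: dict[str, CausalSubnetwork] = {}
    for p in paths:
        net = nets.setdefault(p.causal_gene, CausalSubnetwork(causal_gene=p.causal_gene))
        net.nodes.update(p.nodes)
        net.targets.add(p.target)
        for a, b in zip(p.nodes, p.nodes[1:]):
            net.edges.add((min(a, b), max(a, b)))
    return [nets[g] for g in sorted(nets)]
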