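"""Electric-circuit propagation from a target gene to candidate causal genes.

The information flow from a dysregulated target gene back to its potential
causal genes is modeled as electric current on the interaction network: a unit
current is injected at the target, every candidate gene in the associated
tag-locus region is grounded at voltage 0, and each edge conducts in
proportion to how strongly its endpoints' expression correlates with the
target.  Solving Ohm's and Kirchhoff's laws yields voltages, edge currents and
the current exiting into each candidate; candidates drawing a large share of
the current are the plausible causes.  This is the classical equivalence with
absorbing random walks: the exit currents are the absorption probabilities of
a walk that steps with probability proportional to conductance.

Biology enters through two constraints.  Only transcription factors may act
directly on the target, so every edge incident to the target is removed except
protein–DNA edges from a TF into it.  Protein–DNA and phosphorylation edges
are directed; a cheap iterative heuristic removes directed edges whose current
runs against their admissible orientation, re-solving until at most a small
number (~0.1% of edges) remain wrong.

Significance is assessed against degree-preserving edge-rewired networks: the
same solve with unit conductances on each random network yields a null current
per candidate (and per node), to which a normal distribution is fitted and an
upper-tail Z-test applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.linalg import spsolve

from .core_data import (
    PROTEIN_DNA,
    Edge,
    ExpressionMatrix,
    InteractionNetwork,
    ValidationError,
)
from .eqtl_mapping import TagLocus

__all__ = [
    "CONDUCTANCE_FLOOR",
    "CircuitInstance",
    "CircuitSolution",
    "UnsolvableInstanceError",
    "CandidateRecord",
    "InstanceResult",
    "NullCurrents",
    "edge_conductance",
    "abs_target_correlations",
    "build_instance",
    "build_null_instance",
    "solve_circuit",
    "solve_directed",
    "degree_preserving_rewire",
    "permutation_null",
    "empirical_pvalues",
    "empirical_node_pvalues",
    "select_candidates",
    "nominal_pair_p_bound",
]

CONDUCTANCE_FLOOR = 1e-3
_CURRENT_TOL = 1e-10


class UnsolvableInstanceError(RuntimeError):
    """The circuit instance cannot be solved (no TF in-edge at the target,
    candidates unreachable, or direction pruning disconnected all candidates)."""


# ---------------------------------------------------------------------------
# conductances


def abs_target_correlations(
    expr: ExpressionMatrix | None, target: str, genes, eps: float = CONDUCTANCE_FLOOR
) -> dict[str, float]:
    """|Pearson| of each gene with the target over tumor samples.

    Genes absent from the expression matrix, or with zero variance, contribute
    ``eps`` in place of the correlation magnitude.
    """
    out = {g: eps for g in genes}
    if expr is None:
        return out
    idx = expr.gene_index()
    if target not in idx:
        return out
    tumor = expr.tumor_values
    t = tumor[idx[target]]
    td = t - t.mean()
    tnorm = np.sqrt(td @ td)
    if tnorm == 0:
        return out
    present = [g for g in genes if g in idx]
    if not present:
        return out
    block = tumor[[idx[g] for g in present]]
    bd = block - block.mean(axis=1, keepdims=True)
    norms = np.sqrt((bd * bd).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (bd @ td) / (norms * tnorm)
    for g, c in zip(present, corr):
        out[g] = abs(float(c)) if np.isfinite(c) else eps
    return out


def edge_conductance(
    u: str, v: str, target: str, expr: ExpressionMatrix,
    eps: float = CONDUCTANCE_FLOOR,
) -> float:
    """Conductance of edge (u, v): mean of |corr(u, tg)| and |corr(v, tg)|.

    Computed over tumor samples and floored at ``eps`` so that a single
    uncorrelated node damps, but never interrupts, the current.
    """
    corr = abs_target_correlations(expr, target, [u, v], eps=eps)
    return max(eps, 0.5 * (corr[u] + corr[v]))


# ---------------------------------------------------------------------------
# instances


@dataclass
class CircuitInstance:
    """One solvable circuit: network view, source target, grounded candidates."""

    nodes: list[str]
    edges: list[Edge]
    conductances: np.ndarray
    target: str
    candidates: list[str]

    def __post_init__(self) -> None:
        self.conductances = np.asarray(self.conductances, dtype=float)
        if self.target in self.candidates:
            raise ValidationError("target cannot be its own candidate")
        if not self.candidates:
            raise ValidationError("candidate set is empty")
        if len(self.conductances) != len(self.edges):
            raise ValidationError("one conductance per edge required")
        if np.any(self.conductances <= 0):
            raise ValidationError("conductances must be positive")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _target_edge_allowed(edge: Edge, target: str, is_tf: dict[str, bool]) -> bool:
    # at the target only protein-DNA edges from a TF into the target survive
    return (
        edge.etype == PROTEIN_DNA
        and edge.directed
        and edge.v == target
        and is_tf.get(edge.u, False)
    )


def _component_of(target: str, edges: list[Edge]) -> set[str]:
    adj: dict[str, list[str]] = {}
    for e in edges:
        adj.setdefault(e.u, []).append(e.v)
        adj.setdefault(e.v, []).append(e.u)
    seen = {target}
    stack = [target]
    while stack:
        n = stack.pop()
        for m in adj.get(n, ()):
            if m not in seen:
                seen.add(m)
                stack.append(m)
    return seen


def _assemble(
    network: InteractionNetwork,
    target: str,
    candidates: list[str],
    expr: ExpressionMatrix | None,
    unit_conductance: bool,
) -> CircuitInstance:
    kept = []
    for e in network.edges:
        if target in (e.u, e.v):
            if _target_edge_allowed(e, target, network.nodes):
                kept.append(e)
        else:
            kept.append(e)
    if not any(target in (e.u, e.v) for e in kept):
        raise UnsolvableInstanceError(
            f"target {target!r} has no protein-DNA in-edge from a transcription factor"
        )
    comp = _component_of(target, kept)
    cand = sorted(c for c in candidates if c in comp)
    if not cand:
        raise UnsolvableInstanceError(
            f"no candidate reachable from target {target!r}"
        )
    edges = [e for e in kept if e.u in comp and e.v in comp]
    nodes = sorted(comp)
    if unit_conductance:
        cond = np.ones(len(edges))
    else:
        corr = abs_target_correlations(expr, target, nodes)
        cond = np.array(
            [max(CONDUCTANCE_FLOOR, 0.5 * (corr[e.u] + corr[e.v])) for e in edges]
        )
    return CircuitInstance(nodes=nodes, edges=edges, conductances=cond,
                           target=target, candidates=cand)


def build_instance(
    network: InteractionNetwork,
    target: str,
    tag: TagLocus,
    expr: ExpressionMatrix | None = None,
    unit_conductance: bool = False,
) -> CircuitInstance:
    """Build the circuit for one (target gene, tag locus) pair.

    Candidates are the region's genes present in the network (minus the
    target).  Raises :class:`UnsolvableInstanceError` when the target lacks a
    TF protein-DNA in-edge or no candidate is reachable.
    """
    if target not in network.nodes:
        raise ValidationError(f"target {target!r} not in network")
    candidates = sorted(set(tag.region_genes) & set(network.nodes) - {target})
    if not candidates:
        raise UnsolvableInstanceError(
            f"region of tag {tag.tag_id!r} contributes no network genes"
        )
    return _assemble(network, target, candidates, expr,
                     unit_conductance=unit_conductance)


def build_null_instance(
    network: InteractionNetwork, target: str, candidates: list[str]
) -> CircuitInstance:
    """Unit-conductance instance on a (rewired) topology for a fixed candidate set."""
    return _assemble(network, target, list(candidates), expr=None,
                     unit_conductance=True)


# ---------------------------------------------------------------------------
# solving


@dataclass
class CircuitSolution:
    """Voltages, signed edge currents and per-candidate exit currents.

    ``currents[i] > 0`` means current flows from ``edges[i].u`` to
    ``edges[i].v``.  ``exit_currents`` sums to the unit injected current.
    """

    instance: CircuitInstance
    voltages: np.ndarray
    currents: np.ndarray
    exit_currents: dict[str, float]
    wrong_direction_count: int
    iterations: int = 1

    def node_throughflow(self) -> dict[str, float]:
        """Total current through each node: half the sum of |incident currents|."""
        flow = {n: 0.0 for n in self.instance.nodes}
        for e, i in zip(self.instance.edges, self.currents):
            a = abs(float(i))
            flow[e.u] += a
            flow[e.v] += a
        return {n: 0.5 * v for n, v in flow.items()}

    def kirchhoff_residual(self) -> float:
        """Max |net current| at free nodes (injection subtracted at the target)."""
        net = {n: 0.0 for n in self.instance.nodes}
        for e, i in zip(self.instance.edges, self.currents):
            net[e.u] -= float(i)
            net[e.v] += float(i)
        net[self.instance.target] += 1.0
        grounded = set(self.instance.candidates)
        return max(
            (abs(v) for n, v in net.items() if n not in grounded), default=0.0
        )


def _count_wrong_direction(
    edges: list[Edge], currents: np.ndarray, orientation: str
) -> list[int]:
    """Indices of directed edges whose current opposes the admissible direction.

    ``orientation='reverse'`` (default): current flows from the target toward
    causes, so the admissible current direction on a regulator→regulated edge
    is regulated→regulator; an edge is wrong when current runs u→v.
    ``orientation='forward'``: the opposite convention.
    """
    wrong = []
    for k, (e, i) in enumerate(zip(edges, currents)):
        if not e.directed:
            continue
        if orientation == "reverse" and i > _CURRENT_TOL:
            wrong.append(k)
        elif orientation == "forward" and i < -_CURRENT_TOL:
            wrong.append(k)
    return wrong


def solve_circuit(
    instance: CircuitInstance, orientation: str = "reverse"
) -> CircuitSolution:
    """Solve the linear circuit: unit injection at the target, candidates at 0 V.

    Ohm's law on every edge and current conservation at every non-candidate
    node reduce to a grounded Laplacian system; exit currents are the inflows
    at the grounded candidates and sum to 1.
    """
    if orientation not in ("reverse", "forward"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    nodes = instance.nodes
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    grounded = np.zeros(n, dtype=bool)
    for c in instance.candidates:
        grounded[index[c]] = True
    free = np.flatnonzero(~grounded)
    free_pos = {int(i): k for k, i in enumerate(free)}
    ui = np.array([index[e.u] for e in instance.edges])
    vi = np.array([index[e.v] for e in instance.edges])
    w = instance.conductances

    m = len(free)
    rows, cols, vals = [], [], []
    diag = np.zeros(m)
    for a, b, wt in zip(ui, vi, w):
        fa = free_pos.get(int(a))
        fb = free_pos.get(int(b))
        if fa is not None:
            diag[fa] += wt
        if fb is not None:
            diag[fb] += wt
        if fa is not None and fb is not None:
            rows.extend((fa, fb))
            cols.extend((fb, fa))
            vals.extend((-wt, -wt))
    rhs = np.zeros(m)
    ti = free_pos.get(index[instance.target])
    if ti is None:  # target grounded is excluded upstream, keep a guard
        raise ValidationError("target must not be grounded")
    rhs[ti] = 1.0
    if m <= 600:
        lap = np.zeros((m, m))
        lap[rows, cols] = 0.0  # ensure allocation, then accumulate
        np.add.at(lap, (rows, cols), vals)
        lap[np.arange(m), np.arange(m)] += diag
        try:
            v_free = np.linalg.solve(lap, rhs)
        except np.linalg.LinAlgError as err:
            raise UnsolvableInstanceError(f"singular circuit system: {err}") from err
    else:
        lap = sparse.coo_matrix(
            (np.concatenate([vals, diag]),
             (np.concatenate([rows, np.arange(m)]),
              np.concatenate([cols, np.arange(m)]))),
            shape=(m, m),
        ).tocsc()
        v_free = spsolve(lap, rhs)
        if not np.all(np.isfinite(v_free)):
            raise UnsolvableInstanceError("singular circuit system (sparse solve)")

    voltages = np.zeros(n)
    voltages[free] = v_free
    currents = w * (voltages[ui] - voltages[vi])
    exit_currents: dict[str, float] = {c: 0.0 for c in instance.candidates}
    for e, i in zip(instance.edges, currents):
        if e.u in exit_currents:
            exit_currents[e.u] -= float(i)
        if e.v in exit_currents:
            exit_currents[e.v] += float(i)
    wrong = _count_wrong_direction(instance.edges, currents, orientation)
    return CircuitSolution(
        instance=instance,
        voltages=voltages,
        currents=currents,
        exit_currents=exit_currents,
        wrong_direction_count=len(wrong),
    )


def solve_directed(
    instance: CircuitInstance,
    wrong_dir_max: int | None = None,
    orientation: str = "reverse",
) -> CircuitSolution:
    """Iteratively solve, removing directed edges used in the wrong direction.

    Stops when at most ``wrong_dir_max`` directed edges carry wrong-direction
    current (default: 0.1% of the instance's edges, at least 1) or when
    nothing changes.  Raises :class:`UnsolvableInstanceError` if the removals
    disconnect every candidate from the target.
    """
    if wrong_dir_max is None:
        wrong_dir_max = max(1, round(0.001 * instance.n_edges))
    current = instance
    iterations = 0
    while True:
        iterations += 1
        sol = solve_circuit(current, orientation=orientation)
        wrong = _count_wrong_direction(current.edges, sol.currents, orientation)
        if len(wrong) <= wrong_dir_max or not wrong:
            sol.iterations = iterations
            return sol
        drop = set(wrong)
        edges = [e for k, e in enumerate(current.edges) if k not in drop]
        cond = np.array([w for k, w in enumerate(current.conductances) if k not in drop])
        comp = _component_of(current.target, edges)
        cand = sorted(c for c in current.candidates if c in comp)
        if not cand:
            raise UnsolvableInstanceError(
                "direction pruning disconnected all candidates"
            )
        keep = [k for k, e in enumerate(edges) if e.u in comp and e.v in comp]
        current = CircuitInstance(
            nodes=sorted(comp),
            edges=[edges[k] for k in keep],
            conductances=cond[keep],
            target=current.target,
            candidates=cand,
        )


# ---------------------------------------------------------------------------
# permutation null


def degree_preserving_rewire(
    network: InteractionNetwork,
    rng: np.random.Generator,
    n_swaps: int | None = None,
    max_attempt_factor: int = 100,
    within_type: bool = True,
) -> InteractionNetwork:
    """Randomize the network by degree-preserving double-edge swaps.

    A swap replaces edges (u,v), (x,y) by (u,y), (x,v); each edge keeps its
    type, and for directed edges the first endpoint keeps the regulator/kinase
    role.  With ``within_type=True`` (default) partners are drawn from the
    same type class, so every node additionally preserves its per-type in/out
    degree — in particular a target gene keeps as many TF protein-DNA
    in-edges as in the real network, keeping null instances solvable.
    ``within_type=False`` pairs edges freely and preserves total degree only.
    Undirected edge endpoints are randomly flipped before pairing so the
    chain mixes over the full configuration space.  By default 10×|E| swaps
    are accepted; if fewer than |E| swaps are accepted within
    ``max_attempt_factor``×|E| attempts the network is too constrained and an
    error is raised.
    """
    edges = list(network.edges)
    n_edges = len(edges)
    if n_edges < 2:
        raise ValidationError("need at least 2 edges to rewire")
    if n_swaps is None:
        n_swaps = 10 * n_edges
    by_type: dict[str, list[int]] = {}
    for k, e in enumerate(edges):
        by_type.setdefault(e.etype, []).append(k)
    keys = {e.key() for e in edges}
    accepted = 0
    attempts = 0
    max_attempts = max_attempt_factor * n_edges
    while accepted < n_swaps:
        attempts += 1
        if attempts > max_attempts:
            if accepted < n_edges:
                raise RuntimeError(
                    f"edge-swap acceptance stagnated ({accepted} accepted in "
                    f"{attempts} attempts); the network may be too sparse or "
                    "too constrained — consider a denser network"
                )
            break
        i = int(rng.integers(0, n_edges))
        if within_type:
            pool = by_type[edges[i].etype]
            if len(pool) < 2:
                continue
            j = pool[int(rng.integers(0, len(pool)))]
        else:
            j = int(rng.integers(0, n_edges))
        if i == j:
            continue
        e1, e2 = edges[i], edges[j]
        u, v = e1.u, e1.v
        x, y = e2.u, e2.v
        if not e1.directed and rng.random() < 0.5:
            u, v = v, u
        if not e2.directed and rng.random() < 0.5:
            x, y = y, x
        if u == y or x == v:
            continue
        new1 = Edge(*(sorted((u, y)) if not e1.directed else (u, y)),
                    e1.etype, e1.directed)
        new2 = Edge(*(sorted((x, v)) if not e2.directed else (x, v)),
                    e2.etype, e2.directed)
        k_old1, k_old2 = e1.key(), e2.key()
        k_new1, k_new2 = new1.key(), new2.key()
        if k_new1 == k_new2:
            continue
        remaining = keys - {k_old1, k_old2}
        if k_new1 in remaining or k_new2 in remaining:
            continue
        keys = remaining | {k_new1, k_new2}
        edges[i], edges[j] = new1, new2
        accepted += 1
    return InteractionNetwork(nodes=dict(network.nodes), edges=edges)


@dataclass
class NullCurrents:
    """Per-candidate exit currents and per-node throughflow over random networks."""

    candidates: list[str]
    matrix: np.ndarray  # n_perm × n_candidates
    nodes: list[str]
    node_matrix: np.ndarray  # n_perm × n_nodes
    n_unsolvable: int = 0


def permutation_null(
    network: InteractionNetwork,
    instance: CircuitInstance,
    n_perm: int = 30,
    seed: int | np.random.Generator | None = None,
    rewired: list[InteractionNetwork] | None = None,
    wrong_dir_max: int | None = None,
    orientation: str = "reverse",
) -> NullCurrents:
    """Null exit currents for the instance's candidates on rewired topologies.

    Each of ``n_perm`` degree-preserving rewirings is solved with unit
    conductances, the real target, the real candidate set and the TF
    constraint.  Pre-generated rewired networks may be supplied via
    ``rewired`` (one null set can serve many instances).  Rewirings in which
    the instance becomes unsolvable contribute zero current everywhere.
    """
    if rewired is None:
        if n_perm < 2:
            raise ValidationError("n_perm must be >= 2")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        rewired = [degree_preserving_rewire(network, rng) for _ in range(n_perm)]
    cand = list(instance.candidates)
    node_names = list(instance.nodes)
    mat = np.zeros((len(rewired), len(cand)))
    node_mat = np.zeros((len(rewired), len(node_names)))
    n_unsolvable = 0
    for r, net in enumerate(rewired):
        try:
            null_inst = build_null_instance(net, instance.target, cand)
            sol = solve_directed(null_inst, wrong_dir_max=wrong_dir_max,
                                 orientation=orientation)
        except UnsolvableInstanceError:
            n_unsolvable += 1
            continue
        for k, c in enumerate(cand):
            mat[r, k] = sol.exit_currents.get(c, 0.0)
        flow = sol.node_throughflow()
        for k, nname in enumerate(node_names):
            node_mat[r, k] = flow.get(nname, 0.0)
    return NullCurrents(candidates=cand, matrix=mat, nodes=node_names,
                        node_matrix=node_mat, n_unsolvable=n_unsolvable)


def _normal_upper_tail(x: float, null_values: np.ndarray) -> float:
    mu = float(null_values.mean())
    sd = float(null_values.std(ddof=1))
    if sd == 0:
        return 0.0 if x > mu else 1.0
    return float(stats.norm.sf((x - mu) / sd))


def empirical_pvalues(solution: CircuitSolution, null: NullCurrents) -> dict[str, float]:
    """Upper-tail Z-test of each candidate's observed exit current against the
    normal fitted to its null currents."""
    if null.matrix.shape[0] < 2:
        raise ValidationError("need >= 2 null values per candidate")
    return {
        c: _normal_upper_tail(solution.exit_currents[c], null.matrix[:, k])
        for k, c in enumerate(null.candidates)
        if c in solution.exit_currents
    }


def empirical_node_pvalues(solution: CircuitSolution, null: NullCurrents) -> dict[str, float]:
    """Upper-tail Z-test per node of observed throughflow against its null."""
    if null.node_matrix.shape[0] < 2:
        raise ValidationError("need >= 2 null values per node")
    flow = solution.node_throughflow()
    out = {}
    for k, n in enumerate(null.nodes):
        if n in flow:
            out[n] = _normal_upper_tail(flow[n], null.node_matrix[:, k])
    return out


# ---------------------------------------------------------------------------
# candidate selection


@dataclass(frozen=True)
class CandidateRecord:
    """One selected (target, tag, candidate) triple with its evidence."""

    target: str
    tag_id: str
    gene: str
    current: float
    p_value: float


@dataclass
class InstanceResult:
    """Everything computed for one solved (target, tag) circuit."""

    target: str
    tag_id: str
    solution: CircuitSolution
    candidate_p: dict[str, float]
    node_p: dict[str, float] = field(default_factory=dict)


def select_candidates(
    results: list[InstanceResult],
    current_frac: float = 0.7,
    emp_p: float = 0.05,
) -> list[CandidateRecord]:
    """Filter candidates per (target, tag): keep genes receiving at least
    ``current_frac`` of the region's maximum current whose empirical p-value
    is below ``emp_p``."""
    if not 0 < current_frac <= 1:
        raise ValidationError("current_frac must be in (0,1]")
    records: list[CandidateRecord] = []
    for res in results:
        x = res.solution.exit_currents
        if not x:
            continue
        xmax = max(x.values())
        for gene in sorted(x):
            if x[gene] >= current_frac * xmax and res.candidate_p.get(gene, 1.0) < emp_p:
                records.append(
                    CandidateRecord(
                        target=res.target,
                        tag_id=res.tag_id,
                        gene=gene,
                        current=x[gene],
                        p_value=res.candidate_p[gene],
                    )
                )
    return records


def nominal_pair_p_bound(assoc_p: float = 0.01, emp_p: float = 0.05) -> float:
    """Nominal p-value bound for every retained (target, causal gene) pair:
    pairs survive the regression filter (p < assoc_p) and the empirical
    circuit filter (p < emp_p), so their combined nominal bound is the
    product."""
    return assoc_p * emp_p
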