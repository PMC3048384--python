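"""Final causal-gene selection by greedy weighted multi-set cover of cases.

A candidate causal gene *explains* a disease case when (i) its tag locus is
amplified or deleted in that case and (ii) at least one of its affected target
genes (those it sends a significant current to) is differentially expressed in
that case.  The explanation weight is the number of such targets.  The final
causal set is the (greedy) minimum set of genes whose accumulated weight
reaches ``gamma`` in all but ``delta`` cases; ``delta='auto'`` derives the
outlier count from the data as the number of cases that no candidate set can
explain to weight ``gamma``.

Validation utilities: hypergeometric overlap significance against reference
gene sets, and a permutation test for the size of the selected cover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .core_data import CopyNumberProfile, ValidationError
from .eqtl_mapping import TagLocus
from .circuit_flow import CandidateRecord
from .target_selection import DifferentialCallMatrix, InfeasibleCoverError

__all__ = [
    "ExplanationGraph",
    "build_explanation_graph",
    "greedy_weighted_cover",
    "overlap_significance",
    "cover_significance",
]


@dataclass
class ExplanationGraph:
    """Weighted bipartite graph between candidate causal genes and cases.

    ``weights[(gene, case)]`` is the number of the gene's affected targets
    that are differentially expressed in that case (>= 1 on every edge);
    ``edge_targets`` lists them.
    """

    causal_genes: list[str]
    cases: list[str]
    weights: dict[tuple[str, str], int]
    edge_targets: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    # per-gene circuit evidence (best empirical p, negated best current) used
    # only to break exact gain ties in the greedy cover
    gene_priority: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        genes = set(self.causal_genes)
        cases = set(self.cases)
        for (g, s), w in self.weights.items():
            if g not in genes or s not in cases:
                raise ValidationError(f"edge ({g!r}, {s!r}) off the declared node sets")
            if w < 1:
                raise ValidationError(f"edge ({g!r}, {s!r}) has weight {w} < 1")

    def weight(self, gene: str, case: str) -> int:
        return self.weights.get((gene, case), 0)

    def total_weight(self, genes, case: str) -> int:
        return sum(self.weights.get((g, case), 0) for g in genes)

    def achievable(self) -> dict[str, int]:
        """Total weight each case could receive from the full candidate set."""
        out = {s: 0 for s in self.cases}
        for (g, s), w in self.weights.items():
            out[s] += w
        return out


def build_explanation_graph(
    candidates: list[CandidateRecord],
    cnv: CopyNumberProfile,
    tags: list[TagLocus],
    de_calls: DifferentialCallMatrix,
    cases: list[str] | None = None,
) -> ExplanationGraph:
    """Assemble the causal-gene × case explanation graph.

    Each candidate gene is anchored at the tag locus of its most significant
    circuit instance; condition (i) tests that locus's alteration state in
    the case, condition (ii) collects the gene's affected targets that are
    differentially expressed there.
    """
    if cases is None:
        cases = list(de_calls.cases)
    tag_index = {t.tag_id: t for t in tags}
    locus_row = cnv.locus_index()
    states = cnv.alteration_matrix()
    cnv_col = {s: j for j, s in enumerate(cnv.samples)}
    de_gene = {g: i for i, g in enumerate(de_calls.genes)}
    de_case = {s: j for j, s in enumerate(de_calls.cases)}

    # per causal gene: affected targets, and the tag of its best instance
    affected: dict[str, set[str]] = {}
    best: dict[str, tuple[float, str]] = {}
    priority: dict[str, tuple[float, float]] = {}
    for rec in candidates:
        affected.setdefault(rec.gene, set()).add(rec.target)
        key = (rec.p_value, rec.tag_id)
        if rec.gene not in best or key < best[rec.gene]:
            best[rec.gene] = key
        ev = (rec.p_value, -rec.current)
        if rec.gene not in priority or ev < priority[rec.gene]:
            priority[rec.gene] = ev
    weights: dict[tuple[str, str], int] = {}
    edge_targets: dict[tuple[str, str], list[str]] = {}
    for gene in sorted(affected):
        tag = tag_index[best[gene][1]]
        row = locus_row[tag.tag_id]
        for case in cases:
            col = cnv_col.get(case)
            if col is None or states[row, col] == 0:
                continue  # condition (i): no alteration at the gene's tag locus
            hits = [
                t
                for t in sorted(affected[gene])
                if t in de_gene
                and case in de_case
                and de_calls.calls[de_gene[t], de_case[case]]
            ]
            if hits:
                weights[(gene, case)] = len(hits)
                edge_targets[(gene, case)] = hits
    return ExplanationGraph(
        causal_genes=sorted(affected),
        cases=list(cases),
        weights=weights,
        edge_targets=edge_targets,
        gene_priority=priority,
    )


def resolve_delta(graph: ExplanationGraph, gamma: int, delta) -> int:
    """Resolve ``delta='auto'`` to the number of cases whose total achievable
    weight is below ``gamma``; validate a numeric delta against those cases."""
    achievable = graph.achievable()
    deficient = [s for s in graph.cases if achievable[s] < gamma]
    if delta == "auto":
        return len(deficient)
    delta = int(delta)
    if len(deficient) > delta:
        raise InfeasibleCoverError(
            f"{len(deficient)} case(s) can never reach weight {gamma} with "
            f"outlier budget {delta}: {deficient[:10]}",
            deficient,
        )
    return delta


def greedy_weighted_cover(
    graph: ExplanationGraph, gamma: int = 50, delta="auto"
) -> list[str]:
    """Greedy weighted multi-set cover: repeatedly pick the gene adding the
    most weight, capped per case at the case's remaining demand, until all
    non-exempt cases accumulate weight >= ``gamma``.

    Exempt cases are the ``delta`` with the smallest achievable total weight
    (with ``delta='auto'`` exactly those that can never reach ``gamma``).
    Gain ties break by circuit evidence (smaller best empirical p, then
    larger best current) and finally by gene identifier, so co-located
    passenger genes with identical explanation edges cannot displace the
    gene the current actually singled out.  Returns genes in selection order.
    """
    if gamma < 0:
        raise ValidationError("gamma must be >= 0")
    delta_n = resolve_delta(graph, gamma, delta)
    achievable = graph.achievable()
    order = sorted(graph.cases, key=lambda s: (achievable[s], s))
    exempt = set(order[:delta_n])
    demand = {s: (0 if s in exempt else gamma) for s in graph.cases}

    by_gene: dict[str, list[tuple[str, int]]] = {g: [] for g in graph.causal_genes}
    for (g, s), w in graph.weights.items():
        by_gene[g].append((s, w))
    available = sorted(graph.causal_genes)
    selected: list[str] = []
    while any(d > 0 for d in demand.values()):
        best_gene, best_key = None, None
        for g in available:
            gain = sum(min(w, demand[s]) for s, w in by_gene[g])
            if gain == 0:
                continue
            key = (-gain, *graph.gene_priority.get(g, (1.0, 0.0)), g)
            if best_key is None or key < best_key:
                best_gene, best_key = g, key
        if best_gene is None:  # unreachable once delta is validated
            raise InfeasibleCoverError(
                "no gene adds any weight to the remaining demand",
                [s for s, d in demand.items() if d > 0],
            )
        available.remove(best_gene)
        selected.append(best_gene)
        for s, w in by_gene[best_gene]:
            demand[s] = max(0, demand[s] - w)
    return selected


def overlap_significance(selected, reference, universe) -> float:
    """Upper-tail hypergeometric probability of an overlap at least as large
    as observed between ``selected`` and ``reference`` within ``universe``."""
    universe = set(universe)
    if not universe:
        raise ValidationError("universe must be non-empty")
    selected = set(selected)
    reference = set(reference)
    if not selected <= universe or not reference <= universe:
        raise ValidationError("selected and reference must be subsets of universe")
    overlap = len(selected & reference)
    return float(
        stats.hypergeom.sf(overlap - 1, len(universe), len(reference), len(selected))
    )


def cover_significance(
    graph: ExplanationGraph,
    selected_size: int,
    gamma: int = 50,
    delta="auto",
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Permutation p-value for the selected cover size: the fraction of
    uniformly random candidate subsets of that size that satisfy the
    (gamma, delta) constraint."""
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    delta_n = resolve_delta(graph, gamma, delta)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = list(graph.causal_genes)
    if selected_size > len(genes):
        raise ValidationError("selected_size exceeds the candidate pool")
    hits = 0
    for _ in range(n_perm):
        subset = rng.choice(len(genes), size=selected_size, replace=False)
        chosen = [genes[i] for i in subset]
        short = sum(
            1 for s in graph.cases if graph.total_weight(chosen, s) < gamma
        )
        if short <= delta_n:
            hits += 1
    return hits / n_perm
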