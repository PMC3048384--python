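"""End-to-end driver: from cohort data to final causal genes and pathways.

Stages, each delegating to its module:

1. per-case differential-expression calls and greedy multi-set cover of the
   cases → target genes (:mod:`.target_selection`);
2. tag-locus compression and expression/copy-number regression → associated
   (target, tag locus) pairs (:mod:`.eqtl_mapping`);
3. circuit solve per associated pair with the TF and direction constraints,
   empirical p-values against one shared set of degree-preserving rewirings,
   70%-of-max current filter → candidate causal genes (:mod:`.circuit_flow`);
4. explanation graph and greedy weighted multi-set cover → final causal genes
   (:mod:`.causal_cover`);
5. maximum-current paths, causal subnetworks and hubs
   (:mod:`.pathway_extraction`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import causal_cover, circuit_flow, eqtl_mapping, pathway_extraction, target_selection
from .core_data import CopyNumberProfile, ExpressionMatrix, InteractionNetwork
from .circuit_flow import CandidateRecord, InstanceResult, UnsolvableInstanceError
from .pathway_extraction import CausalPath, CausalSubnetwork

__all__ = ["PipelineResult", "run_pipeline", "analytic_summary"]


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    de_calls: target_selection.DifferentialCallMatrix
    targets: list[str]
    tags: list[eqtl_mapping.TagLocus]
    associations: eqtl_mapping.AssociationResult
    instance_results: list[InstanceResult]
    unsolvable: list[tuple[str, str, str]]  # (target, tag, reason)
    candidate_records: list[CandidateRecord]
    explanation_graph: causal_cover.ExplanationGraph | None
    final_causal: list[str]
    paths: list[CausalPath]
    subnetworks: list[CausalSubnetwork]
    hubs: list[tuple[str, int]] = field(default_factory=list)

    @property
    def candidate_genes(self) -> list[str]:
        return sorted({r.gene for r in self.candidate_records})


def run_pipeline(
    expr: ExpressionMatrix,
    cnv: CopyNumberProfile,
    network: InteractionNetwork,
    *,
    alpha: int = 55,
    beta: int = 3,
    de_p: float = 0.01,
    theta: float = 0.9,
    tag_mode: str = "ltr",
    assoc_p: float = 0.01,
    current_frac: float = 0.7,
    emp_p: float = 0.05,
    n_perm: int = 30,
    wrong_dir_max: int | None = None,
    orientation: str = "reverse",
    gamma: int = 50,
    delta="auto",
    path_objective: str = "bottleneck",
    hub_min: int = 10,
    seed: int | None = None,
) -> PipelineResult:
    """Run all five stages and return the full result bundle.

    One set of ``n_perm`` degree-preserving rewirings is generated up front
    and shared by every circuit instance's permutation null.  ``seed`` drives
    the rewirings (the only stochastic step).
    """
    de = target_selection.compute_de_calls(expr, de_p=de_p)
    targets = target_selection.greedy_multiset_cover(
        target_selection.CoverInstance.from_calls(de, alpha=alpha, beta=beta)
    )
    tags = eqtl_mapping.select_tag_loci(cnv, theta=theta, mode=tag_mode)
    assoc = eqtl_mapping.associate(expr, cnv, tags, targets, assoc_p=assoc_p)

    rng = np.random.default_rng(seed)
    rewired = [
        circuit_flow.degree_preserving_rewire(network, rng) for _ in range(n_perm)
    ]
    tag_map = {t.tag_id: t for t in tags}
    results: list[InstanceResult] = []
    unsolvable: list[tuple[str, str, str]] = []
    for target in targets:
        for tag_id in assoc.associated.get(target, []):
            try:
                inst = circuit_flow.build_instance(network, target, tag_map[tag_id], expr)
                sol = circuit_flow.solve_directed(
                    inst, wrong_dir_max=wrong_dir_max, orientation=orientation
                )
            except UnsolvableInstanceError as err:
                unsolvable.append((target, tag_id, str(err)))
                continue
            null = circuit_flow.permutation_null(
                network, inst, rewired=rewired,
                wrong_dir_max=wrong_dir_max, orientation=orientation,
            )
            results.append(
                InstanceResult(
                    target=target,
                    tag_id=tag_id,
                    solution=sol,
                    candidate_p=circuit_flow.empirical_pvalues(sol, null),
                    node_p=circuit_flow.empirical_node_pvalues(sol, null),
                )
            )
    records = circuit_flow.select_candidates(
        results, current_frac=current_frac, emp_p=emp_p
    )

    graph = None
    final: list[str] = []
    if records:
        graph = causal_cover.build_explanation_graph(records, cnv, tags, de)
        final = causal_cover.greedy_weighted_cover(graph, gamma=gamma, delta=delta)

    paths = _extract_paths(results, records, final, emp_p=emp_p,
                           objective=path_objective)
    subnets = pathway_extraction.assemble_subnetworks(paths)
    hubs = pathway_extraction.count_hubs(paths, min_occurrences=hub_min)
    return PipelineResult(
        de_calls=de,
        targets=targets,
        tags=tags,
        associations=assoc,
        instance_results=results,
        unsolvable=unsolvable,
        candidate_records=records,
        explanation_graph=graph,
        final_causal=final,
        paths=paths,
        subnetworks=subnets,
        hubs=hubs,
    )


def _extract_paths(
    results: list[InstanceResult],
    records: list[CandidateRecord],
    final: list[str],
    emp_p: float,
    objective: str,
) -> list[CausalPath]:
    """One maximum-current path per final (causal gene, affected target) pair,
    taken from the pair's most significant circuit instance."""
    by_key = {(r.target, r.tag_id): r for r in results}
    best: dict[tuple[str, str], CandidateRecord] = {}
    final_set = set(final)
    for rec in records:
        if rec.gene not in final_set:
            continue
        key = (rec.gene, rec.target)
        if key not in best or (rec.p_value, rec.tag_id) < (
            best[key].p_value, best[key].tag_id
        ):
            best[key] = rec
    paths: list[CausalPath] = []
    for (cg, target), rec in sorted(best.items()):
        res = by_key[(target, rec.tag_id)]
        path = pathway_extraction.max_current_path(
            res.solution, res.node_p, target, cg,
            p_max=emp_p, objective=objective, tag_id=rec.tag_id,
        )
        if path is not None:
            paths.append(path)
    return paths


def analytic_summary(
    n_tags: int = 911,
    n_targets: int = 74,
    assoc_p: float = 0.01,
    emp_p: float = 0.05,
) -> dict[str, float]:
    """Closed-form pipeline bounds at a given operating point.

    For the cohort-scale defaults (911 tag loci × 74 target genes, regression
    filter p<0.01, empirical circuit filter p<0.05) this yields the total
    tested-pair count, the Bonferroni family-wise threshold on the pair
    regressions, and the combined nominal p-value bound that every retained
    (target, causal gene) pair satisfies.
    """
    n_pairs = eqtl_mapping.tested_pair_count(n_tags, n_targets)
    return {
        "tested_pair_count": float(n_pairs),
        "bonferroni_pair_threshold": eqtl_mapping.bonferroni_threshold(assoc_p, n_pairs),
        "nominal_pair_p_bound": circuit_flow.nominal_pair_p_bound(assoc_p, emp_p),
    }
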