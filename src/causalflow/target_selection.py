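"""Per-case differential-expression calls and greedy multi-set cover of cases.

Each tumor case gets its own set of differentially expressed genes: a gene's
expression in that case is converted to a Z-score against the control mean and
standard deviation, and called differential when the two-sided normal-tail
p-value falls below ``de_p``.  A small set of *target genes* that represents
the dysregulation of the whole cohort is then chosen as a minimum multi-set
cover: every case must be covered by at least ``alpha`` of the selected genes,
with up to ``beta`` outlier cases exempt.  The exact problem is NP-hard, so a
greedy heuristic picks, at each step, the gene covering the most residual
demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import ExpressionMatrix, ValidationError

__all__ = [
    "DifferentialCallMatrix",
    "CoverInstance",
    "InfeasibleCoverError",
    "compute_de_calls",
    "greedy_multiset_cover",
    "select_targets",
]

logger = logging.getLogger(__name__)


class InfeasibleCoverError(ValidationError):
    """More cases than the outlier budget can never reach the demanded coverage."""

    def __init__(self, message: str, cases: list[str]):
        super().__init__(message)
        self.cases = cases


@dataclass
class DifferentialCallMatrix:
    """Boolean DE calls and signed Z-scores, genes × tumor cases."""

    genes: list[str]
    cases: list[str]
    z: np.ndarray
    calls: np.ndarray
    de_p: float

    def direction(self, gene: str) -> str:
        """Dominant direction of a gene's significant calls ('up'/'down'/'none')."""
        i = self.genes.index(gene)
        signs = np.sign(self.z[i][self.calls[i]])
        if signs.size == 0:
            return "none"
        return "up" if signs.sum() >= 0 else "down"


def compute_de_calls(expr: ExpressionMatrix, de_p: float = 0.01) -> DifferentialCallMatrix:
    """Call per-case differential expression by a two-sided Z-test.

    Z = (x − μ_control) / σ_control per gene and tumor case; a call is made
    when 2·Φ(−|Z|) < ``de_p``.  Genes with zero control standard deviation are
    excluded with a logged warning.
    """
    if not 0 < de_p < 1:
        raise ValidationError(f"de_p must be in (0,1), got {de_p}")
    ctrl = expr.control_values
    mu = ctrl.mean(axis=1)
    sd = ctrl.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = [g for g, k in zip(expr.genes, keep) if not k]
    if dropped:
        logger.warning(
            "excluding %d gene(s) with zero control standard deviation: %s",
            len(dropped), dropped[:10],
        )
    tumor = expr.tumor_values[keep]
    z = (tumor - mu[keep, None]) / sd[keep, None]
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return DifferentialCallMatrix(
        genes=[g for g, k in zip(expr.genes, keep) if k],
        cases=expr.tumor_samples,
        z=z,
        calls=pvals < de_p,
        de_p=de_p,
    )


@dataclass
class CoverInstance:
    """Bipartite gene × case incidence with coverage demand and outlier budget.

    ``incidence[i, j]`` is True when gene i covers case j (a gene covers a
    case at most once).  Every non-exempt case must end up covered at least
    ``alpha`` times; up to ``beta`` cases may be exempted.
    """

    genes: list[str]
    cases: list[str]
    incidence: np.ndarray
    alpha: int
    beta: int

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=bool)
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if not 0 <= self.beta <= len(self.cases):
            raise ValidationError("beta must be in [0, n_cases]")
        if self.incidence.shape != (len(self.genes), len(self.cases)):
            raise ValidationError("incidence shape does not match genes × cases")

    @classmethod
    def from_calls(cls, calls: DifferentialCallMatrix, alpha: int, beta: int) -> "CoverInstance":
        return cls(genes=list(calls.genes), cases=list(calls.cases),
                   incidence=calls.calls.copy(), alpha=alpha, beta=beta)


def greedy_multiset_cover(instance: CoverInstance) -> list[str]:
    """Greedy minimum multi-set cover with an a-priori outlier exemption.

    The ``beta`` cases with the smallest achievable coverage (number of genes
    that can ever cover them) are exempted before the greedy loop; the loop
    then repeatedly picks the gene covering the most cases with remaining
    demand, breaking ties by lexicographic gene identifier.  Returns genes in
    selection order.

    Raises :class:`InfeasibleCoverError` when more than ``beta`` cases can
    never reach ``alpha`` coverage.
    """
    inc = instance.incidence
    n_cases = len(instance.cases)
    achievable = inc.sum(axis=0)  # genes available per case
    deficient = [c for c, a in zip(instance.cases, achievable) if a < instance.alpha]
    if len(deficient) > instance.beta:
        raise InfeasibleCoverError(
            f"{len(deficient)} case(s) can never reach coverage {instance.alpha} "
            f"with outlier budget {instance.beta}: {deficient[:10]}",
            deficient,
        )
    # exempt exactly beta cases: the least coverable, ties by case identifier
    order = sorted(range(n_cases), key=lambda j: (achievable[j], instance.cases[j]))
    exempt = set(order[: instance.beta])
    demand = np.full(n_cases, instance.alpha, dtype=int)
    for j in exempt:
        demand[j] = 0

    # stable lexicographic gene order for tie-breaking
    gene_order = sorted(range(len(instance.genes)), key=lambda i: instance.genes[i])
    available = set(gene_order)
    selected: list[str] = []
    active = demand > 0
    while active.any():
        best_i, best_gain = -1, 0
        for i in gene_order:
            if i not in available:
                continue
            gain = int(np.count_nonzero(inc[i] & active))
            if gain > best_gain:
                best_i, best_gain = i, gain
        if best_i < 0:  # unreachable for feasible instances
            raise InfeasibleCoverError(
                "no gene covers any remaining demand",
                [c for c, d in zip(instance.cases, demand) if d > 0],
            )
        available.remove(best_i)
        selected.append(instance.genes[best_i])
        covered = inc[best_i] & active
        demand[covered] -= 1
        active = demand > 0
    return selected


def select_targets(
    expr: ExpressionMatrix,
    alpha: int = 55,
    beta: int = 3,
    de_p: float = 0.01,
) -> list[str]:
    """Select target genes: DE calls followed by greedy multi-set cover.

    Defaults match the cohort-scale operating point (cover every case 55
    times, 3 outliers, per-case Z-test at p<0.01).
    """
    calls = compute_de_calls(expr, de_p=de_p)
    instance = CoverInstance.from_calls(calls, alpha=alpha, beta=beta)
    return greedy_multiset_cover(instance)
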