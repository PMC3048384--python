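"""Tag-locus compression and copy-number/expression association by regression.

Copy numbers of neighboring loci are highly correlated, so the locus list is
compressed into *tag loci*: a single left-to-right pass per chromosome opens a
region at the first uncovered locus (the tag) and extends it while every new
locus correlates with the tag above ``theta`` (default 0.9).  An alternative
bidirectional mode extends each region both ways from its tag, which can
produce overlapping regions.

Associations between target-gene expression and tag-locus copy number are then
scored by ordinary least squares over the shared tumor samples, with a
two-sided t-test on the slope; pairs below ``assoc_p`` (default 0.01) form the
associated set TL(i) of each target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CopyNumberProfile, ExpressionMatrix, ValidationError

__all__ = [
    "TagLocus",
    "AssociationResult",
    "select_tag_loci",
    "associate",
    "tested_pair_count",
    "bonferroni_threshold",
]

logger = logging.getLogger(__name__)


@dataclass
class TagLocus:
    """A representative locus and the contiguous region it stands for.

    ``start_index``/``end_index`` are inclusive 0-based indices into the
    genome-ordered locus list; the region never spans a chromosome boundary
    and every in-region locus correlates with the tag above the threshold.
    """

    tag_id: str
    tag_index: int
    chromosome: str
    start_index: int
    end_index: int
    region_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start_index <= self.tag_index <= self.end_index:
            raise ValidationError("tag index must lie within its region")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0:
        return np.nan
    return float((xd @ yd) / denom)


def select_tag_loci(
    cnv: CopyNumberProfile,
    theta: float = 0.9,
    mode: str = "ltr",
    _stats: dict | None = None,
) -> list[TagLocus]:
    """Compress loci into tag loci by a linear scan per chromosome.

    ``mode='ltr'`` (default): open a region at the first uncovered locus and
    extend rightward while corr(tag, locus) > theta.  ``mode='bidirectional'``:
    additionally extend leftward from each tag, allowing regions to overlap.
    A zero-variance locus becomes its own singleton tag with a warning.
    ``_stats`` (optional dict) records the number of correlation evaluations,
    used to assert the linear runtime of the scan.
    """
    if not 0 < theta < 1:
        raise ValidationError(f"theta must be in (0,1), got {theta}")
    if mode not in ("ltr", "bidirectional"):
        raise ValidationError(f"unknown scan mode {mode!r}")
    if cnv.n_loci < 1:
        raise ValidationError("need at least one locus")
    values = cnv.log2_ratios
    sds = values.std(axis=1)
    n_corr = 0
    tags: list[TagLocus] = []
    for chrom, lo, hi in cnv.chromosome_blocks():
        i = lo
        while i <= hi:
            tag = i
            if sds[tag] == 0:
                logger.warning(
                    "locus %s has zero variance; emitting singleton tag",
                    cnv.loci[tag].locus_id,
                )
                start = end = tag
                i = tag + 1
            else:
                end = tag
                while end + 1 <= hi:
                    if sds[end + 1] == 0:
                        break
                    n_corr += 1
                    if _pearson(values[tag], values[end + 1]) > theta:
                        end += 1
                    else:
                        break
                start = tag
                if mode == "bidirectional":
                    while start - 1 >= lo and sds[start - 1] > 0:
                        n_corr += 1
                        if _pearson(values[tag], values[start - 1]) > theta:
                            start -= 1
                        else:
                            break
                i = end + 1
            genes = sorted(
                {
                    g
                    for j in range(start, end + 1)
                    for g in cnv.locus_genes.get(cnv.loci[j].locus_id, [])
                }
            )
            tags.append(
                TagLocus(
                    tag_id=cnv.loci[tag].locus_id,
                    tag_index=tag,
                    chromosome=chrom,
                    start_index=start,
                    end_index=end,
                    region_genes=genes,
                )
            )
    if _stats is not None:
        _stats["n_corr_evals"] = n_corr
    return tags


@dataclass
class AssociationResult:
    """Regression results for every tested (target, tag) pair.

    ``pairs`` has columns target, tag_id, slope, p_value; ``associated``
    maps each target to its tag loci with p below the threshold.
    """

    pairs: pd.DataFrame
    associated: dict[str, list[str]]
    assoc_p: float

    def n_tested(self) -> int:
        return len(self.pairs)

    def n_associated(self) -> int:
        return int((self.pairs["p_value"] < self.assoc_p).sum())


def associate(
    expr: ExpressionMatrix,
    cnv: CopyNumberProfile,
    tags: list[TagLocus],
    targets: list[str],
    assoc_p: float = 0.01,
) -> AssociationResult:
    """OLS of tumor-sample expression on tag-locus copy number, per pair.

    The slope is tested two-sided against zero; pairs with p < ``assoc_p``
    form the associated set of each target.  Tags with zero copy-number
    variance are skipped with a warning.
    """
    if not 0 < assoc_p < 1:
        raise ValidationError(f"assoc_p must be in (0,1), got {assoc_p}")
    gene_idx = expr.gene_index()
    missing = [t for t in targets if t not in gene_idx]
    if missing:
        raise ValidationError(f"targets absent from expression matrix: {missing[:10]}")
    tumor = expr.tumor_samples
    shared = [s for s in tumor if s in set(cnv.samples)]
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared tumor samples for regression")
    expr_cols = [expr.samples.index(s) for s in shared]
    cnv_cols = [cnv.samples.index(s) for s in shared]
    rows = []
    for tag in tags:
        cn = cnv.log2_ratios[tag.tag_index, cnv_cols]
        if cn.std() == 0:
            logger.warning("tag %s has zero copy-number variance; skipped", tag.tag_id)
            continue
        for target in targets:
            y = expr.values[gene_idx[target], expr_cols]
            fit = stats.linregress(cn, y)
            rows.append((target, tag.tag_id, fit.slope, fit.pvalue))
    pairs = pd.DataFrame(rows, columns=["target", "tag_id", "slope", "p_value"])
    associated: dict[str, list[str]] = {t: [] for t in targets}
    for row in pairs.itertuples(index=False):
        if row.p_value < assoc_p:
            associated[row.target].append(row.tag_id)
    return AssociationResult(pairs=pairs, associated=associated, assoc_p=assoc_p)


def tested_pair_count(n_tags: int, n_targets: int) -> int:
    """Number of (target, tag) regressions performed genome-wide."""
    return int(n_tags) * int(n_targets)


def bonferroni_threshold(assoc_p: float, n_tests: int) -> float:
    """Family-wise threshold for the pair regressions: assoc_p / n_tests."""
    if n_tests <= 0:
        raise ValidationError("n_tests must be positive")
    return assoc_p / n_tests
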