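"""Synthetic cohorts and networks with planted causal structure.

The generator emulates the statistical structure the pipeline exploits in a
real tumor cohort, at desk scale:

* copy-number profiles whose neighboring loci are correlated (a first-order
  autoregressive process along the genome, per sample), with planted causal
  loci amplified in a configurable fraction of tumors;
* planted causal genes whose copy-number dosage perturbs the expression of a
  downstream target through a short network path whose last hop is a
  protein-DNA edge from a transcription factor into the target;
* a degree-heterogeneous background interaction network carrying all three
  edge types;
* Gaussian per-gene control expression, so the Z-score normalization of the
  target-selection stage is exactly calibrated.

Everything is reproducible from ``SimulationConfig.seed``.  The
:class:`PlantedTruth` record of what was planted supports recovery and
calibration experiments; :func:`worked_toy` returns a fixed 20-node bundle
used in documentation and unit tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core_data import (
    PHOSPHORYLATION,
    PPI,
    PROTEIN_DNA,
    CopyNumberProfile,
    Edge,
    ExpressionMatrix,
    InteractionNetwork,
    Locus,
    ValidationError,
    make_edge,
)
from .eqtl_mapping import TagLocus

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "GenerationError",
    "simulate_cohort",
    "worked_toy",
    "ToyBundle",
]

# fixed generator constants (see docs/methods.md for rationale)
_CN_NOISE_SD = 0.05     # background log2 spread around the diploid level 1
_CN_AMPLITUDE = 1.0     # planted amplification height on the log2 scale
_CN_WINDOW = 1          # planted shift also applied to +-1 neighboring loci
_PATH_RHO = 0.85        # co-expression of planted path nodes with the target
_TF_FRACTION = 0.10     # background transcription-factor fraction
_CTRL_MEAN_LOC, _CTRL_MEAN_SCALE = 7.0, 1.0
_CTRL_SD_LO, _CTRL_SD_HI = 0.3, 0.6


class GenerationError(ValidationError):
    """The requested configuration cannot be realized (e.g. the planted path
    does not fit into the gene pool)."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``path_length`` counts edges of each planted causal path (>= 2; the last
    edge is always TF -> target protein-DNA).  ``effect_size`` is the
    regression slope of target expression on the causal locus's log2 copy
    number; ``cna_fraction`` the fraction of tumors carrying each planted
    amplification; ``neighbor_corr`` the target Pearson correlation of
    adjacent copy-number loci.
    """

    n_tumor: int = 150
    n_control: int = 30
    n_genes: int = 400
    n_loci: int = 48
    genes_per_locus: float = 3.0
    n_planted_causal: int = 4
    path_length: int = 3
    effect_size: float = 2.0
    noise_sd: float = 0.5
    cna_fraction: float = 0.4
    neighbor_corr: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_control", "n_genes", "n_loci",
                     "n_planted_causal"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_control < 2:
            raise ValidationError("need at least 2 controls")
        if self.genes_per_locus <= 0:
            raise ValidationError("genes_per_locus must be positive")
        if not 0 <= self.cna_fraction <= 1:
            raise ValidationError("cna_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.path_length < 2:
            raise ValidationError("path_length must be >= 2 "
                                  "(the last hop is a protein-DNA edge)")
        if not 0 < self.neighbor_corr < 1:
            raise ValidationError("neighbor_corr must be in (0, 1)")


@dataclass
class PlantedTruth:
    """What was planted: causal genes, their targets, paths and loci."""

    causal_genes: list[str]
    target_genes: list[str]
    causal_paths: list[list[str]]  # each: causal gene ... TF, target
    locus_of_causal: dict[str, str]

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.causal_genes, self.target_genes))


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, CopyNumberProfile, InteractionNetwork, PlantedTruth]:
    """Generate one cohort (expression, copy number, network, truth)."""
    rng = np.random.default_rng(config.seed)
    n_path_nodes = config.path_length + 1
    n_special = config.n_planted_causal * n_path_nodes
    if n_special + config.n_planted_causal > config.n_genes:
        raise GenerationError(
            f"{config.n_planted_causal} paths of {n_path_nodes} nodes do not "
            f"fit into {config.n_genes} genes"
        )
    genes = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]
    pool = [str(g) for g in rng.permutation(genes)]

    # planted roles: per path, (causal, intermediates..., TF, target)
    causal_genes, target_genes, path_tfs = [], [], []
    paths: list[list[str]] = []
    for _ in range(config.n_planted_causal):
        nodes = [pool.pop() for _ in range(n_path_nodes)]
        causal_genes.append(nodes[0])
        path_tfs.append(nodes[-2])
        target_genes.append(nodes[-1])
        paths.append(nodes)

    # --- loci and locus->genes map -------------------------------------
    chroms = ["chr1", "chr2", "chr3"]
    per_chrom = _split_sizes(config.n_loci, len(chroms))
    loci: list[Locus] = []
    for chrom, size in zip(chroms, per_chrom):
        for k in range(size):
            loci.append(Locus(f"L{len(loci) + 1:03d}", chrom, (k + 1) * 1_000_000))
    blocks = _blocks(loci)
    planted_idx = _planted_locus_indices(config.n_planted_causal, blocks)

    locus_genes: dict[str, list[str]] = {l.locus_id: [] for l in loci}
    for cg, idx in zip(causal_genes, planted_idx):
        locus_genes[loci[idx].locus_id].append(cg)
    n_resident = min(len(pool), round(config.n_loci * config.genes_per_locus))
    residents = [pool.pop() for _ in range(n_resident)]
    for g in residents:
        locus_genes[loci[rng.integers(config.n_loci)].locus_id].append(g)

    # --- copy number ----------------------------------------------------
    tumor_samples = [f"t{j:03d}" for j in range(1, config.n_tumor + 1)]
    log2 = np.empty((config.n_loci, config.n_tumor))
    phi = config.neighbor_corr
    innov = math.sqrt(1.0 - phi * phi)
    for _, lo, hi in blocks:
        z = np.empty((hi - lo + 1, config.n_tumor))
        z[0] = rng.standard_normal(config.n_tumor)
        for k in range(1, hi - lo + 1):
            z[k] = phi * z[k - 1] + innov * rng.standard_normal(config.n_tumor)
        log2[lo : hi + 1] = 1.0 + _CN_NOISE_SD * z
    carriers_of: dict[str, np.ndarray] = {}
    n_carriers = int(round(config.cna_fraction * config.n_tumor))
    for cg, idx in zip(causal_genes, planted_idx):
        carriers = rng.choice(config.n_tumor, size=n_carriers, replace=False)
        carriers_of[cg] = carriers
        chrom_block = next(b for b in blocks if b[1] <= idx <= b[2])
        lo = max(chrom_block[1], idx - _CN_WINDOW)
        hi = min(chrom_block[2], idx + _CN_WINDOW)
        log2[np.ix_(range(lo, hi + 1), carriers)] += _CN_AMPLITUDE
    cnv = CopyNumberProfile(
        loci=loci,
        samples=tumor_samples,
        log2_ratios=log2,
        locus_genes={k: v for k, v in locus_genes.items() if v},
    )

    # --- interaction network -------------------------------------------
    ba_seed = int(rng.integers(2**31))
    base = nx.barabasi_albert_graph(config.n_genes, 2, seed=ba_seed)
    relabel = {i: str(g) for i, g in enumerate(rng.permutation(genes))}
    is_tf = {g: False for g in genes}
    n_bg_tf = max(1, round(_TF_FRACTION * config.n_genes))
    for g in rng.choice(genes, size=n_bg_tf, replace=False):
        is_tf[str(g)] = True
    for tf in path_tfs:
        is_tf[tf] = True
    edges: dict[tuple[str, str, str], Edge] = {}

    def add(u: str, v: str, etype: str) -> None:
        if u == v:
            return
        e = make_edge(u, v, etype)
        edges.setdefault(e.key(), e)

    # planted edges first so background edges cannot shadow them
    for nodes in paths:
        for a, b in zip(nodes[:-2], nodes[1:-1]):
            add(a, b, PPI)
        add(nodes[-2], nodes[-1], PROTEIN_DNA)  # TF -> target
    for a, b in base.edges():
        add(relabel[a], relabel[b], PPI)
    tf_list = sorted(g for g, f in is_tf.items() if f)
    for tf in tf_list:
        for g in rng.choice(genes, size=2, replace=False):
            add(tf, str(g), PROTEIN_DNA)
    for _ in range(max(2, round(0.02 * config.n_genes))):
        u, v = rng.choice(genes, size=2, replace=False)
        add(str(u), str(v), PHOSPHORYLATION)
    network = InteractionNetwork(nodes=is_tf, edges=list(edges.values()))

    # --- expression -----------------------------------------------------
    control_samples = [f"c{j:03d}" for j in range(1, config.n_control + 1)]
    samples = control_samples + tumor_samples
    is_control = np.array([True] * config.n_control + [False] * config.n_tumor)
    mu = _CTRL_MEAN_LOC + _CTRL_MEAN_SCALE * rng.standard_normal(config.n_genes)
    sd = rng.uniform(_CTRL_SD_LO, _CTRL_SD_HI, size=config.n_genes)
    values = mu[:, None] + sd[:, None] * rng.standard_normal(
        (config.n_genes, len(samples))
    )
    gidx = {g: i for i, g in enumerate(genes)}
    tumor_cols = np.arange(config.n_control, len(samples))
    for cg, tgt, nodes, idx in zip(causal_genes, target_genes, paths, planted_idx):
        ti = gidx[tgt]
        dosage = log2[idx] - 1.0  # causal locus log2 CN, centered at diploid
        # cis effect: the amplified causal gene is itself overexpressed ...
        values[gidx[cg], tumor_cols] += config.effect_size * dosage + rng.normal(
            0.0, config.noise_sd, size=config.n_tumor
        )
        # ... and the dosage propagates to its downstream target
        values[ti, tumor_cols] += config.effect_size * dosage + rng.normal(
            0.0, config.noise_sd, size=config.n_tumor
        )
        t_tumor = values[ti, tumor_cols]
        zt = (t_tumor - t_tumor.mean()) / max(t_tumor.std(), 1e-12)
        for g in nodes[1:-1]:  # intermediates and the TF co-express with target
            k = gidx[g]
            mix = _PATH_RHO * zt + math.sqrt(1 - _PATH_RHO**2) * rng.standard_normal(
                config.n_tumor
            )
            values[k, tumor_cols] = mu[k] + sd[k] * mix
    expr = ExpressionMatrix(genes=genes, samples=samples, values=values,
                            is_control=is_control)

    truth = PlantedTruth(
        causal_genes=causal_genes,
        target_genes=target_genes,
        causal_paths=paths,
        locus_of_causal={
            cg: loci[idx].locus_id for cg, idx in zip(causal_genes, planted_idx)
        },
    )
    return expr, cnv, network, truth


def _split_sizes(total: int, parts: int) -> list[int]:
    base = total // parts
    sizes = [base] * parts
    for k in range(total - base * parts):
        sizes[k] += 1
    return [s for s in sizes if s > 0]


def _blocks(loci: list[Locus]) -> list[tuple[str, int, int]]:
    blocks = []
    start = 0
    for i in range(1, len(loci) + 1):
        if i == len(loci) or loci[i].chromosome != loci[start].chromosome:
            blocks.append((loci[start].chromosome, start, i - 1))
            start = i
    return blocks


def _planted_locus_indices(n_planted: int, blocks) -> list[int]:
    n_loci = blocks[-1][2] + 1
    if n_planted > n_loci:
        raise GenerationError("more planted loci requested than loci available")
    raw = [int((k + 0.5) * n_loci / n_planted) for k in range(n_planted)]
    # keep the amplification window inside its chromosome block
    out = []
    for idx in raw:
        chrom = next(b for b in blocks if b[1] <= idx <= b[2])
        idx = min(max(idx, chrom[1] + _CN_WINDOW), chrom[2] - _CN_WINDOW)
        out.append(idx)
    if len(set(out)) != len(out):
        raise GenerationError(
            "planted loci collide; increase n_loci or reduce n_planted_causal"
        )
    return out


# ---------------------------------------------------------------------------
# worked toy


@dataclass
class ToyBundle:
    """A fixed, hand-checkable 20-node bundle for docs and unit tests."""

    expr: ExpressionMatrix
    cnv: CopyNumberProfile
    network: InteractionNetwork
    target: str
    tag: TagLocus
    cover_genes: list[str]
    cover_cases: list[str]
    cover_incidence: np.ndarray


def worked_toy() -> ToyBundle:
    """Build the fixed toy: 20 genes, 8 samples (3 controls), 6 loci.

    The circuit part wires target ``t`` behind transcription factor ``tf1``;
    two candidate genes ``c1``/``c2`` in the tag region at the end of a short
    conductive path, one decoy ``c3``.  Tumor expression of the path genes
    tracks the target exactly, so the path conductances are 1 and the currents
    can be traced by hand.  The cover part is a tiny 3-gene × 4-case instance
    whose optimum is found by enumeration.
    """
    specials = ["t", "tf1", "mid1", "mid2", "c1", "c2", "c3"]
    fillers = [f"f{k:02d}" for k in range(1, 14)]
    genes = specials + fillers

    # network: 20 nodes; tf1 is the only way into t
    raw_edges = [
        ("tf1", PROTEIN_DNA, "t"),
        ("tf1", PPI, "mid1"),
        ("mid1", PPI, "c1"),
        ("mid1", PPI, "mid2"),
        ("mid2", PPI, "c2"),
        ("tf1", PPI, "c3"),
        ("f01", PPI, "mid2"),
        ("f02", PHOSPHORYLATION, "f03"),
    ]
    raw_edges += [(fillers[k], PPI, fillers[k + 1]) for k in range(len(fillers) - 1)]
    nodes = {g: g == "tf1" for g in genes}
    network = InteractionNetwork(
        nodes=nodes, edges=[make_edge(u, v, et) for u, et, v in raw_edges]
    )

    # cohort: 3 controls then 5 tumors
    samples = ["c1s", "c2s", "c3s", "s1", "s2", "s3", "s4", "s5"]
    is_control = np.array([True, True, True, False, False, False, False, False])
    base = np.array([5.0, 5.1, 4.9])  # controls: mean 5, sd 0.1
    ramp = np.array([1.0, 2.0, 3.0, 4.0, 5.0])  # tumor profile of the path genes
    values = np.tile(np.concatenate([base, np.full(5, 5.0)]), (len(genes), 1))
    for g in ("t", "tf1", "mid1", "mid2", "c1", "c2"):
        values[genes.index(g), 3:] = ramp
    values[genes.index("c3"), 3:] = ramp[::-1]  # anti-correlated decoy
    values[genes.index("f01"), 3:] = np.array([5.0, 5.2, 4.8, 5.1, 4.9])
    expr = ExpressionMatrix(genes=genes, samples=samples, values=values,
                            is_control=is_control)

    # copy number: 6 loci; L2/L3 form the altered tag region harboring c1, c2
    loci = [
        Locus("L1", "chr1", 1_000_000),
        Locus("L2", "chr1", 2_000_000),
        Locus("L3", "chr1", 3_000_000),
        Locus("L4", "chr1", 4_000_000),
        Locus("L5", "chr2", 1_000_000),
        Locus("L6", "chr2", 2_000_000),
    ]
    log2 = np.array(
        [
            [1.00, 1.01, 0.99, 1.02, 0.98],
            [2.00, 2.00, 1.00, 1.00, 1.00],
            [2.00, 2.02, 1.00, 1.02, 1.00],
            [1.01, 0.99, 1.00, 1.01, 0.99],
            [1.00, 1.02, 1.01, 0.99, 1.00],
            [0.99, 1.00, 1.02, 1.00, 1.01],
        ]
    )
    cnv = CopyNumberProfile(
        loci=loci,
        samples=["s1", "s2", "s3", "s4", "s5"],
        log2_ratios=log2,
        locus_genes={"L2": ["c1", "c2"], "L3": ["c3"]},
    )
    tag = TagLocus(tag_id="L2", tag_index=1, chromosome="chr1",
                   start_index=1, end_index=2, region_genes=["c1", "c2", "c3"])

    cover_genes = ["g1", "g2", "g3"]
    cover_cases = ["s1", "s2", "s3", "s4"]
    cover_incidence = np.array(
        [
            [True, True, True, False],   # g1 covers s1,s2,s3
            [False, False, True, True],  # g2 covers s3,s4
            [False, False, False, True], # g3 covers s4
        ]
    )
    return ToyBundle(
        expr=expr,
        cnv=cnv,
        network=network,
        target="t",
        tag=tag,
        cover_genes=cover_genes,
        cover_cases=cover_cases,
        cover_incidence=cover_incidence,
    )


def write_truth(truth: PlantedTruth, path) -> None:
    """Write the planted-truth table: gene, role, locus, path."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene\trole\tlocus\tpath\n")
        for cg, tgt, nodes in zip(truth.causal_genes, truth.target_genes,
                                  truth.causal_paths):
            locus = truth.locus_of_causal[cg]
            handle.write(f"{cg}\tcausal\t{locus}\t{'|'.join(nodes)}\n")
            handle.write(f"{tgt}\ttarget\t\t{'|'.join(nodes)}\n")
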