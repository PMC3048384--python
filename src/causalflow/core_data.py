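"""Core domain containers and plain-text I/O shared by every pipeline stage.

The pipeline couples three data modalities for one disease cohort:

* an :class:`ExpressionMatrix` — log-scale expression, genes × samples, with a
  tumor/control partition (controls supply the mean and standard deviation for
  per-case Z-scores);
* a :class:`CopyNumberProfile` — genome-ordered loci × tumor samples of log2
  copy-number ratios, plus a locus→genes map (diploid sits near log2 CN = 1 on
  this scale, so the alteration statistic is ``log2_ratio - 1``);
* an :class:`InteractionNetwork` — a typed, partially directed molecular graph
  (undirected protein–protein edges; directed protein–DNA and phosphorylation
  edges) with a transcription-factor flag per node.

All file formats are tab-separated UTF-8 text.  Readers validate and reject
malformed input rather than repairing it; writers emit rows in input order so
that reader∘writer is the identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ExpressionMatrix",
    "Locus",
    "CopyNumberProfile",
    "Edge",
    "InteractionNetwork",
    "AMPLIFIED",
    "DELETED",
    "NEUTRAL",
    "PPI",
    "PROTEIN_DNA",
    "PHOSPHORYLATION",
    "EDGE_TYPES",
    "call_alteration",
    "alteration_states",
    "read_expression",
    "write_expression",
    "read_cnv",
    "write_cnv",
    "read_network",
    "write_network",
    "read_gmt",
    "write_gmt",
]

# edge types
PPI = "ppi"
PROTEIN_DNA = "protein_dna"
PHOSPHORYLATION = "phosphorylation"
EDGE_TYPES = frozenset({PPI, PROTEIN_DNA, PHOSPHORYLATION})
DIRECTED_TYPES = frozenset({PROTEIN_DNA, PHOSPHORYLATION})

# alteration states
AMPLIFIED = "amplified"
DELETED = "deleted"
NEUTRAL = "neutral"

# strict thresholds on (log2 CN - 1); equality maps to neutral
ALTERATION_THRESHOLD = 0.1

_FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ValueError):
    """Structurally well-formed input violates a domain invariant."""


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionMatrix:
    """Log-scale expression values for a tumor/control cohort.

    ``values`` is genes × samples; ``is_control`` flags the control subset of
    ``samples``.  At least two controls are required so that per-gene control
    standard deviations are computable.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    is_control: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.is_control = np.asarray(self.is_control, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample identifiers")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.genes)}, {len(self.samples)})"
            )
        if self.is_control.shape != (len(self.samples),):
            raise ValidationError("is_control length does not match samples")
        if int(self.is_control.sum()) < 2:
            raise ValidationError("need at least 2 control samples")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s, c in zip(self.samples, self.is_control) if not c]

    @property
    def control_samples(self) -> list[str]:
        return [s for s, c in zip(self.samples, self.is_control) if c]

    @property
    def tumor_values(self) -> np.ndarray:
        return self.values[:, ~self.is_control]

    @property
    def control_values(self) -> np.ndarray:
        return self.values[:, self.is_control]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def read_expression(expr_path, samples_path) -> ExpressionMatrix:
    """Read an expression table plus its tumor/control sidecar.

    The table has gene identifiers in the first column and sample identifiers
    in the header; the sidecar has rows ``sample<TAB>{tumor|control}``.
    """
    frame = pd.read_csv(expr_path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"duplicate gene row {dup!r}")
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)][0]
        raise FormatError(f"missing value in row {bad!r}")
    labels = _read_sample_labels(samples_path)
    samples = [str(s) for s in frame.columns]
    missing = [s for s in samples if s not in labels]
    if missing:
        raise ValidationError(f"samples without tumor/control label: {missing}")
    is_control = np.array([labels[s] == "control" for s in samples])
    return ExpressionMatrix(
        genes=[str(g) for g in frame.index],
        samples=samples,
        values=frame.to_numpy(dtype=float),
        is_control=is_control,
    )


def _read_sample_labels(path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{line_no}: expected 2 columns")
            sample, label = parts
            if label not in ("tumor", "control"):
                raise FormatError(f"{path}:{line_no}: unknown label {label!r}")
            if sample in labels:
                raise FormatError(f"{path}:{line_no}: duplicate sample {sample!r}")
            labels[sample] = label
    return labels


def write_expression(expr: ExpressionMatrix, expr_path, samples_path) -> None:
    with open(expr_path, "w", encoding="utf-8") as handle:
        handle.write("gene\t" + "\t".join(expr.samples) + "\n")
        for gene, row in zip(expr.genes, expr.values):
            cells = "\t".join(_FLOAT_FMT % x for x in row)
            handle.write(f"{gene}\t{cells}\n")
    with open(samples_path, "w", encoding="utf-8") as handle:
        for sample, ctrl in zip(expr.samples, expr.is_control):
            handle.write(f"{sample}\t{'control' if ctrl else 'tumor'}\n")


# ---------------------------------------------------------------------------
# copy number


@dataclass(frozen=True)
class Locus:
    locus_id: str
    chromosome: str
    position: int


@dataclass
class CopyNumberProfile:
    """Genome-ordered log2 copy-number ratios over the tumor samples.

    ``loci`` must be grouped by chromosome with strictly increasing positions
    within each chromosome; ``locus_genes`` maps each locus to the genes it
    harbors (possibly empty).
    """

    loci: list[Locus]
    samples: list[str]
    log2_ratios: np.ndarray
    locus_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.log2_ratios = np.asarray(self.log2_ratios, dtype=float)
        self.validate()

    def validate(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate locus identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample identifiers")
        if self.log2_ratios.shape != (len(self.loci), len(self.samples)):
            raise ValidationError("log2_ratios shape does not match loci × samples")
        if not np.all(np.isfinite(self.log2_ratios)):
            raise ValidationError("log2 ratios must be finite")
        seen_chroms: list[str] = []
        for prev, cur in zip(self.loci, self.loci[1:]):
            if prev.chromosome == cur.chromosome:
                if cur.position <= prev.position:
                    raise ValidationError(
                        f"positions not increasing at locus {cur.locus_id}"
                    )
            else:
                seen_chroms.append(prev.chromosome)
                if cur.chromosome in seen_chroms:
                    raise ValidationError(
                        f"chromosome {cur.chromosome} split into blocks"
                    )
        unknown = set(self.locus_genes) - set(ids)
        if unknown:
            raise ValidationError(f"locus_genes for unknown loci: {sorted(unknown)}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self) -> dict[str, int]:
        return {l.locus_id: i for i, l in enumerate(self.loci)}

    def chromosome_blocks(self) -> list[tuple[str, int, int]]:
        """Contiguous (chromosome, start, end) index ranges, end inclusive."""
        blocks: list[tuple[str, int, int]] = []
        start = 0
        for i in range(1, len(self.loci) + 1):
            if i == len(self.loci) or self.loci[i].chromosome != self.loci[start].chromosome:
                blocks.append((self.loci[start].chromosome, start, i - 1))
                start = i
        return blocks

    def alteration_matrix(self) -> np.ndarray:
        """Integer states per (locus, sample): +1 amplified, -1 deleted, 0 neutral."""
        return alteration_states(self.log2_ratios)


def call_alteration(log2_ratio: float) -> str:
    """Classify one log2 copy-number value as amplified/deleted/neutral.

    On this scale diploid sits near 1, so the statistic is ``log2_ratio - 1``:
    amplified when it exceeds 0.1, deleted when below -0.1, neutral otherwise
    (boundary equality is neutral — the inequalities are strict).
    """
    if not math.isfinite(log2_ratio):
        raise ValidationError(f"non-finite copy-number value {log2_ratio!r}")
    stat = log2_ratio - 1.0
    if stat > ALTERATION_THRESHOLD:
        return AMPLIFIED
    if stat < -ALTERATION_THRESHOLD:
        return DELETED
    return NEUTRAL


def alteration_states(log2_ratios: np.ndarray) -> np.ndarray:
    """Vectorized :func:`call_alteration`; +1 amplified, -1 deleted, 0 neutral."""
    arr = np.asarray(log2_ratios, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite copy-number value")
    stat = arr - 1.0
    out = np.zeros(arr.shape, dtype=np.int8)
    out[stat > ALTERATION_THRESHOLD] = 1
    out[stat < -ALTERATION_THRESHOLD] = -1
    return out


def read_cnv(cnv_path, locus_genes_path=None) -> CopyNumberProfile:
    """Read a copy-number table (locus_id, chromosome, position, samples...).

    ``locus_genes_path`` is an optional two-column table ``locus_id<TAB>gene``
    with one row per (locus, gene) assignment.
    """
    frame = pd.read_csv(cnv_path, sep="\t", dtype={0: str, 1: str})
    cols = list(frame.columns)
    if cols[:3] != ["locus_id", "chromosome", "position"]:
        raise FormatError(
            "copy-number table must start with locus_id, chromosome, position"
        )
    if frame["locus_id"].duplicated().any():
        dup = frame["locus_id"][frame["locus_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate locus row {dup!r}")
    loci = [
        Locus(str(r.locus_id), str(r.chromosome), int(r.position))
        for r in frame.itertuples(index=False)
    ]
    samples = [str(c) for c in cols[3:]]
    values = frame[cols[3:]].to_numpy(dtype=float)
    locus_genes: dict[str, list[str]] = {}
    if locus_genes_path is not None:
        with open(locus_genes_path, encoding="utf-8") as handle:
            for line_no, line in enumerate(handle, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(f"{locus_genes_path}:{line_no}: expected 2 columns")
                locus_genes.setdefault(parts[0], []).append(parts[1])
    return CopyNumberProfile(loci=loci, samples=samples, log2_ratios=values,
                             locus_genes=locus_genes)


def write_cnv(cnv: CopyNumberProfile, cnv_path, locus_genes_path=None) -> None:
    with open(cnv_path, "w", encoding="utf-8") as handle:
        handle.write("locus_id\tchromosome\tposition\t" + "\t".join(cnv.samples) + "\n")
        for locus, row in zip(cnv.loci, cnv.log2_ratios):
            cells = "\t".join(_FLOAT_FMT % x for x in row)
            handle.write(f"{locus.locus_id}\t{locus.chromosome}\t{locus.position}\t{cells}\n")
    if locus_genes_path is not None:
        with open(locus_genes_path, "w", encoding="utf-8") as handle:
            for locus in cnv.loci:
                for gene in cnv.locus_genes.get(locus.locus_id, []):
                    handle.write(f"{locus.locus_id}\t{gene}\n")


# ---------------------------------------------------------------------------
# interaction network


@dataclass(frozen=True)
class Edge:
    """One molecular interaction.

    For directed types (protein–DNA, phosphorylation) ``u`` is the regulator /
    kinase and ``v`` the regulated gene / substrate.  Undirected protein–protein
    edges are stored with endpoints in lexicographic order.
    """

    u: str
    v: str
    etype: str
    directed: bool

    def key(self) -> tuple[str, str, str]:
        a, b = sorted((self.u, self.v))
        return (a, b, self.etype)


def make_edge(u: str, v: str, etype: str) -> Edge:
    if etype not in EDGE_TYPES:
        raise FormatError(f"unknown interaction type {etype!r}")
    if u == v:
        raise ValidationError(f"self-loop on {u!r}")
    if etype == PPI:
        u, v = sorted((u, v))
        return Edge(u, v, etype, directed=False)
    return Edge(u, v, etype, directed=True)


@dataclass
class InteractionNetwork:
    """Typed, partially directed molecular-interaction graph with TF flags."""

    nodes: dict[str, bool]  # gene -> is_transcription_factor
    edges: list[Edge]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for edge in self.edges:
            if edge.u == edge.v:
                raise ValidationError(f"self-loop on {edge.u!r}")
            if edge.etype not in EDGE_TYPES:
                raise FormatError(f"unknown interaction type {edge.etype!r}")
            if edge.u not in self.nodes or edge.v not in self.nodes:
                raise ValidationError(
                    f"edge ({edge.u!r}, {edge.v!r}) references an undeclared node"
                )
            key = edge.key()
            if key in seen:
                raise ValidationError(f"duplicate edge {key}")
            seen.add(key)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def is_tf(self, gene: str) -> bool:
        return self.nodes[gene]

    def degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.u] += 1
            deg[e.v] += 1
        return deg

    def edge_key_set(self) -> set[tuple[str, str, str]]:
        return {e.key() for e in self.edges}


def read_network(sif_path, attrs_path) -> InteractionNetwork:
    """Read a SIF-dialect edge list plus a node-attribute table flagging TFs.

    SIF rows are ``u<TAB>type<TAB>v`` with type in {ppi, protein_dna,
    phosphorylation}; the attribute table has rows ``gene<TAB>{tf|non_tf}``
    and declares the node set.  Duplicate edges (same unordered pair and
    type) are merged.
    """
    nodes: dict[str, bool] = {}
    with open(attrs_path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{attrs_path}:{line_no}: expected 2 columns")
            gene, flag = parts
            if flag not in ("tf", "non_tf"):
                raise FormatError(f"{attrs_path}:{line_no}: unknown flag {flag!r}")
            nodes[gene] = flag == "tf"
    edges: list[Edge] = []
    seen: set[tuple[str, str, str]] = set()
    with open(sif_path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{sif_path}:{line_no}: expected 3 columns")
            u, etype, v = parts
            edge = make_edge(u, v, etype)
            if u not in nodes or v not in nodes:
                raise ValidationError(f"{sif_path}:{line_no}: undeclared node")
            if edge.key() in seen:
                continue
            seen.add(edge.key())
            edges.append(edge)
    return InteractionNetwork(nodes=nodes, edges=edges)


def write_network(net: InteractionNetwork, sif_path, attrs_path) -> None:
    with open(sif_path, "w", encoding="utf-8") as handle:
        for e in net.edges:
            handle.write(f"{e.u}\t{e.etype}\t{e.v}\n")
    with open(attrs_path, "w", encoding="utf-8") as handle:
        for gene, tf in net.nodes.items():
            handle.write(f"{gene}\t{'tf' if tf else 'non_tf'}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path) -> dict[str, list[str]]:
    """Read reference gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{line_no}: expected name, description, genes")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{line_no}: duplicate gene set {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, genes in sets.items():
            handle.write(name + "\t" + description + "\t" + "\t".join(genes) + "\n")
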