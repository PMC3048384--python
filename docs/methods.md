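# Methods

`causalflow` infers causal genes and the pathways through which they act from
three inputs measured on one disease cohort: a gene × sample expression
matrix with a tumor/control partition, a genome-ordered locus × tumor-sample
matrix of log2 copy-number ratios with a locus→genes map, and a typed
molecular-interaction network (undirected protein–protein edges; directed
protein–DNA and phosphorylation edges; a transcription-factor flag per node).
The model's premise is the standard eQTL one: part of the expression
variation of disease-relevant genes is caused by somatic copy-number
alterations, and the causal influence propagates through physical
interactions.

## Stage 1 — target genes

Expression of each gene in each tumor case is normalized to a Z-score using
the control mean and the control standard deviation of that gene (ddof = 1;
genes with zero control variance are excluded with a warning).  A gene is
*differentially expressed* (DE) in a case when the two-sided normal tail
2·Φ(−|Z|) falls below `de_p` (default 0.01).  A representative set of target
genes is a minimum multi-set cover: each case must be covered by at least
`alpha` DE genes, with `beta` outlier cases exempt.  The exact problem is
NP-hard; the greedy solver exempts, before the loop, the `beta` cases with
the smallest achievable coverage (ties by case identifier), then repeatedly
takes the gene covering the most remaining demand, ties by gene identifier.
A gene covers a case at most once.  The cohort-scale defaults are
`alpha=55`, `beta=3`; on the synthetic cohorts described below the operating
point is `alpha=2`, `beta=12` (four planted targets cannot cover a case 55
times).

The greedy multi-cover inherits the classical (1 + ln n) approximation
guarantee for its fixed-exemption instance; the test suite verifies the
ratio against a brute-force optimum that may also choose its outliers
freely.

## Stage 2 — tag loci and associations

Copy numbers of neighboring loci are strongly correlated, so loci are
compressed to *tag loci*: a single left-to-right pass per chromosome opens a
region at the first uncovered locus (the tag) and extends it while the
Pearson correlation between the tag's and the new locus's copy-number
profiles exceeds `theta` (default 0.9).  A zero-variance locus becomes its
own singleton tag.  An alternative `bidirectional` mode also extends each
region leftwards from its tag, which can create overlapping regions; the
default is the plain left-to-right scan.  The scan evaluates O(1)
correlations per locus, hence linear time.

Each (target gene, tag locus) pair is scored by ordinary least squares of
tumor-sample expression on the tag's log2 copy number — the raw continuous
value, not the discretized alteration call — with a two-sided t-test on the
slope.  Pairs with p < `assoc_p` (default 0.01) form the associated set of
the target.  No multiple-testing correction is applied at this stage on
purpose; the liberal threshold feeds the network stage, which supplies the
real specificity.  At the cohort-scale operating point (911 tag loci × 74
targets = 67,414 regressions) the implied Bonferroni threshold is
0.01/67,414 ≈ 1.5×10⁻⁷, and a pair surviving both the regression filter and
the later empirical circuit filter carries a combined nominal bound of
0.01 × 0.05 = 5×10⁻⁴; `causalflow.pipeline.analytic_summary` computes these
closed-form quantities.

## Stage 3 — circuit flow

For each associated pair, the flow of regulatory information from the target
back to its potential causes is modeled as current in a resistor network.
The target injects a unit current; every gene of the tag region present in
the network is grounded at 0 V; each edge (u, v) has conductance
w(e) = (|corr(u, tg)| + |corr(v, tg)|)/2 over tumor samples, floored at
ε = 10⁻³ (genes without expression contribute ε in place of the correlation
magnitude).  The floor means one uncorrelated node damps but never severs a
path, while a stretch of uncorrelated nodes is effectively resistive.
Absolute correlation is used because a negative regulator carries
information just as well, and negative conductances are physically
inadmissible.

Two biological constraints shape the instance.  First, only transcription
factors act directly on transcription: every edge at the target is deleted
except protein–DNA edges from a TF into the target; an instance whose target
has no such edge is recorded as unsolvable and skipped.  Second, directed
edges must be used in their admissible direction.  Because the current runs
from the *target* toward the *causes* — against the direction of regulation —
the admissible current direction on a regulator→regulated edge is
regulated→regulator (a configurable `orientation` flag provides the opposite
frame).  An exact directed formulation is a linear program too costly at
interactome scale; instead, the solver iterates: solve the undirected
system, delete every directed edge whose current runs the wrong way, stop
when at most `wrong_dir_max` such edges remain (default 0.1% of the
instance's edges, at least 1).  The wrong-edge count is checked to be
non-increasing in the tests.

Solving uses the grounded-Laplacian reduction: with candidate voltages fixed
at 0, the free-node block of the weighted Laplacian is non-singular on the
target's connected component, and one linear solve (dense below ~600 free
nodes, sparse above) yields all voltages, edge currents and the exit current
X[c] into each candidate.  ΣX[c] equals the injected unit current; the
Kirchhoff residual is checked to 10⁻⁸.  The test suite cross-checks the
reduction against an independently coded dense solve of the raw
Ohm/Kirchhoff/ground block system to 10⁻¹⁰, and against simulated
absorbing-random-walk probabilities (the exit currents are exactly the
absorption probabilities of a conductance-weighted walk).

### Permutation null and empirical p-values

Raw currents are incomparable across regions of different size, so
candidates are scored against a topology null: `n_perm` (default 30)
degree-preserving double-edge-swap rewirings of the whole network, each
solved with **unit** conductances, the real target, the real candidate set
and the TF constraint.  Swap partners are drawn within the same edge-type
class, so every node preserves its per-type in/out degree — in particular a
target keeps its TF in-degree and null instances stay solvable.  Each
rewiring accepts 10×|E| swaps (an error is raised if acceptance stagnates).
A normal distribution is fitted to each candidate's null currents and the
empirical p-value is the upper tail 1 − Φ((x_obs − μ)/σ); a degenerate σ = 0
yields 0 above the mean and 1 otherwise.  The same machinery records
per-node throughflow (half the sum of absolute incident currents) in each
rewiring, giving node-level empirical p-values used by the path stage.

One set of rewirings is generated per pipeline run and shared by all
instances: the null is a property of the network, not of the instance.
Rewirings in which an instance becomes unsolvable contribute zero current
(with within-type swapping this does not occur in practice).

*Limitation.*  The normal fit is adequate when the degree distribution is
homogeneous; on strongly scale-free networks the null currents are
log-normal-like (skewness well above 1) and the upper-tail p-values become
conservative in the bulk.  The calibration test therefore uses a
near-regular random network, where p-values under a rewired "observed"
network are verifiably uniform.

Candidates are kept when X[c] is at least `current_frac` (default 0.7) of
the region's maximum exit current **and** the empirical p-value is below
`emp_p` (default 0.05); the union over a target's regions gives its
candidate causal genes.

## Stage 4 — final causal genes

A candidate causal gene *explains* a case when (i) its tag locus is
amplified or deleted there — amplified iff log2 CN − 1 > 0.1, deleted iff
log2 CN − 1 < −0.1, strict inequalities, boundary values neutral — and
(ii) at least one of its affected targets (targets it sends significant
current to) is DE in that case; the explanation weight is the number of such
targets.  When a gene belongs to several regions, the tag of its most
significant circuit instance anchors condition (i).  The final set is a
greedy weighted multi-set cover: each case must accumulate weight `gamma`
(cohort default 50; synthetic operating point 1), `delta` cases exempt;
`delta='auto'` exempts exactly the cases whose total achievable weight is
below `gamma`, replicating the data-derived outlier count.  The greedy gain
caps each case's contribution at its remaining demand.  Exact gain ties are
broken by circuit evidence — smaller best empirical p, then larger best
current — before the gene-identifier fallback; without this, a passenger
gene co-located with a causal gene (identical explanation edges by
construction) displaces it in about half of the ties.

Two validation utilities accompany the cover: the upper-tail hypergeometric
probability of the overlap between the selected set and a reference gene set
within a stated universe, and a permutation p-value for the cover size (the
fraction of uniformly random candidate subsets of the same size that satisfy
the (gamma, delta) constraint).

## Stage 5 — pathways, subnetworks, hubs

For every final (causal gene, target) pair, the solved instance of the
pair's most significant tag locus is filtered: nodes with node-level
empirical p > 0.05 are removed (the two endpoints are always kept).  Among
the remaining simple target→cause paths, the *maximum-current path*
maximizes the bottleneck objective — the minimum total current through any
interior node — found exactly by a maximin variant of Dijkstra's algorithm.
An alternative `product` objective maximizes the product of interior
currents; since node throughflow never exceeds the unit injected current,
−log weights are non-negative and plain Dijkstra applies.  The bottleneck
form is the default because it has an exact polynomial algorithm and matches
the flow metaphor; both are offered because either reading is consistent
with "maximum current path".  The union of a causal gene's paths is its
causal subnetwork; genes interior to more than `hub_min` (default 10) paths
across the cohort are reported as pathway hubs.

## Synthetic cohorts

The `synthetic_data` module generates cohorts with planted causal structure;
its defaults are the study conditions of the recovery experiments:
150 tumors, 30 controls, 400 genes, 48 loci on three chromosomes (~3 genes
per locus), 4 planted causal genes, path length 3, effect size 2.0, residual
noise SD 0.5, alteration carrier fraction 0.4, adjacent-locus correlation
0.9.

* **Copy number** — per sample and chromosome, a first-order autoregressive
  process with coefficient `neighbor_corr` around the diploid level 1
  (background spread 0.05 on the log2 scale).  Each planted locus adds a
  +1.0 log2 shift over a ±1-locus window in a random `cna_fraction` of
  tumors — unambiguously amplified under the ±0.1 calling rule.
* **Network** — a Barabási–Albert backbone (m = 2) for the protein–protein
  layer, 10% of genes flagged TF with two random protein–DNA out-edges each,
  a sprinkling of phosphorylation edges, plus the planted paths: causal gene
  —PPI→ intermediates —PPI→ TF —protein-DNA→ target.  Planted edges are laid
  down first so background edges cannot shadow them.
* **Expression** — per-gene Gaussian controls (mean ~N(7,1), SD ~U(0.3,0.6)),
  matching the Z-score normalization assumption exactly.  The planted causal
  gene receives a cis dosage effect (`effect_size` × centered log2 copy
  number plus N(0, noise_sd)) — an amplified driver is itself overexpressed —
  and its target receives the same dosage signal independently (the trans
  effect).  Path intermediates and the TF are noisy copies of the target's
  standardized tumor profile (correlation 0.85), which is exactly what makes
  the planted path conductive for the circuit.

What the generator does **not** emulate: linkage and recombination structure,
subclonal mixtures and partial copy gains, batch effects, correlated
background co-expression modules, multiple targets per causal gene, and
interactome-scale topology.  Passing recovery tests therefore demonstrate
that the machinery identifies planted dosage→path→target structure under
calibrated noise, not field performance on real cohorts.

Zero-effect cohorts (`effect_size=0`) calibrate the association stage: the
planted-pair regression p-values are verifiably Uniform(0,1), and the full
pipeline recovers planted genes no more often than background.

## Numerical choices and problem sizes

Conductance floor ε = 10⁻³; Kirchhoff residual tolerance 10⁻⁸;
wrong-direction current tolerance 10⁻¹⁰; solver switches dense→sparse at 600
free nodes; all randomness flows through `numpy.random.Generator` seeds.
The test and acceptance workloads use desk-scale problems chosen to finish
in minutes on one CPU: 50 random circuit instances of ≤30 nodes (dense
cross-check at 10⁻¹⁰, 10⁶ simulated walks per instance via multinomial
propagation), 200 brute-forceable cover instances (≤10 genes × ≤8 cases),
100 exhaustively enumerable path graphs (≤15 nodes), 500 zero-effect
replicates, a 150-node near-regular calibration network with 60 rewirings,
and 20 default-condition cohorts for planted recovery.

## Known limitations

The directed-edge heuristic approximates, not solves, the directed flow
problem; the normal null fit is conservative on heavy-tailed degree
distributions (see above); the greedy covers carry logarithmic, not
constant, approximation guarantees; tag-locus regions from the left-to-right
scan never overlap (the bidirectional mode exists precisely because the
accumulation direction is ambiguous); and the explanation graph anchors each
candidate at a single tag locus even when its regions disagree about a
case's alteration state.
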