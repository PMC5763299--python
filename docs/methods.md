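# Methods

This note records the model, the numerical conventions, and the design
choices made where the published description of each ingredient leaves
room, together with what the synthetic benchmark does and does not show.

## Gene similarity networks

**Ontology-based similarity (BP, CC, MF).** Term similarity is the Wang
graph measure: for a term A, every ancestor t (via `is_a` and `part_of`
edges) receives a semantic contribution
`S_A(t) = max over child edges (w_edge · S_A(child))` with `S_A(A) = 1`,
a max-product over downward paths evaluated by memoized post-order
traversal. Contribution factors default to 0.8 (`is_a`) and 0.6
(`part_of`) — the conventional values for this measure — and are
configurable. Two terms compare as the S-value mass of their shared
ancestors over the sum of their total S-values; comparing terms across
aspects is an error, since the three ontologies are independent DAGs.
Gene-level similarity is the best-match average (BMA) of the pairwise
term similarities of the two annotation sets. All evidence codes,
including IEA, are used; rows with a NOT qualifier never count as
annotations. A gene with no annotations in an aspect is simply absent
from that aspect's network; the fusion step handles absence (below).
Term-pair similarities are memoized per ontology; results are identical
regardless of cache state.

**Sequence similarity.** The published description says only that
similarities were "normalized according to their corresponding
bitscores". We normalize by the geometric mean of the two self-alignment
bitscores, `bits(i,j)/√(bits(i,i)·bits(j,j))`, because it is bounded,
symmetric, and exactly 1 on self-comparison; a global-maximum
normalization is available behind `norm="max"`. Hits are filtered at
e-value 1e-6, duplicate HSPs collapse to the maximum bitscore (the
standard best-hit convention), and missing directionality is resolved by
the maximum over the two reported directions. Proteins without a
positive self-hit are dropped — the normalization is undefined for them.

**Domain similarity.** Jaccard index of the Pfam-A accession sets, with
version suffixes stripped and accessions deduplicated.

## Fusion

Status matrices put half the row mass on the diagonal
(`P_ij = W_ij / 2Σ_{k≠i} W_ik`, `P_ii = ½`), which makes the
normalization independent of the scale of self-similarities. A row with
no positive off-diagonal entry becomes absorbing (`P_ii = 1`): such a
gene carries no information in that source. Kernel matrices keep each
row's K strongest neighbors (ties broken toward the lower column index
so runs are bit-reproducible) and renormalize them to sum to 1.

The cross-diffusion update is applied to all M networks simultaneously
from the same iterate; after each round the updated matrix is
symmetrized (the product `S Q Sᵀ` is not exactly symmetric) and then
status-renormalized, so every row sums to 1 exactly at the end of each
iteration. Iteration stops after T rounds or when the largest entrywise
change falls below `tol`. Defaults K = 20, T = 20, tol = 1e-6 follow
common fusion practice; none is prescribed by the method's description,
and all are exposed.

**Alignment across sources.** The five matrices cover different gene
subsets. Before fusion each is expanded to the sorted union of all gene
labels; missing genes get zero off-diagonal similarity (the
non-informative prior) and are caught by the absorbing-row fallback.

## Threshold selection

The scan grid starts at 0 with step 0.001 (configurable) and stops early
once the thresholded graph has no edges. The clustering coefficient
follows the literal equation: nodes with degree ≤ 1 contribute zero, and
the sum is divided by the **total** node count (the accompanying prose
says "all nodes" while the sum runs over degree->1 nodes; the equation
is implemented as printed, with `denominator="deg-gt-1"` as the
alternative). The random-network reference is
`C₀ = (⟨k²⟩−⟨k⟩)²/(⟨k⟩³N)`, the standard closed form for a random graph
with the same degree sequence — evaluated on the thresholded graph at
each cutoff, since both C and C₀ are functions of r. The selected
cutoff is the first grid point whose DCC exceeds the next one's (first
local maximum); a grid on which DCC never decreases raises an error
rather than silently returning the grid end.

Because status-normalized similarities scale like 1/(2n), fused entries
are small and the informative part of the grid is the first few dozen
steps; the early-termination rule keeps the scan cheap at any size.

The degree-distribution diagnostic fits the log-binned degree histogram
in log-density space: power law (linear in log k), lognormal (quadratic
in log k) and Gaussian (quadratic in k), reporting R² per model. The
lognormal form nests the power law, so its raw R² is never lower; the
diagnostic is a descriptive comparison, not a model-selection test.

## The bilayer walk

The transition matrix row-normalizes each block and weights within-layer
moves by λ, cross-layer jumps by 1−λ. Both within-layer blocks keep
their self-similarity diagonal: the phenotype similarity matrix is used
as loaded (unit diagonal), and the IGSN — which itself has no self-loops
— has a unit diagonal restored inside the bilayer. This makes a
singleton layer row-normalize to 1 and leaves every row defined.
Dangling rows follow the convention of restart walks on heterogeneous
networks: a node with no cross-layer links puts full weight (1, not λ)
on its within-layer row, a node empty in both blocks becomes a
self-loop, so the matrix is exactly row-stochastic and probability mass
never leaks. IGSN edge weights (fused similarities) are used as-is, not
binarized.

The update `P(t+1) = (1−γ)MᵀP(t) + γP(0)` iterates to an L1 change below
1e-6 (the walk is a γ-contraction, so the fixed point is unique and
independent of the starting iterate). Defaults γ = 0.7, λ = 0.6, η = 0.6
follow the reported parameter study for this method. The restart term is
γP(0): the published recursion prints an undefined coefficient "r" where
only γ is defined, read here as a typographical slip.

Ranking is by descending steady-state gene score; tied scores share the
worst rank of their tie group, so a tie can never flatter a candidate.

## Validation protocols

For each held-out association the phenotype plus its remaining genes
seed the walk (ab initio: all of the phenotype's links are removed and
the phenotype alone seeds). The linkage-interval control set is the
held-out gene plus its 99 nearest genes by genomic start position on the
same chromosome (ties toward the lower coordinate; spilling to the
nearest genes elsewhere when the chromosome is too small); genome-wide
and ab initio use every gene, the held-out gene ranked among them.

**Seed genes are excluded from the control set** (the held-out gene is
always kept): seeds carry restart mass by construction and are known
genes, not candidates — the same convention the single-phenotype
prioritization uses. Without this exclusion NSP would measure only
whether seeds outrank everything, which they trivially do.

ROC sensitivity at a threshold θ is the fraction of held-out genes with
rank ratio ≤ θ; specificity pools the non-held-out control genes of all
runs. The recall used in the precision/recall/F comparison counts
held-out genes ranked in the top half of their control set
(`recall_direction="bottom"` inverts; the published phrase "rank
proportions higher than 0.5" is ambiguous in direction, and prominence
reads as higher-is-better).

## Synthetic benchmark

The generator emulates the real input formats at toy scale with a
planted community structure: genes are partitioned into modules;
within-module genes share ontology terms and domains and receive high
alignment bitscores; each phenotype is assigned to a module and — when
uncorrupted — links all of that module's designated disease genes, so a
held-out association remains recoverable through the sibling phenotypes
that share the same disease-gene set. Gene locations are uniform and
module-independent, making the linkage interval an honest mixed control
set.

`signal_strength` s interpolates the channels: similarity separations
(term/domain fidelity, bitscore fractions, phenotype similarity) scale
linearly in s, while a phenotype's associations are replaced by uniform
random genes with probability (1−s)². The quadratic rate reflects that
the emulated association data is curated and much cleaner than the
measured similarity channels; at s = 0 every channel, associations
included, is pure noise. One generator stream seeded from the spec
drives all draws in a documented order, so equal seeds give
byte-identical files.

Default sizes (120 genes, 30 phenotypes, 4 modules) keep the full
pipeline — including the all-pairs BMA computation and the threshold
scan — at a few seconds, which is the scale the package's own validation
runs at.

What passing on this benchmark shows: the pipeline recovers a planted
multi-source community signal through the full stack (parsers → networks
→ fusion → thresholding → walk → ranking) and its metrics calibrate to
chance on noise. What it does not show: performance on real ontologies
(whose DAGs are far deeper and annotation sizes skewed), real phenotype
similarity text-mining scores, or genome-scale sparsity — the
fused-matrix scale and the selected threshold on real data depend on n
and on the empirical similarity distributions.

## Known limitations

- The sequence-similarity normalization is a declared choice, not a
  reconstruction of the original (which is not recoverable from its
  description); both variants are exposed.
- The clustering-based threshold rule requires a DCC local maximum;
  matrices with no scale separation (e.g. constant weights) correctly
  raise instead of selecting a cutoff.
- Identifier reconciliation across sources is verbatim matching plus an
  optional two-column mapping table; no web services are consulted.
- Dense matrices throughout: the implementation targets
  tens-of-thousands of genes at most, and the all-pairs BMA step is
  quadratic in gene count.
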