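# rwrb — disease-gene prioritization on a phenotype–gene bilayer network

`rwrb` ranks candidate disease genes for a phenotype by a **random walk
with restart on a bilayer network** that joins a phenotype similarity
network to an **integrated gene similarity network (IGSN)** fused from
five genomic data sources. It is written for computational biologists who
have per-source gene similarity evidence (ontology annotations, sequence
alignments, domain assignments) plus curated phenotype–gene associations,
and want a reproducible, inspectable prioritization pipeline with its
validation protocols built in.

## The method

**Five gene similarity networks.** Gene functional similarity on the BP,
CC and MF ontology aspects uses the Wang graph-based term measure
aggregated by best-match average (BMA); sequence similarity normalizes
pairwise alignment bitscores as `bits(i,j) / √(bits(i,i)·bits(j,j))`;
domain similarity is the Jaccard index of Pfam-A accession sets.

**Similarity network fusion.** Each matrix `W⁽ᵐ⁾` becomes a row-stochastic
status matrix `P⁽ᵐ⁾` (off-diagonal mass ½, diagonal ½) and a K-nearest-
neighbor kernel `S⁽ᵐ⁾`. The status matrices are cross-diffused,

    P⁽ᵐ⁾ ← S⁽ᵐ⁾ · ( 1/(M−1) Σₙ≠ₘ P⁽ⁿ⁾ ) · S⁽ᵐ⁾ᵀ ,

renormalized and symmetrized each round, and averaged at convergence.

**Threshold selection.** The fused network is scanned over an ascending
cutoff grid; at each cutoff `r` the average clustering coefficient `C(r)`
is compared with that of a degree-matched random network,
`C₀ = (⟨k²⟩−⟨k⟩)² / (⟨k⟩³N)`. The selected cutoff is the first local
maximum of `DCC(r) = C(r) − C₀(r)` — the point where the network is
maximally more clustered than chance. Edges above the cutoff form the IGSN.

**The walk.** The bilayer adjacency stacks the phenotype similarity
matrix `A_P`, the 0/1 association blocks, and the IGSN `W_G`. The
transition matrix weights within-layer moves by `λ` and cross-layer jumps
by `1−λ`; the walker restarts with probability `γ` to a seed distribution
splitting mass `1−η : η` between the seed phenotype(s) and seed gene(s):

    P(t+1) = (1−γ) Mᵀ P(t) + γ P(0) .

Candidate genes are ranked by their steady-state probabilities.

**Validation.** Three leave-one-out protocols (linkage-interval,
genome-wide, ab initio) with NSP (held-out gene ranked first), MRR (mean
rank ratio, percent; random guessing gives 50), ROC/AUC, and
precision/recall/F.

## Worked example

All inputs can be generated synthetically, with a planted module
structure linking phenotypes to the disease genes of their community:

```console
$ rwrb simulate --genes 120 --phenotypes 30 --modules 4 --signal 0.8 \
      --seed 42 --out fixtures/
wrote 10 files + manifest to fixtures/

$ rwrb run-all --obo fixtures/go.obo --gaf-bp fixtures/annotations_bp.gaf \
      --gaf-cc fixtures/annotations_cc.gaf --gaf-mf fixtures/annotations_mf.gaf \
      --blast fixtures/blast_hits.tsv --domains fixtures/domains.tsv \
      --locations fixtures/gene_locations.tsv \
      --pheno-sim fixtures/phenotype_similarity.tsv \
      --associations fixtures/associations.tsv \
      --outdir out/ --mode linkage --seed 1 --report report.json
threshold=0.007 NSP=90 MRR=1.02 AUC=1.0000 -> report.json
```

The pipeline fused the five networks, selected cutoff 0.007 as the first
DCC peak, and the linkage-interval validation recovered all 90 held-out
associations at rank 1 (NSP=90), with a mean rank ratio of 1.02% — far
below the 50% chance level — and AUC 1.0: the planted signal is fully
recovered. Prioritizing a single phenotype ranks its community's genes
first (seed genes are excluded as known):

```console
$ rwrb rank --obo fixtures/go.obo ... --seed-phenotype MIM:600001 --top 5
gene    score       rank
GENE0014    0.0014196   1
GENE0003    0.00140815  2
GENE0017    0.00140135  3
GENE0005    0.00139979  4
GENE0013    0.00139394  5
```

Every stage is also exposed alone (`rwrb gonet`, `seqnet`, `domnet`,
`fuse`, `threshold`, `evaluate`, `io validate`) and as library functions
(`rwrb.build_igsn_pipeline`, `rwrb.run_cv`, ...).

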