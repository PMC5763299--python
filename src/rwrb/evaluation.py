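"""Leave-one-out cross-validation protocols and ranking metrics.

Three protocols are supported.  *linkage*: the control set is the
held-out gene plus its nearest genes by genomic location, emulating a
linkage-interval candidate region.  *genomewide*: the control set is
every gene in the network.  *abinitio*: like genomewide, but all of the
phenotype's gene links are removed and only the phenotype seeds the walk.
Metrics: NSP (runs whose held-out gene ranks first), MRR (mean rank
ratio, percent; random guessing gives 50), a thresholded ROC curve with
its AUC, and precision/recall/F against top-half ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bilayer import (BilayerNetwork, WalkConfig, initial_vector, rank_candidates,
                      rwr, transition_matrix)
from .io import AssociationList, GeneLocationTable

logger = logging.getLogger(__name__)

MODES = ("linkage", "genomewide", "abinitio")


@dataclass
class CVRun:
    """One validation round: a held-out association and the resulting rank."""

    phenotype: str
    held_out: str
    rank: int
    control_size: int
    control_ratios: np.ndarray = field(repr=False)  # non-held-out control genes

    @property
    def rank_ratio(self) -> float:
        return self.rank / self.control_size


@dataclass
class CVReport:
    runs: list[CVRun]
    skipped: list[tuple[str, str, str]]  # (phenotype, gene, reason)
    mode: str

    @property
    def nsp(self) -> int:
        return sum(1 for r in self.runs if r.rank == 1)

    @property
    def mrr(self) -> float:
        return summarize(self.runs)[1]

    @property
    def auc(self) -> float:
        return roc_auc(self.runs)[1]


def make_control_set(held_out_gene: str, locations: GeneLocationTable | None,
                     mode: str, gene_index, interval_size: int = 99) -> list[str]:
    """Build the ordered control gene list for one validation round.

    linkage: the held-out gene plus its ``interval_size`` nearest genes by
    |start - start| on the same chromosome (spilling over to the nearest
    genes elsewhere when the chromosome is too small; distance ties break
    toward the lower coordinate).  genomewide / abinitio: all genes.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode in ("genomewide", "abinitio"):
        return list(gene_index.labels)
    if locations is None or held_out_gene not in locations.rows:
        raise KeyError(f"no genomic location for {held_out_gene}")
    chrom, start = locations.rows[held_out_gene]
    same, other = [], []
    for g in gene_index.labels:
        if g == held_out_gene or g not in locations.rows:
            continue
        g_chrom, g_start = locations.rows[g]
        rec = (abs(g_start - start), g_start, g)
        (same if g_chrom == chrom else other).append(rec)
    same.sort()
    other.sort()
    picked = [g for _, _, g in same[:interval_size]]
    if len(picked) < interval_size:
        spill = interval_size - len(picked)
        logger.info("linkage interval for %s spilled %d genes across chromosomes",
                    held_out_gene, spill)
        picked += [g for _, _, g in other[:spill]]
    return [held_out_gene] + picked


def run_cv(bilayer: BilayerNetwork, associations: AssociationList, mode: str,
           config: WalkConfig | None = None,
           locations: GeneLocationTable | None = None,
           interval_size: int = 99,
           exclude_seed_genes: bool = True) -> CVReport:
    """Hold out each association in turn and rank the removed gene.

    For linkage/genomewide the seeds are the phenotype plus its remaining
    genes; for abinitio every link of the phenotype is removed and the
    phenotype alone seeds the walk.  Seed genes are excluded from the
    control set by default — they carry restart mass and are known, not
    candidates — while the held-out gene is always retained.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    config = config or WalkConfig()
    if not associations.pairs:
        raise ValueError("no associations to validate")
    runs: list[CVRun] = []
    skipped: list[tuple[str, str, str]] = []
    pheno_index, gene_index = bilayer.pheno_index, bilayer.gene_index
    base_b = bilayer.b_pg

    for phenotype, gene in associations.pairs:
        if phenotype not in pheno_index or gene not in gene_index:
            skipped.append((phenotype, gene, "not in bilayer indexes"))
            continue
        try:
            control = make_control_set(gene, locations, mode, gene_index,
                                       interval_size=interval_size)
        except KeyError:
            skipped.append((phenotype, gene, "no genomic location"))
            continue
        pi, gi = pheno_index[phenotype], gene_index[gene]
        b = base_b.copy()
        linked = [g for p, g in associations.pairs
                  if p == phenotype and g != gene and g in gene_index]
        if mode == "abinitio":
            b[pi, :] = 0.0
            seed_genes: list[str] = []
        else:
            b[pi, gi] = 0.0
            seed_genes = linked
        trial = BilayerNetwork(pheno_index=pheno_index, gene_index=gene_index,
                               a_p=bilayer.a_p, b_pg=b, w_g=bilayer.w_g)
        M = transition_matrix(trial, lam=config.lam)
        p0 = initial_vector([phenotype], seed_genes, config.eta,
                            pheno_index, gene_index)
        p_inf = rwr(M, p0, gamma=config.gamma, tol=config.tol,
                    max_iter=config.max_iter)
        if exclude_seed_genes:
            drop = set(seed_genes)
            control = [g for g in control if g == gene or g not in drop]
        ranked = rank_candidates(p_inf, gene_index, control)
        rank_of = {g: r for g, _s, r in ranked}
        size = len(control)
        ratios = np.array([r / size for g, _s, r in ranked if g != gene])
        runs.append(CVRun(phenotype=phenotype, held_out=gene,
                          rank=rank_of[gene], control_size=size,
                          control_ratios=ratios))
    if skipped:
        logger.warning("%s validation skipped %d runs", mode, len(skipped))
    return CVReport(runs=runs, skipped=skipped, mode=mode)


def summarize(runs) -> tuple[int, float]:
    """NSP and mean rank ratio (percent scale)."""
    if not runs:
        raise ValueError("no validation runs to summarize")
    nsp = sum(1 for r in runs if r.rank == 1)
    mrr = 100.0 * float(np.mean([r.rank_ratio for r in runs]))
    return nsp, mrr


def roc_auc(runs, grid_step: float = 0.01) -> tuple[np.ndarray, float]:
    """ROC over rank-ratio thresholds from 0 to 1.

    At each threshold, sensitivity is the fraction of held-out genes with
    rank ratio <= threshold; specificity is the fraction of pooled
    (non-held-out) control genes with rank ratio > threshold.  Returns
    the (1 - specificity, sensitivity) curve and its trapezoidal AUC.
    """
    if not runs:
        raise ValueError("no validation runs")
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    held = np.array([r.rank_ratio for r in runs])
    pooled = np.concatenate([r.control_ratios for r in runs])
    sens = (held[None, :] <= grid[:, None]).mean(axis=1)
    if pooled.size:
        fpr = (pooled[None, :] <= grid[:, None]).mean(axis=1)
    else:
        fpr = grid.copy()
    curve = np.column_stack([fpr, sens])
    auc = float(np.trapezoid(sens, fpr))
    return curve, auc


def feature_metrics(runs, recall_direction: str = "top") -> tuple[float, float, float]:
    """Precision, recall and F-measure for the feature-style comparison.

    precision = NSP / #runs; recall = fraction of held-out genes ranked in
    the top half of their control set (``recall_direction="bottom"``
    inverts); F is their harmonic mean.
    """
    if not runs:
        raise ValueError("no validation runs")
    nsp, _ = summarize(runs)
    precision = nsp / len(runs)
    if recall_direction == "top":
        recall = float(np.mean([r.rank_ratio <= 0.5 for r in runs]))
    else:
        recall = float(np.mean([r.rank_ratio > 0.5 for r in runs]))
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f
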