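"""Random walk with restart on the phenotype-gene bilayer network.

The bilayer network stacks the phenotype similarity network, the 0/1
phenotype-gene association blocks, and the thresholded gene similarity
network into one block adjacency matrix.  A restarting random walker
started from a phenotype and/or its known genes converges to a steady
distribution whose gene part ranks candidate disease genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import AssociationList, EntityIndex, SimilarityMatrix
from .threshold import IGSN

logger = logging.getLogger(__name__)


@dataclass
class WalkConfig:
    """Random-walk parameters.

    gamma : restart probability (mass returned to the seeds each step)
    lam   : jumping probability between the phenotype and gene layers
    eta   : seed-mass share given to the gene layer at initialization
    """

    gamma: float = 0.7
    lam: float = 0.6
    eta: float = 0.6
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self):
        for name in ("gamma", "lam", "eta"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie strictly inside (0, 1), got {v}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class BilayerNetwork:
    """Block adjacency of phenotype similarity, associations and the IGSN.

    The within-layer blocks keep their self-similarity diagonal so that
    every row normalizes (a singleton layer row-normalizes to 1).
    """

    pheno_index: EntityIndex
    gene_index: EntityIndex
    a_p: np.ndarray    # m x m phenotype similarity
    b_pg: np.ndarray   # m x n 0/1 associations
    w_g: np.ndarray    # n x n gene similarity (unit diagonal)

    def __post_init__(self):
        m, n = len(self.pheno_index), len(self.gene_index)
        if self.a_p.shape != (m, m) or self.b_pg.shape != (m, n) \
                or self.w_g.shape != (n, n):
            raise ValueError("bilayer block shapes are not conformable")
        if (self.a_p < 0).any() or (self.b_pg < 0).any() or (self.w_g < 0).any():
            raise ValueError("bilayer blocks must be nonnegative")

    @property
    def b_gp(self) -> np.ndarray:
        return self.b_pg.T

    @property
    def adjacency(self) -> np.ndarray:
        return np.block([[self.a_p, self.b_pg], [self.b_gp, self.w_g]])

    @classmethod
    def from_components(cls, pheno_sim: SimilarityMatrix,
                        associations: AssociationList,
                        igsn: IGSN) -> "BilayerNetwork":
        """Assemble the bilayer from its three source networks.

        The IGSN has no self-loops; a unit diagonal is restored here so
        the gene layer row-normalizes like the phenotype layer does.
        """
        w_g = igsn.adjacency.copy()
        np.fill_diagonal(w_g, 1.0)
        b_pg = _aligned_associations(associations, pheno_sim.index, igsn.index)
        return cls(pheno_index=pheno_sim.index, gene_index=igsn.index,
                   a_p=pheno_sim.values.copy(), b_pg=b_pg, w_g=w_g)


def _aligned_associations(associations: AssociationList,
                          pheno_index: EntityIndex,
                          gene_index: EntityIndex) -> np.ndarray:
    b = np.zeros((len(pheno_index), len(gene_index)))
    dropped = 0
    for p, g in associations.pairs:
        if p in pheno_index and g in gene_index:
            b[pheno_index[p], gene_index[g]] = 1.0
        else:
            dropped += 1
    if dropped:
        logger.warning("dropped %d associations outside the bilayer indexes", dropped)
    return b


@dataclass
class ProbabilityVector:
    """Walker distribution split into its phenotype (u) and gene (v) parts."""

    u: np.ndarray
    v: np.ndarray
    converged: bool = True

    @property
    def full(self) -> np.ndarray:
        return np.concatenate([self.u, self.v])

    @property
    def mass(self) -> float:
        return float(self.u.sum() + self.v.sum())


def _row_normalize(block: np.ndarray) -> np.ndarray:
    sums = block.sum(axis=1)
    out = np.zeros_like(block, dtype=float)
    ok = sums > 0
    out[ok] = block[ok] / sums[ok, None]
    return out


def transition_matrix(bilayer: BilayerNetwork, lam: float = 0.6) -> np.ndarray:
    """Row-stochastic bilayer transition matrix.

    Within-layer blocks are weighted by lam and cross-layer blocks by
    (1 - lam).  A row with no cross-layer links puts its full weight on
    the within-layer block (and vice versa); a row empty in both blocks
    becomes a self-loop, so no probability mass ever leaks.
    """
    m_p = _row_normalize(bilayer.a_p)
    m_pg = _row_normalize(bilayer.b_pg)
    m_gp = _row_normalize(bilayer.b_gp)
    m_g = _row_normalize(bilayer.w_g)
    m, n = len(bilayer.pheno_index), len(bilayer.gene_index)

    def _combine(within: np.ndarray, cross: np.ndarray) -> np.ndarray:
        has_within = within.sum(axis=1) > 0
        has_cross = cross.sum(axis=1) > 0
        w_within = np.where(has_within & has_cross, lam,
                            np.where(has_within, 1.0, 0.0))
        w_cross = np.where(has_within & has_cross, 1.0 - lam,
                           np.where(has_cross & ~has_within, 1.0, 0.0))
        return w_within[:, None] * within, w_cross[:, None] * cross

    top_within, top_cross = _combine(m_p, m_pg)
    bot_within, bot_cross = _combine(m_g, m_gp)
    M = np.block([[top_within, top_cross], [bot_cross, bot_within]])
    # rows empty in both blocks become self-loops
    empty = M.sum(axis=1) == 0
    idx = np.nonzero(empty)[0]
    M[idx, idx] = 1.0
    return M


def initial_vector(seed_phenotypes, seed_genes, eta: float,
                   pheno_index: EntityIndex,
                   gene_index: EntityIndex) -> ProbabilityVector:
    """Restart distribution: (1 - eta) spread over seed phenotypes, eta
    over seed genes; a side without seeds cedes its mass to the other."""
    seed_phenotypes = sorted(seed_phenotypes)
    seed_genes = sorted(seed_genes)
    if not seed_phenotypes and not seed_genes:
        raise ValueError("at least one seed phenotype or seed gene is required")
    u = np.zeros(len(pheno_index))
    v = np.zeros(len(gene_index))
    if seed_phenotypes and seed_genes:
        w_u, w_v = 1.0 - eta, eta
    elif seed_phenotypes:
        w_u, w_v = 1.0, 0.0
        logger.debug("no seed genes: full restart mass on the phenotype layer")
    else:
        w_u, w_v = 0.0, 1.0
        logger.debug("no seed phenotypes: full restart mass on the gene layer")
    for p in seed_phenotypes:
        u[pheno_index[p]] = w_u / len(seed_phenotypes)
    for g in seed_genes:
        v[gene_index[g]] = w_v / len(seed_genes)
    return ProbabilityVector(u=u, v=v)


def rwr(M: np.ndarray, p0: ProbabilityVector, gamma: float = 0.7,
        tol: float = 1e-6, max_iter: int = 1000) -> ProbabilityVector:
    """Power-iterate P(t+1) = (1 - gamma) M^T P(t) + gamma P(0) to its
    stationary point (L1 change below ``tol``)."""
    if not np.allclose(M.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix must be row-stochastic")
    start = p0.full
    if not np.isclose(start.sum(), 1.0, atol=1e-9):
        raise ValueError("initial vector must carry unit probability mass")
    m = len(p0.u)
    Mt = M.T
    p = start.copy()
    converged = False
    for _ in range(max_iter):
        p_next = (1.0 - gamma) * (Mt @ p) + gamma * start
        if np.abs(p_next - p).sum() < tol:
            p = p_next
            converged = True
            break
        p = p_next
    if not converged:
        warnings.warn(f"random walk did not converge within {max_iter} iterations",
                      stacklevel=2)
    return ProbabilityVector(u=p[:m], v=p[m:], converged=converged)


def rank_candidates(p_inf: ProbabilityVector, gene_index: EntityIndex,
                    control_genes) -> list[tuple[str, float, int]]:
    """Rank control genes by their steady-state gene scores, descending.

    Tied scores share the worst (maximum) rank of the tie group.
    Returns (gene, score, rank) sorted best-first.
    """
    control = list(control_genes)
    if not control:
        raise ValueError("control gene set is empty")
    scores = np.array([p_inf.v[gene_index[g]] for g in control])
    ranked = []
    for g, s in zip(control, scores):
        rank = int((scores > s).sum() + (scores == s).sum())  # worst shared rank
        ranked.append((g, float(s), rank))
    ranked.sort(key=lambda t: (t[2], t[0]))
    return ranked
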