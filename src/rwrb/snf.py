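"""Similarity network fusion (SNF) of the per-source gene networks.

Each similarity matrix W^(m) is converted to a full-information status
matrix P^(m) (row-stochastic, diagonal fixed at 1/2) and a sparse local
kernel S^(m) (row-normalized K-nearest-neighbor restriction).  The status
matrices are then cross-diffused,

    P^(m) <- S^(m) ( mean of the other P^(n) ) S^(m)^T,

renormalized and symmetrized each round, until they converge to a single
integrated matrix (their average).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import EntityIndex, SimilarityMatrix, align_to_index

logger = logging.getLogger(__name__)


@dataclass
class StatusMatrix:
    """Row-stochastic full-similarity matrix with diagonal 1/2."""

    index: EntityIndex
    values: np.ndarray


@dataclass
class KernelMatrix:
    """Row-normalized K-nearest-neighbor restriction of a similarity matrix."""

    index: EntityIndex
    values: np.ndarray
    K: int


@dataclass
class FusedNetwork:
    """The converged integrated similarity matrix, before thresholding."""

    index: EntityIndex
    values: np.ndarray
    iterations_run: int
    M: int


def _status_values(W: np.ndarray) -> np.ndarray:
    """Status normalization: off-diagonal row mass 1/2, diagonal 1/2.

    Rows without positive off-diagonal mass collapse to an absorbing
    self-entry (P_ii = 1): such genes carry no information in this source.
    """
    n = W.shape[0]
    off = W.copy().astype(float)
    np.fill_diagonal(off, 0.0)
    rowsums = off.sum(axis=1)
    P = np.zeros_like(off)
    ok = rowsums > 0
    P[ok] = off[ok] / (2.0 * rowsums[ok, None])
    np.fill_diagonal(P, 0.5)
    if (~ok).any():
        P[~ok] = 0.0
        bad = np.nonzero(~ok)[0]
        P[bad, bad] = 1.0
    return P


def status_matrix(W: SimilarityMatrix) -> StatusMatrix:
    """Normalized weighted matrix: P_ij = W_ij / (2 sum_{k!=i} W_ik), P_ii = 1/2."""
    if not np.any(W.values):
        raise ValueError("cannot normalize an all-zero similarity matrix")
    values = _status_values(W.values)
    n_isolated = int((np.diag(values) == 1.0).sum())
    if n_isolated:
        logger.info("status matrix: %d rows without off-diagonal mass", n_isolated)
    return StatusMatrix(index=W.index, values=values)


def kernel_matrix(W: SimilarityMatrix, K: int) -> KernelMatrix:
    """Local kernel: keep each row's K strongest off-diagonal neighbors.

    S_ij = W_ij / sum_{k in V_i} W_ik for j in V_i, else 0, where V_i holds
    the K largest off-diagonal entries of row i (ties broken toward lower
    column index so runs are bit-reproducible).
    """
    n = W.values.shape[0]
    if not (1 <= K <= n - 1):
        raise ValueError(f"K must be in [1, {n - 1}], got {K}")
    off = W.values.copy().astype(float)
    np.fill_diagonal(off, -np.inf)
    # stable sort on descending value; ties keep ascending index order
    order = np.argsort(-off, axis=1, kind="stable")
    S = np.zeros((n, n))
    cols = order[:, :K]
    rows = np.repeat(np.arange(n), K)
    vals = np.maximum(off[rows, cols.ravel()], 0.0)
    S[rows, cols.ravel()] = vals
    sums = S.sum(axis=1)
    ok = sums > 0
    S[ok] /= sums[ok, None]
    return KernelMatrix(index=W.index, values=S, K=K)


def snf_update_step(S: np.ndarray, P_others_mean: np.ndarray) -> np.ndarray:
    """One cross-diffusion update: S x (mean of the other status matrices) x S^T."""
    return S @ P_others_mean @ S.T


def align_networks(networks: list[SimilarityMatrix]) -> list[SimilarityMatrix]:
    """Expand all matrices to the sorted union of their entity indexes."""
    union = EntityIndex.union(*(net.index for net in networks))
    return [align_to_index(net, union) for net in networks]


def fuse(networks: list[SimilarityMatrix], K: int = 20, T: int = 20,
         tol: float = 1e-6) -> FusedNetwork:
    """Cross-diffuse M >= 2 pre-aligned similarity matrices to convergence.

    Stops after T iterations or when the largest entrywise change of any
    status matrix falls below ``tol``.  Returns the average of the final
    status matrices, symmetrized.
    """
    M = len(networks)
    if M < 2:
        raise ValueError("fusion needs at least two networks")
    index = networks[0].index
    for net in networks[1:]:
        if net.index.labels != index.labels:
            raise ValueError("networks must share one entity index; "
                             "align them with align_networks() first")
    n = len(index)
    K_eff = min(K, n - 1)
    P_list = [status_matrix(net).values for net in networks]
    S_list = [kernel_matrix(net, K_eff).values for net in networks]

    iterations = 0
    for _t in range(T):
        total = np.sum(P_list, axis=0)
        new_list = []
        for m in range(M):
            others_mean = (total - P_list[m]) / (M - 1)
            Q = snf_update_step(S_list[m], others_mean)
            Q = (Q + Q.T) / 2.0
            new_list.append(_status_values(Q))
        delta = max(np.abs(new - old).max()
                    for new, old in zip(new_list, P_list))
        P_list = new_list
        iterations += 1
        if delta < tol:
            break

    fused = np.mean(P_list, axis=0)
    fused = (fused + fused.T) / 2.0
    fused = np.maximum(fused, 0.0)
    return FusedNetwork(index=index, values=fused, iterations_run=iterations, M=M)
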