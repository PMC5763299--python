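"""Clustering-coefficient threshold selection for the fused network.

The fused similarity matrix is scanned over an ascending threshold grid;
at each cutoff the network keeps only edges whose similarity exceeds it.
The selected threshold is the first local maximum of DCC, the difference
between the network's average clustering coefficient and that of a
degree-matched random network — the point where the thresholded network
is maximally more clustered than chance before structure starts eroding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import EntityIndex
from .snf import FusedNetwork

logger = logging.getLogger(__name__)


@dataclass
class IGSN:
    """Thresholded weighted gene similarity graph G(V, E, t)."""

    index: EntityIndex
    adjacency: np.ndarray   # weighted, symmetric, zero diagonal
    threshold: float

    @property
    def n_edges(self) -> int:
        return int((self.adjacency > 0).sum() // 2)

    def degrees(self) -> np.ndarray:
        return (self.adjacency > 0).sum(axis=1)


@dataclass
class ThresholdScan:
    """Grid of candidate thresholds with both clustering statistics."""

    grid: np.ndarray
    c: np.ndarray
    c0: np.ndarray
    selected: float

    @property
    def dcc(self) -> np.ndarray:
        return self.c - self.c0


def network_clustering(adjacency: np.ndarray,
                       denominator: str = "all") -> float:
    """Average clustering coefficient of a simple undirected graph.

    Per-node C_i = 2 E_i / (k_i (k_i - 1)) where E_i counts edges among
    node i's neighbors; nodes with degree <= 1 contribute 0.  With
    ``denominator="all"`` (default) the sum is divided by the total node
    count; ``"deg-gt-1"`` divides by the number of contributing nodes.
    Edge weights are ignored (topology only).
    """
    A = (np.asarray(adjacency) > 0).astype(float)
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    if n == 0:
        return 0.0
    k = A.sum(axis=1)
    mask = k > 1
    if not mask.any():
        return 0.0
    # edges among neighbors of i = (A^3)_ii / 2
    tri = np.einsum("ij,jk,ki->i", A, A, A)
    ci = np.zeros(n)
    ci[mask] = tri[mask] / (k[mask] * (k[mask] - 1.0))
    denom = n if denominator == "all" else int(mask.sum())
    return float(ci.sum() / denom)


def random_clustering(adjacency: np.ndarray) -> float:
    """Expected clustering of a degree-matched random network.

    C_0 = (<k^2> - <k>)^2 / (<k>^3 N) from the graph's degree sequence.
    """
    A = (np.asarray(adjacency) > 0).astype(float)
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    if n == 0:
        return 0.0
    k = A.sum(axis=1)
    k_mean = k.mean()
    if k_mean == 0:
        return 0.0
    k2_mean = (k ** 2).mean()
    return float((k2_mean - k_mean) ** 2 / (k_mean ** 3 * n))


def threshold_scan(fused: FusedNetwork, step: float = 0.001,
                   denominator: str = "all") -> ThresholdScan:
    """Scan thresholds r_0 = 0, r_1 = step, ... and pick the first DCC peak.

    The scan stops once the thresholded graph has no edges; the selected
    threshold r* is the smallest grid point whose DCC exceeds the next
    grid point's (first local maximum).  A grid on which DCC never
    decreases raises, since no local maximum exists.
    """
    P = fused.values.copy()
    np.fill_diagonal(P, 0.0)
    grid_full = np.arange(0.0, 1.0 + step / 2, step)
    grid, cs, c0s = [], [], []
    for r in grid_full:
        A = (P > r).astype(float)
        if not A.any():
            break
        grid.append(r)
        cs.append(network_clustering(A, denominator=denominator))
        c0s.append(random_clustering(A))
    if len(grid) < 2:
        raise ValueError("threshold grid collapsed before a local maximum "
                         "could form (network too sparse)")
    grid_a, c_a, c0_a = np.array(grid), np.array(cs), np.array(c0s)
    dcc = c_a - c0_a
    drops = np.nonzero(dcc[:-1] > dcc[1:])[0]
    if drops.size == 0:
        raise ValueError("no local maximum: DCC never decreases on the grid")
    selected = float(grid_a[drops[0]])
    return ThresholdScan(grid=grid_a, c=c_a, c0=c0_a, selected=selected)


def apply_threshold(fused: FusedNetwork, r: float) -> IGSN:
    """Keep edges with similarity strictly greater than r (weights retained)."""
    if not (0 <= r < 1):
        raise ValueError(f"threshold must be in [0, 1), got {r}")
    W = fused.values.copy()
    np.fill_diagonal(W, 0.0)
    W[W <= r] = 0.0
    return IGSN(index=fused.index, adjacency=W, threshold=r)


def degree_fit_diagnostic(igsn: IGSN, n_bins: int = 15) -> dict[str, float]:
    """R-squared of power-law, lognormal and Gaussian fits to the
    log-binned degree distribution.

    Power-law and lognormal are fitted linearly/quadratically in
    (log k, log p); Gaussian quadratically in (k, log p).  Returns an
    empty mapping with a warning when fewer than 10 distinct positive
    degrees are available.
    """
    k = igsn.degrees()
    k = k[k > 0]
    if len(np.unique(k)) < 10:
        warnings.warn("degree-fit diagnostic skipped: fewer than 10 distinct degrees",
                      stacklevel=2)
        return {}
    edges = np.unique(np.geomspace(k.min(), k.max() + 1, n_bins).round())
    counts, bin_edges = np.histogram(k, bins=edges)
    widths = np.diff(bin_edges)
    centers = np.sqrt(bin_edges[:-1] * bin_edges[1:])
    density = counts / (widths * len(k))
    keep = density > 0
    x, p = centers[keep], density[keep]
    if len(x) < 4:
        warnings.warn("degree-fit diagnostic skipped: too few occupied bins",
                      stacklevel=2)
        return {}
    logp = np.log(p)
    logk = np.log(x)

    def _r2(xv: np.ndarray, deg: int) -> float:
        coef = np.polyfit(xv, logp, deg)
        resid = logp - np.polyval(coef, xv)
        ss_tot = ((logp - logp.mean()) ** 2).sum()
        if ss_tot == 0:
            return 1.0
        return float(1.0 - (resid ** 2).sum() / ss_tot)

    return {
        "power_law": _r2(logk, 1),
        "lognormal": _r2(logk, 2),
        "gaussian": _r2(x, 2),
    }
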