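"""Sequence- and domain-based protein similarity networks.

Sequence similarity normalizes pairwise alignment bitscores by the
geometric mean of the two self-alignment bitscores, giving a bounded,
symmetric score that equals 1 on self-comparison.  Domain similarity is
the Jaccard index of the two proteins' domain-accession sets.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import DomainMap, EntityIndex, PairScoreTable, SimilarityMatrix

logger = logging.getLogger(__name__)


def sequence_similarity_network(scores: PairScoreTable,
                                norm: str = "self") -> SimilarityMatrix:
    """Bitscore-normalized protein similarity.

    With ``norm="self"`` (default): sim(i,j) = bits(i,j) / sqrt(bits(i,i) *
    bits(j,j)), where bits(i,j) is the max over the two reported alignment
    directions (0 if absent).  ``norm="max"`` divides by the global maximum
    self-bitscore instead.  Proteins without a positive self-hit are dropped.
    """
    if norm not in ("self", "max"):
        raise ValueError(f"unknown normalization {norm!r}")
    self_bits = {q: b for q, s, b, _ in scores.records if q == s and b > 0}
    dropped = set(scores.proteins()) - set(self_bits)
    if dropped:
        logger.warning("dropping %d proteins without a positive self-hit", len(dropped))
    proteins = sorted(self_bits)
    if not proteins:
        raise ValueError("no proteins with self-hits in the score table")
    index = EntityIndex.from_labels(proteins)
    n = len(proteins)
    bits = np.zeros((n, n))
    for q, s, b, _ in scores.records:
        if q in self_bits and s in self_bits:
            i, j = index[q], index[s]
            bits[i, j] = max(bits[i, j], b)
    bits = np.maximum(bits, bits.T)  # max over reported directions

    selfs = np.diag(bits).copy()
    if norm == "self":
        denom = np.sqrt(np.outer(selfs, selfs))
    else:
        denom = np.full((n, n), selfs.max())
    values = np.clip(bits / denom, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(index=index, values=values)


def domain_similarity_network(domains: DomainMap) -> SimilarityMatrix:
    """Jaccard similarity of domain-accession sets, unit diagonal."""
    proteins = sorted(p for p, ds in domains.domains.items() if ds)
    if not proteins:
        raise ValueError("no proteins with domain assignments")
    all_domains = sorted(set().union(*(domains.domains[p] for p in proteins)))
    dom_pos = {d: k for k, d in enumerate(all_domains)}
    incidence = np.zeros((len(proteins), len(all_domains)))
    for i, p in enumerate(proteins):
        for d in domains.domains[p]:
            incidence[i, dom_pos[d]] = 1.0
    inter = incidence @ incidence.T
    sizes = incidence.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    values = inter / union
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(index=EntityIndex.from_labels(proteins), values=values)
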