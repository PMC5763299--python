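"""Gene functional similarity from ontology annotations.

Term-level similarity follows the Wang graph-based measure: each term's
ancestor DAG is scored by a max-product recursion over edge contribution
factors (is_a and part_of edges carry different weights), and two terms
are compared through the S-values of their shared ancestors.  Gene-level
similarity aggregates the pairwise term similarities of two annotation
sets with the best-match-average (BMA) strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AnnotationMap, EntityIndex, Ontology, SimilarityMatrix

#: conventional contribution factors for the two retained edge types
DEFAULT_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class TermDAG:
    """The scored ancestor DAG of a single term.

    ``svalues`` maps every term in the ancestor closure (the term itself
    included) to its semantic contribution S in (0, 1]; ``sv`` is their sum.
    """

    term: str
    aspect: str
    svalues: dict[str, float]
    sv: float


def build_term_dag(term: str, ontology: Ontology,
                   w_is_a: float = DEFAULT_WEIGHTS["is_a"],
                   w_part_of: float = DEFAULT_WEIGHTS["part_of"]) -> TermDAG:
    """Score the ancestor closure of ``term``.

    S(term) = 1 and for each ancestor t,
    S(t) = max over child edges (c -> t) inside the closure of w_edge * S(c),
    evaluated bottom-up (max-product over all downward paths).
    """
    if term not in ontology.terms:
        raise KeyError(f"unknown ontology term: {term}")
    weights = {"is_a": w_is_a, "part_of": w_part_of}
    closure = {term} | ontology.ancestors(term)

    # children-within-closure adjacency: parent -> [(child, weight)]
    children: dict[str, list[tuple[str, float]]] = {t: [] for t in closure}
    for child in closure:
        for parent, rel in ontology.parents.get(child, ()):
            if parent in closure:
                children[parent].append((child, weights[rel]))

    # max-product over all downward paths to the focal term; iterative
    # post-order so deep ontologies cannot hit the recursion limit
    svalues: dict[str, float] = {term: 1.0}

    def score(t0: str) -> float:
        stack = [(t0, False)]
        while stack:
            t, expanded = stack.pop()
            if t in svalues:
                continue
            if expanded:
                svalues[t] = max(w * svalues[c] for c, w in children[t])
            else:
                stack.append((t, True))
                stack.extend((c, False) for c, _w in children[t] if c not in svalues)
        return svalues[t0]

    for t in closure:
        score(t)
    return TermDAG(term=term, aspect=ontology.namespace.get(term, "BP"),
                   svalues=svalues, sv=float(sum(svalues.values())))


def term_similarity(dag1: TermDAG, dag2: TermDAG) -> float:
    """Wang similarity of two terms: shared-ancestor S-value mass over total."""
    if dag1.aspect != dag2.aspect:
        raise ValueError(
            f"cross-aspect term comparison ({dag1.aspect} vs {dag2.aspect}) is "
            "not defined: the three ontologies are independent"
        )
    common = sorted(dag1.svalues.keys() & dag2.svalues.keys())
    if not common:
        return 0.0
    num = sum(dag1.svalues[t] + dag2.svalues[t] for t in common)
    # num <= sv1 + sv2 analytically; guard the last-ulp rounding overshoot
    return min(1.0, num / (dag1.sv + dag2.sv))


class TermSimilarityCache:
    """Memoizes term DAGs and pairwise term similarities for one ontology."""

    def __init__(self, ontology: Ontology,
                 w_is_a: float = DEFAULT_WEIGHTS["is_a"],
                 w_part_of: float = DEFAULT_WEIGHTS["part_of"]):
        self.ontology = ontology
        self.w_is_a = w_is_a
        self.w_part_of = w_part_of
        self._dags: dict[str, TermDAG] = {}
        self._sims: dict[tuple[str, str], float] = {}

    def dag(self, term: str) -> TermDAG:
        if term not in self._dags:
            self._dags[term] = build_term_dag(
                term, self.ontology, self.w_is_a, self.w_part_of)
        return self._dags[term]

    def sim(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        if key not in self._sims:
            self._sims[key] = term_similarity(self.dag(key[0]), self.dag(key[1]))
        return self._sims[key]


def gene_functional_similarity(terms1, terms2,
                               cache: TermSimilarityCache) -> float:
    """BMA aggregation of pairwise term similarities between two genes.

    With term sets {a_1..a_m} and {b_1..b_n}:
    (sum_i max_j sim(a_i, b_j) + sum_j max_i sim(a_i, b_j)) / (m + n).
    """
    a, b = sorted(terms1), sorted(terms2)
    if not a or not b:
        raise ValueError("gene has no annotation in this aspect")
    sims = np.array([[cache.sim(x, y) for y in b] for x in a])
    return float((sims.max(axis=1).sum() + sims.max(axis=0).sum())
                 / (len(a) + len(b)))


def build_go_network(annotations: AnnotationMap, ontology: Ontology,
                     w_is_a: float = DEFAULT_WEIGHTS["is_a"],
                     w_part_of: float = DEFAULT_WEIGHTS["part_of"]) -> SimilarityMatrix:
    """All-pairs BMA gene similarity over the genes annotated in one aspect."""
    genes = annotations.genes()
    if not genes:
        raise ValueError(f"no annotated genes in aspect {annotations.aspect}")
    cache = TermSimilarityCache(ontology, w_is_a, w_part_of)
    n = len(genes)
    values = np.eye(n)
    term_sets = [annotations.annotations[g] for g in genes]
    for i in range(n):
        for j in range(i + 1, n):
            s = gene_functional_similarity(term_sets[i], term_sets[j], cache)
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(index=EntityIndex.from_labels(genes), values=values)
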