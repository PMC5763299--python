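"""Readers and writers for the external formats the pipeline touches.

Every matrix and association table in the pipeline is anchored to an
:class:`EntityIndex` so that genes and phenotypes coming from different
sources (ontology annotations, alignment hits, domain assignments, curated
associations) line up unambiguously.  Identifiers are matched verbatim; an
optional two-column mapping table can translate between naming schemes
(e.g. protein accession -> gene symbol) before matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

_ASPECT_BY_NAMESPACE = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}
#: GAF column 9 single-letter aspect codes.
_ASPECT_BY_CODE = {"P": "BP", "C": "CC", "F": "MF"}


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass(frozen=True)
class EntityIndex:
    """Ordered, unique identifiers with O(1) label -> position lookup."""

    labels: tuple[str, ...]
    position: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self):
        if len(self.labels) == 0:
            raise ValueError("EntityIndex must hold at least one label")
        pos = {lab: i for i, lab in enumerate(self.labels)}
        if len(pos) != len(self.labels):
            raise ValueError("EntityIndex labels must be unique")
        object.__setattr__(self, "position", pos)

    @classmethod
    def from_labels(cls, labels) -> "EntityIndex":
        return cls(tuple(str(x) for x in labels))

    @classmethod
    def union(cls, *indexes: "EntityIndex") -> "EntityIndex":
        """Deterministic (sorted) union of several indexes."""
        pool: set[str] = set()
        for idx in indexes:
            pool.update(idx.labels)
        return cls(tuple(sorted(pool)))

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.position

    def __getitem__(self, label: str) -> int:
        return self.position[label]


@dataclass
class Ontology:
    """A directed acyclic term graph restricted to is_a / part_of edges."""

    terms: set[str]
    parents: dict[str, set[tuple[str, str]]]   # term -> {(parent, relation)}
    namespace: dict[str, str]                  # term -> BP | CC | MF

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable upward from ``term`` (term itself excluded)."""
        if term not in self.terms:
            raise KeyError(f"unknown ontology term: {term}")
        seen: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            for parent, _rel in self.parents.get(t, ()):
                if parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen


@dataclass
class AnnotationMap:
    """Gene -> GO term sets for one ontology aspect."""

    aspect: str
    annotations: dict[str, set[str]]

    def genes(self) -> list[str]:
        return sorted(self.annotations)


@dataclass
class PairScoreTable:
    """Filtered all-vs-all alignment hits: (query, subject, bitscore, evalue)."""

    records: list[tuple[str, str, float, float]]

    def proteins(self) -> list[str]:
        pool = {q for q, _, _, _ in self.records} | {s for _, s, _, _ in self.records}
        return sorted(pool)


@dataclass
class DomainMap:
    """Protein -> set of domain accessions (version suffixes stripped)."""

    domains: dict[str, set[str]]


@dataclass
class AssociationList:
    """Phenotype-gene association pairs with their 0/1 incidence matrix."""

    pairs: list[tuple[str, str]]
    pheno_index: EntityIndex
    gene_index: EntityIndex

    @property
    def b_pg(self) -> np.ndarray:
        """0/1 phenotype x gene incidence matrix."""
        mat = np.zeros((len(self.pheno_index), len(self.gene_index)))
        for p, g in self.pairs:
            mat[self.pheno_index[p], self.gene_index[g]] = 1.0
        return mat

    @property
    def b_gp(self) -> np.ndarray:
        return self.b_pg.T

    def genes_of(self, phenotype: str) -> list[str]:
        return sorted(g for p, g in self.pairs if p == phenotype)


@dataclass
class GeneLocationTable:
    """Genomic anchor per gene: chromosome and 0-based start coordinate."""

    rows: dict[str, tuple[str, int]]  # gene -> (chrom, start)


@dataclass
class SimilarityMatrix:
    """Symmetric nonnegative gene-by-gene similarity with an entity index."""

    index: EntityIndex
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.index)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match index size {n}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("similarity matrix must be nonnegative")
        self.values = v


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_obo(path) -> Ontology:
    """Load an OBO ontology, keeping only is_a / part_of edges.

    Obsolete terms are dropped, every other relation (regulates, ...) is
    ignored, and each term is tagged with its aspect (BP/CC/MF).
    """
    try:
        graph = obonet.read_obo(Path(path), ignore_obsolete=True)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise FormatError(f"malformed OBO file {path}: {exc}") from exc

    terms = set(graph.nodes)
    parents: dict[str, set[tuple[str, str]]] = {}
    namespace: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace", "biological_process")
        namespace[term] = _ASPECT_BY_NAMESPACE.get(ns, "BP")
    # obonet edges run child -> parent with the relation as the edge key
    for child, parent, rel in graph.edges(keys=True):
        if rel not in ("is_a", "part_of"):
            continue
        if parent not in terms:
            continue
        parents.setdefault(child, set()).add((parent, rel))

    onto = Ontology(terms=terms, parents=parents, namespace=namespace)
    _check_acyclic(onto)
    return onto


def _check_acyclic(onto: Ontology) -> None:
    state: dict[str, int] = {}  # 0 visiting, 1 done

    for start in onto.terms:
        if start in state:
            continue
        stack: list[tuple[str, iter]] = [(start, iter(onto.parents.get(start, ())))]
        state[start] = 0
        while stack:
            node, it = stack[-1]
            advanced = False
            for parent, _rel in it:
                if state.get(parent) == 0:
                    raise FormatError(f"ontology contains a cycle through {parent}")
                if parent not in state:
                    state[parent] = 0
                    stack.append((parent, iter(onto.parents.get(parent, ()))))
                    advanced = True
                    break
            if not advanced:
                state[node] = 1
                stack.pop()


def read_gaf(path, ontology: Ontology, aspect: str) -> AnnotationMap:
    """Load GAF 2.x annotations for one aspect.

    All evidence codes are kept (including IEA); NOT-qualified rows are
    dropped; terms missing from the ontology are dropped with a warning.
    Gene identifiers are taken from the DB Object Symbol column.
    """
    if aspect not in ("BP", "CC", "MF"):
        raise ValueError(f"aspect must be BP, CC or MF, got {aspect!r}")
    annotations: dict[str, set[str]] = {}
    n_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                raise FormatError(
                    f"{path}:{lineno}: GAF row has {len(cols)} columns, expected >=15"
                )
            qualifier, term, code = cols[3], cols[4], cols[8]
            gene = cols[2] or cols[1]
            if "NOT" in qualifier.split("|"):
                continue
            if _ASPECT_BY_CODE.get(code) != aspect:
                continue
            if term not in ontology.terms:
                n_unknown += 1
                continue
            if ontology.namespace.get(term) != aspect:
                continue
            annotations.setdefault(gene, set()).add(term)
    if n_unknown:
        logger.warning("%s: dropped %d annotations to unknown terms", path, n_unknown)
    annotations = {g: ts for g, ts in annotations.items() if ts}
    return AnnotationMap(aspect=aspect, annotations=annotations)


def read_pair_scores(path, evalue_cutoff: float = 1e-6) -> PairScoreTable:
    """Load pairwise alignment hits from BLAST tabular (outfmt 6) output.

    Accepts the full 12-column dialect or a reduced 4-column
    (query, subject, evalue, bitscore) table.  Hits above the e-value
    cutoff are removed and duplicate (query, subject) HSPs collapse to
    their maximum bitscore.
    """
    best: dict[tuple[str, str], tuple[float, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) >= 12:
                q, s, ev_s, bits_s = cols[0], cols[1], cols[10], cols[11]
            elif len(cols) == 4:
                q, s, ev_s, bits_s = cols
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 or 4 columns, got {len(cols)}"
                )
            try:
                evalue, bits = float(ev_s), float(bits_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score field") from exc
            if bits < 0:
                raise FormatError(f"{path}:{lineno}: negative bitscore")
            if evalue > evalue_cutoff:
                continue
            key = (q, s)
            if key not in best or bits > best[key][0]:
                best[key] = (bits, evalue)
    records = [(q, s, bits, ev) for (q, s), (bits, ev) in sorted(best.items())]
    return PairScoreTable(records=records)


def read_domain_table(path) -> DomainMap:
    """Load protein -> domain accession assignments from a 2-column TSV."""
    domains: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2 or not cols[1].strip():
                logger.warning("%s:%d: empty accession, row skipped", path, lineno)
                continue
            protein, acc = cols[0].strip(), cols[1].strip()
            acc = acc.split(".")[0]  # strip version suffix PFxxxxx.N
            domains.setdefault(protein, set()).add(acc)
    return DomainMap(domains=domains)


def read_associations(path, pheno_index: EntityIndex,
                      gene_index: EntityIndex) -> AssociationList:
    """Load phenotype-gene pairs, dropping those not resolvable in the indexes."""
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dropped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            p, g = cols[0].strip(), cols[1].strip()
            if p not in pheno_index or g not in gene_index:
                n_dropped += 1
                continue
            if (p, g) in seen:
                continue
            seen.add((p, g))
            pairs.append((p, g))
    if n_dropped:
        logger.warning("%s: dropped %d unresolvable association pairs", path, n_dropped)
    return AssociationList(pairs=pairs, pheno_index=pheno_index, gene_index=gene_index)


def read_locations(path) -> GeneLocationTable:
    """Load gene -> (chromosome, 0-based start) from a 3-column TSV."""
    rows: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            gene, chrom, start_s = cols[0], cols[1], cols[2]
            start = int(start_s)
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start coordinate")
            rows[gene] = (chrom, start)
    return GeneLocationTable(rows=rows)


def read_id_map(path) -> dict[str, str]:
    """Optional 2-column identifier translation table (from, to)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            src, dst = line.rstrip("\n").split("\t")[:2]
            mapping[src] = dst
    return mapping


# ---------------------------------------------------------------------------
# similarity-matrix persistence
# ---------------------------------------------------------------------------

def write_matrix(matrix: SimilarityMatrix, path) -> None:
    """Write a dense labelled TSV (header row and column of labels)."""
    df = pd.DataFrame(matrix.values,
                      index=list(matrix.index.labels),
                      columns=list(matrix.index.labels))
    df.to_csv(path, sep="\t", index_label="")


def read_matrix(path) -> SimilarityMatrix:
    """Read a similarity matrix from dense labelled TSV or 3-column edge list.

    The dialect is auto-detected: a square labelled table is dense, a
    3-column (node, node, weight) file is an undirected edge list whose
    missing direction is completed by symmetry (diagonal set to 1).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    ncols = len(header)
    probe = pd.read_csv(path, sep="\t", nrows=5, header=None)
    is_edgelist = ncols == 3 and probe.shape[1] == 3 and _is_number(str(probe.iloc[0, 2]))
    if is_edgelist:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["a", "b", "w"], dtype={"a": str, "b": str})
        labels = sorted(set(df["a"]) | set(df["b"]))
        index = EntityIndex.from_labels(labels)
        values = np.eye(len(index))
        for a, b, w in df.itertuples(index=False):
            i, j = index[a], index[b]
            values[i, j] = values[j, i] = float(w)
        return SimilarityMatrix(index=index, values=values)

    df = pd.read_csv(path, sep="\t", index_col=0)
    row_labels = [str(x) for x in df.index]
    col_labels = [str(x) for x in df.columns]
    if row_labels != col_labels:
        raise FormatError(f"{path}: header row and column labels differ")
    index = EntityIndex.from_labels(row_labels)
    return SimilarityMatrix(index=index, values=df.to_numpy(dtype=float))


def write_edge_list(matrix: SimilarityMatrix, path) -> None:
    """Write nonzero upper-triangle entries as a 3-column edge list."""
    labels = matrix.index.labels
    with open(path, "w") as fh:
        iu, ju = np.nonzero(np.triu(matrix.values, k=1))
        for i, j in zip(iu, ju):
            fh.write(f"{labels[i]}\t{labels[j]}\t{matrix.values[i, j]:.12g}\n")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def align_to_index(matrix: SimilarityMatrix, index: EntityIndex) -> SimilarityMatrix:
    """Expand/reorder a matrix to a target index.

    Genes absent from the source matrix get zero off-diagonal similarity
    (the non-informative prior) and unit self-similarity.
    """
    n = len(index)
    out = np.zeros((n, n))
    np.fill_diagonal(out, 1.0)
    src = [matrix.index.position.get(lab, -1) for lab in index.labels]
    present = [(tgt, s) for tgt, s in enumerate(src) if s >= 0]
    tgt_ids = np.array([t for t, _ in present], dtype=int)
    src_ids = np.array([s for _, s in present], dtype=int)
    if len(tgt_ids):
        out[np.ix_(tgt_ids, tgt_ids)] = matrix.values[np.ix_(src_ids, src_ids)]
    return SimilarityMatrix(index=index, values=out)
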