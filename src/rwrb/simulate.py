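"""Deterministic toy-scale generators for every input the pipeline reads.

The generator plants a module structure: genes are partitioned into
communities, and within-community gene pairs share ontology terms and
domains and receive high alignment bitscores.  Phenotypes are assigned to
the same communities; each community designates a few disease genes that
all of its (informative) phenotypes link to, so held-out associations are
recoverable through the remaining links and the community structure.

``signal_strength`` (s) interpolates between structureless noise (0) and
clean planted signal (1).  The similarity channels (ontology terms,
bitscores, domains, phenotype similarity) degrade linearly in s.  The
association channel corrupts a phenotype with probability (1 - s)^2 —
quadratically, because the emulated association data is curated and far
cleaner than the measured similarity channels — replacing its links with
uniform random genes; at s = 0 every association is pure noise.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

_ASPECTS = (("BP", "biological_process", "P"),
            ("CC", "cellular_component", "C"),
            ("MF", "molecular_function", "F"))


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic benchmark; same seed means identical bytes."""

    n_genes: int = 120
    n_phenotypes: int = 30
    n_modules: int = 4
    signal_strength: float = 0.8
    seed: int = 42
    terms_per_module: int = 5       # per aspect
    noise_terms: int = 8            # per aspect, shared background
    annotations_per_gene: int = 3   # per aspect
    domains_per_module: int = 8
    noise_domains: int = 8
    domains_per_gene: int = 3
    disease_genes_per_module: int = 3
    chromosomes: int = 2

    def __post_init__(self):
        if min(self.n_genes, self.n_phenotypes, self.n_modules) < 1:
            raise ValueError("all counts must be >= 1")
        if not (0 <= self.signal_strength <= 1):
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.n_genes % self.n_modules:
            raise ValueError("n_genes must be divisible by n_modules")


@dataclass
class GeneData:
    """In-memory gene-side fixture content, ready to serialize."""

    genes: list[str]
    modules: dict[str, int]
    obo_text: str
    gaf_texts: dict[str, str]          # aspect -> GAF content
    blast_rows: list[str]
    domain_rows: list[str]
    location_rows: list[str]


@dataclass
class PhenomeData:
    phenotypes: list[str]
    assignment: dict[str, int]
    similarity_text: str
    association_rows: list[str]
    truth_rows: list[str]


def _gene_names(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n + 1)]


def _term_id(k: int) -> str:
    return f"GO:{k:07d}"


def simulate_gene_data(spec: FixtureSpec,
                       rng: np.random.Generator | None = None) -> GeneData:
    """Generate ontology, annotations, alignment hits, domains and locations."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    s = spec.signal_strength
    genes = _gene_names(spec.n_genes)
    per_module = spec.n_genes // spec.n_modules
    modules = {g: i // per_module for i, g in enumerate(genes)}

    # --- ontology: one root per aspect, a small subtree per module plus
    # shared noise terms hanging off the root ----------------------------
    obo_lines = ["format-version: 1.2", "ontology: synthetic", ""]
    module_terms: dict[str, list[list[str]]] = {}
    noise_pool: dict[str, list[str]] = {}
    counter = 1

    def add_term(tid: str, ns: str, parents=()):
        nonlocal obo_lines
        obo_lines += [f"[Term]", f"id: {tid}", f"name: synthetic term {tid}",
                      f"namespace: {ns}"]
        for parent, rel in parents:
            if rel == "is_a":
                obo_lines.append(f"is_a: {parent} ! parent")
            else:
                obo_lines.append(f"relationship: part_of {parent} ! parent")
        obo_lines.append("")

    for aspect, ns, _code in _ASPECTS:
        root = _term_id(counter); counter += 1
        add_term(root, ns)
        module_terms[aspect] = []
        for _mod in range(spec.n_modules):
            ids = [_term_id(counter + k) for k in range(spec.terms_per_module)]
            counter += spec.terms_per_module
            # small DAG: chain with one part_of side branch
            add_term(ids[0], ns, [(root, "is_a")])
            for k in range(1, len(ids)):
                rel = "part_of" if k == 3 else "is_a"
                add_term(ids[k], ns, [(ids[max(k - 2, 0)] if k == 3 else ids[k - 1],
                                       rel)])
            module_terms[aspect].append(ids)
        pool = [_term_id(counter + k) for k in range(spec.noise_terms)]
        counter += spec.noise_terms
        for tid in pool:
            add_term(tid, ns, [(root, "is_a")])
        noise_pool[aspect] = pool

    # --- annotations: module terms with prob s, else any term -----------
    gaf_texts: dict[str, str] = {}
    for aspect, _ns, code in _ASPECTS:
        all_terms = [t for ids in module_terms[aspect] for t in ids] + noise_pool[aspect]
        rows = ["!gaf-version: 2.1"]
        for g in genes:
            own = module_terms[aspect][modules[g]]
            chosen: set[str] = set()
            while len(chosen) < spec.annotations_per_gene:
                if rng.random() < s:
                    chosen.add(own[rng.integers(len(own))])
                else:
                    chosen.add(all_terms[rng.integers(len(all_terms))])
            for t in sorted(chosen):
                rows.append("\t".join([
                    "SYNTH", g, g, "", t, "SYNTH:0001", "IEA", "", code,
                    f"synthetic product {g}", "", "protein",
                    "taxon:0000", "20150101", "SYNTH", "", ""]))
        gaf_texts[aspect] = "\n".join(rows) + "\n"

    # --- alignment bitscores: self-score from a synthetic length; pair
    # score = geometric-mean self-score times a module-dependent fraction
    lengths = rng.integers(200, 801, size=spec.n_genes)
    self_bits = 2.0 * lengths
    blast_rows = []
    for i, g in enumerate(genes):
        blast_rows.append(_blast_row(g, g, 1e-180, self_bits[i]))
    base, sep = 0.15, 0.65
    for i in range(spec.n_genes):
        for j in range(i + 1, spec.n_genes):
            frac = base + (sep * s if modules[genes[i]] == modules[genes[j]] else 0.0)
            frac += rng.normal(0.0, 0.05)
            frac = float(np.clip(frac, 0.0, 0.95))
            if frac > 0.05:
                bits = frac * float(np.sqrt(self_bits[i] * self_bits[j]))
                blast_rows.append(_blast_row(genes[i], genes[j], 1e-30, bits))

    # --- domains: module pool with prob s, else shared background -------
    n_dom = spec.n_modules * spec.domains_per_module + spec.noise_domains
    dom_names = [f"PF{10000 + k}" for k in range(n_dom)]
    module_pools = [dom_names[m * spec.domains_per_module:
                              (m + 1) * spec.domains_per_module]
                    for m in range(spec.n_modules)]
    all_pool = dom_names
    domain_rows = []
    for g in genes:
        own = module_pools[modules[g]]
        chosen = set()
        while len(chosen) < spec.domains_per_gene:
            if rng.random() < s:
                chosen.add(own[rng.integers(len(own))])
            else:
                chosen.add(all_pool[rng.integers(len(all_pool))])
        for d in sorted(chosen):
            domain_rows.append(f"{g}\t{d}")

    # --- locations: uniform on synthetic chromosomes, module-independent
    starts = rng.choice(5_000_000, size=spec.n_genes, replace=False)
    chroms = rng.integers(spec.chromosomes, size=spec.n_genes)
    location_rows = [f"{g}\tchrS{chroms[i] + 1}\t{int(starts[i])}"
                     for i, g in enumerate(genes)]

    return GeneData(genes=genes, modules=modules,
                    obo_text="\n".join(obo_lines) + "\n",
                    gaf_texts=gaf_texts, blast_rows=blast_rows,
                    domain_rows=domain_rows, location_rows=location_rows)


def _blast_row(q: str, s: str, evalue: float, bits: float) -> str:
    # full 12-column outfmt-6 row; alignment fields are placeholders
    return "\t".join([q, s, "100.0", "100", "0", "0", "1", "100", "1", "100",
                      f"{evalue:.2g}", f"{bits:.1f}"])


def simulate_phenome(spec: FixtureSpec, modules: dict[str, int],
                     rng: np.random.Generator | None = None) -> PhenomeData:
    """Generate phenotype similarity, associations and the recovery truth list."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    s = spec.signal_strength
    phenos = [f"MIM:{600000 + i}" for i in range(1, spec.n_phenotypes + 1)]
    assignment = {p: i % spec.n_modules for i, p in enumerate(phenos)}
    genes = sorted(modules)
    by_module: dict[int, list[str]] = {}
    for g, m in modules.items():
        by_module.setdefault(m, []).append(g)
    for m in by_module:
        by_module[m].sort()

    # phenotype similarity: separation grows linearly with signal
    mvec = np.array([assignment[p] for p in phenos])
    same = mvec[:, None] == mvec[None, :]
    base, sep = 0.2, 0.6
    values = base + sep * s * same + rng.normal(0.0, 0.03, size=same.shape)
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    header = "\t" + "\t".join(phenos)
    lines = [header]
    for i, p in enumerate(phenos):
        lines.append(p + "\t" + "\t".join(f"{x:.6f}" for x in values[i]))
    similarity_text = "\n".join(lines) + "\n"

    # per-module shared disease-gene sets; corrupted phenotypes link
    # uniform random genes instead
    disease: dict[int, list[str]] = {
        m: sorted(rng.choice(by_module[m], size=spec.disease_genes_per_module,
                             replace=False))
        for m in range(spec.n_modules)
    }
    association_rows, truth_rows = [], []
    p_noise = (1.0 - s) ** 2
    for p in phenos:
        if rng.random() < p_noise:
            picked = sorted(rng.choice(genes, size=spec.disease_genes_per_module,
                                       replace=False))
            for g in picked:
                association_rows.append(f"{p}\t{g}")
        else:
            for g in disease[assignment[p]]:
                association_rows.append(f"{p}\t{g}")
                truth_rows.append(f"{p}\t{g}")
    return PhenomeData(phenotypes=phenos, assignment=assignment,
                       similarity_text=similarity_text,
                       association_rows=association_rows, truth_rows=truth_rows)


#: benchmark file inventory (name -> attribute path used by make_benchmark)
BENCHMARK_FILES = (
    "go.obo", "annotations_bp.gaf", "annotations_cc.gaf", "annotations_mf.gaf",
    "blast_hits.tsv", "domains.tsv", "gene_locations.tsv",
    "phenotype_similarity.tsv", "associations.tsv", "truth_associations.tsv",
)


def make_benchmark(spec: FixtureSpec, outdir, force: bool = False) -> dict:
    """Write a complete self-consistent input set plus a checksum manifest.

    Returns the manifest (spec and SHA-256 per file).  Refuses to write
    into a non-empty directory unless ``force`` is set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    existing = [p for p in outdir.iterdir() if p.name in BENCHMARK_FILES]
    if existing and not force:
        raise FileExistsError(f"{outdir} already holds benchmark files; "
                              "pass force=True to overwrite")
    rng = np.random.default_rng(spec.seed)
    gene_data = simulate_gene_data(spec, rng)
    phenome = simulate_phenome(spec, gene_data.modules, rng)

    contents = {
        "go.obo": gene_data.obo_text,
        "annotations_bp.gaf": gene_data.gaf_texts["BP"],
        "annotations_cc.gaf": gene_data.gaf_texts["CC"],
        "annotations_mf.gaf": gene_data.gaf_texts["MF"],
        "blast_hits.tsv": "\n".join(gene_data.blast_rows) + "\n",
        "domains.tsv": "\n".join(gene_data.domain_rows) + "\n",
        "gene_locations.tsv": "\n".join(gene_data.location_rows) + "\n",
        "phenotype_similarity.tsv": phenome.similarity_text,
        "associations.tsv": "\n".join(phenome.association_rows) + "\n",
        "truth_associations.tsv": "\n".join(phenome.truth_rows) + "\n"
        if phenome.truth_rows else "",
    }
    checksums = {}
    for name, text in contents.items():
        (outdir / name).write_text(text)
        checksums[name] = hashlib.sha256(text.encode()).hexdigest()
    manifest = {"spec": asdict(spec), "files": checksums}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
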