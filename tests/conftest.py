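import numpy as np
import pytest

from rwrb.io import EntityIndex, Ontology, SimilarityMatrix
from rwrb.pipeline import PipelineConfig
from rwrb.simulate import FixtureSpec, make_benchmark


@pytest.fixture(scope="session")
def chain_ontology():
    """A is_a B is_a R, all in the BP aspect."""
    return Ontology(
        terms={"A", "B", "R"},
        parents={"A": {("B", "is_a")}, "B": {("R", "is_a")}},
        namespace={"A": "BP", "B": "BP", "R": "BP"},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def random_similarity(rng, n):
    """A random symmetric nonnegative matrix with unit diagonal."""
    raw = rng.random((n, n))
    values = (raw + raw.T) / 2
    np.fill_diagonal(values, 1.0)
    index = EntityIndex.from_labels([f"g{i:03d}" for i in range(n)])
    return SimilarityMatrix(index=index, values=values)


@pytest.fixture(scope="session")
def small_benchmark(tmp_path_factory):
    """A 40-gene benchmark with strong planted signal, for pipeline tests."""
    outdir = tmp_path_factory.mktemp("bench-small")
    spec = FixtureSpec(n_genes=40, n_phenotypes=12, n_modules=4,
                       signal_strength=0.9, seed=11)
    make_benchmark(spec, outdir)
    return spec, outdir


def benchmark_config(bench_dir, **kw) -> PipelineConfig:
    defaults = dict(
        obo=str(bench_dir / "go.obo"),
        gaf_bp=str(bench_dir / "annotations_bp.gaf"),
        gaf_cc=str(bench_dir / "annotations_cc.gaf"),
        gaf_mf=str(bench_dir / "annotations_mf.gaf"),
        blast=str(bench_dir / "blast_hits.tsv"),
        domains=str(bench_dir / "domains.tsv"),
        locations=str(bench_dir / "gene_locations.tsv"),
        pheno_sim=str(bench_dir / "phenotype_similarity.tsv"),
        associations=str(bench_dir / "associations.tsv"),
        seed=1,
    )
    defaults.update(kw)
    return PipelineConfig(**defaults)
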