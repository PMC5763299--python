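"""End-to-end orchestration: raw inputs -> IGSN -> prioritization/validation.

The pipeline configuration is a flat key:value text file mirroring the
CLI flags; every output directory receives a serialized copy of the
effective configuration for provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

from . import io as rio
from .bilayer import BilayerNetwork, WalkConfig, initial_vector, rank_candidates, \
    rwr, transition_matrix
from .evaluation import CVReport, run_cv
from .semantic import build_go_network
from .seqdom import domain_similarity_network, sequence_similarity_network
from .snf import FusedNetwork, align_networks, fuse
from .threshold import IGSN, ThresholdScan, apply_threshold, threshold_scan

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run."""

    obo: str = ""
    gaf_bp: str = ""
    gaf_cc: str = ""
    gaf_mf: str = ""
    blast: str = ""
    domains: str = ""
    locations: str = ""
    pheno_sim: str = ""
    associations: str = ""
    outdir: str = "rwrb_out"
    # similarity / fusion
    evalue_cutoff: float = 1e-6
    seq_norm: str = "self"
    snf_k: int = 20
    snf_t: int = 20
    snf_tol: float = 1e-6
    # thresholding
    threshold_step: float = 0.001
    cc_denominator: str = "all"
    # walk
    gamma: float = 0.7
    lam: float = 0.6
    eta: float = 0.6
    walk_tol: float = 1e-6
    max_iter: int = 1000
    # evaluation
    mode: str = "linkage"
    interval_size: int = 99
    seed: int | None = None

    def walk_config(self) -> WalkConfig:
        return WalkConfig(gamma=self.gamma, lam=self.lam, eta=self.eta,
                          tol=self.walk_tol, max_iter=self.max_iter)

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Parse a flat key:value config file; keyword overrides win."""
        values: dict[str, object] = {}
        types = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if ":" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key: value'")
                key, raw = (x.strip() for x in line.split(":", 1))
                key = key.replace("-", "_")
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                values[key] = _coerce(raw, types[key])
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def to_file(self, path) -> None:
        lines = [f"{f.name}: {getattr(self, f.name)}" for f in fields(self)
                 if getattr(self, f.name) not in ("", None)]
        Path(path).write_text("\n".join(lines) + "\n")


def _coerce(raw: str, typ) -> object:
    typ = str(typ)
    if "int" in typ:
        return int(raw)
    if "float" in typ:
        return float(raw)
    return raw


@dataclass
class IGSNResult:
    igsn: IGSN
    fused: FusedNetwork
    scan: ThresholdScan
    networks: dict[str, rio.SimilarityMatrix] = field(default_factory=dict)


def build_similarity_networks(config: PipelineConfig) -> dict[str, rio.SimilarityMatrix]:
    """Build the five per-source gene similarity networks from raw inputs."""
    ontology = rio.read_obo(config.obo)
    nets: dict[str, rio.SimilarityMatrix] = {}
    for aspect, path in (("BP", config.gaf_bp), ("CC", config.gaf_cc),
                         ("MF", config.gaf_mf)):
        ann = rio.read_gaf(path, ontology, aspect)
        nets[aspect] = build_go_network(ann, ontology)
        logger.info("%s network: %d genes", aspect, len(nets[aspect].index))
    scores = rio.read_pair_scores(config.blast, evalue_cutoff=config.evalue_cutoff)
    nets["SEQ"] = sequence_similarity_network(scores, norm=config.seq_norm)
    logger.info("sequence network: %d genes", len(nets["SEQ"].index))
    doms = rio.read_domain_table(config.domains)
    nets["DOM"] = domain_similarity_network(doms)
    logger.info("domain network: %d genes", len(nets["DOM"].index))
    return nets


def build_igsn_pipeline(config: PipelineConfig,
                        persist: bool = True) -> IGSNResult:
    """Raw inputs -> five networks -> fused network -> threshold -> IGSN."""
    nets = build_similarity_networks(config)
    aligned = align_networks(list(nets.values()))
    nets_aligned = dict(zip(nets.keys(), aligned))
    logger.info("union gene index: %d genes", len(aligned[0].index))
    fused = fuse(aligned, K=config.snf_k, T=config.snf_t, tol=config.snf_tol)
    logger.info("fusion converged after %d iterations", fused.iterations_run)
    scan = threshold_scan(fused, step=config.threshold_step,
                          denominator=config.cc_denominator)
    igsn = apply_threshold(fused, scan.selected)
    logger.info("selected threshold %.4g; IGSN has %d genes, %d edges",
                scan.selected, len(igsn.index), igsn.n_edges)
    if persist:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_file(outdir / "config.txt")
        for name, net in nets_aligned.items():
            rio.write_matrix(net, outdir / f"network_{name.lower()}.tsv")
        rio.write_matrix(
            rio.SimilarityMatrix(index=fused.index, values=fused.values),
            outdir / "fused.tsv")
        _write_scan(scan, outdir / "scan.tsv")
        rio.write_edge_list(
            rio.SimilarityMatrix(index=igsn.index, values=igsn.adjacency),
            outdir / "igsn_edges.tsv")
    return IGSNResult(igsn=igsn, fused=fused, scan=scan, networks=nets_aligned)


def _write_scan(scan: ThresholdScan, path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tC\tC0\tDCC\n")
        for r, c, c0 in zip(scan.grid, scan.c, scan.c0):
            fh.write(f"{r:.6g}\t{c:.8g}\t{c0:.8g}\t{c - c0:.8g}\n")


def load_bilayer(config: PipelineConfig, igsn: IGSN) -> tuple[BilayerNetwork,
                                                              rio.AssociationList]:
    pheno_sim = rio.read_matrix(config.pheno_sim)
    associations = rio.read_associations(config.associations,
                                         pheno_sim.index, igsn.index)
    bilayer = BilayerNetwork.from_components(pheno_sim, associations, igsn)
    return bilayer, associations


def prioritize_pipeline(config: PipelineConfig, phenotype: str,
                        igsn: IGSN | None = None,
                        top: int | None = None) -> list[tuple[str, float, int]]:
    """Rank candidate genes for one phenotype (its seed genes excluded)."""
    if igsn is None:
        igsn = build_igsn_pipeline(config, persist=False).igsn
    bilayer, associations = load_bilayer(config, igsn)
    if phenotype not in bilayer.pheno_index:
        near = [p for p in bilayer.pheno_index.labels if phenotype in p][:5]
        raise KeyError(f"unknown phenotype {phenotype!r}; nearest ids: {near}")
    seeds = [g for g in associations.genes_of(phenotype) if g in igsn.index]
    wc = config.walk_config()
    M = transition_matrix(bilayer, lam=wc.lam)
    p0 = initial_vector([phenotype], seeds, wc.eta,
                        bilayer.pheno_index, bilayer.gene_index)
    p_inf = rwr(M, p0, gamma=wc.gamma, tol=wc.tol, max_iter=wc.max_iter)
    candidates = [g for g in igsn.index.labels if g not in set(seeds)]
    ranked = rank_candidates(p_inf, bilayer.gene_index, candidates)
    return ranked[:top] if top else ranked


def evaluate_pipeline(config: PipelineConfig,
                      igsn: IGSN | None = None) -> CVReport:
    """Run the configured leave-one-out protocol end to end."""
    if igsn is None:
        igsn = build_igsn_pipeline(config, persist=False).igsn
    bilayer, associations = load_bilayer(config, igsn)
    locations = rio.read_locations(config.locations) if config.locations else None
    return run_cv(bilayer, associations, config.mode,
                  config=config.walk_config(), locations=locations,
                  interval_size=config.interval_size)
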