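"""End-to-end orchestration of the five-stage analysis.

Stages: weighted-network construction -> drug-target bipartite overlap ->
pathway enrichment of the formula targets -> propagation effect scores with
permutation z-scores (per drug, per component, whole formula) -> disease
subnetwork + topology report.  All outputs are plain TSV/JSON under one
directory, and a manifest captures every parameter, seed and input checksum
needed to re-run the pipeline bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import netio
from .bipartite import build_bipartite, shared_targets
from .enrich import enrich_targets
from .nullmodel import drug_significance
from .propagate import disease_effect
from .topology import annotate_targets, extract_top_fraction
from .util import derive_seed

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All file paths and parameters of one analysis run.

    Numeric defaults are the study conventions: restart probability 0.3,
    approved-drug seed strength 1.0 vs herbal-component strength 0.01,
    enrichment alpha 0.01, 3000 permutations, top-3% subnetwork, and
    high-confidence edge threshold 0.9.
    """

    network_path: str
    disease_genes_path: str
    drug_targets_path: str
    pathways_path: str
    r: float = 0.3
    tol: float = 1e-10
    max_iter: int = 10_000
    drug_strength: float = 1.0
    component_strength: float = 0.01
    alpha: float = 0.01
    n_perm: int = 3000
    top_fraction: float = 0.03
    rng_seed: int = 0
    weight_scale: float = 1.0
    high_conf: float = 0.9

    def __post_init__(self):
        if not (0.0 < self.r <= 1.0):
            raise ValueError("r must be in (0, 1]")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")
        if self.drug_strength <= 0 or self.component_strength <= 0:
            raise ValueError("seed strengths must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 2:
            raise ValueError("n_perm must be >= 2")
        if not (0.0 < self.top_fraction < 1.0):
            raise ValueError("top_fraction must be in (0, 1)")
        if self.weight_scale <= 0:
            raise ValueError("weight_scale must be > 0")
        if not (0.0 < self.high_conf <= 1.0):
            raise ValueError("high_conf must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with path.open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the report bundle under ``outdir``.

    Returns a dict of the in-memory results.  Any stage failure is re-raised
    with the stage name prepended.  Output is a pure function of the inputs
    and ``config.rng_seed`` (per-drug permutation seeds are derived by
    stable hashing), so two runs with the same config are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "read-inputs"
    try:
        raw_edges = netio.read_edge_list(config.network_path, config.weight_scale)
        disease_genes = netio.read_gene_list(config.disease_genes_path)
        drug_table = netio.read_drug_targets(config.drug_targets_path)
        pathways = netio.read_gmt(config.pathways_path)

        stage = "build-network"
        focus = set(disease_genes) | set(drug_table.all_targets)
        build = netio.build_network(raw_edges, focus, config.high_conf)
        network = build.network
        logger.info(
            "network: %d nodes, %d edges (%d rescued, %d unmapped)",
            network.number_of_nodes(), network.number_of_edges(),
            len(build.rescued), len(build.unmapped),
        )
        netio.write_edge_list(network, outdir / "network.tsv")

        stage = "bipartite"
        classes = drug_table.drugs
        components = sorted(
            d for d, c in classes.items() if c == "herbal_component"
        )
        formula_targets = frozenset().union(
            *(drug_table.targets_of(d) for d in components)
        ) if components else frozenset()
        binet = build_bipartite(drug_table)
        binet.write_tsv(outdir / "bipartite_edges.tsv", outdir / "bipartite_nodes.tsv")
        shared = shared_targets(formula_targets, binet)
        _write_json(
            {
                "by_class": {c: sorted(s) for c, s in shared.by_class.items()},
                "overall": sorted(shared.overall),
                "n_classes_overlapping": shared.n_classes_overlapping,
            },
            outdir / "shared_targets.json",
        )

        stage = "enrich"
        enrichment = None
        if formula_targets:
            enrichment = enrich_targets(formula_targets, pathways, config.alpha)
            enrichment.to_tsv(outdir / "enrichment.tsv")

        stage = "propagate-disease"
        disease = disease_effect(
            network, disease_genes, r=config.r, tol=config.tol,
            max_iter=config.max_iter,
        )
        with (outdir / "disease_scores.tsv").open("w") as fh:
            fh.write("node\tscore\n")
            for v in network.node_order:
                fh.write(f"{v}\t{disease.scores[v]:.10g}\n")

        stage = "score-drugs"
        reports: dict[str, dict] = {}
        seed_sets: dict[str, tuple[frozenset[str], float]] = {}
        for drug_id, cls in sorted(classes.items()):
            strength = (
                config.component_strength
                if cls == "herbal_component"
                else config.drug_strength
            )
            seed_sets[drug_id] = (drug_table.targets_of(drug_id), strength)
        if components:
            seed_sets["FORMULA"] = (formula_targets, config.component_strength)
        for name, (targets, strength) in sorted(seed_sets.items()):
            rep = drug_significance(
                network, disease, targets, strength=strength,
                n_perm=config.n_perm,
                rng_seed=derive_seed(config.rng_seed, f"null:{name}"),
                r=config.r, tol=config.tol, max_iter=config.max_iter,
            )
            reports[name] = {
                "drug_id": name,
                "drug_class": classes.get(name, "formula"),
                "n_targets": len(targets),
                "n_targets_on_network": len(rep.drug.seeds.strengths),
                "strength": strength,
                "E": rep.E,
                "z": rep.z,
                "null_mean": rep.null.mean,
                "null_sd": rep.null.sd,
                "n_perm": rep.null.n_perm,
                "seed": rep.null.rng_seed,
                "significant": rep.significant,
            }
            logger.info("%s: E=%.4g z=%.2f", name, rep.E, rep.z)
        _write_json(reports, outdir / "effect_scores.json")

        stage = "subnetwork"
        sub = extract_top_fraction(
            network, disease, fraction=config.top_fraction,
            disease_genes=disease_genes,
        )
        with (outdir / "subnetwork_edges.tsv").open("w") as fh:
            fh.write("node_a\tnode_b\tweight\n")
            for a, b in sorted(tuple(sorted(e)) for e in sub.graph.edges):
                fh.write(f"{a}\t{b}\t{sub.graph[a][b]['weight']:.6g}\n")

        stage = "topology"
        topo = annotate_targets(sub, disease_genes, drug_table)
        topo.to_tsv(outdir / "topology.tsv")
        _write_json(
            {
                "n_nodes": sub.number_of_nodes(),
                "n_edges": sub.number_of_edges(),
                "disease_genes_retained": sub.disease_genes_retained,
                "disease_genes_total": sub.disease_genes_total,
                "disease_gene_coverage_pct": sub.disease_gene_coverage_pct,
                **topo.summary,
            },
            outdir / "topology_summary.json",
        )

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "inputs": {
                "network": _sha256(config.network_path),
                "disease_genes": _sha256(config.disease_genes_path),
                "drug_targets": _sha256(config.drug_targets_path),
                "pathways": _sha256(config.pathways_path),
            },
            "network_nodes": network.number_of_nodes(),
            "network_edges": network.number_of_edges(),
            "rescued_genes": {g: w for g, w in sorted(build.rescued.items())},
            "unmapped_genes": list(build.unmapped),
        }
        _write_json(manifest, outdir / "manifest.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "network": network,
        "build": build,
        "bipartite": binet,
        "shared_targets": shared,
        "enrichment": enrichment,
        "disease": disease,
        "drug_reports": reports,
        "subnetwork": sub,
        "topology": topo,
        "manifest": manifest,
    }
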