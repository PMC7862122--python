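"""End-to-end orchestration of the network-pharmacology funnel.

The stages run in the classical order: ADME screen of candidate
compounds, target prediction and union, intersection with the disease
gene set, interaction-network construction on the overlap genes,
two-round median-threshold hub screening, overrepresentation analysis of
the hubs, and the compound-target(-pathway) network exports.  Inputs are
produced by the synthetic generators stage-by-stage, so each generator
consumes the genuine output of the previous stage (the annotation
collection, for example, is planted against the hub set the screen
actually produced).  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io, synthetic
from .config import SimulationConfig
from .enrichment import ora, top_terms
from .errors import HerbnetError, ValidationError
from .network import build_ct_network, build_ctp_network, export_graph
from .screen import filter_adme
from .targets import intersect_with_disease, per_compound_key_counts, union_compound_targets
from .topology import centrality_table, iterative_screen
from .validation import delta_delta_ct

logger = logging.getLogger("herbnet")


@dataclass
class PipelineConfig:
    """Stage parameters and the simulation settings feeding them."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    ob_min: float = 30.0
    dl_min: float = 0.18
    adme_inclusive: bool = True
    screen_rounds: int = 2
    screen_inclusive: bool = True
    until_stable: bool = False
    fdr_cutoff: float = 0.05
    top_n_terms: int = 20
    top_n_pathways: int = 10
    export_format: str = "graphml"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("sim", {}).items()
        })
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown pipeline settings: {sorted(unknown)}")
        params = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
        return cls(sim=sim, **params)


@dataclass
class FunnelReport:
    """Stage-by-stage counts of the screening funnel."""

    seed: int
    n_compounds_in: int = 0
    n_compounds_passing: int = 0
    n_targets_union: int = 0
    n_disease_genes: int = 0
    n_overlap: int = 0
    ppi_nodes: int = 0
    ppi_edges: int = 0
    rounds: list[dict] = field(default_factory=list)
    n_final_hubs: int = 0
    n_terms_passing: int = 0
    per_compound_targets: dict[str, int] = field(default_factory=dict)
    per_compound_key_targets: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FunnelReport":
        return cls(**d)


def write_report(report: FunnelReport, path: str | Path, format: str = "json") -> Path:
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    elif format == "markdown":
        lines = [
            "| stage | count |",
            "| --- | --- |",
            f"| candidate compounds | {report.n_compounds_in} |",
            f"| compounds passing ADME | {report.n_compounds_passing} |",
            f"| predicted targets (union) | {report.n_targets_union} |",
            f"| disease genes | {report.n_disease_genes} |",
            f"| compound-disease overlap | {report.n_overlap} |",
            f"| PPI nodes / edges | {report.ppi_nodes} / {report.ppi_edges} |",
        ]
        for r in report.rounds:
            lines.append(
                f"| screening round {r['round_index']} survivors / edges "
                f"| {r['n_survivors']} / {r['induced_edge_count']} |"
            )
        lines.append(f"| final hub targets | {report.n_final_hubs} |")
        lines.append(f"| enriched terms (FDR pass) | {report.n_terms_passing} |")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown report format {format!r}")
    return path


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> FunnelReport:
    """Run the full synthetic funnel and write every stage artifact.

    Artifacts (all under ``outdir``): compounds.tsv, passing_compounds.tsv,
    associations.tsv, disease_genes.txt, venn_summary.json,
    overlap_genes.txt, ppi_edges.tsv, centrality_table.tsv,
    screening_report.json, hubs.txt, annotation.gmt (+ categories),
    enrichment.tsv, ct_network.* and ctp_network.* exports, ct_table.tsv,
    fold_changes.tsv, ground_truth.json, funnel_report.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    report = FunnelReport(seed=sim.seed)
    stage = "simulate compounds"
    try:
        compounds, truth = synthetic.generate_compound_table(sim)
        io.write_tsv(compounds, outdir / "compounds.tsv")
        report.n_compounds_in = len(compounds)

        stage = "ADME screen"
        passing = filter_adme(
            compounds, ob_min=config.ob_min, dl_min=config.dl_min,
            inclusive=config.adme_inclusive,
        )
        io.write_tsv(passing, outdir / "passing_compounds.tsv")
        report.n_compounds_passing = len(passing)
        logger.info("screen: %d/%d compounds pass", len(passing), len(compounds))

        stage = "target mapping"
        associations = synthetic.generate_target_associations(sim, passing)
        io.write_tsv(associations, outdir / "associations.tsv")
        _, union, counts = union_compound_targets(associations)
        report.n_targets_union = len(union)
        report.per_compound_targets = dict(sorted(counts.items()))

        stage = "disease intersection"
        disease_genes, t_dis = synthetic.generate_disease_genes(sim, associations)
        truth.true_overlap_genes = t_dis.true_overlap_genes
        io.write_gene_list(disease_genes, outdir / "disease_genes.txt")
        venn = intersect_with_disease(union, disease_genes)
        (outdir / "venn_summary.json").write_text(
            json.dumps(venn.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        overlap = sorted(venn.overlap)
        io.write_gene_list(overlap, outdir / "overlap_genes.txt")
        report.n_disease_genes = venn.n_disease_genes
        report.n_overlap = venn.n_overlap
        logger.info("map: %d union targets, %d overlap disease", len(union), venn.n_overlap)

        stage = "PPI construction"
        ppi, t_ppi = synthetic.generate_ppi(sim, overlap)
        truth.planted_hub_ids = t_ppi.planted_hub_ids
        io.write_edge_list(ppi, outdir / "ppi_edges.tsv")
        report.ppi_nodes = ppi.number_of_nodes()
        report.ppi_edges = ppi.number_of_edges()

        stage = "topological screening"
        io.write_tsv(centrality_table(ppi), outdir / "centrality_table.tsv")
        screening = iterative_screen(
            ppi, rounds=config.screen_rounds,
            inclusive=config.screen_inclusive, until_stable=config.until_stable,
        )
        (outdir / "screening_report.json").write_text(
            json.dumps(screening.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        hubs = sorted(screening.final_hubs)
        io.write_gene_list(hubs, outdir / "hubs.txt")
        report.rounds = [r.to_dict() for r in screening.rounds]
        report.n_final_hubs = len(hubs)
        report.per_compound_key_targets = dict(
            sorted(per_compound_key_counts(associations, set(hubs)).items())
        )
        logger.info("topo: %d hubs after %d rounds", len(hubs), len(screening.rounds))

        stage = "enrichment"
        universe = synthetic.gene_universe(sim)
        annotation, t_ann = synthetic.generate_annotation(sim, universe, set(hubs))
        truth.planted_term_id = t_ann.planted_term_id
        io.write_gmt(annotation, outdir / "annotation.gmt")
        rows = ora(set(hubs), annotation, universe=universe) if hubs else []
        io.write_tsv(io.enrichment_to_frame(rows), outdir / "enrichment.tsv")
        selected = top_terms(rows, top_n=config.top_n_terms, fdr_cutoff=config.fdr_cutoff)
        report.n_terms_passing = len(selected)
        logger.info("enrich: %d terms pass FDR < %g", len(selected), config.fdr_cutoff)

        stage = "network export"
        ct_net = build_ct_network(associations, restrict_to=set(hubs) if hubs else None)
        export_graph(ct_net, config.export_format, outdir / f"ct_network.{config.export_format}")
        pathway_rows = [r for r in selected if r.category == "pathway"]
        ctp = build_ctp_network(
            ct_net, pathway_rows, top_n=min(config.top_n_pathways, len(pathway_rows))
        )
        export_graph(ctp, config.export_format, outdir / f"ctp_network.{config.export_format}")

        stage = "expression validation"
        ct_table, t_ct = synthetic.generate_ct_table(sim)
        truth.true_fold = t_ct.true_fold
        io.write_tsv(ct_table, outdir / "ct_table.tsv")
        per_sample, summary = delta_delta_ct(
            ct_table, synthetic.TARGET_GENE, synthetic.REFERENCE_GENE
        )
        io.write_tsv(per_sample, outdir / "fold_changes.tsv")
        io.write_tsv(summary, outdir / "fold_summary.tsv")

        io.write_ground_truth(truth, outdir / "ground_truth.json")
        write_report(report, outdir / "funnel_report.json", "json")
        write_report(report, outdir / "funnel_report.md", "markdown")
    except HerbnetError as err:
        raise HerbnetError(f"pipeline stage '{stage}' failed: {err}") from err
    return report


def recount_from_artifacts(outdir: str | Path) -> dict:
    """Independent recount of the funnel from the written stage artifacts.

    Used to audit that the report's numbers equal what the files contain.
    """
    outdir = Path(outdir)
    compounds = io.read_compounds(outdir / "compounds.tsv")
    passing = io.read_compounds(outdir / "passing_compounds.tsv")
    associations = io.read_associations(outdir / "associations.tsv")
    disease = io.read_gene_list(outdir / "disease_genes.txt")
    overlap = io.read_gene_list(outdir / "overlap_genes.txt")
    hubs = io.read_gene_list(outdir / "hubs.txt")
    ppi = io.read_edge_list(outdir / "ppi_edges.tsv")
    return {
        "n_compounds_in": len(compounds),
        "n_compounds_passing": len(passing),
        "n_targets_union": len(set(associations["target_id"])),
        "n_disease_genes": len(set(disease)),
        "n_overlap": len(set(overlap)),
        "ppi_edges": ppi.number_of_edges(),
        "n_final_hubs": len(set(hubs)),
    }
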