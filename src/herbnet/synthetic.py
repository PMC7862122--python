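"""Synthetic generators for every pipeline input.

Each generator draws from its own pseudo-random stream derived from
``(seed, stage)``, so a stage can be regenerated on its own (e.g. the
annotation collection can be re-planted against the hub set produced by a
live pipeline run) without disturbing the other stages.  All outputs are
deterministic: the same :class:`~herbnet.config.SimulationConfig` yields
byte-identical tables.

Conventions: gene symbols are ``G0001``..``G{n_target_universe}``; extra
disease-only genes not in the prediction universe are ``HF0001``...;
compounds are ``CMP01``...; annotation terms are ``T0001``....
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .config import GroundTruth, SimulationConfig
from .enrichment import GeneSetCollection, GeneSetTerm
from .errors import ConfigurationError, InputError

# Fixed per-stage codes so streams are independent yet reproducible.
_STAGE_CODES = {
    "compounds": 11,
    "associations": 23,
    "disease": 37,
    "ppi": 53,
    "annotation": 71,
    "ct": 89,
}

# Decorative source labels mimicking the usual five target-prediction
# services; they only exist to exercise cross-source deduplication.
SOURCES = ("tcmsp", "pubchem", "stitch", "superpred", "swisstarget")

TARGET_GENE = "ACTA2"
REFERENCE_GENE = "GAPDH"


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STAGE_CODES[stage]]))


def gene_universe(config: SimulationConfig) -> list[str]:
    """The ordered symbol universe the target/annotation generators draw from."""
    width = len(str(config.n_target_universe))
    return [f"G{i:0{width}d}" for i in range(1, config.n_target_universe + 1)]


def generate_compound_table(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Candidate-compound table with a known subset passing the ADME screen.

    Exactly ``round(n_compounds * ob_pass_fraction)`` records satisfy
    OB >= 30 and DL >= 0.18; every other record fails at least one cutoff.
    Values are kept clear of the cutoffs (pass: OB in [35, 95], DL in
    [0.22, 0.95]; fail: OB <= 29.5 and/or DL <= 0.17) so rounding for
    display can never flip a record across the boundary.
    """
    rng = _rng(config, "compounds")
    n = config.n_compounds
    n_pass = round(n * config.ob_pass_fraction)
    ids = [f"CMP{i:02d}" for i in range(1, n + 1)]
    passing = set(rng.choice(ids, size=n_pass, replace=False).tolist())

    rows = []
    for cid in ids:
        if cid in passing:
            ob = rng.uniform(35.0, 95.0)
            dl = rng.uniform(0.22, 0.95)
        else:
            mode = rng.choice(["ob", "dl", "both"])
            ob = rng.uniform(2.0, 29.5) if mode in ("ob", "both") else rng.uniform(35.0, 95.0)
            dl = rng.uniform(0.01, 0.17) if mode in ("dl", "both") else rng.uniform(0.22, 0.95)
        rows.append((cid, f"flavonoid-{cid[3:]}", round(float(ob), 2), round(float(dl), 3)))

    table = pd.DataFrame(rows, columns=["id", "name", "ob", "dl"])
    truth = GroundTruth(passing_compound_ids=passing)
    return table, truth


def generate_target_associations(
    config: SimulationConfig, compounds: pd.DataFrame
) -> pd.DataFrame:
    """Compound -> target association table across mock prediction sources.

    Each compound receives a target-set size drawn uniformly within
    ``targets_per_compound``; roughly a third of the associations are
    duplicated under a second source label, so downstream deduplication is
    actually exercised.
    """
    if compounds is None or len(compounds) == 0:
        raise InputError("compound table is empty; cannot generate target associations")
    rng = _rng(config, "associations")
    universe = np.array(gene_universe(config))
    lo, hi = config.targets_per_compound

    rows: list[tuple[str, str, str]] = []
    for cid in compounds["id"]:
        size = int(rng.integers(lo, hi + 1))
        targets = rng.choice(universe, size=size, replace=False)
        for t in targets:
            src = rng.choice(SOURCES)
            rows.append((cid, str(t), str(src)))
            if rng.random() < 0.3:  # duplicate hit under another source
                other = rng.choice([s for s in SOURCES if s != src])
                rows.append((cid, str(t), str(other)))
    return pd.DataFrame(rows, columns=["compound_id", "target_id", "source"])


def generate_disease_genes(
    config: SimulationConfig, associations: pd.DataFrame
) -> tuple[list[str], GroundTruth]:
    """Disease gene list with a planted overlap against the compound targets.

    The intersection with the compound-target union has size exactly
    ``round(disease_overlap_fraction * |union|)``.  Disease-only genes are
    drawn first from the part of the universe no compound hits, then from a
    disease-specific namespace (``HF####``) if more are needed, so the
    planted intersection is exact by construction.
    """
    if associations is None or len(associations) == 0:
        raise InputError("association table is empty; cannot generate disease genes")
    rng = _rng(config, "disease")
    union = sorted(set(associations["target_id"]))
    n_overlap = round(config.disease_overlap_fraction * len(union))
    if n_overlap > config.n_disease_genes:
        raise ConfigurationError(
            f"planted overlap ({n_overlap}) exceeds n_disease_genes ({config.n_disease_genes})"
        )
    overlap = set(rng.choice(union, size=n_overlap, replace=False).tolist()) if n_overlap else set()

    n_rest = config.n_disease_genes - n_overlap
    outside = sorted(set(gene_universe(config)) - set(union))
    rest = rng.choice(outside, size=min(n_rest, len(outside)), replace=False).tolist()
    rest += [f"HF{i:04d}" for i in range(1, n_rest - len(rest) + 1)]

    genes = sorted(overlap) + sorted(rest)
    order = rng.permutation(len(genes))
    genes = [genes[i] for i in order]
    return genes, GroundTruth(true_overlap_genes=overlap)


def generate_ppi(
    config: SimulationConfig, nodes: list[str]
) -> tuple[nx.Graph, GroundTruth]:
    """Planted-hub interaction network on ``ppi_n_nodes`` of the given genes.

    A random subset of ``ppi_n_planted_hubs`` nodes attaches to every other
    node (hubs included) independently with ``ppi_hub_attach_prob``;
    all remaining pairs use ``ppi_background_edge_prob``.  The result is a
    simple undirected graph: no self-loops, no duplicate edges, and
    isolated nodes are kept as nodes.
    """
    nodes = list(dict.fromkeys(nodes))
    if config.ppi_n_nodes > len(nodes):
        raise ConfigurationError(
            f"ppi_n_nodes ({config.ppi_n_nodes}) exceeds the available gene list ({len(nodes)})"
        )
    rng = _rng(config, "ppi")
    chosen = sorted(rng.choice(np.array(nodes), size=config.ppi_n_nodes, replace=False).tolist())
    hubs = set(rng.choice(chosen, size=config.ppi_n_planted_hubs, replace=False).tolist())

    n = len(chosen)
    is_hub = np.array([c in hubs for c in chosen])
    prob = np.full((n, n), config.ppi_background_edge_prob)
    prob[is_hub, :] = config.ppi_hub_attach_prob
    prob[:, is_hub] = config.ppi_hub_attach_prob
    draw = rng.random((n, n))
    iu, ju = np.triu_indices(n, k=1)
    keep = draw[iu, ju] < prob[iu, ju]

    g = nx.Graph()
    g.add_nodes_from(chosen)
    g.add_edges_from((chosen[i], chosen[j]) for i, j in zip(iu[keep], ju[keep]))
    return g, GroundTruth(planted_hub_ids=hubs)


def generate_annotation(
    config: SimulationConfig, universe: list[str], query: set[str]
) -> tuple[GeneSetCollection, GroundTruth]:
    """Annotation gene-set collection with one planted enriched term.

    Term sizes are uniform within ``term_size_range`` and members are drawn
    at random from the universe; categories rotate through the usual
    BP/CC/MF/pathway split.  One randomly chosen term (assigned to the
    pathway category) has its overlap with the query inflated to
    ``planted_term_enrichment`` times the hypergeometric expectation
    ``K * n / N``.  With ``planted_term_enrichment == 1`` nothing is
    planted, which is the null collection used for calibration checks.
    """
    universe = list(dict.fromkeys(universe))
    uset = set(universe)
    query = set(query)
    if not query <= uset:
        raise ConfigurationError("query gene set must be a subset of the universe")
    rng = _rng(config, "annotation")
    lo, hi = config.term_size_range
    if hi > len(universe):
        raise ConfigurationError(f"term size {hi} exceeds universe of {len(universe)}")

    plant = config.planted_term_enrichment > 1.0 and len(query) > 0
    planted_idx = int(rng.integers(config.n_terms)) if plant else -1
    categories = ("BP", "CC", "MF", "pathway")
    uarr = np.array(universe)
    qarr = np.array(sorted(query))
    non_query = np.array(sorted(uset - query))

    terms = []
    planted_id = None
    for i in range(config.n_terms):
        tid = f"T{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if i == planted_idx:
            expected = size * len(query) / len(universe)
            k_plant = min(size, len(query), max(1, round(config.planted_term_enrichment * expected)))
            members = set(rng.choice(qarr, size=k_plant, replace=False).tolist())
            members |= set(rng.choice(non_query, size=size - k_plant, replace=False).tolist())
            category = "pathway"
            planted_id = tid
        else:
            members = set(rng.choice(uarr, size=size, replace=False).tolist())
            category = categories[i % len(categories)]
        terms.append(GeneSetTerm(tid, f"synthetic gene set {i + 1}", category, frozenset(members)))

    return GeneSetCollection(terms), GroundTruth(planted_term_id=planted_id)


def generate_ct_table(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """qPCR Ct table with a known expression fold change.

    Reference-gene Ct sits near 20 cycles and the target near 26 in the
    control group; treated target Ct is shifted by ``-log2(ct_true_fold)``
    (more template, earlier threshold crossing).  Gaussian noise of
    ``ct_noise_sd`` cycles is added to every measurement; with zero noise
    the Livak arithmetic inverts the table exactly.
    """
    rng = _rng(config, "ct")
    shift = -np.log2(config.ct_true_fold)
    rows = []
    for group, target_base in (("control", 26.0), ("treated", 26.0 + shift)):
        for r in range(1, config.n_ct_replicates + 1):
            sid = f"{group}_{r}"
            rows.append((sid, group, TARGET_GENE, target_base + rng.normal(0, config.ct_noise_sd)))
            rows.append((sid, group, REFERENCE_GENE, 20.0 + rng.normal(0, config.ct_noise_sd)))
    table = pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])
    table["ct"] = table["ct"].round(4)
    return table, GroundTruth(true_fold=config.ct_true_fold)


@dataclass
class SyntheticDataset:
    """One coherent draw of every pipeline input plus its ground truth."""

    compounds: pd.DataFrame
    associations: pd.DataFrame
    disease_genes: list[str]
    ppi: nx.Graph
    annotation: GeneSetCollection
    ct_table: pd.DataFrame
    truth: GroundTruth


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full input stack in funnel order.

    Target associations are generated for the compounds that pass the ADME
    screen (the funnel predicts targets only for active compounds); the
    interaction network is built on the planted compound-disease overlap
    genes, and the annotation collection is planted against that same
    overlap set.
    """
    compounds, truth = generate_compound_table(config)
    passing = compounds[compounds["id"].isin(truth.passing_compound_ids)]
    associations = generate_target_associations(config, passing)
    disease_genes, t_dis = generate_disease_genes(config, associations)
    truth.true_overlap_genes = t_dis.true_overlap_genes
    ppi, t_ppi = generate_ppi(config, sorted(truth.true_overlap_genes))
    truth.planted_hub_ids = t_ppi.planted_hub_ids
    annotation, t_ann = generate_annotation(
        config, gene_universe(config), truth.true_overlap_genes
    )
    truth.planted_term_id = t_ann.planted_term_id
    ct_table, t_ct = generate_ct_table(config)
    truth.true_fold = t_ct.true_fold
    return SyntheticDataset(
        compounds, associations, disease_genes, ppi, annotation, ct_table, truth
    )
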