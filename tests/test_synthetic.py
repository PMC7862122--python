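"""Generators: planted structure, determinism, ground-truth consistency."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import herbnet.synthetic as syn
from herbnet import (
    ConfigurationError,
    InputError,
    SimulationConfig,
    filter_adme,
    intersect_with_disease,
    ora,
)


def test_compound_table_plants_exact_pass_count():
    cfg = SimulationConfig(seed=1, n_compounds=20, ob_pass_fraction=0.25)
    table, truth = syn.generate_compound_table(cfg)
    passing = table[(table.ob >= 30) & (table.dl >= 0.18)]
    assert len(passing) == 5
    assert set(passing.id) == truth.passing_compound_ids
    failing = table[~table.id.isin(truth.passing_compound_ids)]
    assert ((failing.ob < 30) | (failing.dl < 0.18)).all()
    assert table.id.is_unique


def test_adme_filter_recovers_planted_passers():
    cfg = SimulationConfig(seed=2, n_compounds=200, ob_pass_fraction=0.5)
    table, truth = syn.generate_compound_table(cfg)
    assert set(filter_adme(table).id) == truth.passing_compound_ids


@pytest.mark.parametrize(
    "generator",
    [
        syn.generate_compound_table,
        syn.generate_ct_table,
    ],
)
def test_generator_determinism(generator):
    cfg = SimulationConfig(seed=7)
    a = generator(cfg)[0]
    b = generator(cfg)[0]
    assert a.to_csv() == b.to_csv()


def test_association_determinism_and_universe():
    cfg = SimulationConfig(seed=7)
    comp, _ = syn.generate_compound_table(cfg)
    a = syn.generate_target_associations(cfg, comp)
    b = syn.generate_target_associations(cfg, comp)
    pd.testing.assert_frame_equal(a, b)
    assert set(a.target_id) <= set(syn.gene_universe(cfg))


def test_fixed_target_count_per_compound():
    cfg = SimulationConfig(seed=3, targets_per_compound=(3, 3))
    comp, _ = syn.generate_compound_table(cfg)
    assoc = syn.generate_target_associations(cfg, comp)
    per = assoc.drop_duplicates(["compound_id", "target_id"]).groupby("compound_id").size()
    assert (per == 3).all()
    assert set(per.index) == set(comp.id)


def test_associations_reject_empty_compounds():
    cfg = SimulationConfig(seed=3)
    with pytest.raises(InputError):
        syn.generate_target_associations(cfg, pd.DataFrame(columns=["id"]))


@pytest.mark.parametrize("fraction,check", [(0.0, "empty"), (1.0, "subset")])
def test_disease_overlap_extremes(fraction, check):
    cfg = SimulationConfig(seed=4, disease_overlap_fraction=fraction, n_disease_genes=400)
    comp, truth = syn.generate_compound_table(cfg)
    passing = comp[comp.id.isin(truth.passing_compound_ids)]
    assoc = syn.generate_target_associations(cfg, passing)
    genes, t = syn.generate_disease_genes(cfg, assoc)
    union = set(assoc.target_id)
    if check == "empty":
        assert union.isdisjoint(genes)
        assert t.true_overlap_genes == set()
    else:
        assert union <= set(genes)
        assert t.true_overlap_genes == union


def test_disease_intersection_round_trip(dataset):
    venn = intersect_with_disease(set(dataset.associations.target_id), dataset.disease_genes)
    assert set(venn.overlap) == dataset.truth.true_overlap_genes


def test_disease_overlap_exact_size():
    cfg = SimulationConfig(seed=5)
    comp, truth = syn.generate_compound_table(cfg)
    assoc = syn.generate_target_associations(cfg, comp[comp.id.isin(truth.passing_compound_ids)])
    genes, t = syn.generate_disease_genes(cfg, assoc)
    union = set(assoc.target_id)
    assert len(union & set(genes)) == round(cfg.disease_overlap_fraction * len(union))
    assert len(genes) == cfg.n_disease_genes


def test_ppi_two_star_construction():
    # background 0, hub attach 1: the graph is exactly the union of two
    # stars whose centers are also linked to each other.
    cfg = SimulationConfig(
        seed=6,
        ppi_n_nodes=10,
        ppi_n_planted_hubs=2,
        ppi_background_edge_prob=0.0,
        ppi_hub_attach_prob=1.0,
    )
    nodes = [f"X{i}" for i in range(10)]
    g, truth = syn.generate_ppi(cfg, nodes)
    hubs = truth.planted_hub_ids
    assert all(g.degree(h) == 9 for h in hubs)
    assert all(g.degree(v) == 2 for v in set(g) - hubs)
    assert g.number_of_edges() == 2 * 8 + 1


def test_ppi_is_simple_and_deterministic(dataset, easy_config):
    g = dataset.ppi
    assert not any(u == v for u, v in g.edges())
    assert g.number_of_nodes() == easy_config.ppi_n_nodes
    g2, t2 = syn.generate_ppi(easy_config, sorted(dataset.truth.true_overlap_genes))
    assert set(g2.edges()) == set(g.edges())
    assert t2.planted_hub_ids == dataset.truth.planted_hub_ids


def test_ppi_hubs_have_higher_mean_degree():
    gaps = []
    for seed in range(20):
        cfg = SimulationConfig(seed=seed, ppi_n_nodes=40, ppi_n_planted_hubs=6)
        nodes = [f"X{i}" for i in range(40)]
        g, truth = syn.generate_ppi(cfg, nodes)
        hub_deg = np.mean([g.degree(v) for v in truth.planted_hub_ids])
        rest_deg = np.mean([g.degree(v) for v in set(g) - truth.planted_hub_ids])
        gaps.append(hub_deg - rest_deg)
    assert all(gap > 0 for gap in gaps)


def test_ppi_rejects_too_few_nodes():
    cfg = SimulationConfig(seed=1, ppi_n_nodes=80)
    with pytest.raises(ConfigurationError):
        syn.generate_ppi(cfg, ["A", "B", "C"])


def test_annotation_members_within_universe(dataset, easy_config):
    universe = set(syn.gene_universe(easy_config))
    for term in dataset.annotation:
        assert term.members <= universe
    assert len(dataset.annotation) == easy_config.n_terms
    assert dataset.truth.planted_term_id in {t.term_id for t in dataset.annotation}


def test_annotation_planted_term_ranks_first():
    hits = 0
    for seed in range(20):
        cfg = SimulationConfig(seed=seed, n_target_universe=1000, n_terms=40,
                               term_size_range=(20, 60), planted_term_enrichment=5.0)
        universe = syn.gene_universe(cfg)
        rng = np.random.default_rng(seed + 1000)
        query = set(rng.choice(universe, size=50, replace=False).tolist())
        collection, truth = syn.generate_annotation(cfg, universe, query)
        rows = ora(query, collection, universe=universe)
        hits += rows[0].term_id == truth.planted_term_id
    assert hits >= 18


def test_annotation_rejects_query_outside_universe():
    cfg = SimulationConfig(seed=1)
    with pytest.raises(ConfigurationError):
        syn.generate_annotation(cfg, syn.gene_universe(cfg), {"NOT_A_GENE"})


def test_ct_table_structure(dataset, easy_config):
    ct = dataset.ct_table
    assert set(ct.group) == {"control", "treated"}
    assert set(ct.gene) == {syn.TARGET_GENE, syn.REFERENCE_GENE}
    per_sample = ct.groupby("sample_id").gene.nunique()
    assert (per_sample == 2).all()
    assert len(ct) == 2 * 2 * easy_config.n_ct_replicates


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(ppi_n_planted_hubs=80, ppi_n_nodes=80)
    with pytest.raises(ConfigurationError):
        SimulationConfig(ppi_hub_attach_prob=0.05, ppi_background_edge_prob=0.06)
    with pytest.raises(ConfigurationError):
        SimulationConfig(ob_pass_fraction=1.5)
    with pytest.raises(ConfigurationError):
        SimulationConfig(ct_true_fold=0.0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_compounds=0)
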