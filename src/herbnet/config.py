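"""Simulation configuration for the synthetic network-pharmacology inputs.

The generator stands in for the interactive database queries a real
analysis would make (ADME tables, target-prediction services, disease gene
collections, a protein-interaction network, annotation gene sets, qPCR
plates).  Every planted feature -- which compounds pass the ADME screen,
which genes overlap the disease list, which nodes are hubs, which term is
enriched, what the true expression fold change is -- is recorded so the
downstream stages have an exact ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters controlling every synthetic input.

    Defaults are the package's documented "easy" setting: strong planted
    structure at desk scale, chosen so that each downstream stage can
    recover the planted truth (exactly for deterministic stages, with high
    recall/precision for the stochastic hub screen).

    Attributes
    ----------
    seed
        Master seed.  Each generator derives its own independent stream
        from ``(seed, stage)`` so stages can be regenerated independently.
    n_compounds, ob_pass_fraction
        Size of the candidate-compound table and the exact fraction that is
        constructed to pass the oral-bioavailability / drug-likeness screen
        (OB >= 30 %, DL >= 0.18).
    n_target_universe
        Number of genes in the prediction universe (symbols ``G0001``...).
    targets_per_compound
        Inclusive ``(low, high)`` range for per-compound target-set sizes.
    n_disease_genes, disease_overlap_fraction
        Disease gene-list size and the fraction of the compound-target
        union that is planted into it.
    ppi_n_nodes, ppi_n_planted_hubs
        Interaction-network size and number of planted high-centrality
        hubs.  Two rounds of above-median screening retain roughly a
        quarter of the nodes, so hubs are planted at just under a fifth of
        the network to leave them the clear majority of the survivors.
    ppi_background_edge_prob, ppi_hub_attach_prob
        Bernoulli edge probabilities for background pairs and for any pair
        involving a hub (hub-hub pairs also use the attach probability).
    n_terms, term_size_range, planted_term_enrichment
        Annotation collection size, term-size range, and the multiplier
        applied to the hypergeometric expected overlap for the single
        planted term.  A multiplier of 1 plants nothing (null collection).
    ct_true_fold, ct_noise_sd, n_ct_replicates
        True expression fold change simulated into the treated group's
        target-gene Ct values, Gaussian noise (cycles) added to every Ct,
        and replicates per group.
    """

    seed: int = 0
    n_compounds: int = 20
    ob_pass_fraction: float = 0.25
    n_target_universe: int = 400
    targets_per_compound: tuple[int, int] = (40, 80)
    n_disease_genes: int = 300
    disease_overlap_fraction: float = 0.5
    ppi_n_nodes: int = 80
    ppi_n_planted_hubs: int = 15
    ppi_background_edge_prob: float = 0.06
    ppi_hub_attach_prob: float = 0.70
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    planted_term_enrichment: float = 5.0
    ct_true_fold: float = 2.0
    ct_noise_sd: float = 0.2
    n_ct_replicates: int = 4

    def __post_init__(self) -> None:
        counts = {
            "n_compounds": self.n_compounds,
            "n_target_universe": self.n_target_universe,
            "n_disease_genes": self.n_disease_genes,
            "ppi_n_nodes": self.ppi_n_nodes,
            "ppi_n_planted_hubs": self.ppi_n_planted_hubs,
            "n_terms": self.n_terms,
            "n_ct_replicates": self.n_ct_replicates,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        for name, value in (
            ("ob_pass_fraction", self.ob_pass_fraction),
            ("disease_overlap_fraction", self.disease_overlap_fraction),
            ("ppi_background_edge_prob", self.ppi_background_edge_prob),
            ("ppi_hub_attach_prob", self.ppi_hub_attach_prob),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        if self.ppi_n_planted_hubs >= self.ppi_n_nodes:
            raise ConfigurationError(
                "ppi_n_planted_hubs must be smaller than ppi_n_nodes "
                f"({self.ppi_n_planted_hubs} >= {self.ppi_n_nodes})"
            )
        if self.ppi_hub_attach_prob <= self.ppi_background_edge_prob:
            raise ConfigurationError(
                "ppi_hub_attach_prob must exceed ppi_background_edge_prob "
                f"({self.ppi_hub_attach_prob} <= {self.ppi_background_edge_prob})"
            )
        for name, rng in (
            ("targets_per_compound", self.targets_per_compound),
            ("term_size_range", self.term_size_range),
        ):
            lo, hi = rng
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"{name} must be a positive (low, high) range, got {rng!r}")
        if self.term_size_range[1] > self.n_target_universe:
            raise ConfigurationError(
                "term_size_range exceeds the gene universe "
                f"({self.term_size_range[1]} > {self.n_target_universe})"
            )
        if self.targets_per_compound[1] > self.n_target_universe:
            raise ConfigurationError(
                "targets_per_compound exceeds the gene universe "
                f"({self.targets_per_compound[1]} > {self.n_target_universe})"
            )
        if self.planted_term_enrichment < 1.0:
            raise ConfigurationError(
                f"planted_term_enrichment must be >= 1, got {self.planted_term_enrichment!r}"
            )
        if self.ct_true_fold <= 0:
            raise ConfigurationError(f"ct_true_fold must be positive, got {self.ct_true_fold!r}")
        if self.ct_noise_sd < 0:
            raise ConfigurationError(f"ct_noise_sd must be non-negative, got {self.ct_noise_sd!r}")


@dataclass
class GroundTruth:
    """Planted structure recorded by the generators.

    Every identifier here also appears in the corresponding generated
    table, so round-trip tests can compare recovered sets against it
    directly.
    """

    passing_compound_ids: set[str] = field(default_factory=set)
    planted_hub_ids: set[str] = field(default_factory=set)
    planted_term_id: str | None = None
    true_overlap_genes: set[str] = field(default_factory=set)
    true_fold: float | None = None

    def to_dict(self) -> dict:
        return {
            "passing_compound_ids": sorted(self.passing_compound_ids),
            "planted_hub_ids": sorted(self.planted_hub_ids),
            "planted_term_id": self.planted_term_id,
            "true_overlap_genes": sorted(self.true_overlap_genes),
            "true_fold": self.true_fold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            passing_compound_ids=set(d.get("passing_compound_ids", [])),
            planted_hub_ids=set(d.get("planted_hub_ids", [])),
            planted_term_id=d.get("planted_term_id"),
            true_overlap_genes=set(d.get("true_overlap_genes", [])),
            true_fold=d.get("true_fold"),
        )
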