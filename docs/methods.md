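# Methods

## The funnel

`herbnet` implements the standard network-pharmacology funnel for a
multi-compound herbal preparation against a disease, as a tested,
re-runnable pipeline rather than a sequence of manual web-database
queries:

1. **ADME screen.** Candidate compounds are kept when predicted oral
   bioavailability (OB, percent) and drug-likeness (DL, unitless) reach
   the conventional cutoffs OB ≥ 30 %, DL ≥ 0.18. Comparison is
   inclusive (≥) by default with a strict (>) mode, because published
   analyses state the rule both ways and the boundary matters for
   reproducibility.
2. **Target mapping.** Per-compound target predictions from several
   sources are normalized to uppercase gene symbols (with optional
   synonym resolution; alias chains are collapsed to their terminal
   symbol so normalization is idempotent, and cyclic alias tables are
   rejected), deduplicated, unioned, and intersected with a disease gene
   list to give the candidate target set.
3. **PPI topology.** On the protein-interaction network of the overlap
   genes, three node centralities are computed — degree, betweenness and
   closeness — and nodes at or above the median of *all three* are kept.
   The induced subgraph is re-analysed and screened a second time (the
   thresholds of round 2 differ from round 1 precisely because the
   centralities are recomputed on the induced subgraph). Survivors of the
   final round are the hub ("key") targets.
4. **Enrichment.** Hubs are tested for overrepresentation in an
   annotation collection (GO BP/CC/MF plus pathway sets) with the
   one-sided hypergeometric test; Benjamini–Hochberg adjustment is
   applied within each category (a flag switches to global adjustment);
   reporting keeps the top 20 terms at FDR < 0.05 (both configurable).
5. **Networks.** The compound–target bipartite network (optionally
   restricted to hubs) and its compound–target–pathway extension (top-10
   enriched pathways) are exported as SIF, GraphML or edge TSV, with a
   node-attribute sidecar for the formats that cannot carry attributes.
6. **Validation arithmetic.** Livak 2^−ΔΔCt relative expression from a
   long Ct table, and classification of docking scores as strong binders
   strictly below −7 kcal/mol.

## Centrality conventions

Published analyses of this kind use Cytoscape's NetworkAnalyzer, so the
package follows its conventions exactly:

* **Betweenness** is normalized by (n−1)(n−2)/2 for the *current*
  (sub)graph's n, giving values in [0, 1]; shortest-path multiplicity is
  weighted fractionally and path endpoints are excluded.
* **Closeness** is the reciprocal of the mean shortest-path distance to
  the nodes of the same connected component; isolated nodes score 0.
* **Medians** over an even node count are the mean of the two central
  order statistics.

Degree/betweenness/closeness are computed with networkx; the test suite
checks them against an independent exhaustive BFS all-pairs enumeration
oracle (σ_sv·σ_vt/σ_st summed over all pairs) to 1e−9 on 200 random
graphs, so the library choice is verified rather than trusted.

## The synthetic-data model

The generators replace the external databases with inputs whose relevant
structure is *planted* and recorded in a `GroundTruth` object:

* **Compounds** — exactly `round(n_compounds · ob_pass_fraction)` records
  pass both ADME cutoffs; values are sampled clear of the boundaries so
  display rounding can never flip a record.
* **Associations** — per-compound target sets drawn from a symbol
  universe, with ~30 % of hits duplicated under a second source label to
  exercise deduplication.
* **Disease list** — contains exactly
  `round(disease_overlap_fraction · |union|)` genes of the compound-target
  union; remaining entries come from outside the union, so the planted
  intersection is exact by construction.
* **PPI** — a planted-hub random graph: any pair involving a hub is an
  edge with `ppi_hub_attach_prob` (hub–hub pairs included, one consistent
  rule), background pairs with `ppi_background_edge_prob`.
* **Annotation** — random gene sets; one randomly placed pathway-category
  term has its query overlap inflated to `planted_term_enrichment` times
  the hypergeometric expectation Kn/N. A multiplier of 1 plants nothing
  and yields the null collection used for FDR calibration.
* **Ct table** — treated-group target Ct shifted by −log2(true fold)
  around a 26-cycle baseline with a 20-cycle reference gene, plus
  Gaussian noise in cycles.

Each generator draws from its own stream seeded by `(seed, stage)`, so
the pipeline can re-plant a stage against a *computed* upstream result —
in `run_pipeline` the annotation collection is planted against the hub
set the screen actually produced — while remaining bit-reproducible.

### Default ("easy") setting and why

20 compounds with a quarter passing; a 400-gene universe; 40–80 targets
per compound; a 300-gene disease list overlapping half the union
(≈ 110 genes); an 80-node PPI with 15 hubs, attach probability 0.7 over
a 0.06 background; 50 annotation terms of 10–40 genes with a 5× planted
term; fold 2 with 0.2-cycle noise and 4 replicates per group. These
sizes keep a full funnel run around a second while leaving every stage's
recovery nondegenerate.

The hub count is an analytic choice, not a tuned one: one round of
"at-or-above the median on all three metrics" keeps about half the
nodes, two rounds about a quarter, and since well-separated hubs always
survive, expected precision is ≈ 4h/n for h planted hubs among n nodes.
Planting h/n ≈ 0.19 (15 of 80) therefore targets precision ≈ 0.75 and
recall ≈ 1 — comfortably inside the documented recovery contract
(recall ≥ 0.8, precision ≥ 0.6).

### What passing tests do and do not show

The generators emulate the *combinatorics* of the funnel (set sizes,
overlaps, hub separation, enrichment signal), not real biology: there is
no attempt to mimic empirical OB/DL or interaction-score distributions,
the PPI degree distribution is a two-level Bernoulli model rather than
the heavy-tailed networks curated databases produce, and annotation
terms are disjointly random rather than hierarchically nested (no GO DAG
propagation). Recovery results therefore certify the implementation's
correctness on known structure, not the biological validity of median
hub screening on real networks.

## Statistical details

* **ORA** uses P(X ≥ k) for X ~ Hypergeom(N, K, n) via scipy's
  log-space survival function; exactness is tested against direct
  integer-combinatorics summation to 1e−12. The universe defaults to the
  genes appearing in the collection and is overridable; terms are
  intersected with the universe before testing. Rows are ranked by
  (FDR, p, term id).
* **BH** is the standard step-up (statsmodels), tested against a literal
  transcription of the rule. Under a null collection the fraction of
  terms called at FDR < 0.05 stays within 0.05 + 3·SE over 200 simulated
  collections (the discrete hypergeometric p-values make the procedure
  conservative, so the observed fraction is far below the bound).
* **ΔΔCt** uses the Livak convention: ΔCt per sample against the
  same-sample reference gene, ΔΔCt against the arithmetic mean of
  control-group ΔCt, fold = 2^−ΔΔCt. The control group's geometric mean
  fold is exactly 1 by construction; SEM uses the n−1 variance. The
  per-sample-vs-control-mean calibrator (rather than a single calibrator
  sample) is a documented choice.
* At the default setting the planted term is FDR-rank 1 against the hub
  query in every tested seed, but with only ~19 hub genes its absolute
  FDR fluctuates around the 0.05 cutoff, so the funnel report's
  "terms passing" count is legitimately 0 or 1; rank-based recovery is
  the stable contract.

## Numerical and degenerate-input choices

* Empty screening round: survivors = ∅ is returned as a flagged result
  (`converged=False`), not an exception; an edgeless graph keeps all
  nodes (all metrics 0 ≥ median 0) and converges immediately.
* Strict (>) median mode on a vertex-transitive graph eliminates every
  node in one round — the inclusive default exists precisely because of
  such tie structures.
* Graphs must be simple and undirected; self-loops are rejected.
* Exports sort nodes and edges, so identical networks always serialize
  byte-identically; determinism of the whole pipeline is asserted at the
  artifact-byte level.

## Known limitations

* No live database access, no docking execution or structure handling,
  no GO DAG-aware enrichment, no weighted/directed network support, no
  layout or rendering.
* The two-node discrepancy real studies show between the overlap gene
  count and the PPI node count (disconnected singletons dropped by the
  network export) is noted but not modeled; the synthetic PPI keeps
  isolated nodes.
* Problem sizes in tests and the acceptance script (80-node networks,
  20-seed sweeps, 200-collection calibrations) are the package's chosen
  desk-scale defaults; all statistics scale with the config if larger
  runs are wanted.
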