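"""Compound-target and compound-target-pathway network construction.

Networks are layered: compound and target layers for the bipartite C-T
network, plus a pathway layer once enrichment results are folded in.
Edges only connect adjacent layers (compound-target, target-pathway); the
constraint is enforced at construction and again at import.  Exports are
deterministic (sorted nodes and edges) in SIF, GraphML or a two-column
edge TSV, with a sidecar attribute table for the formats that cannot
carry node attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentRow
from .errors import ValidationError
from .targets import union_compound_targets

LAYERS = ("compound", "target", "pathway")
# stored lexicographically sorted, as add_edge/validate sort before lookup
_ALLOWED_LAYER_PAIRS = {("compound", "target"), ("pathway", "target")}
RELATION_LABELS = {("compound", "target"): "targets", ("target", "pathway"): "member_of"}
FORMATS = ("sif", "graphml", "tsv")


@dataclass
class LayeredNetwork:
    """Undirected graph whose nodes carry a ``layer`` attribute."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for v, data in self.graph.nodes(data=True):
            if data.get("layer") not in LAYERS:
                raise ValidationError(f"node {v!r} has invalid layer {data.get('layer')!r}")
        for u, v in self.graph.edges():
            pair = tuple(sorted((self.graph.nodes[u]["layer"], self.graph.nodes[v]["layer"])))
            if pair not in _ALLOWED_LAYER_PAIRS:
                raise ValidationError(
                    f"edge {u!r}-{v!r} connects non-adjacent layers {pair}"
                )

    def add_node(self, node_id: str, layer: str) -> None:
        if layer not in LAYERS:
            raise ValidationError(f"invalid layer {layer!r}")
        existing = self.graph.nodes.get(node_id)
        if existing is not None and existing.get("layer") != layer:
            raise ValidationError(
                f"node {node_id!r} already exists in layer {existing.get('layer')!r}"
            )
        self.graph.add_node(node_id, layer=layer)

    def add_edge(self, u: str, v: str) -> None:
        if u not in self.graph or v not in self.graph:
            raise ValidationError(f"edge endpoints must exist before linking: {u!r}, {v!r}")
        lu, lv = self.graph.nodes[u]["layer"], self.graph.nodes[v]["layer"]
        pair = tuple(sorted((lu, lv)))
        if pair not in _ALLOWED_LAYER_PAIRS:
            raise ValidationError(f"cannot link layer {lu!r} to layer {lv!r}")
        self.graph.add_edge(u, v)

    def nodes_in_layer(self, layer: str) -> set[str]:
        return {v for v, d in self.graph.nodes(data=True) if d["layer"] == layer}

    def relation(self, u: str, v: str) -> str:
        lu, lv = self.graph.nodes[u]["layer"], self.graph.nodes[v]["layer"]
        key = (lu, lv) if (lu, lv) in RELATION_LABELS else (lv, lu)
        return RELATION_LABELS[key]

    def copy(self) -> "LayeredNetwork":
        return LayeredNetwork(self.graph.copy())


def build_ct_network(
    associations: pd.DataFrame, restrict_to: set[str] | None = None
) -> LayeredNetwork:
    """Bipartite compound-target network from an association table.

    With ``restrict_to`` given, only targets inside that set appear (the
    usual key-target restriction); every compound node is kept even if it
    loses all its edges, so compound degrees equal their (restricted)
    target counts.
    """
    net = LayeredNetwork()
    per_compound, _, _ = union_compound_targets(associations)
    for cid in per_compound:
        net.add_node(cid, "compound")
    for cid, targets in per_compound.items():
        kept = targets if restrict_to is None else targets & set(restrict_to)
        for t in sorted(kept):
            net.add_node(t, "target")
            net.add_edge(cid, t)
    return net


def build_ctp_network(
    ct: LayeredNetwork, enrichment: Sequence[EnrichmentRow], top_n: int = 10
) -> LayeredNetwork:
    """Extend a C-T network with the top enriched pathways.

    The first ``top_n`` ranked rows become pathway nodes, linked to each
    member gene already present as a target node.  Compound-target edges
    are untouched.  Asking for more terms than exist uses all of them and
    warns.
    """
    net = ct.copy()
    rows = sorted(enrichment, key=lambda r: r.rank)
    if top_n > len(rows):
        warnings.warn(
            f"top_n={top_n} exceeds the {len(rows)} available terms; using all",
            stacklevel=2,
        )
        top_n = len(rows)
    targets = net.nodes_in_layer("target")
    for row in rows[:top_n]:
        net.add_node(row.term_id, "pathway")
        for gene in sorted(row.members & targets):
            net.add_edge(gene, row.term_id)
    return net


def _as_layered(net: LayeredNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, LayeredNetwork) else net


def node_attribute_table(net: LayeredNetwork) -> pd.DataFrame:
    g = net.graph
    nodes = sorted(g.nodes())
    return pd.DataFrame(
        {
            "id": nodes,
            "layer": [g.nodes[v]["layer"] for v in nodes],
            "degree": [g.degree(v) for v in nodes],
        }
    )


def export_graph(net: LayeredNetwork | nx.Graph, format: str, path: str | Path) -> Path:
    """Write the network in SIF, GraphML or two-column edge TSV.

    SIF and TSV carry no node attributes, so a ``<stem>.nodes.tsv``
    sidecar (id, layer, degree) is written next to them for layered
    networks.  Output is sorted and deterministic.
    """
    fmt = format.lower()
    if fmt not in FORMATS:
        raise ValidationError(f"unknown export format {format!r}; choose from {FORMATS}")
    path = Path(path)
    g = _as_layered(net)
    edges = sorted(tuple(sorted(e)) for e in g.edges())

    if fmt == "sif":
        lines = []
        for u, v in edges:
            rel = net.relation(u, v) if isinstance(net, LayeredNetwork) else "pp"
            lines.append(f"{u}\t{rel}\t{v}")
        for v in sorted(set(g.nodes()) - {x for e in edges for x in e}):
            lines.append(v)  # isolated nodes: bare-name SIF line
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "tsv":
        with path.open("w") as fh:
            fh.write("source\ttarget\n")
            for u, v in edges:
                fh.write(f"{u}\t{v}\n")
    else:  # graphml
        h = nx.Graph()
        h.add_nodes_from(sorted(g.nodes(data=True)))
        h.add_edges_from(edges)
        nx.write_graphml(h, path)

    if isinstance(net, LayeredNetwork) and fmt in ("sif", "tsv"):
        sidecar = path.with_suffix(path.suffix + ".nodes.tsv")
        node_attribute_table(net).to_csv(sidecar, sep="\t", index=False)
    return path


def import_graph(path: str | Path, format: str) -> LayeredNetwork:
    """Read a network written by :func:`export_graph`, re-validating layers."""
    fmt = format.lower()
    if fmt not in FORMATS:
        raise ValidationError(f"unknown import format {format!r}; choose from {FORMATS}")
    path = Path(path)
    g = nx.Graph()

    if fmt == "graphml":
        read = nx.read_graphml(path)
        g.add_nodes_from(read.nodes(data=True))
        g.add_edges_from(read.edges())
        return LayeredNetwork(g)

    sidecar = path.with_suffix(path.suffix + ".nodes.tsv")
    if not sidecar.exists():
        raise ValidationError(f"missing node-attribute sidecar {sidecar}")
    attrs = pd.read_csv(sidecar, sep="\t", dtype={"id": str})
    for _, row in attrs.iterrows():
        g.add_node(row["id"], layer=row["layer"])

    if fmt == "sif":
        for line in path.read_text().splitlines():
            parts = line.split("\t")
            if len(parts) == 3:
                g.add_edge(parts[0], parts[2])
    else:
        edges = pd.read_csv(path, sep="\t", dtype=str)
        for _, row in edges.iterrows():
            g.add_edge(row["source"], row["target"])
    return LayeredNetwork(g)
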