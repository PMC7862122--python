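"""PPI topology: centralities and iterative median-threshold hub screening.

The screening procedure mirrors the Cytoscape-style workflow common in
network pharmacology: compute degree, betweenness and closeness for every
node, take the median of each, keep the nodes at or above all three
medians, induce the subgraph on the survivors, and repeat.  Two rounds are
the convention; the thresholds of the second round differ from the first
because the centralities are recomputed on the induced subgraph.

Conventions (chosen to match Cytoscape's NetworkAnalyzer, whose normalized
values the published thresholds of this style of analysis fall in):

* betweenness is normalized by ``(n - 1)(n - 2) / 2`` for the current
  (sub)graph's ``n``, so values lie in [0, 1];
* closeness is the reciprocal of the mean shortest-path distance to the
  nodes of the same connected component; isolated nodes score 0;
* an even node count takes the median as the mean of the two central
  order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError, ValidationError


def validate_graph(g: nx.Graph) -> None:
    if g.is_directed() or g.is_multigraph():
        raise ValidationError("graph must be simple and undirected")
    loops = list(nx.nodes_with_selfloops(g))
    if loops:
        raise ValidationError(f"graph has self-loops at {sorted(loops)[:5]}")


def compute_degree(g: nx.Graph) -> dict[str, int]:
    validate_graph(g)
    return dict(g.degree())


def compute_betweenness(g: nx.Graph, normalized: bool = True) -> dict[str, float]:
    """Shortest-path betweenness; endpoints excluded, multiplicity fractional."""
    validate_graph(g)
    return nx.betweenness_centrality(g, normalized=normalized)


def compute_closeness(g: nx.Graph) -> dict[str, float]:
    """Component-wise closeness: 1 / mean distance to reachable peers."""
    validate_graph(g)
    # wf_improved=False gives (reachable)/(sum of distances) with no
    # cross-component rescaling, i.e. the reciprocal mean distance within
    # the node's component; isolated nodes come out as 0.
    return nx.closeness_centrality(g, wf_improved=False)


def centrality_table(g: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness for every node, sorted by node id."""
    validate_graph(g)
    deg = compute_degree(g)
    bet = compute_betweenness(g)
    clo = compute_closeness(g)
    nodes = sorted(g.nodes())
    return pd.DataFrame(
        {
            "node": nodes,
            "degree": [deg[v] for v in nodes],
            "betweenness": [bet[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
        }
    )


def median_thresholds(ct: pd.DataFrame) -> tuple[float, float, float]:
    """Medians of the three centralities over the current node set."""
    if ct is None or len(ct) == 0:
        raise InputError("empty centrality table has no medians")
    return (
        float(np.median(ct["degree"])),
        float(np.median(ct["betweenness"])),
        float(np.median(ct["closeness"])),
    )


@dataclass
class ScreeningRound:
    round_index: int
    thresholds: tuple[float, float, float]
    n_nodes_in: int
    survivors: set[str]
    induced_edge_count: int

    def to_dict(self) -> dict:
        return {
            "round_index": self.round_index,
            "degree_median": self.thresholds[0],
            "betweenness_median": self.thresholds[1],
            "closeness_median": self.thresholds[2],
            "n_nodes_in": self.n_nodes_in,
            "n_survivors": len(self.survivors),
            "induced_edge_count": self.induced_edge_count,
        }


@dataclass
class ScreeningResult:
    rounds: list[ScreeningRound] = field(default_factory=list)
    final_hubs: set[str] = field(default_factory=set)
    converged: bool = False

    def to_dict(self) -> dict:
        return {
            "rounds": [r.to_dict() for r in self.rounds],
            "final_hubs": sorted(self.final_hubs),
            "converged": self.converged,
        }


def screen_round(
    g: nx.Graph, inclusive: bool = True, round_index: int = 1
) -> tuple[ScreeningRound, nx.Graph]:
    """One round of above-median screening on all three centralities.

    Survivors meet the degree, betweenness and closeness medians jointly
    (``>=`` by default, ``>`` in strict mode).  Returns the round record
    and the induced subgraph on the survivors.  If every node is
    eliminated the round is returned with an empty survivor set rather
    than raising.
    """
    validate_graph(g)
    if g.number_of_nodes() < 2:
        raise InputError("screening needs a graph with at least 2 nodes")
    ct = centrality_table(g)
    m_d, m_b, m_c = median_thresholds(ct)
    if inclusive:
        mask = (ct["degree"] >= m_d) & (ct["betweenness"] >= m_b) & (ct["closeness"] >= m_c)
    else:
        mask = (ct["degree"] > m_d) & (ct["betweenness"] > m_b) & (ct["closeness"] > m_c)
    survivors = set(ct.loc[mask, "node"])
    induced = g.subgraph(survivors).copy()
    rnd = ScreeningRound(
        round_index=round_index,
        thresholds=(m_d, m_b, m_c),
        n_nodes_in=g.number_of_nodes(),
        survivors=survivors,
        induced_edge_count=induced.number_of_edges(),
    )
    return rnd, induced


def iterative_screen(
    g: nx.Graph,
    rounds: int = 2,
    inclusive: bool = True,
    until_stable: bool = False,
) -> ScreeningResult:
    """Repeated median screening with centralities recomputed each round.

    Runs ``rounds`` rounds (or fewer with ``until_stable`` once a round
    keeps every remaining node).  Node and edge counts are non-increasing
    across rounds by construction.  An emptied graph stops the procedure
    with ``converged=False``.
    """
    if rounds < 1:
        raise ValidationError(f"rounds must be >= 1, got {rounds}")
    result = ScreeningResult()
    current = g
    for i in range(1, rounds + 1):
        if current.number_of_nodes() < 2:
            break
        rnd, induced = screen_round(current, inclusive=inclusive, round_index=i)
        result.rounds.append(rnd)
        stable = len(rnd.survivors) == rnd.n_nodes_in
        if not rnd.survivors:
            result.final_hubs = set()
            result.converged = False
            return result
        current = induced
        if stable:
            result.converged = True
            if until_stable:
                break
    result.final_hubs = set(current.nodes())
    if result.rounds and len(result.rounds[-1].survivors) == result.rounds[-1].n_nodes_in:
        result.converged = True
    return result
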