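"""Topological centrality of the predator-prey graph.

The binary trophic graph has one node per living group (detritus is
excluded) and a link wherever one group consumes another.  The degree
index uses the directed link counts (prey links plus predator links,
self-loops counted once); closeness and betweenness use unweighted
shortest paths on the undirected graph, with unreachable pairs excluded
from the closeness sum.

Raw scores are reported alongside two common standardizations: degree
divided by the mean degree, closeness as (n-1)/sum(d) and max-rescaled,
betweenness divided by the number of node pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .ecopath_balance import BalancedModel
from .model_io import FoodWebModel


@dataclass
class TrophicGraph:
    graph: nx.Graph  # undirected, no self-loops
    prey_counts: pd.Series  # directed: number of prey of each node
    predator_counts: pd.Series  # directed: number of predators of each node
    cannibals: set[str]


@dataclass
class CentralityScores:
    raw: pd.Series
    normalized: pd.Series
    #: Secondary standardization: max-rescaled for closeness, otherwise
    #: identical to ``normalized``.
    rescaled: pd.Series

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"raw": self.raw, "normalized": self.normalized, "rescaled": self.rescaled}
        )


def build_graph(
    model: BalancedModel | FoodWebModel, link_threshold: float = 0.0
) -> TrophicGraph:
    """Binary predator-prey graph over living groups.

    A link i--j exists when the diet fraction of prey i in predator j
    exceeds ``link_threshold`` (default: any positive consumption).
    """
    m = model.model if isinstance(model, BalancedModel) else model
    living = m.living
    g = nx.Graph()
    g.add_nodes_from(living)
    prey_counts = pd.Series(0, index=living, dtype=int)
    predator_counts = pd.Series(0, index=living, dtype=int)
    cannibals: set[str] = set()
    for j in m.consumers:
        for i in living:
            if float(m.diet.loc[i, j]) > link_threshold:
                prey_counts[j] += 1
                predator_counts[i] += 1
                if i == j:
                    cannibals.add(i)
                else:
                    g.add_edge(i, j)
    return TrophicGraph(
        graph=g,
        prey_counts=prey_counts,
        predator_counts=predator_counts,
        cannibals=cannibals,
    )


def degree(tg: TrophicGraph) -> CentralityScores:
    """Directed degree: prey links + predator links, self-loops once."""
    raw = tg.prey_counts + tg.predator_counts
    for c in tg.cannibals:
        raw[c] -= 1  # a self-loop is one link, not two
    raw = raw.astype(float)
    mean = raw.mean()
    norm = raw / mean if mean > 0 else raw * 0.0
    return CentralityScores(raw=raw, normalized=norm, rescaled=norm)


def closeness(tg: TrophicGraph) -> CentralityScores:
    """Inverse total shortest-path distance to all reachable groups."""
    g = tg.graph
    nodes = list(g.nodes)
    n = len(nodes)
    raw = pd.Series(0.0, index=nodes)
    norm = pd.Series(0.0, index=nodes)
    for v in nodes:
        dist = nx.single_source_shortest_path_length(g, v)
        total = sum(d for u, d in dist.items() if u != v)
        if total > 0:
            raw[v] = 1.0 / total
            norm[v] = (n - 1) / total
    peak = raw.max()
    rescaled = raw / peak if peak > 0 else raw
    return CentralityScores(raw=raw, normalized=norm, rescaled=rescaled)


def betweenness(tg: TrophicGraph) -> CentralityScores:
    """Share of shortest paths between other pairs passing through a node."""
    g = tg.graph
    n = g.number_of_nodes()
    raw = pd.Series(nx.betweenness_centrality(g, normalized=False), dtype=float)
    pairs = (n - 1) * (n - 2) / 2.0
    norm = raw / pairs if pairs > 0 else raw * 0.0
    return CentralityScores(raw=raw, normalized=norm, rescaled=norm)


def centrality_table(
    model: BalancedModel | FoodWebModel, link_threshold: float = 0.0
) -> pd.DataFrame:
    """Degree, closeness and betweenness for every living group."""
    tg = build_graph(model, link_threshold=link_threshold)
    d, c, b = degree(tg), closeness(tg), betweenness(tg)
    return pd.DataFrame(
        {
            "degree_raw": d.raw,
            "degree": d.normalized,
            "closeness_raw": c.raw,
            "closeness": c.rescaled,
            "betweenness_raw": b.raw,
            "betweenness": b.normalized,
        }
    )
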