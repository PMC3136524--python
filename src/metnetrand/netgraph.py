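"""Graph representations of metabolic networks and their structural statistics.

Two views of a genotype:

* the directed *bipartite* graph (metabolite and reaction nodes; arcs
  metabolite->reaction for reactants, reaction->metabolite for products,
  both orientations for reversible reactions), used for degree counts;
* the directed *metabolite graph*: currency metabolites are removed
  globally, then every non-currency reactant points to every non-currency
  product of each reaction (reverse arcs added for reversible reactions).

The statistics battery on the metabolite graph: global clustering C
(transitivity of the undirected simplification), average directed
shortest-path length L over reachable ordered pairs, path probability
P_C, and the bow-tie decomposition around the largest strong component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from metnetrand.universe_io import CurrencyList, ReactionUniverse
from metnetrand import powerfit

logger = logging.getLogger(__name__)


@dataclass
class GraphStats:
    """Per-genotype structural summary of the metabolite graph."""

    C: float = 0.0
    L: float = float("nan")
    P_C: float = 0.0
    f_LSC: float = 0.0
    f_bowtie: float = 0.0
    gamma: float = float("nan")
    n_nodes: int = 0
    n_arcs: int = 0

    def as_dict(self) -> dict:
        return {
            "C": self.C, "L": self.L, "P_C": self.P_C, "f_LSC": self.f_LSC,
            "f_bowtie": self.f_bowtie, "gamma": self.gamma,
            "n_nodes": self.n_nodes, "n_arcs": self.n_arcs,
        }


def _genotype_reactions(genotype, universe: ReactionUniverse):
    universe.validate_genotype(genotype)
    return [universe.reactions[rid] for rid in sorted(genotype)]


def build_bipartite(genotype, universe: ReactionUniverse) -> nx.DiGraph:
    """Directed bipartite metabolite/reaction graph of a genotype."""
    g = nx.DiGraph()
    for r in _genotype_reactions(genotype, universe):
        g.add_node(r.id, kind="reaction")
        for m in r.stoich:
            g.add_node(m, kind="metabolite")
        for m in r.reactants:
            g.add_edge(m, r.id)
            if r.reversible:
                g.add_edge(r.id, m)
        for m in r.products:
            g.add_edge(r.id, m)
            if r.reversible:
                g.add_edge(m, r.id)
    return g


def build_metabolite_graph(genotype, universe: ReactionUniverse, currency: CurrencyList) -> nx.DiGraph:
    """Currency-filtered directed metabolite-metabolite graph.

    Nodes are all non-currency metabolites of the genotype's reactions
    (isolated ones kept); self-loops discarded; parallel arcs collapse.
    """
    cur = set(currency)
    g = nx.DiGraph()
    for r in _genotype_reactions(genotype, universe):
        reac = [m for m in r.reactants if m not in cur]
        prod = [m for m in r.products if m not in cur]
        g.add_nodes_from(reac)
        g.add_nodes_from(prod)
        for a in reac:
            for b in prod:
                if a == b:
                    continue
                g.add_edge(a, b)
                if r.reversible:
                    g.add_edge(b, a)
    return g


def metabolite_degrees(genotype, universe: ReactionUniverse) -> dict:
    """k_i = number of distinct reactions metabolite i participates in (currency included)."""
    deg: dict = {}
    for r in _genotype_reactions(genotype, universe):
        for m in r.stoich:
            deg[m] = deg.get(m, 0) + 1
    return deg


def universe_metabolite_degrees(universe: ReactionUniverse, metabolic_only: bool = True) -> dict:
    """Degrees over a whole universe (the database-level degree distribution)."""
    deg: dict = {}
    for r in universe.reactions.values():
        if metabolic_only and r.category != "metabolic":
            continue
        for m in r.stoich:
            deg[m] = deg.get(m, 0) + 1
    return deg


def reaction_degree_table(universe: ReactionUniverse, currency: CurrencyList, metabolic_only: bool = True) -> pd.DataFrame:
    """Reaction-degree distribution stratified by currency-substrate count.

    One row per (degree, n_currency) with the number of reactions whose
    distinct-metabolite count is ``degree``, of which ``n_currency`` are
    in the currency list.
    """
    cur = set(currency)
    counts: dict = {}
    for r in universe.reactions.values():
        if metabolic_only and r.category != "metabolic":
            continue
        mets = r.metabolite_ids
        key = (len(mets), sum(1 for m in mets if m in cur))
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"degree": d, "n_currency": c, "count": n}
        for (d, c), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["degree", "n_currency", "count"])


def global_clustering(graph: nx.Graph, with_factor3: bool = True) -> float:
    """Global clustering of the undirected simplification.

    Default is the transitivity convention C = 3 N_triangles / N_triples;
    ``with_factor3=False`` divides the raw triangle count by the triple
    count instead (both are exposed because the normalization convention
    differs between texts).
    """
    u = graph.to_undirected() if graph.is_directed() else graph
    u = nx.Graph(u)  # drop parallel/self structure if any
    if u.number_of_nodes() < 3:
        return 0.0
    t = nx.transitivity(u)
    return t if with_factor3 else t / 3.0


def path_stats(graph: nx.DiGraph) -> tuple:
    """(L, P_C) over ordered pairs of distinct nodes.

    P_C is the fraction of ordered pairs joined by a directed path; L is
    the mean shortest directed path length over those pairs (NaN when no
    pair is reachable).
    """
    n = graph.number_of_nodes()
    if n < 2:
        return float("nan"), 0.0
    reachable = 0
    total_len = 0
    for source, lengths in nx.all_pairs_shortest_path_length(graph):
        reachable += len(lengths) - 1  # drop the source itself
        total_len += sum(lengths.values())  # source contributes 0
    if reachable == 0:
        return float("nan"), 0.0
    return total_len / reachable, reachable / (n * (n - 1))


def bow_tie(graph: nx.DiGraph) -> tuple:
    """(LSC, IN, OUT) node sets of the bow-tie decomposition.

    LSC is the largest strongly connected component (ties broken toward
    the lexicographically smallest sorted member list, logged); IN reaches
    the LSC, OUT is reached from it.
    """
    if graph.number_of_nodes() == 0:
        return set(), set(), set()
    sccs = list(nx.strongly_connected_components(graph))
    best = max(len(s) for s in sccs)
    candidates = sorted((sorted(s) for s in sccs if len(s) == best))
    if len(candidates) > 1:
        logger.info("LSC tie among %d components of size %d; smallest member set chosen", len(candidates), best)
    lsc = set(candidates[0])
    anchor = next(iter(lsc))
    reach_from = set(nx.descendants(graph, anchor)) | lsc
    reach_to = set(nx.ancestors(graph, anchor)) | lsc
    return lsc, reach_to - lsc, reach_from - lsc


def genotype_stats(genotype, universe: ReactionUniverse, currency: CurrencyList) -> GraphStats:
    """Full structural summary of one genotype's metabolite graph."""
    if not genotype:
        return GraphStats()
    g = build_metabolite_graph(genotype, universe, currency)
    n = g.number_of_nodes()
    stats = GraphStats(n_nodes=n, n_arcs=g.number_of_edges())
    if n == 0:
        return stats
    stats.C = global_clustering(g)
    stats.L, stats.P_C = path_stats(g)
    lsc, in_set, out_set = bow_tie(g)
    stats.f_LSC = len(lsc) / n
    stats.f_bowtie = len(lsc | in_set | out_set) / n
    degs = list(metabolite_degrees(genotype, universe).values())
    try:
        stats.gamma = powerfit.fit_discrete_power_law(degs).gamma
    except powerfit.PowerFitError:
        stats.gamma = float("nan")
    return stats


def stats_frame(samples, universe: ReactionUniverse, currency: CurrencyList) -> pd.DataFrame:
    """One GraphStats row per genotype (column order fixed for the TSV output)."""
    rows = []
    for i, g in enumerate(samples):
        rec = {"genotype": i}
        rec.update(genotype_stats(g, universe, currency).as_dict())
        rows.append(rec)
    return pd.DataFrame(rows)
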