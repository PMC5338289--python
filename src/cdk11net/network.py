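"""Seed-gene subnetwork construction, merging, filtering and centrality.

A transparent replacement for proprietary gene-network reconstruction:
candidate subnetworks are the connected components of the subgraph
induced by the seed genes plus "linker" nodes (non-seeds adjacent to at
least two seeds), each scored for seed enrichment by a hypergeometric
tail. Subnetworks containing a chosen anchor gene are merged, filtered
to nodes annotated to allowed tissue/disease tags (seeds and the anchor
are always kept), trimmed of isolated hangers-on, and ranked by a
composite of degree and betweenness centrality to nominate the central
node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats

from .errors import AnalysisError, InputError

logger = logging.getLogger(__name__)


@dataclass
class ScoredSubnetwork:
    """A node subset of the parent graph with its seed-enrichment score."""

    graph: nx.Graph  # induced subgraph (carries node tags)
    seeds: set[str]  # seeds inside this subnetwork
    enrichment_p: float
    contains_anchor: bool = False

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def seed_count(self) -> int:
        return len(self.seeds)

    def __len__(self) -> int:
        return len(self.graph)


def seed_enrichment_p(
    population: int, n_seeds: int, subnet_size: int, seeds_inside: int
) -> float:
    """P(X >= seeds_inside) drawing ``subnet_size`` nodes from a
    population containing ``n_seeds`` seeds, without replacement."""
    if not 0 <= seeds_inside <= min(n_seeds, subnet_size):
        raise InputError("seeds_inside exceeds draw or seed count")
    return float(stats.hypergeom.sf(seeds_inside - 1, population, n_seeds, subnet_size))


def build_seed_subnetworks(
    g: nx.Graph,
    seeds: set[str],
    min_seed_neighbors: int = 2,
    max_linker_degree: int | None = None,
) -> list[ScoredSubnetwork]:
    """Candidate subnetworks around the seed genes.

    A linker is a non-seed node adjacent to at least
    ``min_seed_neighbors`` seeds (optionally capped at
    ``max_linker_degree`` total degree to exclude promiscuous nodes).
    Candidates are the connected components of the subgraph induced by
    seeds plus linkers, sorted by hypergeometric seed-enrichment
    p-value, most enriched first.
    """
    present = set(seeds) & set(g.nodes)
    if not present:
        raise AnalysisError("no seed gene is present in the interaction graph")
    linkers = set()
    for node in g.nodes:
        if node in present:
            continue
        if max_linker_degree is not None and g.degree(node) > max_linker_degree:
            continue
        if sum(1 for nb in g.neighbors(node) if nb in present) >= min_seed_neighbors:
            linkers.add(node)
    induced = g.subgraph(present | linkers)
    subnets = []
    for comp in nx.connected_components(induced):
        sub = g.subgraph(comp).copy()
        inside = comp & present
        p = seed_enrichment_p(len(g), len(present), len(comp), len(inside))
        subnets.append(ScoredSubnetwork(graph=sub, seeds=inside, enrichment_p=p))
    subnets.sort(key=lambda s: (s.enrichment_p, sorted(s.nodes)))
    return subnets


def select_containing(
    subnets: list[ScoredSubnetwork], anchor: str
) -> list[ScoredSubnetwork]:
    """Subnetworks whose node set contains the anchor gene, order kept."""
    selected = []
    for s in subnets:
        if anchor in s.nodes:
            s.contains_anchor = True
            selected.append(s)
    if not selected:
        logger.warning("anchor %r not found in any candidate subnetwork", anchor)
    return selected


def merge_subnetworks(
    subnets: list[ScoredSubnetwork],
    parent: nx.Graph,
    all_seeds: set[str] | None = None,
) -> ScoredSubnetwork:
    """Union of node sets, with edges re-induced from the parent graph
    and the enrichment p-value recomputed on the merged set.

    ``all_seeds`` is the full seed set used for scoring (successes in
    the hypergeometric population); it defaults to the union of the
    merged subnetworks' own seeds.
    """
    if not subnets:
        raise AnalysisError("cannot merge an empty list of subnetworks")
    nodes = set().union(*(s.nodes for s in subnets))
    seeds = set().union(*(s.seeds for s in subnets))
    n_seed_pop = len(set(all_seeds) & set(parent.nodes)) if all_seeds else len(seeds)
    sub = parent.subgraph(nodes).copy()
    p = seed_enrichment_p(len(parent), n_seed_pop, len(nodes), len(seeds))
    return ScoredSubnetwork(
        graph=sub,
        seeds=seeds,
        enrichment_p=p,
        contains_anchor=any(s.contains_anchor for s in subnets),
    )


def filter_by_annotation(
    subnet: ScoredSubnetwork,
    allowed_tags: set[str],
    anchor_whitelist: set[str] = frozenset(),
) -> ScoredSubnetwork:
    """Keep nodes tagged with an allowed tissue/disease tag, then trim.

    Seeds and whitelisted nodes (typically the anchor) always survive.
    After the tag filter, non-whitelisted nodes left with no remaining
    edge are dropped — the "trim irrelevant members" step.
    """
    protected = set(subnet.seeds) | set(anchor_whitelist)
    kept = set()
    for node in subnet.graph.nodes:
        tags = set(subnet.graph.nodes[node].get("tags", ()))
        if node in protected or tags & allowed_tags:
            kept.add(node)
    trimmed = subnet.graph.subgraph(kept).copy()
    isolated = {
        n for n in trimmed.nodes if trimmed.degree(n) == 0 and n not in protected
    }
    trimmed.remove_nodes_from(isolated)
    return ScoredSubnetwork(
        graph=trimmed,
        seeds=set(subnet.seeds) & set(trimmed.nodes),
        enrichment_p=subnet.enrichment_p,
        contains_anchor=subnet.contains_anchor,
    )


def rank_central_nodes(subnet: ScoredSubnetwork) -> pd.DataFrame:
    """Degree + betweenness composite ranking of the subnetwork's nodes.

    Each centrality is ranked descending with mid-ranks for ties; the
    composite score is the mean of the two rank positions and the final
    rank (1 = most central) breaks remaining ties lexicographically.
    Betweenness on a disconnected subnetwork is computed per component
    by the shortest-path definition, which only counts reachable pairs.
    """
    g = subnet.graph
    if len(g) < 2:
        raise InputError("centrality ranking needs at least 2 nodes")
    deg = pd.Series(nx.degree_centrality(g))
    btw = pd.Series(nx.betweenness_centrality(g, normalized=True))
    report = pd.DataFrame({"degree": deg, "betweenness": btw}).sort_index()
    rank_deg = report["degree"].rank(ascending=False, method="average")
    rank_btw = report["betweenness"].rank(ascending=False, method="average")
    report["composite_score"] = (rank_deg + rank_btw) / 2.0
    report = report.loc[
        sorted(report.index, key=lambda n: (report.at[n, "composite_score"], n))
    ]
    report["rank"] = range(1, len(report) + 1)
    report.index.name = "gene"
    return report


def nominate_central_node(report: pd.DataFrame) -> str:
    """The top-ranked gene of a centrality report."""
    return report.index[report["rank"].to_numpy().argmin()]
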