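"""Centrality summaries, cross-group comparisons and organ-system aggregation.

A group's network is summarised by node/edge counts and by average (and
average weighted) degree over all diagnosed nodes.  Two networks' densities
are compared with a two-proportion chi-squared test, treating each network's
edge count as successes out of the C(N, 2) possible connections; degree
distributions across groups are compared with one-way ANOVA, treating nodes
as observations.

For the macro view, diagnosis-level edges are aggregated to the 18
organ-system chapters: the weight between chapters A and B is the sum of
SCI over all diagnosis edges with one endpoint in each; within-chapter
edges accumulate into a chapter self-weight (reported, not drawn).  Chapter
pairs whose aggregate weight exceeds a highlight threshold (strictly more
than 10 by default) are the group's prominent organ-level comorbidities,
tabulated across groups as a presence/absence grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_chisquare

from .comorbidity import MultimorbidityNetwork
from .icd9 import SYMPTOM_CHAPTER, chapter_of

__all__ = [
    "NetworkSummary",
    "OrganNetwork",
    "aggregate_to_organs",
    "compare_group_degrees",
    "degree_centrality",
    "density_proportion_test",
    "presence_table",
    "summarize_network",
    "weighted_degree_centrality",
]

log = logging.getLogger(__name__)


def _graph_of(network) -> nx.Graph:
    return network.graph if isinstance(network, MultimorbidityNetwork) else network


def degree_centrality(network) -> dict[str, int]:
    """Number of direct connections of each diagnosis; sums to 2*E."""
    return dict(_graph_of(network).degree())


def weighted_degree_centrality(network, weight: str = "sci") -> dict[str, float]:
    """Sum of incident edge SCI weights of each diagnosis; sums to 2*sum(w)."""
    return {v: float(d) for v, d in _graph_of(network).degree(weight=weight)}


@dataclass
class NetworkSummary:
    """Node/edge counts and degree averages for one group network."""

    group_label: str
    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_weighted_degree: float


def summarize_network(network, group_label: str | None = None) -> NetworkSummary:
    """Average degree = 2E/N and average weighted degree = 2*sum(SCI)/N over
    the network's node list (all diagnosed codes, isolated ones included)."""
    g = _graph_of(network)
    label = group_label or getattr(network, "group_label", "")
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return NetworkSummary(label, 0, 0, 0.0, 0.0)
    total_w = sum(d.get("sci", 0.0) for _, _, d in g.edges(data=True))
    return NetworkSummary(label, n, e, 2.0 * e / n, 2.0 * total_w / n)


def _nodes_edges(network) -> tuple[int, int]:
    if isinstance(network, tuple):
        return int(network[0]), int(network[1])
    g = _graph_of(network)
    return g.number_of_nodes(), g.number_of_edges()


def density_proportion_test(net_a, net_b) -> tuple[float, float]:
    """Two-proportion chi-squared test of network density.

    Each network contributes successes = edge count out of trials =
    N*(N-1)/2 possible connections.  Accepts networks or plain
    ``(n_nodes, n_edges)`` tuples.  Returns ``(chi2, p)``.
    """
    (na, ea), (nb, eb) = _nodes_edges(net_a), _nodes_edges(net_b)
    if na < 2 or nb < 2:
        raise ValueError("both networks need >= 2 nodes")
    trials = np.array([na * (na - 1) // 2, nb * (nb - 1) // 2])
    successes = np.array([ea, eb])
    chi2, p, _ = proportions_chisquare(successes, trials)
    return float(chi2), float(p)


def density_proportion_test_k(networks) -> tuple[float, float]:
    """k-sample extension: chi-squared homogeneity of edge densities."""
    ne = [_nodes_edges(n) for n in networks]
    successes = np.array([e for _, e in ne])
    trials = np.array([n * (n - 1) // 2 for n, _ in ne])
    chi2, p, _ = proportions_chisquare(successes, trials)
    return float(chi2), float(p)


def compare_group_degrees(networks, weighted: bool = False) -> tuple[float, float]:
    """One-way ANOVA on per-node (weighted) degree across group networks.

    Nodes are the observations within each group.  Networks with fewer than
    2 nodes are excluded with a warning.  Returns ``(F, p)``.
    """
    samples = []
    for net in networks:
        g = _graph_of(net)
        if g.number_of_nodes() < 2:
            log.warning("excluding %s from ANOVA: fewer than 2 nodes", getattr(net, "group_label", "?"))
            continue
        deg = weighted_degree_centrality(net) if weighted else degree_centrality(net)
        samples.append(np.fromiter(deg.values(), dtype=float))
    if len(samples) < 2:
        raise ValueError("need at least two networks with >= 2 nodes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input F is reported as inf
        f, p = stats.f_oneway(*samples)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# Organ-system aggregation
# ---------------------------------------------------------------------------

@dataclass
class OrganNetwork:
    """18-chapter aggregate of a diagnosis-level network (chapter 17 absent).

    Edge weights are summed SCI over cross-chapter diagnosis edges; each
    chapter's within-chapter sum is kept in ``self_weights``.  Edges carry a
    ``highlighted`` flag: aggregate weight strictly greater than
    ``highlight_threshold``.
    """

    group_label: str
    graph: nx.Graph
    self_weights: dict[int, float] = field(default_factory=dict)
    highlight_threshold: float = 10.0

    def total_weight(self) -> float:
        cross = sum(d["weight"] for _, _, d in self.graph.edges(data=True))
        return float(cross + sum(self.self_weights.values()))

    def highlighted_pairs(self) -> list[tuple[int, int]]:
        return sorted(
            tuple(sorted((u, v))) for u, v, d in self.graph.edges(data=True) if d["highlighted"]
        )


def aggregate_to_organs(
    network: MultimorbidityNetwork,
    threshold: float = 10.0,
    chapter_map=None,
) -> OrganNetwork:
    """Sum diagnosis-level SCI weights into chapter-level edges.

    ``chapter_map`` maps a 3-digit code to its chapter id (default:
    :func:`comorbnet.icd9.chapter_of`).  Symptom-chapter codes must have
    been excluded upstream; finding one (or an unmappable code) is an error
    naming the code.
    """
    mapper = chapter_map or chapter_of
    g = _graph_of(network)
    chap: dict[str, int] = {}
    for v in g.nodes:
        try:
            chap[v] = int(mapper(v))
        except Exception as exc:
            raise ValueError(f"node {v!r} cannot be mapped to a chapter: {exc}") from exc
        if chap[v] == SYMPTOM_CHAPTER:
            raise ValueError(f"symptom-chapter code {v!r} present in comorbidity network")
    og = nx.Graph()
    og.add_nodes_from(sorted({c for c in chap.values()}))
    self_weights: dict[int, float] = {}
    for u, v, d in g.edges(data=True):
        a, b = sorted((chap[u], chap[v]))
        w = float(d["sci"])
        if a == b:
            self_weights[a] = self_weights.get(a, 0.0) + w
        elif og.has_edge(a, b):
            og[a][b]["weight"] += w
        else:
            og.add_edge(a, b, weight=w)
    for _, _, d in og.edges(data=True):
        d["highlighted"] = bool(d["weight"] > threshold)
    return OrganNetwork(
        group_label=getattr(network, "group_label", ""),
        graph=og,
        self_weights=self_weights,
        highlight_threshold=float(threshold),
    )


def presence_table(organ_networks: list[OrganNetwork], threshold: float | None = None) -> pd.DataFrame:
    """Presence/absence grid of prominent organ-level comorbidities.

    Rows are cross-chapter pairs (any pair with nonzero weight in at least
    one group), columns are group labels; a cell is True when that group's
    aggregate weight strictly exceeds the threshold (each network's own
    highlight threshold when ``threshold`` is None).
    """
    if not organ_networks:
        raise ValueError("need at least one organ network")
    pairs = sorted(
        {tuple(sorted((u, v))) for on in organ_networks for u, v in on.graph.edges()}
    )
    data = {}
    for on in organ_networks:
        thr = on.highlight_threshold if threshold is None else float(threshold)
        col = []
        for a, b in pairs:
            w = on.graph[a][b]["weight"] if on.graph.has_edge(a, b) else 0.0
            col.append(bool(w > thr))
        data[on.group_label] = col
    idx = pd.Index([f"{a}-{b}" for a, b in pairs], name="chapter_pair")
    return pd.DataFrame(data, index=idx)
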