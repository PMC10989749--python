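"""Co-occurrence networks over community features.

Nodes are features (taxa, KOs or pathways); an edge joins two features
whose Spearman correlation across samples is strong (|rho| >= 0.6 by
default) and significant after Benjamini-Hochberg correction over all
tested pairs. Density, diameter, radius and Freeman degree
centralization summarise the graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AbundanceTable

__all__ = ["CooccurrenceNetwork", "NetworkStats", "build_network", "network_stats"]

PREVALENCE_MIN = 0.20  # stricter than the biomarker screen: correlations
# on near-absent features are rank noise


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph  # nodes = features; edge attrs: rho, q

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float, float]]:
        return [
            (u, v, data["rho"], data["q"]) for u, v, data in self.graph.edges(data=True)
        ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["u", "v", "rho", "q"])


@dataclass
class NetworkStats:
    density: float
    diameter: float
    radius: float
    centralization: float
    component_count: int


def build_network(
    t: AbundanceTable, rho_threshold: float = 0.6, q_threshold: float = 0.05
) -> CooccurrenceNetwork:
    """Spearman co-occurrence graph over prevalence-filtered features."""
    x = t.data
    if x.shape[0] < 4:
        raise ValueError("too few samples for correlation (need >= 4)")
    prev = (x.to_numpy() > 0).mean(axis=0)
    x = x.loc[:, prev >= PREVALENCE_MIN]
    # constant features have zero rank variance; drop before correlating
    x = x.loc[:, np.ptp(x.to_numpy(), axis=0) > 0]
    feats = list(x.columns)
    g = nx.Graph()
    g.add_nodes_from(feats)
    m = len(feats)
    if m >= 2:
        n = x.shape[0]
        ranks = np.apply_along_axis(stats.rankdata, 0, x.to_numpy(dtype=float))
        rho = np.corrcoef(ranks, rowvar=False)
        iu = np.triu_indices(m, 1)
        rvals = rho[iu]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = rvals * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rvals**2))
        ps = np.where(np.abs(rvals) >= 1.0, 0.0, 2 * stats.t.sf(np.abs(tstat), df=n - 2))
        qs = stats.false_discovery_control(ps, method="bh")
        for k in range(len(rvals)):
            if abs(rvals[k]) >= rho_threshold and qs[k] <= q_threshold:
                u, v = feats[iu[0][k]], feats[iu[1][k]]
                g.add_edge(u, v, rho=float(rvals[k]), q=float(qs[k]))
    return CooccurrenceNetwork(g)


def network_stats(net: CooccurrenceNetwork) -> NetworkStats:
    """Density (over all nodes), diameter/radius (unweighted shortest paths
    on the largest connected component) and Freeman degree centralization
    (whole graph; 0 when V < 3)."""
    g = net.graph
    v = g.number_of_nodes()
    if v == 0:
        raise ValueError("network has no nodes")
    e = g.number_of_edges()
    density = 0.0 if v < 2 else 2.0 * e / (v * (v - 1))
    if e == 0:
        return NetworkStats(density, 0.0, 0.0, 0.0, v)
    components = list(nx.connected_components(g))
    giant = g.subgraph(max(components, key=lambda c: (len(c), sorted(c)[0])))
    ecc = nx.eccentricity(giant)
    diameter = float(max(ecc.values()))
    radius = float(min(ecc.values()))
    if v < 3:
        centralization = 0.0
    else:
        degrees = np.array([d for _, d in g.degree()], dtype=float)
        centralization = float((degrees.max() - degrees).sum() / ((v - 1) * (v - 2)))
    return NetworkStats(density, diameter, radius, centralization, len(components))
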