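"""Node centralities, network-level properties and cross-network screens.

All measures are computed on the unweighted graph induced by the exported
edges (the convention of Cytoscape's network analyzer, which the closeness
and betweenness semantics here reproduce):

* DG — degree, the number of incident edges;
* BW — betweenness, Brandes' algorithm normalized by (N-1)(N-2)/2 over the
  whole graph even when disconnected;
* CN — closeness, 1 / (mean shortest-path length to reachable nodes),
  0 for isolated nodes;
* CC — local clustering coefficient, 2*triangles / (DG*(DG-1)), 0 when
  DG < 2.

High-centrality screens follow the dual-condition comparison design:
high-degree genes are adjacent to at least half of the other network
genes; high-closeness genes have CN >= 0.75 (both boundaries inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import ValidationError

DEFAULT_DEGREE_FRACTION = 0.5
DEFAULT_CLOSENESS_FLOOR = 0.75
WEAK_FRACTION = 0.1


@dataclass
class NetworkProperties:
    """Whole-network summary statistics (the shape of a properties table)."""

    n_nodes: int
    n_edges: int
    diameter: int
    radius: int
    avg_neighbors: float
    avg_shortest_path: float
    density: float
    heterogeneity: float
    clustering_coefficient: float
    n_components: int

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


def compute_centralities(net: nx.Graph) -> pd.DataFrame:
    """Per-gene DG/BW/CN/CC table for one network.

    Returns a DataFrame indexed by gene with columns DG, BW, CN, CC,
    sorted by gene ID for deterministic output.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("empty network")
    dg = dict(net.degree())
    bw = nx.betweenness_centrality(net, normalized=True)
    # closeness as inverse mean distance to reachable nodes (no
    # component-size rescaling)
    cn = nx.closeness_centrality(net, wf_improved=False)
    cc = nx.clustering(net)
    genes = sorted(net.nodes())
    tab = pd.DataFrame(
        {
            "DG": [dg[g] for g in genes],
            "BW": [bw[g] for g in genes],
            "CN": [cn[g] for g in genes],
            "CC": [cc[g] for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return tab


def network_properties(net: nx.Graph) -> NetworkProperties:
    """Diameter, radius, density and companions, per connected component.

    Diameter and radius are the max/min eccentricity over connected node
    pairs (infinite distances excluded); the average shortest path is the
    mean over all connected pairs.  Heterogeneity is the coefficient of
    variation of the degree distribution.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("empty network")
    n = net.number_of_nodes()
    e = net.number_of_edges()
    comps = [net.subgraph(c) for c in nx.connected_components(net)]
    eccs: list[int] = []
    total_dist = 0.0
    total_pairs = 0
    for comp in comps:
        if comp.number_of_nodes() == 1:
            eccs.append(0)
            continue
        ecc = nx.eccentricity(comp)
        eccs.extend(ecc.values())
        spl = dict(nx.all_pairs_shortest_path_length(comp))
        m = comp.number_of_nodes()
        total_dist += sum(sum(d.values()) for d in spl.values()) / 2.0
        total_pairs += m * (m - 1) // 2
    degrees = np.array([d for _, d in net.degree()], dtype=float)
    mean_deg = degrees.mean()
    return NetworkProperties(
        n_nodes=n,
        n_edges=e,
        diameter=int(max(eccs)),
        radius=int(min(eccs)),
        avg_neighbors=2.0 * e / n,
        avg_shortest_path=total_dist / total_pairs if total_pairs else 0.0,
        density=2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
        heterogeneity=float(degrees.std() / mean_deg) if mean_deg > 0 else 0.0,
        clustering_coefficient=float(np.mean(list(nx.clustering(net).values()))),
        n_components=len(comps),
    )


def select_high_centrality(
    tab: pd.DataFrame,
    n_nodes: int | None = None,
    degree_fraction: float = DEFAULT_DEGREE_FRACTION,
    closeness_floor: float = DEFAULT_CLOSENESS_FLOOR,
) -> tuple[set[str], set[str]]:
    """Apply the high-degree and high-closeness screens.

    high_degree: DG >= degree_fraction * (n_nodes - 1)
    high_closeness: CN >= closeness_floor
    Both boundaries are inclusive.  ``n_nodes`` defaults to the number of
    rows in the table.
    """
    if not (0.0 <= degree_fraction <= 1.0 and 0.0 <= closeness_floor <= 1.0):
        raise ValidationError("thresholds must be in [0, 1]")
    if n_nodes is None:
        n_nodes = len(tab)
    dg_floor = degree_fraction * (n_nodes - 1)
    high_degree = set(tab.index[tab["DG"] >= dg_floor])
    high_closeness = set(tab.index[tab["CN"] >= closeness_floor])
    return high_degree, high_closeness


def flag_centrality_table(
    tab: pd.DataFrame,
    n_nodes: int | None = None,
    degree_fraction: float = DEFAULT_DEGREE_FRACTION,
    closeness_floor: float = DEFAULT_CLOSENESS_FLOOR,
) -> pd.DataFrame:
    """Return the centrality table with boolean high_degree / high_closeness
    flag columns added."""
    hd, hc = select_high_centrality(tab, n_nodes, degree_fraction, closeness_floor)
    out = tab.copy()
    out["high_degree"] = out.index.isin(hd)
    out["high_closeness"] = out.index.isin(hc)
    return out


def cross_network_comparison(
    tab_a: pd.DataFrame,
    tab_b: pd.DataFrame,
    measure: str = "DG",
    degree_fraction: float = DEFAULT_DEGREE_FRACTION,
    closeness_floor: float = DEFAULT_CLOSENESS_FLOOR,
) -> pd.DataFrame:
    """Compare genes that are high-centrality in either of two networks.

    For each such gene the table reports its value in network A and B
    (0 when the gene is absent from that network), a classification
    {A-only, B-only, shared}, and — for the degree measure — a
    ``weak_in_other`` flag set when the gene is present in the other
    network but connected to at most 10% of its other genes.
    """
    if measure not in ("DG", "CN"):
        raise ValidationError("measure must be 'DG' or 'CN'")

    def _high(tab: pd.DataFrame) -> set[str]:
        hd, hc = select_high_centrality(
            tab, degree_fraction=degree_fraction, closeness_floor=closeness_floor
        )
        return hd if measure == "DG" else hc

    high_a, high_b = _high(tab_a), _high(tab_b)
    rows = []
    for gene in sorted(high_a | high_b):
        va = float(tab_a[measure].get(gene, 0.0))
        vb = float(tab_b[measure].get(gene, 0.0))
        if gene in high_a and gene in high_b:
            cls = "shared"
        elif gene in high_a:
            cls = "A-only"
        else:
            cls = "B-only"
        weak = False
        if measure == "DG":
            if cls == "A-only":
                weak = 0 < vb <= WEAK_FRACTION * (len(tab_b) - 1)
            elif cls == "B-only":
                weak = 0 < va <= WEAK_FRACTION * (len(tab_a) - 1)
        rows.append((gene, va, vb, cls, weak))
    return pd.DataFrame(
        rows, columns=["gene", f"{measure}_A", f"{measure}_B", "class", "weak_in_other"]
    )
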