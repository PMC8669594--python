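"""Graph metrics of thresholded PLV brain networks.

Five measures summarise each weighted graph: mean weighted degree (DE),
density (DS), mean clustering coefficient (CC), characteristic path length
(CPL) and modularity (M).  DE sums incident edge weights per node; DS is
the realised fraction of the n(n-1)/2 possible edges; CC uses the weighted
geometric-mean triangle formulation (weights rescaled by the graph maximum,
isolated and degree-1 nodes contributing 0); CPL averages shortest-path
lengths over connected node pairs with edge distances 1/weight; M is the
weighted Newman modularity of the best Louvain partition (resolution 1,
seeded tie-breaking).  A ``binary`` switch computes the unweighted variants
on the same supra-threshold edge set.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities, modularity

from .connectivity import PLVTensor, threshold_graph


def degree_density(g: nx.Graph, binary: bool = False) -> tuple[float, float]:
    """(DE, DS): mean (weighted) node degree and edge density."""
    n = g.number_of_nodes()
    if n == 0:
        return 0.0, 0.0
    weight = None if binary else "weight"
    de = float(np.mean([d for _, d in g.degree(weight=weight)]))
    ds = g.number_of_edges() / (n * (n - 1) / 2) if n > 1 else 0.0
    return de, float(ds)


def clustering(g: nx.Graph, binary: bool = False) -> float:
    """Mean clustering coefficient over all nodes."""
    if g.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(g, weight=None if binary else "weight"))


def char_path_length(g: nx.Graph, binary: bool = False) -> float:
    """Mean shortest-path length over connected node pairs (1/weight metric).

    NaN when no pair of distinct nodes is connected.
    """
    if not binary:
        for _, _, d in g.edges(data=True):
            d["dist"] = 1.0 / d["weight"]
    weight = None if binary else "dist"
    total, pairs = 0.0, 0
    for _, dists in nx.all_pairs_dijkstra_path_length(g, weight=weight):
        total += sum(dists.values())
        pairs += len(dists) - 1  # exclude self
    return total / pairs if pairs else float("nan")


def modularity_partition(
    g: nx.Graph, seed: int = 0, binary: bool = False, resolution: float = 1.0
) -> tuple[float, dict]:
    """Louvain-maximised weighted Newman modularity and the node->module map.

    An edgeless graph has undefined modularity (NaN) with every node its
    own module.  The trivial one-module partition always scores Q = 0.
    """
    weight = None if binary else "weight"
    if g.number_of_edges() == 0:
        return float("nan"), {n: i for i, n in enumerate(g.nodes)}
    comms = louvain_communities(g, weight=weight, seed=seed, resolution=resolution)
    q = modularity(g, comms, weight=weight, resolution=resolution)
    membership = {}
    for i, c in enumerate(comms):
        for node in c:
            membership[node] = i
    return float(q), membership


def graph_metrics(g: nx.Graph, seed: int = 0, binary: bool = False) -> dict:
    de, ds = degree_density(g, binary=binary)
    m, modules = modularity_partition(g, seed=seed, binary=binary)
    return dict(
        DE=de,
        DS=ds,
        M=m,
        CC=clustering(g, binary=binary),
        CPL=char_path_length(g, binary=binary),
        n_modules=len(set(modules.values())),
    )


def metrics_timecourse(
    plv: PLVTensor,
    condition: str,
    times: tuple[float, ...] = (-1.0, 0.0, 1.4),
    threshold: float = 0.65,
    seed: int = 0,
    binary: bool = False,
) -> pd.DataFrame:
    """One metrics row per requested time on the thresholded graph.

    ``times`` must be covered by the tensor's window centres (within half a
    step); metrics are evaluated on the window whose centre is nearest.
    """
    rows = []
    lo = plv.window_centers[0] - plv.step_s / 2
    hi = plv.window_centers[-1] + plv.step_s / 2
    for t in times:
        if not lo <= t <= hi:
            raise ValueError(f"time {t} s outside PLV coverage [{lo:.2f}, {hi:.2f}]")
        g = threshold_graph(plv.at_time(t), threshold=threshold, roi_labels=plv.roi_labels)
        rows.append(
            dict(condition=condition, time_s=t, **graph_metrics(g, seed=seed, binary=binary))
        )
    return pd.DataFrame(rows)
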