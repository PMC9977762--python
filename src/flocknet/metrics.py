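"""Individual- and flock-level descriptors of the association network.

Degree, betweenness and path-based metrics are computed on a binarized graph
(an edge wherever the association index exceeds a threshold; the default
threshold of 0 keeps every positive association, which suits the dense,
highly connected networks typical of captive flocks). Average association
strength is computed on the weighted matrix itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .types import AssociationMatrix

logger = logging.getLogger(__name__)

__all__ = ["FlockMetrics", "binarize", "node_metrics", "flock_metrics"]


@dataclass
class FlockMetrics:
    """Whole-network summary.

    ``clustering_coefficient`` is the mean local (Watts–Strogatz) clustering
    over nodes of degree >= 2; ``transitivity`` (the global triangle ratio) is
    reported alongside because the two variants are often conflated in the
    applied literature. ``average_path_length`` is the mean geodesic over
    connected ordered pairs only. Degenerate (edgeless) networks get NaN
    metrics and ``defined=False`` rather than fabricated values.
    """

    clustering_coefficient: float
    transitivity: float
    average_path_length: float
    mean_association_strength: float
    n_components: int
    n_nodes: int
    n_edges: int
    defined: bool = True


def binarize(m: AssociationMatrix, threshold: float = 0.0) -> nx.Graph:
    """Binarize the association matrix: edge present iff HWI > threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    g = nx.Graph()
    g.add_nodes_from(m.ids)
    ii, jj = np.nonzero(np.triu(m.values, k=1) > threshold)
    g.add_edges_from((m.ids[i], m.ids[j]) for i, j in zip(ii, jj))
    return g


def node_metrics(m: AssociationMatrix, threshold: float = 0.0) -> pd.DataFrame:
    """Per-bird degree, betweenness and average association strength.

    Betweenness is unweighted shortest-path betweenness with fractional
    credit shared among tied geodesics (Freeman/Brandes), unnormalised raw
    path counts. Average association strength is the mean index to the other
    N-1 birds (row mean of the weighted matrix excluding self).
    """
    if m.n < 2:
        raise ValueError("node metrics need at least 2 birds")
    g = binarize(m, threshold)
    betw = nx.betweenness_centrality(g, normalized=False)
    strength = m.values.sum(axis=1) / (m.n - 1)
    return pd.DataFrame(
        {
            "bird_id": m.ids,
            "degree": [g.degree(b) for b in m.ids],
            "betweenness": [betw[b] for b in m.ids],
            "avg_association_strength": strength,
        }
    ).set_index("bird_id")


def flock_metrics(m: AssociationMatrix, threshold: float = 0.0) -> FlockMetrics:
    """Flock-level clustering, path length, mean strength and connectivity."""
    g = binarize(m, threshold)
    n = m.n
    mean_strength = (
        float(m.values.sum() / (n * (n - 1))) if n > 1 else float("nan")
    )
    n_edges = g.number_of_edges()
    n_components = nx.number_connected_components(g) if n else 0
    if n_edges == 0:
        logger.warning("edgeless network: clustering and path length undefined")
        return FlockMetrics(
            clustering_coefficient=float("nan"),
            transitivity=float("nan"),
            average_path_length=float("nan"),
            mean_association_strength=mean_strength,
            n_components=n_components,
            n_nodes=n,
            n_edges=0,
            defined=False,
        )
    local = nx.clustering(g)
    eligible = [b for b in g if g.degree(b) >= 2]
    skipped = n - len(eligible)
    if skipped:
        logger.info("%d nodes of degree < 2 excluded from mean local clustering", skipped)
    clustering = (
        float(np.mean([local[b] for b in eligible])) if eligible else float("nan")
    )

    total = 0
    n_pairs = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        total += sum(lengths.values())
        n_pairs += len(lengths) - 1  # drop the zero-distance self entry
    if n_pairs == 0:
        apl = float("nan")
    else:
        apl = total / n_pairs
    if n_components > 1:
        logger.warning(
            "network has %d components; disconnected pairs excluded from path length",
            n_components,
        )
    return FlockMetrics(
        clustering_coefficient=clustering,
        transitivity=float(nx.transitivity(g)),
        average_path_length=apl,
        mean_association_strength=mean_strength,
        n_components=n_components,
        n_nodes=n,
        n_edges=n_edges,
        defined=True,
    )
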