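"""Deterministic descriptive statistics for binary directed network layers.

The four per-layer statistics — density, average directed distance,
reciprocity, and transitivity — follow the conventions used when
tabulating roster-based economic-game networks:

* density is E / (V(V-1)), edges over all possible directed non-self pairs;
* reciprocity is the probability that a tie j -> k is matched by k -> j;
* transitivity is the global clustering coefficient of the symmetrized
  (undirected) graph;
* average distance is the mean directed shortest-path length over ordered
  pairs that are connected by some path (unreachable pairs are excluded,
  so sparse layers still get a finite value).

Isolates stay in V: descriptives are computed over the full roster.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data import MultiplexNetwork

__all__ = [
    "LayerSummary",
    "density",
    "reciprocity",
    "transitivity",
    "avg_distance",
    "reputation_score",
    "summarize",
]


@dataclass(frozen=True)
class LayerSummary:
    """Per-layer descriptive statistics (one row of a Table-1-style table)."""

    layer: str
    vertices: int
    edges: int
    density: float
    avg_distance: float
    reciprocity: float
    transitivity: float


def _as_digraph(layer) -> nx.DiGraph:
    if isinstance(layer, nx.DiGraph):
        g = layer
    else:
        A = np.asarray(layer)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        g = nx.from_numpy_array((A == 1).astype(int), create_using=nx.DiGraph)
    if any(g.has_edge(v, v) for v in g):
        raise ValueError("self-loops are not allowed")
    return g


def density(layer) -> float:
    """Fraction of observed directed edges over all V(V-1) possible edges."""
    g = _as_digraph(layer)
    V = g.number_of_nodes()
    if V < 2:
        raise ValueError("density needs at least two vertices")
    return g.number_of_edges() / (V * (V - 1))


def reciprocity(layer) -> float:
    """Probability that a directed tie j -> k is reciprocated by k -> j."""
    g = _as_digraph(layer)
    if g.number_of_edges() == 0:
        return 0.0
    return float(nx.overall_reciprocity(g))


def transitivity(layer) -> float:
    """Global clustering coefficient of the symmetrized graph.

    Probability that two adjacent nodes' common neighbour pattern closes:
    closed triplets over connected triplets, on the undirected projection.
    Returns 0 when the graph has no connected triplets.
    """
    g = _as_digraph(layer)
    return float(nx.transitivity(g.to_undirected()))


def avg_distance(layer) -> float:
    """Mean directed shortest-path length over reachable ordered pairs."""
    g = _as_digraph(layer)
    total = 0
    n_pairs = 0
    for source, lengths in nx.shortest_path_length(g):
        for target, d in lengths.items():
            if target != source:
                total += d
                n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no reachable ordered pairs; average distance undefined")
    return total / n_pairs


def reputation_score(generous_layer, selfish_layer) -> np.ndarray:
    """Nominations as generous minus nominations as selfish, per person.

    Both layers must be adjacency matrices over the same roster; the score
    of person k is their in-degree in the generous layer minus their
    in-degree in the selfish layer.
    """
    A = np.asarray(generous_layer)
    B = np.asarray(selfish_layer)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("layers must be square matrices over one roster")
    return (A == 1).sum(axis=0) - (B == 1).sum(axis=0)


def summarize(net: MultiplexNetwork) -> pd.DataFrame:
    """Apply the four layer statistics to every layer of a network.

    Unobserved cells count as absent edges, matching how field tables are
    compiled from the recorded decisions only. Layers with no reachable
    pair report NaN average distance.
    """
    rows = []
    V = net.roster.size
    for m, spec in enumerate(net.layers):
        A = net.layer_adjacency(m)
        E = int(A.sum())
        try:
            ad = avg_distance(A)
        except ValueError:
            ad = float("nan")
        rows.append(
            LayerSummary(
                layer=spec.name,
                vertices=V,
                edges=E,
                density=density(A),
                avg_distance=ad,
                reciprocity=reciprocity(A),
                transitivity=transitivity(A),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
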