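"""Weighted graph metrics for muscle networks.

Metrics always operate on the weighted adjacency (thresholding is for
visualization only).  Conventions follow the weighted connectivity-toolbox
definitions:

* Clustering coefficient — Onnela geometric-mean form on weights normalized
  by the network maximum; the directed generalization (Fagiolo) counts all
  triangle orientations and corrects the degree pair count for bilateral
  edges.
* Global efficiency — mean inverse shortest-path length over ordered node
  pairs, with edge length = 1 / weight (zero-weight edges are absent,
  i.e. infinite length; disconnected pairs contribute 0).
* Betweenness centrality — weighted shortest-path betweenness on the same
  lengths, fractional over equal-length path multiplicities, unnormalized,
  averaged across nodes for the global value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import InvalidInputError, InvalidParameterError
from .pairs import directed_pairs, undirected_pairs
from .unmixing import MuscleNetwork


@dataclass
class NetworkMetrics:
    """Per-node and global CC / GE / BC of one weighted network."""

    cc_nodes: np.ndarray
    cc_mean: float
    ge: float
    bc_nodes: np.ndarray
    bc_mean: float
    directed: bool
    weight_to_length: str = "inverse"


def _check_weights(net: MuscleNetwork) -> np.ndarray:
    A = np.asarray(net.adjacency, dtype=float)
    if np.any(A < 0):
        raise InvalidInputError("network weights must be nonnegative")
    return A


def clustering_coefficient(net: MuscleNetwork) -> tuple[np.ndarray, float]:
    """Weighted clustering coefficient per node, plus the node average.

    Weights are normalized by the network's maximum weight, so each node's
    value lies in [0, 1]; nodes with fewer than two neighbours get 0.
    """
    A = _check_weights(net)
    n = A.shape[0]
    wmax = A.max()
    if wmax == 0:
        return np.zeros(n), 0.0
    W13 = np.cbrt(A / wmax)
    B = (A > 0).astype(float)
    if net.directed:
        # Fagiolo: all triangle orientations; degree term corrected for
        # bilateral (reciprocal) edges.
        T = np.diagonal((W13 + W13.T) @ (W13 + W13.T) @ (W13 + W13.T))
        d_tot = B.sum(axis=0) + B.sum(axis=1)
        d_bi = (B * B.T).sum(axis=1)
        denom = 2.0 * (d_tot * (d_tot - 1) - 2.0 * d_bi)
    else:
        T = np.diagonal(W13 @ W13 @ W13)
        k = B.sum(axis=1)
        denom = k * (k - 1)
    cc = np.zeros(n)
    ok = denom > 0
    cc[ok] = T[ok] / denom[ok]
    return cc, float(cc.mean())


def _length_matrix(A: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        L = np.where(A > 0, 1.0 / np.where(A > 0, A, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def global_efficiency(net: MuscleNetwork) -> float:
    """Mean inverse weighted shortest-path length over ordered node pairs."""
    A = _check_weights(net)
    n = A.shape[0]
    if n < 2:
        return 0.0
    L = _length_matrix(A)
    finite = np.where(np.isfinite(L) & (L > 0), L, 0.0)
    D = dijkstra(csr_matrix(finite), directed=net.directed)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _to_graph(net: MuscleNetwork) -> nx.Graph | nx.DiGraph:
    A = net.adjacency
    G: nx.Graph | nx.DiGraph = nx.DiGraph() if net.directed else nx.Graph()
    G.add_nodes_from(range(A.shape[0]))
    it = directed_pairs(A.shape[0]) if net.directed else undirected_pairs(A.shape[0])
    for a, b in it:
        if A[a, b] > 0:
            G.add_edge(a, b, weight=A[a, b], length=1.0 / A[a, b])
    return G


def betweenness_centrality(net: MuscleNetwork, normalized: bool = False
                           ) -> tuple[np.ndarray, float]:
    """Weighted shortest-path betweenness per node, plus the node average."""
    A = _check_weights(net)
    G = _to_graph(net)
    bc_dict = nx.betweenness_centrality(G, weight="length", normalized=normalized)
    bc = np.array([bc_dict[i] for i in range(A.shape[0])])
    return bc, float(bc.mean())


def network_metrics(net: MuscleNetwork) -> NetworkMetrics:
    cc, cc_mean = clustering_coefficient(net)
    ge = global_efficiency(net)
    bc, bc_mean = betweenness_centrality(net)
    return NetworkMetrics(cc_nodes=cc, cc_mean=cc_mean, ge=ge,
                          bc_nodes=bc, bc_mean=bc_mean, directed=net.directed)


def metrics_table(networks: list[MuscleNetwork]) -> pd.DataFrame:
    """Tidy table of global CC / GE / BC for a list of muscle networks."""
    rows = []
    for net in networks:
        m = network_metrics(net)
        rows.append({"subject": net.subject, "condition": net.condition,
                     "component": net.component, "directed": net.directed,
                     "CC": m.cc_mean, "GE": m.ge, "BC": m.bc_mean})
    return pd.DataFrame(rows)


def proportional_threshold(net: MuscleNetwork, keep_fraction: float
                           ) -> MuscleNetwork:
    """Binarise a network keeping the top fraction of candidate edges.

    Keeps the ``ceil(keep_fraction * n_candidates)`` strongest edges
    (candidates: 45 unordered pairs for a 10-node undirected network, 90
    ordered pairs directed).  Ties at the cutoff resolve deterministically
    by pair-index order.  Zero-weight edges are never retained.  For
    visualization only; metrics use the weighted matrices.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise InvalidParameterError("keep_fraction must be in (0, 1]")
    A = _check_weights(net)
    n = A.shape[0]
    cands = directed_pairs(n) if net.directed else undirected_pairs(n)
    k = math.ceil(keep_fraction * len(cands))
    weights = np.array([A[a, b] for a, b in cands])
    # Stable sort by descending weight keeps pair-index order among ties.
    order = np.argsort(-weights, kind="stable")
    out = np.zeros_like(A)
    kept = 0
    for idx in order:
        if kept >= k or weights[idx] <= 0:
            break
        a, b = cands[idx]
        out[a, b] = 1.0
        if not net.directed:
            out[b, a] = 1.0
        kept += 1
    return MuscleNetwork(adjacency=out, directed=net.directed,
                         channel_labels=net.channel_labels,
                         component=net.component, condition=net.condition,
                         subject=net.subject)
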