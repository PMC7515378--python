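"""Network permutation entropy (NPE).

The embedded vectors of a series become the nodes of a graph. Scanning
nodes in temporal order, each vector i >= 2 looks back through its
predecessors j = 1, ..., i-1 (in ascending order) for the FIRST vector
with the same ordinal pattern whose signed variance weight lies within
``error`` of its own; that predecessor gains one edge and one score
increment, and the scan for i stops. Unmatched nodes keep a tiny score
floor (1e-5 by default) so the final score vector normalizes to a full
distribution over all N-d+1 nodes. The NPE is the Shannon entropy of
that distribution normalized by ln(N-d+1).

Periodic series funnel nearly all connections onto a handful of early
nodes, concentrating the distribution and driving the NPE toward zero;
irregular series rarely connect, leaving the distribution near uniform
and the NPE near one. This resolves the failure mode of plain
permutation entropy, whose pattern distribution can be uniform (hence
maximally entropic) for a purely periodic series.

The weight comparison uses the absolute difference |w_i - w_j| <= error:
the tolerance bounds how far apart two spreads may be, regardless of
which vector came first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .embedding import signed_weights, symbolize

__all__ = [
    "ComplexityNetwork",
    "NpeResult",
    "build_network",
    "npe_value",
    "network_summary",
    "write_edge_list",
    "write_scores",
    "write_graphml",
    "DEFAULT_SCORE_FLOOR",
    "DEFAULT_ERROR",
]

#: Initial per-node score before any connection is recorded.
DEFAULT_SCORE_FLOOR = 1e-5

#: Default weight tolerance when the caller does not supply one
#: (suitable for short series; long-series analyses typically use
#: 0.0005). Results always echo the tolerance actually used.
DEFAULT_ERROR = 0.005


@dataclass
class ComplexityNetwork:
    """Connection network over the embedded vectors of one series.

    Nodes are numbered 1..n_nodes (vector order). ``edges`` holds
    (later, earlier) node pairs; ``raw_scores[j-1]`` is the score floor
    plus the number of times node j was chosen as the earlier endpoint.
    The edge list is canonical; the dense adjacency matrix is built on
    demand.
    """

    n_nodes: int
    raw_scores: np.ndarray
    edges: list = field(default_factory=list)
    floor: float = DEFAULT_SCORE_FLOOR
    d: int = 0
    error: float = 0.0

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix with zero diagonal."""
        m = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        for i, j in self.edges:
            m[i - 1, j - 1] = 1
            m[j - 1, i - 1] = 1
        return m

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            deg[i - 1] += 1
            deg[j - 1] += 1
        return deg

    def probabilities(self) -> np.ndarray:
        """Raw scores normalized to a distribution over all nodes."""
        return self.raw_scores / self.raw_scores.sum()


@dataclass(frozen=True)
class NpeResult:
    """NPE value plus the node distribution and network behind it."""

    value: float
    probabilities: np.ndarray
    network: ComplexityNetwork
    d: int
    error: float

    def to_dict(self) -> dict:
        return {
            "method": "npe",
            "value": self.value,
            "d": self.d,
            "error": self.error,
            "n_nodes": self.network.n_nodes,
            "n_edges": self.network.n_edges,
        }


def build_network(x, d: int, error: float, floor: float = DEFAULT_SCORE_FLOOR) -> ComplexityNetwork:
    """Build the pattern-and-weight connection network of ``x``.

    Equivalent to the naive quadratic scan (each node checks all its
    predecessors in order and links to the first same-pattern one
    within the weight tolerance), but candidates are indexed by pattern
    code so each node only touches same-pattern predecessors. Only the
    earlier endpoint's score is incremented; the later node keeps its
    floor. Because a later match would always stop at the earlier node
    of its class first, an incremented node is never a later endpoint.
    """
    if error < 0:
        raise ValueError(f"weight tolerance error={error} must be >= 0")
    seq = symbolize(x, d)
    n = len(seq)
    if n < 2:
        raise ValueError(f"too short to form >= 2 vectors: N={n + d - 1}, d={d}")

    scores = np.full(n, floor, dtype=float)
    edges: list = []
    codes = seq.codes
    weights = seq.weights
    # Group nodes by pattern code; stable sort keeps ascending node
    # order within each class, so the first in-tolerance predecessor in
    # the class is the first in the full backward scan.
    order = np.argsort(codes, kind="stable")
    boundaries = np.flatnonzero(np.diff(codes[order])) + 1
    for members in np.split(order, boundaries):
        wv = weights[members]
        for t in range(1, len(members)):
            hits = np.flatnonzero(np.abs(wv[:t] - wv[t]) <= error)
            if hits.size:
                j = int(members[hits[0]])
                scores[j] += 1.0
                edges.append((int(members[t]) + 1, j + 1))
    edges.sort()
    return ComplexityNetwork(
        n_nodes=n, raw_scores=scores, edges=edges, floor=floor, d=d, error=error
    )


def npe_value(
    x, d: int, error: float = DEFAULT_ERROR, floor: float = DEFAULT_SCORE_FLOOR
) -> NpeResult:
    """Network permutation entropy of ``x`` at dimension ``d``.

    Returns the normalized entropy of the node-score distribution
    together with the distribution and the network itself.
    """
    network = build_network(x, d, error, floor=floor)
    probs = network.probabilities()
    value = float(-(probs * np.log(probs)).sum() / math.log(network.n_nodes))
    value = min(max(value, 0.0), 1.0)  # guard one-ulp excursions at uniformity
    return NpeResult(value=value, probabilities=probs, network=network, d=d, error=error)


def network_summary(network: ComplexityNetwork) -> dict:
    """Edge count, isolation count, degree sequence and node distribution."""
    deg = network.degrees()
    return {
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "n_isolated": int((deg == 0).sum()),
        "degree_sequence": deg,
        "probabilities": network.probabilities(),
    }


def write_edge_list(network: ComplexityNetwork, path) -> None:
    """Tab-separated (later, earlier) node pairs, 1-based."""
    with open(path, "w") as fh:
        fh.write(f"# npe edge list\td={network.d}\terror={network.error}\n")
        fh.write("node_i\tnode_j\n")
        for i, j in network.edges:
            fh.write(f"{i}\t{j}\n")


def write_scores(network: ComplexityNetwork, path) -> None:
    """Per-node raw score and normalized probability as TSV."""
    probs = network.probabilities()
    with open(path, "w") as fh:
        fh.write(f"# npe node scores\td={network.d}\terror={network.error}\n")
        fh.write("node\traw_score\tprobability\n")
        for k in range(network.n_nodes):
            fh.write(f"{k + 1}\t{network.raw_scores[k]:.10g}\t{probs[k]:.10g}\n")


def write_graphml(network: ComplexityNetwork, path) -> None:
    """Export the network as GraphML (node scores as attributes)."""
    import networkx as nx

    g = nx.Graph()
    probs = network.probabilities()
    for k in range(network.n_nodes):
        g.add_node(k + 1, raw_score=float(network.raw_scores[k]), probability=float(probs[k]))
    g.add_edges_from(network.edges)
    nx.write_graphml(g, path)
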