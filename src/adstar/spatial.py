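"""Spatial priors on the district adjacency graph.

The spatial term of the model decomposes into an unstructured district effect
u_s (exchangeable normal, variance sigma2_u) and a structured effect eta_s
with an intrinsic conditional autoregressive (CAR) prior, i.e. a Gaussian
Markov random field on the adjacency graph: given its neighbours, eta_s is
normal with mean equal to the neighbour average and variance sigma2_s / N_s,
where N_s is the number of neighbouring districts.

The joint intrinsic CAR density is improper, proportional to
``exp(-eta' Q eta / (2 sigma2_s))`` with the structure matrix Q returned by
:func:`car_precision`; identifiability is restored downstream by a
sum-to-zero constraint on eta.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np

__all__ = [
    "car_precision",
    "full_conditional",
    "sample_unstructured",
    "sample_intrinsic_car",
]

logger = logging.getLogger(__name__)


def _check_graph(graph: nx.Graph) -> list:
    nodes = list(graph.nodes)
    if len(nodes) == 0:
        raise ValueError("adjacency graph has no nodes")
    for s in nodes:
        if graph.degree(s) == 0:
            raise ValueError(
                f"district {s!r} has no neighbours; its conditional "
                "variance sigma2_s / N_s is undefined"
            )
    if not nx.is_connected(graph):
        logger.warning("adjacency graph is not connected")
    return nodes


def car_precision(graph: nx.Graph) -> np.ndarray:
    """Intrinsic CAR structure matrix Q for an undirected adjacency graph.

    ``Q[s, s] = N_s`` (neighbour count) and ``Q[s, s'] = -1`` for adjacent
    districts.  Q equals the graph Laplacian: symmetric, positive
    semidefinite, row sums zero.
    """
    nodes = _check_graph(graph)
    return nx.laplacian_matrix(graph, nodelist=nodes).toarray().astype(float)


def full_conditional(
    eta: np.ndarray, s: int, sigma2_s: float, graph: nx.Graph
) -> tuple[float, float]:
    """Mean and variance of eta_s given all other structured effects.

    mean = average of the neighbours' effects; variance = sigma2_s / N_s.
    ``s`` indexes ``eta`` positionally, in ``list(graph.nodes)`` order.
    """
    nodes = list(graph.nodes)
    eta = np.asarray(eta, dtype=float)
    neigh = [nodes.index(v) for v in graph.neighbors(nodes[s])]
    if len(neigh) == 0:
        raise ValueError(f"district {nodes[s]!r} has no neighbours")
    return float(np.mean(eta[neigh])), float(sigma2_s / len(neigh))


def sample_unstructured(
    S: int, sigma2_u: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw the exchangeable (unstructured) district effects u ~ N(0, sigma2_u)."""
    if sigma2_u < 0:
        raise ValueError(f"variance must be nonnegative, got {sigma2_u}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if sigma2_u == 0:
        return np.zeros(S)
    return rng.normal(0.0, np.sqrt(sigma2_u), size=S)


def sample_intrinsic_car(
    graph: nx.Graph, sigma2_s: float, rng: np.random.Generator | int
) -> np.ndarray:
    """One draw from the intrinsic CAR prior, constrained to sum to zero.

    Sampling is done in the eigenbasis of Q restricted to its non-null
    eigenvectors (variance sigma2_s / lambda_i along eigenvector i), which is
    the proper Gaussian on the sum-to-zero subspace.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    Q = car_precision(graph)
    lam, V = np.linalg.eigh(Q)
    pos = lam > 1e-10 * lam.max()
    z = rng.normal(size=pos.sum()) * np.sqrt(sigma2_s / lam[pos])
    eta = V[:, pos] @ z
    return eta - eta.mean()
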