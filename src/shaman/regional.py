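"""Node-level motion impact scores, iterative node exclusion, RMS projection.

The whole-matrix Stouffer combination restricts naturally to any edge
subset, so a node's motion impact score combines the z-values of the edges
incident to it, and significance recombines the existing permutation
ensemble over the same subset — no re-permutation needed.  Iteratively
excluding the highest-scoring node until the whole-brain score loses
significance counts how many regions contribute to the motion impact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fc import edge_nodes, n_edges
from .inference import NullEnsemble


@dataclass
class NodeScoreTable:
    node_z: np.ndarray
    node_p: np.ndarray
    n_edges_per_node: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.node_z.shape[0]


@dataclass
class ExclusionTrace:
    order: list[int]
    omnibus_p_path: list[float]

    @property
    def n_contributing(self) -> int:
        return len(self.order)


def _incidence(n_nodes: int) -> np.ndarray:
    """Boolean (n_nodes, E) matrix: node k incident to edge e."""
    i, j = edge_nodes(n_nodes)
    inc = np.zeros((n_nodes, n_edges(n_nodes)), dtype=bool)
    inc[i, np.arange(i.size)] = True
    inc[j, np.arange(j.size)] = True
    return inc


def _subset_omnibus(edge_z: np.ndarray, null_edge_z: np.ndarray,
                    include: np.ndarray) -> tuple[float, float]:
    k = int(include.sum())
    if k == 0:
        return 0.0, 1.0
    Z = float(edge_z[include].sum() / np.sqrt(k))
    Z_perm = null_edge_z[:, include].sum(axis=1) / np.sqrt(k)
    P = null_edge_z.shape[0]
    p = float((1 + np.sum(Z_perm >= Z)) / (P + 1))
    return Z, p


def node_scores(edge_z: np.ndarray, null_edge_z: np.ndarray | NullEnsemble,
                n_nodes: int,
                active_edges: np.ndarray | None = None) -> NodeScoreTable:
    """Per-node Stouffer Z over incident edges, with recombined permutation p.

    A node with no remaining incident edge (after exclusions) gets NaN score
    and p = 1.
    """
    edge_z = np.asarray(edge_z, dtype=float)
    nz = null_edge_z.stats if isinstance(null_edge_z, NullEnsemble) else null_edge_z
    nz = np.asarray(nz, dtype=float)
    if edge_z.shape[0] != n_edges(n_nodes):
        raise ValueError("edge_z length does not match node count")
    if active_edges is None:
        active_edges = np.ones(edge_z.shape[0], dtype=bool)
    inc = _incidence(n_nodes)
    node_z = np.full(n_nodes, np.nan)
    node_p = np.ones(n_nodes)
    counts = (inc & active_edges[None, :]).sum(axis=1)
    for k in range(n_nodes):
        sel = inc[k] & active_edges
        if not sel.any():
            continue
        node_z[k], node_p[k] = _subset_omnibus(edge_z, nz, sel)
    return NodeScoreTable(node_z=node_z, node_p=node_p, n_edges_per_node=counts)


def exclusion_trace(edge_z: np.ndarray, null: np.ndarray | NullEnsemble,
                    n_nodes: int, alpha: float = 0.05) -> ExclusionTrace:
    """Count motion-contributing regions by iterative node exclusion.

    Loop: compute the omnibus score over the remaining edges (recombining the
    same null ensemble restricted to those edges); if it is no longer
    significant at ``alpha``, stop.  Otherwise exclude the node with the
    largest node score (ties broken toward the lowest node index) by deleting
    its incident edges, and repeat.  ``n_contributing`` is the number of
    exclusions performed before the score lost significance.
    """
    edge_z = np.asarray(edge_z, dtype=float)
    nz = null.stats if isinstance(null, NullEnsemble) else np.asarray(null, float)
    inc = _incidence(n_nodes)
    active_edges = np.ones(edge_z.shape[0], dtype=bool)
    remaining = np.ones(n_nodes, dtype=bool)
    order: list[int] = []
    p_path: list[float] = []
    while True:
        _, p = _subset_omnibus(edge_z, nz, active_edges)
        p_path.append(p)
        if p > alpha or not remaining.any():
            break
        if not active_edges.any():
            # remaining nodes have no incident edges left; at alpha = 1 they
            # are excluded trivially so the trace covers every node
            order.extend(int(k) for k in np.flatnonzero(remaining))
            remaining[:] = False
            continue
        table = node_scores(edge_z, nz, n_nodes, active_edges=active_edges)
        z = np.where(remaining, table.node_z, -np.inf)
        z = np.where(np.isnan(z), -np.inf, z)
        best = int(np.argmax(z))  # argmax takes the lowest index on ties
        order.append(best)
        remaining[best] = False
        active_edges &= ~inc[best]
    return ExclusionTrace(order=order, omnibus_p_path=p_path)


def parcel_rms(effect: np.ndarray) -> np.ndarray:
    """Root-mean-square of each node's off-diagonal row in a symmetric map."""
    effect = np.asarray(effect, dtype=float)
    if effect.ndim != 2 or effect.shape[0] != effect.shape[1]:
        raise ValueError("effect must be a square symmetric matrix")
    n = effect.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    off = effect.copy()
    np.fill_diagonal(off, 0.0)
    return np.sqrt((off**2).sum(axis=1) / (n - 1))
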