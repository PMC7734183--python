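"""Per-subject layer networks and the cohort multiplex.

Each subject contributes one *layer*: a weighted undirected network whose
nodes are the grid's valid patches and whose link weights are absolute
Pearson correlations between patch intensity vectors, with correlations
below the noise threshold removed.  The multiplex is the collection of all
layers on the shared node set; its degree ``k_multi[i]`` counts the
distinct partners node ``i`` is linked to in at least one layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .defaults import EDGE_THRESHOLD
from .grid import Box, PatchGrid

__all__ = ["LayerNetwork", "MultiplexNetwork", "patch_vector", "edge_weight", "build_layer", "assemble_multiplex"]


@dataclass
class LayerNetwork:
    """One subject's weighted network over the shared patch nodes.

    ``weights`` is symmetric with zero diagonal and entries in
    ``{0} ∪ [threshold, 1]``; ``node_ids`` are the grid box indices of the
    valid patches, identical across a cohort.
    """

    subject_id: str
    weights: np.ndarray
    node_ids: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def degree(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1)

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Upper-triangle edges as (node_id_i, node_id_j, weight)."""
        ii, jj = np.nonzero(np.triu(self.weights, 1))
        return [(int(self.node_ids[i]), int(self.node_ids[j]), float(self.weights[i, j])) for i, j in zip(ii, jj)]


@dataclass
class MultiplexNetwork:
    """All subjects' layers on one node set, plus the union adjacency."""

    layers: list[LayerNetwork]
    a_multi: np.ndarray  # binary union adjacency
    k_multi: np.ndarray  # per-node multiplex degree
    node_ids: np.ndarray

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def patch_vector(volume: np.ndarray, box: Box) -> np.ndarray:
    """Flatten a patch to a vector in fixed x-fastest order.

    The order is identical for every subject, so element ``t`` of two
    subjects' vectors refers to the same voxel of the shared space.
    """
    return np.asarray(volume[box.slices], float).ravel(order="F")


def edge_weight(u: np.ndarray, v: np.ndarray, threshold: float = EDGE_THRESHOLD) -> float:
    """|Pearson r| between two patch vectors, or 0 below the threshold.

    Correlations with ``|r|`` strictly lower than ``threshold`` are treated
    as noise (``|r| == threshold`` is kept).  A zero-variance vector has no
    defined correlation and yields weight 0.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.size} vs {v.size}")
    du = u - u.mean()
    dv = v - v.mean()
    denom = float(du @ du) * float(dv @ dv)
    if denom == 0:
        return 0.0
    r = min(abs(float(du @ dv)) / np.sqrt(denom), 1.0)
    return r if r >= threshold else 0.0


def build_layer(volume: np.ndarray, grid: PatchGrid, subject_id: str = "",
                threshold: float = EDGE_THRESHOLD) -> LayerNetwork:
    """Build one subject's layer from all valid-patch pairs."""
    node_ids = grid.node_ids
    if len(node_ids) < 2:
        raise ValueError("grid must provide at least 2 valid patches")
    X = np.stack([patch_vector(volume, grid.boxes[i]) for i in node_ids])
    sd = X.std(axis=1)
    live = sd > 0
    W = np.zeros((len(node_ids), len(node_ids)))
    if live.sum() >= 2:
        C = np.corrcoef(X[live])
        C = np.clip(np.abs(C), 0.0, 1.0)
        np.fill_diagonal(C, 0.0)
        C[C < threshold] = 0.0
        idx = np.flatnonzero(live)
        W[np.ix_(idx, idx)] = C
    W = (W + W.T) / 2  # corrcoef is symmetric; enforce exactly
    return LayerNetwork(subject_id=subject_id, weights=W, node_ids=node_ids)


def assemble_multiplex(layers: list[LayerNetwork]) -> MultiplexNetwork:
    """Union the layers into the multiplex and compute its degree.

    ``a_multi[i, j] = 1`` iff some layer links ``i`` and ``j``; an edge
    present in every layer still contributes 1.  Consequently
    ``k_multi[i] >= k_i`` in every single layer.
    """
    if not layers:
        raise ValueError("at least one layer required")
    ref = layers[0].node_ids
    for lay in layers[1:]:
        if not np.array_equal(lay.node_ids, ref):
            raise ValueError(f"layer {lay.subject_id!r} has a different node set than {layers[0].subject_id!r}")
    a = np.zeros_like(layers[0].weights, dtype=bool)
    for lay in layers:
        a |= lay.weights > 0
    a_multi = a.astype(int)
    return MultiplexNetwork(layers=layers, a_multi=a_multi, k_multi=a_multi.sum(axis=1), node_ids=ref)
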