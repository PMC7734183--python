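"""Nodal network metrics and the subjects x 8N feature matrix.

For each layer (subject) and node i four single-layer metrics are computed:

* strength      s_i = sum_j w_ij
* inverse participation ratio  y_i = sum_j (w_ij / s_i)^2
* their conditional means over nodes of equal degree, s(k_i) and Y(k_i)

and four multiplex counterparts obtained by weighing on the multiplex
degree: multiS_i = s_i * k_multi_i/(N-1), multiY_i likewise, and
conditional means over nodes sharing the same multiplex degree.  1/y_i
lies in [1, k_i]: it is k_i when a node's weight is spread uniformly over
its links and 1 when a single link dominates.  Stacking the 8 metrics for
all N nodes gives 8N features per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .defaults import CORR_FILTER
from .network import LayerNetwork, MultiplexNetwork

__all__ = [
    "METRIC_ORDER",
    "LayerFeatures",
    "FeatureMatrix",
    "layer_features",
    "multiplex_features",
    "build_feature_matrix",
    "filter_features",
    "feature_node",
    "feature_metric",
]

#: Column-block order of the feature matrix.
METRIC_ORDER = ("S", "Y", "Sc", "Yc", "multiS", "multiY", "multiSc", "multiYc")


@dataclass
class LayerFeatures:
    """Per-node single-layer metrics of one subject."""

    k: np.ndarray       # degree
    s: np.ndarray       # strength
    y: np.ndarray       # inverse participation ratio (0 for isolated nodes)
    s_cond: np.ndarray  # mean strength over the node's degree class
    y_cond: np.ndarray  # mean IPR over the node's degree class


@dataclass
class DroppedFeature:
    name: str
    reason: str                 # "null_mean_variance" | "high_correlation"
    partner: str | None = None  # retained correlated feature, for high_correlation


@dataclass
class FeatureMatrix:
    """Subjects x features with filtering provenance."""

    values: pd.DataFrame                       # index: subject_id, columns: feature names
    dropped: list[DroppedFeature] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.values)


def _conditional_mean(values: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Per-node mean of ``values`` over nodes sharing the node's class."""
    out = np.empty_like(values, dtype=float)
    for c in np.unique(classes):
        m = classes == c
        out[m] = values[m].mean()
    return out


def layer_features(layer: LayerNetwork) -> LayerFeatures:
    W = layer.weights
    k = (W > 0).sum(axis=1)
    s = W.sum(axis=1)
    y = np.zeros_like(s)
    pos = s > 0
    y[pos] = ((W[pos] / s[pos, None]) ** 2).sum(axis=1)
    return LayerFeatures(k=k, s=s, y=y, s_cond=_conditional_mean(s, k), y_cond=_conditional_mean(y, k))


def multiplex_features(lf: LayerFeatures, k_multi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weigh a layer's metrics on the multiplex degree.

    Nodal metrics are scaled by the normalized multiplex degree
    ``k_multi/(N-1)`` (so they reduce to the single-layer metrics on a
    complete multiplex and vanish for multiplex-isolated nodes); the
    conditional counterparts average s and y over nodes sharing the same
    multiplex degree.  Returns (multiS, multiY, multiSc, multiYc).
    """
    N = len(k_multi)
    if N < 2:
        raise ValueError("multiplex weighting needs at least 2 nodes")
    if len(lf.s) != N:
        raise ValueError("k_multi not aligned to the layer's nodes")
    f = k_multi / (N - 1)
    return (lf.s * f, lf.y * f, _conditional_mean(lf.s, k_multi), _conditional_mean(lf.y, k_multi))


def build_feature_matrix(multiplex: MultiplexNetwork) -> FeatureMatrix:
    """Assemble the M x 8N matrix, one row per subject.

    Columns come in 8 blocks of N in :data:`METRIC_ORDER`, named
    ``{metric}_n{node_id}`` with the grid's box index as the node id; the
    order is deterministic and shared across subjects.
    """
    if multiplex.n_layers < 2:
        raise ValueError("feature matrix needs at least 2 subjects")
    names = [f"{m}_n{int(i):04d}" for m in METRIC_ORDER for i in multiplex.node_ids]
    rows = {}
    for lay in multiplex.layers:
        lf = layer_features(lay)
        mS, mY, mSc, mYc = multiplex_features(lf, multiplex.k_multi)
        rows[lay.subject_id] = np.concatenate([lf.s, lf.y, lf.s_cond, lf.y_cond, mS, mY, mSc, mYc])
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df.columns = names
    return FeatureMatrix(values=df)


def filter_features(fm: FeatureMatrix, corr_threshold: float = CORR_FILTER) -> FeatureMatrix:
    """Remove uninformative and redundant columns.

    First drops constant columns (null variance, which covers null mean and
    variance); then scans the remaining columns in order and drops any
    later column whose correlation with an already-kept column strictly
    exceeds ``corr_threshold``, recording the retained partner.  The
    operation is idempotent.
    """
    X = fm.values
    if len(X) < 3:
        raise ValueError("filtering needs at least 3 subjects")
    dropped = list(fm.dropped)

    sd = X.std(axis=0, ddof=0)
    const = sd == 0
    for name in X.columns[const]:
        dropped.append(DroppedFeature(name=name, reason="null_mean_variance"))
    X = X.loc[:, ~const]

    if X.shape[1] == 0:
        raise ValueError("all features were dropped by filtering")

    arr = X.to_numpy()
    arr = (arr - arr.mean(axis=0)) / arr.std(axis=0, ddof=0)
    C = (arr.T @ arr) / len(arr)
    kept: list[int] = []
    for j in range(X.shape[1]):
        partner = next((i for i in kept if C[i, j] > corr_threshold), None)
        if partner is None:
            kept.append(j)
        else:
            dropped.append(DroppedFeature(name=X.columns[j], reason="high_correlation", partner=X.columns[partner]))
    if not kept:
        raise ValueError("all features were dropped by filtering")
    return FeatureMatrix(values=X.iloc[:, kept].copy(), dropped=dropped)


def feature_node(name: str) -> int:
    """Node id (grid box index) a feature name refers to."""
    return int(name.rsplit("_n", 1)[1])


def feature_metric(name: str) -> str:
    """Metric block a feature name belongs to."""
    return name.rsplit("_n", 1)[0]
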