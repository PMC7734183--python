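"""Which features were selected more often than chance, and where they live.

A feature selected in ``count`` of ``rounds`` CV rounds is compared with
the null selection proportion ``p0`` (0.25 under the third-quartile rule)
by a one-sided test of equal or given proportions — the chi-square test
with continuity correction, as in R's ``prop.test`` — and declared
significant below the Bonferroni-corrected level ``alpha / N`` where ``N``
is the number of network nodes.  Significant features map back to patches,
and patches map to the anatomical regions occupying more than 10% of
their volume in a user-supplied label volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest, norm

from .defaults import ALPHA, NULL_SELECTION_P0, REGION_MIN_FRACTION
from .features import feature_metric, feature_node
from .grid import Box, PatchGrid
from .io import LabelVolume

__all__ = ["AssessmentResult", "proportion_test", "significant_features", "assess_selection", "map_patch_regions"]


@dataclass
class AssessmentResult:
    """Per-feature stability-test results and the patch/region mapping."""

    table: pd.DataFrame            # feature, node, metric, count, p_value, significant
    alpha: float
    n_nodes: int
    p0: float
    rounds: int
    regions: dict[int, list[tuple[str, float]]] = field(default_factory=dict)  # node -> regions

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def significant_nodes(self) -> list[int]:
        return sorted(self.significant["node"].unique().tolist())


def proportion_test(count: int, rounds: int, p0: float = NULL_SELECTION_P0,
                    method: str = "chisq") -> float:
    """One-sided (greater) test of a selection proportion against ``p0``.

    ``method="chisq"`` is the chi-square test of equal or given proportions
    with Yates continuity correction (matching R ``prop.test``);
    ``method="exact"`` is the exact binomial tail, used as an independent
    oracle in the test suite.
    """
    if rounds <= 0:
        raise ValueError("rounds must be positive")
    if not 0 <= count <= rounds:
        raise ValueError("count must lie in [0, rounds]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if method == "exact":
        return float(binomtest(count, rounds, p0, alternative="greater").pvalue)
    if method != "chisq":
        raise ValueError(f"unknown method {method!r}")
    num = count - rounds * p0
    yates = min(0.5, abs(num))
    z = np.sign(num) * (abs(num) - yates) / np.sqrt(rounds * p0 * (1 - p0))
    return float(norm.sf(z))


def significant_features(counts: pd.Series, rounds: int, alpha: float = ALPHA,
                         n_nodes: int = 1, p0: float = NULL_SELECTION_P0,
                         method: str = "chisq") -> pd.DataFrame:
    """Stability table for all features; Bonferroni divisor is the node count N."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    pvals = np.array([proportion_test(int(c), rounds, p0, method) for c in counts])
    tab = pd.DataFrame({
        "feature": counts.index,
        "node": [feature_node(nm) for nm in counts.index],
        "metric": [feature_metric(nm) for nm in counts.index],
        "count": counts.to_numpy(dtype=int),
        "p_value": pvals,
        "significant": pvals < alpha / n_nodes,
    }).reset_index(drop=True)
    return tab


def assess_selection(counts: pd.Series, rounds: int, n_nodes: int,
                     alpha: float = ALPHA, p0: float = NULL_SELECTION_P0,
                     grid: PatchGrid | None = None, label_volume: LabelVolume | None = None,
                     region_min_fraction: float = REGION_MIN_FRACTION) -> AssessmentResult:
    """Full assessment: proportion tests, Bonferroni, optional region naming."""
    tab = significant_features(counts, rounds, alpha, n_nodes, p0)
    res = AssessmentResult(table=tab, alpha=alpha, n_nodes=n_nodes, p0=p0, rounds=rounds)
    if grid is not None and label_volume is not None:
        for node in res.significant_nodes:
            res.regions[node] = map_patch_regions(grid.boxes[node], label_volume, region_min_fraction)
    return res


def map_patch_regions(patch_box: Box, label_volume: LabelVolume,
                      min_fraction: float = REGION_MIN_FRACTION) -> list[tuple[str, float]]:
    """Regions occupying strictly more than ``min_fraction`` of the patch.

    Fractions are labeled voxels of the region inside the box over the
    patch volume; code 0 (unlabeled) is ignored; result sorted by fraction
    descending.
    """
    sub = label_volume.data[patch_box.slices]
    V = sub.size
    codes, counts = np.unique(sub, return_counts=True)
    out = []
    for code, n in zip(codes, counts):
        if code == 0:
            continue
        frac = n / V
        if frac > min_fraction:
            out.append((label_volume.lut[int(code)], float(frac)))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out
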