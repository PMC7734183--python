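"""Homologous patch grids over a shared volume space.

A *patch* is an axis-aligned parallelepiped of exactly ``V`` voxels.  All
subjects share one grid per scale, so patch ``i`` samples the same anatomy
in every co-registered volume and can serve as a network node.  The tiling
is anchored at the medial sagittal plane (x is the left-right axis) so each
hemisphere is covered by an equal number of boxes; on y and z the grid
starts at voxel 0.  Incomplete boundary boxes are dropped: nodes must be
homologous full-size patches.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .defaults import BRAIN_FRACTION_MIN

log = logging.getLogger(__name__)

__all__ = ["PatchShape", "Box", "PatchGrid", "choose_patch_shape", "build_grid", "apply_mask", "make_grid"]


@dataclass(frozen=True)
class PatchShape:
    """Edge lengths of a patch in voxels; ``V = dx*dy*dz``."""

    dx: int
    dy: int
    dz: int

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) < 1:
            raise ValueError("patch dimensions must be positive")

    @property
    def V(self) -> int:
        return self.dx * self.dy * self.dz

    @property
    def dims(self) -> tuple[int, int, int]:
        return (self.dx, self.dy, self.dz)


@dataclass(frozen=True)
class Box:
    """Half-open voxel box ``[x0,x1) x [y0,y1) x [z0,z1)``."""

    x0: int
    x1: int
    y0: int
    y1: int
    z0: int
    z1: int

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(self.x0, self.x1), slice(self.y0, self.y1), slice(self.z0, self.z1))

    @property
    def n_voxels(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0) * (self.z1 - self.z0)

    @property
    def center(self) -> tuple[float, float, float]:
        return ((self.x0 + self.x1 - 1) / 2, (self.y0 + self.y1 - 1) / 2, (self.z0 + self.z1 - 1) / 2)


@dataclass
class PatchGrid:
    """The shared tiling at one scale, with per-patch brain fractions.

    ``boxes`` is the full ordered tiling; after :func:`apply_mask`,
    ``valid`` marks the boxes whose brain fraction is at least
    ``BRAIN_FRACTION_MIN`` and ``node_ids`` indexes them.  Node order is
    identical for every subject at a given scale.
    """

    shape: PatchShape
    volume_shape: tuple[int, int, int]
    boxes: list[Box]
    brain_fraction: np.ndarray | None = None
    valid: np.ndarray | None = None

    @property
    def n_boxes(self) -> int:
        return len(self.boxes)

    @property
    def n_nodes(self) -> int:
        if self.valid is None:
            return len(self.boxes)
        return int(self.valid.sum())

    @property
    def node_ids(self) -> np.ndarray:
        """Indices (into ``boxes``) of the valid patches, in box order."""
        if self.valid is None:
            return np.arange(len(self.boxes))
        return np.flatnonzero(self.valid)

    @property
    def valid_boxes(self) -> list[Box]:
        return [self.boxes[i] for i in self.node_ids]

    def to_json(self) -> str:
        d = {
            "patch_shape": self.shape.dims,
            "volume_shape": list(self.volume_shape),
            "boxes": [[b.x0, b.x1, b.y0, b.y1, b.z0, b.z1] for b in self.boxes],
            "brain_fraction": None if self.brain_fraction is None else self.brain_fraction.tolist(),
            "valid": None if self.valid is None else self.valid.astype(int).tolist(),
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PatchGrid":
        d = json.loads(text)
        return cls(
            shape=PatchShape(*d["patch_shape"]),
            volume_shape=tuple(d["volume_shape"]),
            boxes=[Box(*b) for b in d["boxes"]],
            brain_fraction=None if d["brain_fraction"] is None else np.asarray(d["brain_fraction"], float),
            valid=None if d["valid"] is None else np.asarray(d["valid"], bool),
        )


def _factor_triples(V: int):
    for a in range(1, V + 1):
        if V % a:
            continue
        rest = V // a
        for b in range(1, rest + 1):
            if rest % b:
                continue
            yield (a, b, rest // b)


def choose_patch_shape(V: int) -> PatchShape:
    """Most isotropic factorization of ``V`` into box edge lengths.

    Among all ordered factor triples of ``V`` the one minimizing the aspect
    ratio (max edge / min edge) is returned, ties broken by the
    lexicographically smallest triple; cubes are returned exactly when ``V``
    is a perfect cube (e.g. V=1000 -> 10x10x10).
    """
    if V < 1:
        raise ValueError("V must be >= 1")
    best = min(_factor_triples(V), key=lambda t: (max(t) / min(t), t))
    if max(best) / min(best) > 4:
        log.warning("patch volume %d admits only extreme aspect ratios; using %s", V, best)
    return PatchShape(*best)


def build_grid(volume_shape: Sequence[int], patch_shape: PatchShape) -> PatchGrid:
    """Tile the volume with full-size patches anchored at the midplane.

    The x tiling grows outward from the medial sagittal plane at
    ``floor(X/2)`` in both directions; y and z tile from voxel 0 upward.
    Only complete boxes are kept, so thin slabs at the volume boundary are
    uncovered.  For even ``X`` the box multiset is mirror symmetric about
    the midplane (homologous left/right patches).
    """
    X, Y, Z = (int(s) for s in volume_shape)
    dx, dy, dz = patch_shape.dims
    for name, d, s in (("x", dx, X), ("y", dy, Y), ("z", dz, Z)):
        if d > s:
            raise ValueError(f"patch {name}-extent {d} exceeds volume {name}-dimension {s}")
    if X < 2 * dx:
        raise ValueError(f"volume x-dimension {X} cannot hold one patch per hemisphere (needs >= {2 * dx})")

    mid = X // 2
    x_starts = sorted(
        [x for x in range(mid, X - dx + 1, dx)] + [x for x in range(mid - dx, -1, -dx)]
    )
    y_starts = range(0, Y - dy + 1, dy)
    z_starts = range(0, Z - dz + 1, dz)
    boxes = [
        Box(x, x + dx, y, y + dy, z, z + dz)
        for x in x_starts
        for y in y_starts
        for z in z_starts
    ]
    return PatchGrid(shape=patch_shape, volume_shape=(X, Y, Z), boxes=boxes)


def apply_mask(grid: PatchGrid, mask: np.ndarray, brain_fraction_min: float = BRAIN_FRACTION_MIN) -> PatchGrid:
    """Decide patch validity from the brain mask.

    A patch is a node iff its non-brain fraction does not exceed
    ``1 - brain_fraction_min`` (strictly more non-brain excludes it, so a
    patch at exactly the boundary is kept).  The comparison is done on
    integer voxel counts to avoid float-boundary surprises.
    """
    if mask.shape != grid.volume_shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {grid.volume_shape}")
    m = np.asarray(mask).astype(bool)
    V = grid.shape.V
    counts = np.array([int(m[b.slices].sum()) for b in grid.boxes])
    # valid  <=>  brain_count/V >= brain_fraction_min, exact in integers
    thr_num = round(brain_fraction_min * 1000)
    valid = counts * 1000 >= thr_num * V
    if not valid.any():
        raise ValueError("no patch reaches the minimum brain fraction; mask and grid are incompatible")
    return PatchGrid(
        shape=grid.shape,
        volume_shape=grid.volume_shape,
        boxes=list(grid.boxes),
        brain_fraction=counts / V,
        valid=valid,
    )


def make_grid(volume_shape: Sequence[int], V: int, mask: np.ndarray | None = None,
              brain_fraction_min: float = BRAIN_FRACTION_MIN) -> PatchGrid:
    """Convenience: choose a patch shape for ``V``, tile, and apply the mask."""
    g = build_grid(volume_shape, choose_patch_shape(V))
    if mask is not None:
        g = apply_mask(g, mask, brain_fraction_min)
    return g


def central_patches(grid: PatchGrid, n: int) -> list[int]:
    """Indices (into ``grid.boxes``) of the ``n`` valid patches nearest the volume center.

    Deterministic helper used to plant effects well inside the brain mask.
    """
    c = np.asarray(grid.volume_shape, float) / 2
    ids = grid.node_ids
    d = [float(np.linalg.norm(np.asarray(grid.boxes[i].center) - c)) for i in ids]
    order = np.lexsort((ids, np.asarray(d)))
    return [int(ids[j]) for j in order[:n]]
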