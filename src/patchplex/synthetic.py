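"""Phantom cohorts of co-registered 3D volumes with known planted effects.

The generator emulates what the pipeline assumes of real data: a cohort of
skull-stripped, intensity-normalized volumes all in one space, two clinical
groups, and group-specific structural alterations confined to known
patches.  A shared template provides the anatomy-like intensity pattern;
each subject adds i.i.d. Gaussian noise inside the brain mask, and case
subjects additionally carry the planted effect (a mean shift, or a
decorrelation that replaces a patch's texture with an independent smooth
field of matched mean and variance — the patch-level analogue of focal
edema or hemorrhage wiping out normal tissue texture).

The template is a sum of two zero-mean smooth Gaussian random fields: a
fine texture (kernel width 2 voxels) and a coarse component (kernel width
~ one fifth of the smallest volume edge, weight 3) standing in for global
tissue-intensity structure.  The coarse component is what gives distinct
patches correlated intensity profiles, so control-group networks have
supra-threshold links for the planted decorrelation to destroy.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import Box, PatchShape, build_grid, central_patches  # noqa: F401 (re-exported helper)

__all__ = ["CohortSpec", "SyntheticCohort", "make_template", "simulate_subject", "simulate_cohort", "save_cohort"]

_FINE_SIGMA = 2.0
_COARSE_WEIGHT = 3.0
#: Kernel width of the decorrelation replacement texture. Finer than the
#: template texture so the replaced patch spans many independent dimensions
#: and its spurious correlation with intact patches stays below the link
#: threshold — disordered tissue rather than smooth anatomy.
_REPL_SIGMA = 1.0

_EFFECT_KINDS = ("mean_shift", "decorrelate")
_MASK_KINDS = ("ellipsoid", "full")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of one phantom cohort.

    ``effect_patches`` are indices into the full box list of the grid that
    ``patch_shape`` implies on ``volume_shape``; ``effect_magnitude`` is in
    units of the template's intensity SD inside the mask (for
    ``decorrelate`` it is capped at 1 = full texture replacement).
    """

    volume_shape: tuple[int, int, int] = (40, 40, 40)
    patch_shape: tuple[int, int, int] = (8, 8, 8)
    mask_kind: str = "ellipsoid"
    n_control: int = 15
    n_case: int = 15
    effect_patches: tuple[int, ...] = ()
    effect_kind: str = "decorrelate"
    effect_magnitude: float = 0.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.effect_magnitude < 0:
            raise ValueError("effect_magnitude must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.mask_kind not in _MASK_KINDS:
            raise ValueError(f"unknown mask_kind {self.mask_kind!r}")
        if self.effect_kind not in _EFFECT_KINDS:
            raise ValueError(f"unknown effect_kind {self.effect_kind!r}")
        n_boxes = len(build_grid(self.volume_shape, PatchShape(*self.patch_shape)).boxes)
        bad = [i for i in self.effect_patches if not (0 <= i < n_boxes)]
        if bad:
            raise ValueError(f"effect_patches {bad} outside the {n_boxes}-box grid")

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_case


@dataclass
class SyntheticCohort:
    volumes: list[np.ndarray]
    mask: np.ndarray
    labels: np.ndarray            # 0 = control/seizure-free, 1 = case/seizure-affected
    truth: list[int]              # planted patch indices (full-grid box indices)
    spec: CohortSpec
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:03d}" for i in range(len(self.volumes))]


def _smooth_field(rng: np.random.Generator, shape: Sequence[int], sigma: float) -> np.ndarray:
    """Unit-SD smooth Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(tuple(shape)), sigma, mode="nearest")
    return f / f.std()


def _smooth_patch(rng: np.random.Generator, shape: Sequence[int], sigma: float) -> np.ndarray:
    """Smooth field for a small box, generated on a padded support.

    Filtering directly inside a box a few voxels wide would let the kernel's
    boundary handling dominate and produce a near-rank-one blob; padding by
    3*sigma and cropping keeps the texture statistics of an interior crop of
    a large field.
    """
    pad = int(np.ceil(3 * sigma))
    big = gaussian_filter(rng.standard_normal(tuple(s + 2 * pad for s in shape)), sigma, mode="nearest")
    crop = big[tuple(slice(pad, pad + s) for s in shape)]
    return crop / crop.std()


def make_template(volume_shape: Sequence[int], mask_kind: str = "ellipsoid",
                  seed: int | np.random.SeedSequence = 0) -> tuple[np.ndarray, np.ndarray]:
    """Shared template volume and brain mask.

    The mask is mirror symmetric about the medial sagittal plane (and the
    other midplanes); the template is standardized to mean 0 / SD 1 inside
    the mask and exactly zero outside, reproducible from ``seed``.
    """
    shape = tuple(int(s) for s in volume_shape)
    for ax, s in enumerate(shape):
        if s < 8:
            raise ValueError(f"axis {ax} has size {s}; each dimension must be >= 8 voxels")
    if mask_kind not in _MASK_KINDS:
        raise ValueError(f"unknown mask_kind {mask_kind!r}")

    if mask_kind == "full":
        mask = np.ones(shape, dtype=bool)
    else:
        center = (np.asarray(shape) - 1) / 2
        semi = 0.45 * np.asarray(shape)
        gx, gy, gz = np.ogrid[: shape[0], : shape[1], : shape[2]]
        q = (((gx - center[0]) / semi[0]) ** 2
             + ((gy - center[1]) / semi[1]) ** 2
             + ((gz - center[2]) / semi[2]) ** 2)
        mask = q <= 1.0

    rng = np.random.default_rng(seed)
    fine = _smooth_field(rng, shape, _FINE_SIGMA)
    coarse = _smooth_field(rng, shape, max(min(shape) / 5, _FINE_SIGMA))
    template = fine + _COARSE_WEIGHT * coarse
    inside = template[mask]
    template = (template - inside.mean()) / inside.std()
    template[~mask] = 0.0
    return template, mask


def simulate_subject(template: np.ndarray, mask: np.ndarray, group: int,
                     effect_patches: Sequence[Box], effect_kind: str, effect_magnitude: float,
                     noise_sd: float, seed: int | np.random.SeedSequence) -> np.ndarray:
    """One subject's volume: template + noise (+ planted effect for cases).

    ``mean_shift`` adds ``effect_magnitude * template_SD`` to the masked
    voxels of each effect patch (a pure intensity offset); ``decorrelate``
    replaces a fraction ``min(effect_magnitude, 1)`` of the patch's
    variance with an independent width-2 smooth field matched in mean and
    SD, so the patch keeps its intensity statistics but loses its
    correlation with the rest of the brain.
    """
    if template.shape != mask.shape:
        raise ValueError("template and mask must share a shape")
    if effect_kind not in _EFFECT_KINDS:
        raise ValueError(f"unknown effect_kind {effect_kind!r}")
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask).astype(bool)
    signal = np.array(template, float, copy=True)

    if group == 1 and effect_magnitude > 0:
        t_sd = template[mask].std()
        for box in effect_patches:
            sl = box.slices
            sub = signal[sl]
            inb = mask[sl]
            if not inb.any():
                continue
            if effect_kind == "mean_shift":
                sub[inb] += effect_magnitude * t_sd
            else:  # decorrelate
                lam = min(effect_magnitude, 1.0)
                vals = sub[inb]
                m, sd = vals.mean(), vals.std()
                repl = _smooth_patch(rng, sub.shape, _REPL_SIGMA)[inb]
                repl = (repl - repl.mean()) / repl.std() * sd
                # independent fields: sqrt weights preserve the patch variance
                sub[inb] = m + np.sqrt(1 - lam) * (vals - m) + np.sqrt(lam) * repl

    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=template.shape)
        signal[mask] += noise[mask]
    return signal


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Deterministic cohort from ``spec``.

    The template stream and each subject's stream are derived by hashing
    ``(spec.seed, index)`` through :class:`numpy.random.SeedSequence`, so
    subjects are independent and reproducible regardless of evaluation
    order.  Controls come first, then cases.
    """
    template, mask = make_template(spec.volume_shape, spec.mask_kind, np.random.SeedSequence((spec.seed, 0)))
    boxes = build_grid(spec.volume_shape, PatchShape(*spec.patch_shape)).boxes
    effect_boxes = [boxes[i] for i in spec.effect_patches]
    labels = np.array([0] * spec.n_control + [1] * spec.n_case)
    volumes = [
        simulate_subject(template, mask, int(g), effect_boxes, spec.effect_kind,
                         spec.effect_magnitude, spec.noise_sd, np.random.SeedSequence((spec.seed, i + 1)))
        for i, g in enumerate(labels)
    ]
    return SyntheticCohort(volumes=volumes, mask=mask, labels=labels,
                           truth=list(spec.effect_patches), spec=spec)


def save_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write the cohort as gzipped NIfTI + labels CSV + truth JSON."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for sid, vol in zip(cohort.subject_ids, cohort.volumes):
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), outdir / f"{sid}.nii.gz")
    nib.save(nib.Nifti1Image(cohort.mask.astype(np.uint8), affine), outdir / "mask.nii.gz")
    with open(outdir / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "group"])
        for sid, g in zip(cohort.subject_ids, cohort.labels):
            w.writerow([sid, int(g)])
    with open(outdir / "truth.json", "w") as fh:
        json.dump({"effect_patches": cohort.truth, "spec": asdict(cohort.spec)}, fh, indent=2, sort_keys=True)
    return outdir
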