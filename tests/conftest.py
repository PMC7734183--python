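import numpy as np
import pytest

import patchplex as pp

#: Study conditions of the desk-scale phantom experiment: 40^3 volumes,
#: ellipsoid mask, 512-voxel patches, 15 controls vs 15 cases with a strong
#: decorrelation planted in 3 central patches, 100 CV rounds.
PHANTOM_SEED = 11
PHANTOM_ROUNDS = 100
PHANTOM_SCALE = 512
PHANTOM_MAGNITUDE = 3.0


def random_layer(rng: np.random.Generator, n: int = 8, p_edge: float = 0.5,
                 subject_id: str = "toy") -> pp.LayerNetwork:
    """Random weighted layer: edges i.i.d. present with weight in [0.3, 1]."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                W[i, j] = W[j, i] = rng.uniform(0.3, 1.0)
    return pp.LayerNetwork(subject_id=subject_id, weights=W, node_ids=np.arange(n))


def layer_from_weights(W: np.ndarray, subject_id: str = "toy") -> pp.LayerNetwork:
    W = np.asarray(W, float)
    return pp.LayerNetwork(subject_id=subject_id, weights=W, node_ids=np.arange(W.shape[0]))


def planted_spec(seed: int = PHANTOM_SEED, magnitude: float = PHANTOM_MAGNITUDE) -> pp.CohortSpec:
    """Cohort spec with 3 effect patches planted at the central valid nodes."""
    base = pp.CohortSpec(seed=seed)
    _, mask = pp.make_template(base.volume_shape, base.mask_kind, np.random.SeedSequence((seed, 0)))
    grid = pp.make_grid(mask.shape, PHANTOM_SCALE, mask)
    planted = tuple(pp.central_patches(grid, 3))
    return pp.CohortSpec(effect_patches=planted, effect_kind="decorrelate",
                         effect_magnitude=magnitude, seed=seed)


@pytest.fixture(scope="session")
def strong_run():
    """Full pipeline on the strong-effect phantom (slow; shared across tests)."""
    spec = planted_spec()
    cohort = pp.simulate_cohort(spec)
    config = pp.PipelineConfig(scales=(PHANTOM_SCALE,), rounds=PHANTOM_ROUNDS, seed=PHANTOM_SEED)
    result = pp.run_single_scale(cohort.volumes, cohort.labels, cohort.mask, PHANTOM_SCALE, config)
    return cohort, result


@pytest.fixture(scope="session")
def null_run():
    """Full pipeline on the same phantom with no planted effect."""
    spec = pp.CohortSpec(effect_magnitude=0.0, seed=PHANTOM_SEED)
    cohort = pp.simulate_cohort(spec)
    config = pp.PipelineConfig(scales=(PHANTOM_SCALE,), rounds=PHANTOM_ROUNDS, seed=PHANTOM_SEED)
    result = pp.run_single_scale(cohort.volumes, cohort.labels, cohort.mask, PHANTOM_SCALE, config)
    return cohort, result


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small fast cohort (16^3 volumes, 4+4 subjects) for plumbing tests."""
    spec = pp.CohortSpec(volume_shape=(16, 16, 16), patch_shape=(4, 4, 4), mask_kind="full",
                         n_control=4, n_case=4, effect_patches=(10,), effect_kind="decorrelate",
                         effect_magnitude=1.0, noise_sd=0.2, seed=5)
    return pp.simulate_cohort(spec)
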