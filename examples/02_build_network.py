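"""Build a subject's patch network and the cohort multiplex.

Each subject's layer links two patches when the absolute Pearson
correlation of their voxel intensity vectors reaches 0.3; the multiplex
degree k_multi counts the partners a node has in at least one subject.
"""

import numpy as np

import patchplex as pp

spec = pp.CohortSpec(volume_shape=(24, 24, 24), patch_shape=(8, 8, 8), mask_kind="full",
                     n_control=4, n_case=4, seed=7)
cohort = pp.simulate_cohort(spec)

# shared grid at a patch volume of 512 voxels; patches must be >= 90% brain
grid = pp.make_grid(cohort.mask.shape, 512, cohort.mask)
print(f"grid: {grid.n_boxes} boxes of {grid.shape.dims}, {grid.n_nodes} valid nodes")

layers = [pp.build_layer(v, grid, f"sub-{i:03d}") for i, v in enumerate(cohort.volumes)]
lay = layers[0]
print(f"subject 0: {len(lay.edge_list())} edges, "
      f"mean degree {lay.degree.mean():.1f}, mean strength {lay.weights.sum(1).mean():.2f}")

multiplex = pp.assemble_multiplex(layers)
print(f"multiplex over {multiplex.n_layers} layers: "
      f"k_multi range {multiplex.k_multi.min()}..{multiplex.k_multi.max()}")
# k_multi always dominates any single layer's degree (it is a union of edge sets):
assert np.all(multiplex.k_multi >= np.max([l.degree for l in layers], axis=0))
print("k_multi >= every single-layer degree: True")
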