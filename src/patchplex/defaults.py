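"""Canonical numeric defaults of the pipeline.

Every threshold or size the method fixes appears here exactly once; the
rest of the package and the CLI default to these names.
"""

#: Minimum |Pearson r| for a link to be kept in a layer network.
EDGE_THRESHOLD = 0.3

#: Minimum brain fraction of a patch for it to become a network node
#: (patches whose non-brain fraction strictly exceeds 10% are excluded).
BRAIN_FRACTION_MIN = 0.9

#: Feature columns whose pairwise correlation strictly exceeds this are
#: reduced to the first of the pair.
CORR_FILTER = 0.95

#: Quantile of the importance distribution a feature must strictly exceed
#: to be selected in a cross-validation round (third quartile).
IMPORTANCE_QUANTILE = 0.75

#: Trees per random forest.
N_TREES = 500

#: Fraction of each (balanced) class used for training in a round.
TRAIN_FRACTION = 0.8

#: Cross-validation rounds.
CV_ROUNDS = 1000

#: Family-wise significance level before Bonferroni correction.
ALPHA = 0.05

#: Null selection proportion for the feature-stability test: under the
#: third-quartile rule a feature is selected in a quarter of rounds by chance.
NULL_SELECTION_P0 = 0.25

#: Minimum fraction of a patch an anatomical region must occupy (strictly)
#: to be reported for that patch.
REGION_MIN_FRACTION = 0.10

#: Patch volumes (voxels) swept at full scale.
SCALES = tuple(range(1000, 8001, 1000))
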