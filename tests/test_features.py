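"""Nodal metrics, multiplex weighting, feature matrix assembly and filtering."""

import numpy as np
import pandas as pd
import pytest

import patchplex as pp
from patchplex.features import DroppedFeature, METRIC_ORDER, feature_metric, feature_node

from conftest import layer_from_weights, random_layer


def naive_layer_features(W):
    """Independent double-loop oracle for strength, IPR and conditional means."""
    n = W.shape[0]
    k = np.array([sum(W[i, j] > 0 for j in range(n)) for i in range(n)])
    s = np.array([sum(W[i, j] for j in range(n)) for i in range(n)])
    y = np.zeros(n)
    for i in range(n):
        if s[i] > 0:
            y[i] = sum((W[i, j] / s[i]) ** 2 for j in range(n))
    s_cond = np.zeros(n)
    y_cond = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if k[j] == k[i]]
        s_cond[i] = sum(s[j] for j in same) / len(same)
        y_cond[i] = sum(y[j] for j in same) / len(same)
    return k, s, y, s_cond, y_cond


class TestLayerFeatures:
    def test_uniform_weights_saturate_ipr_bound(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = 0.5
        lf = pp.layer_features(layer_from_weights(W))
        assert lf.s[0] == pytest.approx(1.0)
        assert lf.y[0] == pytest.approx(0.5)
        assert 1 / lf.y[0] == pytest.approx(lf.k[0])  # == degree for uniform weights

    def test_skewed_weights_formula(self):
        # illustrative weights ignoring the 0.3 floor: y = 0.81 + 0.01
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.9
        W[0, 2] = W[2, 0] = 0.1
        lf = pp.layer_features(layer_from_weights(W))
        assert lf.s[0] == pytest.approx(1.0)
        assert lf.y[0] == pytest.approx(0.82)

    def test_conditional_mean_by_degree_class(self):
        # degrees (2,2,1), strengths (0.8,1.2,0.3) -> s_cond (1.0,1.0,0.3)
        from patchplex.features import _conditional_mean
        out = _conditional_mean(np.array([0.8, 1.2, 0.3]), np.array([2, 2, 1]))
        assert out.tolist() == pytest.approx([1.0, 1.0, 0.3])

    def test_conditional_mean_structure_on_layer(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = 0.3
        lf = pp.layer_features(layer_from_weights(W))
        assert lf.k.tolist() == [2, 1, 1]
        assert lf.s_cond[0] == pytest.approx(lf.s[0])
        assert lf.s_cond[1] == lf.s_cond[2] == pytest.approx((lf.s[1] + lf.s[2]) / 2)

    def test_matches_naive_oracle_on_random_layers(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            lay = random_layer(rng, n=8)
            lf = pp.layer_features(lay)
            k, s, y, sc, yc = naive_layer_features(lay.weights)
            assert np.allclose(lf.k, k)
            for got, want in ((lf.s, s), (lf.y, y), (lf.s_cond, sc), (lf.y_cond, yc)):
                assert np.max(np.abs(got - want)) < 1e-12

    def test_conservation_of_strength_over_degree_classes(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            lay = random_layer(rng, n=10, p_edge=0.4)
            lf = pp.layer_features(lay)
            # sum over degree classes of N_k * s(k) recovers total strength
            total = sum(int((lf.k == k).sum()) * lf.s_cond[lf.k == k][0] for k in np.unique(lf.k))
            assert total == pytest.approx(lf.s.sum(), abs=1e-12)


class TestMultiplexFeatures:
    def test_complete_multiplex_reduces_to_single_layer(self):
        rng = np.random.default_rng(2)
        lay = random_layer(rng, n=5, p_edge=1.0)
        lf = pp.layer_features(lay)
        k_multi = np.full(5, 4)
        mS, mY, _, _ = pp.multiplex_features(lf, k_multi)
        assert np.allclose(mS, lf.s)
        assert np.allclose(mY, lf.y)

    def test_isolated_node_zeroed(self):
        rng = np.random.default_rng(3)
        lay = random_layer(rng, n=5)
        lf = pp.layer_features(lay)
        k_multi = np.array([4, 3, 0, 2, 1])
        mS, mY, _, _ = pp.multiplex_features(lf, k_multi)
        assert mS[2] == 0 and mY[2] == 0

    def test_declared_convention_three_nodes(self):
        # k_multi=(2,1,1), s=(0.5,0.5,0.0) -> multiS=(0.5,0.25,0.0), multiSc=(0.5,0.25,0.25)
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        lf = pp.layer_features(layer_from_weights(W))
        assert lf.s.tolist() == [0.5, 0.5, 0.0]
        mS, _, mSc, _ = pp.multiplex_features(lf, np.array([2, 1, 1]))
        assert mS.tolist() == pytest.approx([0.5, 0.25, 0.0])
        assert mSc.tolist() == pytest.approx([0.5, 0.25, 0.25])

    def test_single_node_errors(self):
        lf = pp.layer_features(layer_from_weights(np.zeros((1, 1))))
        with pytest.raises(ValueError, match="2 nodes"):
            pp.multiplex_features(lf, np.array([0]))


class TestIPRBound:
    def test_bound_holds_on_random_layers(self):
        """1 <= 1/y_i <= k_i for every connected node; equality at k_i iff
        the node's weights are uniform."""
        rng = np.random.default_rng(4)
        for _ in range(100):
            lay = random_layer(rng, n=8)
            lf = pp.layer_features(lay)
            for i in range(8):
                if lf.k[i] >= 1:
                    inv = 1 / lf.y[i]
                    assert 1 - 1e-9 <= inv <= lf.k[i] + 1e-9
                    w = lay.weights[i][lay.weights[i] > 0]
                    if np.ptp(w) < 1e-12:
                        assert inv == pytest.approx(lf.k[i], abs=1e-9)
                    elif np.ptp(w) > 1e-6:
                        assert inv < lf.k[i]


class TestFeatureMatrix:
    def _multiplex(self, n_subjects=5, n=8, seed=5):
        rng = np.random.default_rng(seed)
        layers = [random_layer(rng, n=n, subject_id=f"s{i}") for i in range(n_subjects)]
        return pp.assemble_multiplex(layers)

    def test_shape_is_8N(self):
        fm = pp.build_feature_matrix(self._multiplex())
        assert fm.values.shape == (5, 64)

    def test_names_unique_and_block_ordered(self):
        fm = pp.build_feature_matrix(self._multiplex())
        assert len(set(fm.feature_names)) == 64
        metrics = [feature_metric(nm) for nm in fm.feature_names]
        assert metrics == [m for m in METRIC_ORDER for _ in range(8)]
        assert feature_node(fm.feature_names[0]) == 0

    def test_identical_subjects_identical_rows(self):
        rng = np.random.default_rng(6)
        lay = random_layer(rng, n=6)
        layers = [pp.LayerNetwork(f"s{i}", lay.weights.copy(), lay.node_ids) for i in range(3)]
        fm = pp.build_feature_matrix(pp.assemble_multiplex(layers))
        assert np.array_equal(fm.values.iloc[0].to_numpy(), fm.values.iloc[1].to_numpy())


class TestFilterFeatures:
    def _fm(self, cols):
        return pp.FeatureMatrix(values=pd.DataFrame(cols))

    def test_constant_zero_column_dropped(self):
        rng = np.random.default_rng(7)
        fm = self._fm({"S_n0000": np.zeros(5), "S_n0001": rng.normal(size=5)})
        out = pp.filter_features(fm)
        assert out.feature_names == ["S_n0001"]
        assert out.dropped[0].reason == "null_mean_variance"

    def test_duplicate_column_dropped_with_partner(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=6)
        fm = self._fm({"S_n0000": a, "Y_n0000": a.copy(), "S_n0001": rng.normal(size=6)})
        out = pp.filter_features(fm)
        assert out.feature_names == ["S_n0000", "S_n0001"]
        d = [d for d in out.dropped if d.reason == "high_correlation"]
        assert d[0].name == "Y_n0000" and d[0].partner == "S_n0000"

    def test_correlation_below_threshold_kept(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=200)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=200)  # corr ~ 0.90
        fm = self._fm({"S_n0000": a, "S_n0001": b})
        out = pp.filter_features(fm)
        assert len(out.feature_names) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=8)
        fm = self._fm({"a_n0000": a, "b_n0000": a * 2, "c_n0000": rng.normal(size=8),
                       "d_n0000": np.full(8, 3.0)})
        once = pp.filter_features(fm)
        twice = pp.filter_features(once)
        assert once.feature_names == twice.feature_names
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_dropped_errors(self):
        fm = self._fm({"a_n0000": np.zeros(5), "b_n0000": np.ones(5)})
        with pytest.raises(ValueError, match="all features"):
            pp.filter_features(fm)

    def test_too_few_subjects_errors(self):
        fm = self._fm({"a_n0000": np.array([1.0, 2.0])})
        with pytest.raises(ValueError, match="3 subjects"):
            pp.filter_features(fm)
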