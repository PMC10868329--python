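"""Neighbor feature fusion: relation coding, attention pieces, full layer."""

import numpy as np
import pytest

from _oracles import nff_layer_loop
from ngmda import autodiff as ad
from ngmda.nff import (NFFLayer, NFFStack, fused_attention,
                       position_topology_importance, relation_type_matrix,
                       relationship_type, similarity_attention_score)


class TestRelationshipType:
    @pytest.mark.parametrize("target,source,expected", [
        ("drug", "drug", 0),
        ("microbe", "drug", 1),
        ("drug", "microbe", 2),
        ("microbe", "microbe", 3),
    ])
    def test_coding(self, target, source, expected):
        assert relationship_type(target, source) == expected

    def test_unknown_type(self):
        with pytest.raises(ValueError):
            relationship_type("drug", "gene")

    def test_matrix_matches_scalar(self):
        types = np.array([0, 0, 1, 1])
        psi = relation_type_matrix(types)
        for i in range(4):
            for j in range(4):
                assert psi[i, j] == relationship_type(int(types[i]), int(types[j]))


class TestAttentionScore:
    def test_zero_key_gives_zero(self):
        rng = np.random.default_rng(0)
        s = similarity_attention_score(rng.random(3), np.zeros(3),
                                       rng.random((3, 4)), np.zeros((3, 4)),
                                       rng.random((4, 4)))
        assert s == 0.0

    def test_bounded_by_one(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            s = similarity_attention_score(
                rng.standard_normal(5), rng.standard_normal(5),
                rng.standard_normal((5, 6)), rng.standard_normal((5, 6)),
                rng.standard_normal((6, 6)))
            assert abs(s) <= 1.0 + 1e-12


class TestStructuralImportance:
    def test_extremes_and_arithmetic(self):
        v = np.array([1.0, 0.0])
        assert position_topology_importance(v, v, v, v, 0.4) == pytest.approx(1.0)
        assert position_topology_importance(v, -v, v, -v, 0.4) == pytest.approx(0.0)
        # tau=0.4, cos_posi=1, cos_topo=0 -> 0.7
        w = np.array([0.0, 1.0])
        assert position_topology_importance(v, v, v, w, 0.4) == pytest.approx(0.7)

    def test_zero_norm_contributes_zero(self):
        v = np.array([1.0, 0.0])
        z = np.zeros(2)
        # topo cosine term drops out: c = (0.4*1 + 0 + 1)/2
        assert position_topology_importance(v, v, z, v, 0.4) == pytest.approx(0.7)


class TestFusedAttention:
    def test_singleton_and_symmetry(self):
        s = np.array([[0.3, 0.9], [0.1, 0.2]])
        c = np.ones((2, 2))
        r = np.ones(4)
        psi = np.zeros((2, 2), dtype=int)
        only_self = np.eye(2, dtype=bool)
        a = fused_attention(s, c, r, psi, only_self)
        np.testing.assert_allclose(np.diag(a), 1.0)
        equal = fused_attention(np.full((2, 2), 0.5), c, r, psi,
                                np.ones((2, 2), dtype=bool))
        np.testing.assert_allclose(equal, np.full((2, 2), 0.5))

    def test_softmax_arithmetic(self):
        # products (ln 2, 0) -> weights (2/3, 1/3)
        s = np.array([[np.log(2.0), 0.0]])
        a = fused_attention(s, np.ones((1, 2)), np.ones(4),
                            np.zeros((1, 2), dtype=int), np.ones((1, 2), dtype=bool))
        np.testing.assert_allclose(a[0], [2 / 3, 1 / 3])

    def test_empty_neighbor_set_rejected(self):
        with pytest.raises(ValueError):
            fused_attention(np.zeros((1, 1)), np.ones((1, 1)), np.ones(4),
                            np.zeros((1, 1), dtype=int),
                            np.zeros((1, 1), dtype=bool))


def _random_problem(rng, n_drugs=3, n_microbes=3, embed_dim=8, heads=2):
    n = n_drugs + n_microbes
    node_types = np.array([0] * n_drugs + [1] * n_microbes)
    mask = rng.random((n, n)) < 0.5
    np.fill_diagonal(mask, True)
    mask |= mask.T
    reps = {
        "simi": rng.standard_normal((n, embed_dim)),
        "posi": rng.random((n, n)),
        "topo": rng.random((n, 2)),
    }
    layer = NFFLayer({"simi": embed_dim, "posi": n, "topo": 2}, embed_dim,
                     heads, rng)
    layer.rel_weights.data[:] = rng.random(4) + 0.5
    return layer, reps, mask, node_types


class TestLayer:
    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(42)
        layer, reps, mask, node_types = _random_problem(rng)
        tau = 0.4
        expected, c_expected = nff_layer_loop(layer, reps, mask, node_types, tau)
        out = layer.forward({k: ad.Tensor(v) for k, v in reps.items()},
                            mask, relation_type_matrix(node_types),
                            n_drugs=3, tau=tau)
        np.testing.assert_allclose(layer.last_importance, c_expected, atol=1e-10)
        for ch in ("simi", "posi", "topo"):
            np.testing.assert_allclose(out[ch].data, expected[ch], atol=1e-6)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        layer, reps, mask, node_types = _random_problem(rng)
        layer.forward({k: ad.Tensor(v) for k, v in reps.items()}, mask,
                      relation_type_matrix(node_types), n_drugs=3, tau=0.4)
        for ch, attns in layer.last_attention.items():
            for a in attns:
                np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-12)
                assert (a[~mask] == 0).all()

    def test_importance_in_unit_interval_and_symmetric(self):
        rng = np.random.default_rng(8)
        layer, reps, mask, node_types = _random_problem(rng)
        layer.forward({k: ad.Tensor(v) for k, v in reps.items()}, mask,
                      relation_type_matrix(node_types), n_drugs=3, tau=0.4)
        c = layer.last_importance
        assert c.min() >= -1e-12 and c.max() <= 1.0 + 1e-12
        np.testing.assert_allclose(c, c.T, atol=1e-10)

    def test_homogeneous_degenerate_case(self):
        """With r = 1, parallel structural rows (c = 1) and one node type,
        the attention reduces to a plain softmax of the semantic scores."""
        rng = np.random.default_rng(9)
        n, d = 4, 6
        node_types = np.zeros(n, dtype=int)
        mask = np.ones((n, n), dtype=bool)
        reps = {
            "simi": rng.standard_normal((n, d)),
            "posi": np.tile(rng.random(n), (n, 1)),   # identical rows -> cos 1
            "topo": np.tile(rng.random(2), (n, 1)),
        }
        layer = NFFLayer({"simi": d, "posi": n, "topo": 2}, d, 1, rng)
        layer.forward({k: ad.Tensor(v) for k, v in reps.items()}, mask,
                      relation_type_matrix(node_types), n_drugs=n, tau=0.4)
        np.testing.assert_allclose(layer.last_importance, 1.0, atol=1e-12)
        # recompute the plain softmax of s for the simi channel
        w = layer.w_type["simi"][0][0].data
        wp = layer.w_p["simi"][0].data
        transformed = reps["simi"] @ w
        q = np.exp(transformed @ wp - (transformed @ wp).max(axis=1, keepdims=True))
        q /= q.sum(axis=1, keepdims=True)
        keys = transformed / np.linalg.norm(transformed, axis=1, keepdims=True)
        s = q @ keys.T
        e = np.exp(s - s.max(axis=1, keepdims=True))
        np.testing.assert_allclose(layer.last_attention["simi"][0],
                                   e / e.sum(axis=1, keepdims=True), atol=1e-10)


class TestStack:
    def test_layer_zero_holds_inputs_and_shapes(self):
        rng = np.random.default_rng(10)
        n_d, n_m, d = 3, 2, 8
        n = n_d + n_m
        stack = NFFStack(embed_dim=d, n_nodes=n, walk_steps=2, n_layers=2,
                         n_heads=2, rng=rng)
        simi0 = ad.Tensor(rng.standard_normal((n, d)))
        posi0 = ad.Tensor(rng.random((n, n)))
        topo0 = ad.Tensor(rng.random((n, 2)))
        mask = np.ones((n, n), dtype=bool)
        types = np.array([0] * n_d + [1] * n_m)
        reps = stack.forward(simi0, posi0, topo0, mask,
                             relation_type_matrix(types), n_d)
        assert reps.n_layers == 2
        assert reps.simi[0] is simi0 and reps.posi[0] is posi0
        for layer_out in (reps.simi[1], reps.posi[2], reps.topo[1]):
            assert layer_out.shape == (n, d)
            assert np.isfinite(layer_out.data).all()

    def test_relation_weights_fixed_when_disabled(self):
        rng = np.random.default_rng(11)
        stack = NFFStack(embed_dim=4, n_nodes=4, walk_steps=2, n_layers=1,
                         n_heads=1, rng=rng, learn_relations=False)
        assert all(not layer.rel_weights.requires_grad for layer in stack.layers)
        np.testing.assert_array_equal(stack.layers[0].rel_weights.data, 1.0)
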