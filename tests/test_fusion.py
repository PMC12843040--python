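"""Fusion heads: algebraic identities, symmetry, and differentiability."""

import numpy as np
import pytest

from petreid import (
    FusionModel,
    GateHead,
    TextWeight,
    fuse_concat,
    fuse_cross_attention,
    fuse_gated,
    fuse_weighted_text,
)
from petreid.autodiff import Tensor
from petreid.errors import UsageError
from petreid.fusion import CrossAttentionHead


class TestConcat:
    def test_concatenation_order_vision_first(self):
        out = fuse_concat(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))
        np.testing.assert_array_equal(out, [[1.0, 0.0, 0.0, 1.0]])

    def test_zero_text_block(self, rng):
        v = rng.normal(size=(3, 4))
        out = fuse_concat(v, np.zeros((3, 4)))
        np.testing.assert_array_equal(out[:, 4:], 0)
        np.testing.assert_array_equal(out[:, :4], v)

    def test_output_length_contract(self, rng):
        out = fuse_concat(rng.normal(size=(5, 7)), rng.normal(size=(5, 3)))
        assert out.shape == (5, 10)

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(UsageError):
            fuse_concat(rng.normal(size=(2, 4)), rng.normal(size=(3, 4)))


class TestWeightedText:
    def test_unit_weight_equals_concat(self, rng):
        v, t = rng.normal(size=(4, 5)), rng.normal(size=(4, 5))
        w = TextWeight()
        np.testing.assert_array_equal(fuse_weighted_text(v, t, w), fuse_concat(v, t))

    def test_zero_weight_annihilates_text(self, rng):
        w = TextWeight()
        w.w.data[:] = 0.0
        out = fuse_weighted_text(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)), w)
        np.testing.assert_array_equal(out[:, 3:], 0)

    def test_scalar_scaling(self):
        w = TextWeight()
        w.w.data[:] = 2.0
        out = fuse_weighted_text(np.zeros((1, 2)), np.array([[1.0, -1.0]]), w)
        np.testing.assert_array_equal(out, [[0.0, 0.0, 2.0, -2.0]])


class TestGated:
    def test_gates_sum_to_one(self, rng):
        gate = GateHead(shared_dim=6, seed=0)
        v, t = rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
        _, g = fuse_gated(v, t, gate, return_gates=True)
        np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-12)
        assert (g >= 0).all()

    def test_equal_logits_give_even_blend(self, rng):
        gate = GateHead(shared_dim=4, seed=0)
        for p in gate.parameters():  # zeroed MLP -> equal logits
            p.data[:] = 0.0
        v, t = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        out = fuse_gated(v, t, gate)
        np.testing.assert_allclose(out, 0.5 * v + 0.5 * t, atol=1e-12)

    def test_saturated_gate_recovers_vision(self, rng):
        gate = GateHead(shared_dim=4, seed=0)
        for p in gate.parameters():
            p.data[:] = 0.0
        gate.mlp.b2.data[:] = [50.0, -50.0]  # logits strongly favor image
        v, t = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        np.testing.assert_allclose(fuse_gated(v, t, gate), v, atol=1e-12)

    def test_dim_mismatch_rejected(self, rng):
        with pytest.raises(UsageError):
            fuse_gated(rng.normal(size=(2, 4)), rng.normal(size=(2, 5)),
                       GateHead(shared_dim=4, seed=0))


class TestCrossAttention:
    def test_single_token_single_patch_weight_is_one(self, rng):
        head = CrossAttentionHead(shared_dim=8, n_heads=4, seed=0)
        patch = rng.normal(size=(1, 8))
        token = rng.normal(size=(1, 8))
        out = fuse_cross_attention(patch, token, head)
        # softmax over one key is 1: output = (patch @ Wv) @ Wo
        expected = (patch @ head.wv.data) @ head.wo.data
        np.testing.assert_allclose(out, expected[0], atol=1e-12)

    def test_identical_patches_make_attention_irrelevant(self, rng):
        head = CrossAttentionHead(shared_dim=8, seed=0)
        patch = np.repeat(rng.normal(size=(1, 8)), 5, axis=0)
        out1 = fuse_cross_attention(patch, rng.normal(size=(3, 8)), head)
        out2 = fuse_cross_attention(patch, rng.normal(size=(4, 8)), head)
        np.testing.assert_allclose(out1, out2, atol=1e-10)

    def test_patch_permutation_symmetry(self, rng):
        head = CrossAttentionHead(shared_dim=8, seed=0)
        patches = rng.normal(size=(6, 8))
        tokens = rng.normal(size=(3, 8))
        out1 = fuse_cross_attention(patches, tokens, head)
        out2 = fuse_cross_attention(patches[::-1].copy(), tokens, head)
        np.testing.assert_allclose(out1, out2, atol=1e-10)

    def test_empty_sequences_rejected(self, rng):
        head = CrossAttentionHead(shared_dim=8, seed=0)
        with pytest.raises(UsageError):
            fuse_cross_attention(np.zeros((0, 8)), rng.normal(size=(2, 8)), head)


class TestFusionModel:
    @pytest.mark.parametrize("kind,out_dim", [
        ("concat", 16), ("weighted_text", 16), ("gated", 8), ("cross_attention", 8),
    ])
    def test_shapes_and_inference_determinism(self, kind, out_dim, rng):
        model = FusionModel(kind, vision_dim=5, text_dim=3, shared_dim=8, seed=1)
        v, t = rng.normal(size=(4, 5)), rng.normal(size=(4, 3))
        out = model.fuse(v, t)
        assert out.shape == (4, out_dim) and model.output_dim == out_dim
        np.testing.assert_array_equal(out, model.fuse(v, t))

    def test_gated_fuse_exposes_gate_weights(self, rng):
        model = FusionModel("gated", 5, 3, shared_dim=8, seed=1)
        model.fuse(rng.normal(size=(4, 5)), rng.normal(size=(4, 3)))
        assert model.last_gates.shape == (4, 2)
        np.testing.assert_allclose(model.last_gates.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("kind", ["concat", "weighted_text", "gated", "cross_attention"])
    def test_gradient_flows_to_head_parameters(self, kind, rng):
        """Finite-difference check of d(loss)/d(param) through each head."""
        model = FusionModel(kind, 4, 3, shared_dim=8, seed=2)
        v = Tensor(rng.normal(size=(2, 4)))
        t = Tensor(rng.normal(size=(2, 3)))
        loss = (model.fuse(v, t) ** 2).sum()
        loss.backward()
        param = model.projection.text_proj
        assert param.grad is not None
        i, j = 1, 2
        h = 1e-6
        param.data[i, j] += h
        up = (model.fuse(v.detach(), t.detach()) ** 2).sum().item()
        param.data[i, j] -= 2 * h
        dn = (model.fuse(v.detach(), t.detach()) ** 2).sum().item()
        param.data[i, j] += h
        assert param.grad[i, j] == pytest.approx((up - dn) / (2 * h), abs=1e-4)
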