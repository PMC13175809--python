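"""Aggregator, fusion and loss contracts of the exam classifier."""

import numpy as np
import pytest

from kneemil.autodiff import Tensor
from kneemil.exceptions import ConfigurationError, ContractError
from kneemil.model import (AttentionMILAggregator, ConvSliceEncoder,
                           ExamClassifier, FusionClassifier,
                           MeanPixelEncoder, MeanPoolAggregator,
                           MaxPoolAggregator, ModelConfig,
                           MultiScaleAttentionAggregator, bce_loss,
                           bce_with_logits, encode_slices,
                           moving_average_matrix)

RNG = np.random.default_rng(0)


# -- encoder contract --------------------------------------------------------

def test_mean_pixel_encoder_copies_mean_d_fold():
    stack = np.stack([np.full((6, 6), v, dtype=np.float32)
                      for v in (0.1, 0.7)])
    seq = encode_slices(stack, MeanPixelEncoder(5))
    np.testing.assert_allclose(seq.embeddings[0], 0.1, atol=1e-6)
    np.testing.assert_allclose(seq.embeddings[1], 0.7, atol=1e-6)


def test_encoding_is_per_slice_so_permutation_permutes_rows():
    enc = ConvSliceEncoder(8, np.random.default_rng(1), (4, 6))
    stack = RNG.normal(size=(5, 16, 16)).astype(np.float32)
    perm = np.array([4, 2, 0, 1, 3])
    base = encode_slices(stack, enc).embeddings
    permuted = encode_slices(stack[perm], enc).embeddings
    np.testing.assert_allclose(permuted, base[perm], atol=1e-6)
    # identical slices give identical rows
    twin = np.stack([stack[0], stack[0]])
    rows = encode_slices(twin, enc).embeddings
    np.testing.assert_allclose(rows[0], rows[1], atol=0)


def test_encoder_contract_violation_names_dims():
    with pytest.raises(ContractError, match="rank"):
        encode_slices(np.zeros((4, 4)), MeanPixelEncoder(3))


# -- multi-scale pooling -----------------------------------------------------

def test_kernel_one_pooling_is_identity():
    np.testing.assert_array_equal(moving_average_matrix(7, 1), np.eye(7))


def test_truncated_window_kernel_three_example():
    mat = moving_average_matrix(4, 3)
    seq = np.array([1.0, 2.0, 3.0, 4.0])
    np.testing.assert_allclose(mat @ seq, [1.5, 2.0, 3.0, 3.5])


def test_constant_sequence_invariant_under_all_scales():
    for k in (1, 3, 5):
        mat = moving_average_matrix(6, k)
        np.testing.assert_allclose(mat @ np.full(6, 2.5), 2.5, atol=1e-12)
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-12)


def test_even_kernel_rejected():
    with pytest.raises(ConfigurationError):
        moving_average_matrix(4, 2)


def test_token_count_is_kernels_times_slices():
    cfg = ModelConfig.tiny()
    agg = MultiScaleAttentionAggregator(cfg, S=5, rng=np.random.default_rng(2))
    tokens = agg.multiscale_tokens(
        Tensor(RNG.normal(size=(2, 5, cfg.encoder_dim)).astype(np.float32)))
    assert tokens.shape == (2, len(cfg.pool_kernels) * 5, cfg.embed_dim)


# -- attention readout -------------------------------------------------------

def test_zeroed_readout_gives_uniform_weights_and_token_mean():
    cfg = ModelConfig.tiny()
    agg = MultiScaleAttentionAggregator(cfg, S=4, rng=np.random.default_rng(3))
    agg.readout_query.data[:] = 0.0
    tokens = Tensor(RNG.normal(size=(3, 6, cfg.embed_dim)).astype(np.float32))
    for block in agg.blocks:
        block.zero_residual_()
    summary, weights = agg.attend(tokens)
    np.testing.assert_allclose(weights.data, 1.0 / 6.0, atol=1e-7)
    np.testing.assert_allclose(summary.data, tokens.data.mean(axis=1),
                               atol=1e-6)


def test_readout_weights_form_probability_vector():
    cfg = ModelConfig.tiny()
    agg = MultiScaleAttentionAggregator(cfg, S=4, rng=np.random.default_rng(4))
    seq = Tensor(RNG.normal(size=(5, 4, cfg.encoder_dim)).astype(np.float32))
    _, weights = agg(seq)
    assert np.all(weights.data >= 0)
    np.testing.assert_allclose(weights.data.sum(axis=-1), 1.0, atol=1e-6)


def test_permuting_slices_leaves_summary_unchanged_without_positions():
    cfg = ModelConfig.tiny(pool_kernels=(1,), positional_encoding=False)
    agg = MultiScaleAttentionAggregator(cfg, S=6, rng=np.random.default_rng(5))
    seq = RNG.normal(size=(2, 6, cfg.encoder_dim)).astype(np.float32)
    perm = np.random.default_rng(0).permutation(6)
    base, _ = agg(Tensor(seq))
    permuted, _ = agg(Tensor(seq[:, perm]))
    np.testing.assert_allclose(permuted.data, base.data, atol=1e-5)


def test_multiscale_with_positions_is_order_sensitive():
    cfg = ModelConfig.tiny()
    agg = MultiScaleAttentionAggregator(cfg, S=6, rng=np.random.default_rng(6))
    seq = RNG.normal(size=(1, 6, cfg.encoder_dim)).astype(np.float32)
    base, _ = agg(Tensor(seq))
    reversed_, _ = agg(Tensor(seq[:, ::-1].copy()))
    assert not np.allclose(base.data, reversed_.data, atol=1e-5)


# -- baseline aggregators ----------------------------------------------------

def test_mean_and_max_pooling_arithmetic():
    cfg = ModelConfig.tiny(encoder_dim=2)
    seq = Tensor(np.array([[[1.0, 2.0], [3.0, 4.0]]], dtype=np.float32))
    mean_agg = MeanPoolAggregator(cfg, np.random.default_rng(7))
    max_agg = MaxPoolAggregator(cfg, np.random.default_rng(7))
    pooled_mean = seq.data.mean(axis=1)
    pooled_max = seq.data.max(axis=1)
    np.testing.assert_allclose(mean_agg(seq)[0].data,
                               mean_agg.proj(Tensor(pooled_mean)).data,
                               atol=1e-6)
    np.testing.assert_allclose(max_agg(seq)[0].data,
                               max_agg.proj(Tensor(pooled_max)).data,
                               atol=1e-6)


def test_pooling_single_slice_is_identity_and_permutation_invariant():
    cfg = ModelConfig.tiny(encoder_dim=3)
    seq = RNG.normal(size=(2, 5, 3)).astype(np.float32)
    perm = np.array([3, 1, 4, 0, 2])
    for cls in (MeanPoolAggregator, MaxPoolAggregator):
        agg = cls(cfg, np.random.default_rng(8))
        np.testing.assert_allclose(agg(Tensor(seq))[0].data,
                                   agg(Tensor(seq[:, perm]))[0].data,
                                   atol=1e-6)
        single = Tensor(seq[:, :1])
        np.testing.assert_allclose(agg(single)[0].data,
                                   agg.proj(Tensor(seq[:, 0])).data, atol=1e-6)


def test_gated_attention_mil_equal_scores_reduce_to_mean():
    cfg = ModelConfig.tiny(encoder_dim=3)
    agg = AttentionMILAggregator(cfg, np.random.default_rng(9))
    agg.w.weight.data[:] = 0.0       # all scores 0 -> uniform softmax
    agg.w.bias.data[:] = 0.0
    seq = Tensor(RNG.normal(size=(2, 4, 3)).astype(np.float32))
    summary, weights = agg(seq)
    np.testing.assert_allclose(weights.data, 0.25, atol=1e-7)
    np.testing.assert_allclose(summary.data,
                               agg.proj(Tensor(seq.data.mean(axis=1))).data,
                               atol=1e-6)


def test_gated_attention_mil_matches_hand_arithmetic():
    # 1-dim instances, 1-dim gate: a_i ∝ exp(w * tanh(v h_i) * sigmoid(u h_i))
    cfg = ModelConfig(encoder_dim=1, embed_dim=4, heads=1, mil_hidden=1,
                      mlp_hidden=4)
    agg = AttentionMILAggregator(cfg, np.random.default_rng(10))
    v, u, w = 0.7, -0.4, 1.3
    agg.V.weight.data[:] = v
    agg.V.bias.data[:] = 0.0
    agg.U.weight.data[:] = u
    agg.U.bias.data[:] = 0.0
    agg.w.weight.data[:] = w
    agg.w.bias.data[:] = 0.0
    h = np.array([0.5, -1.0])
    scores = w * np.tanh(v * h) / (1.0 + np.exp(-u * h))
    e = np.exp(scores - scores.max())
    a = e / e.sum()
    expected = float(np.sum(a * h))
    seq = Tensor(h.reshape(1, 2, 1).astype(np.float32))
    summary, weights = agg(seq)
    np.testing.assert_allclose(weights.data.ravel(), a, atol=1e-6)
    np.testing.assert_allclose(
        summary.data, agg.proj(Tensor(np.float32([[expected]]))).data,
        atol=1e-6)


# -- reduction oracle --------------------------------------------------------

def test_single_scale_zeroed_attention_equals_mean_pooling():
    cfg = ModelConfig.tiny(pool_kernels=(1,))
    rng = np.random.default_rng(11)
    agg = MultiScaleAttentionAggregator(cfg, S=5, rng=rng)
    agg.zero_attention_()
    mean_agg = MeanPoolAggregator(cfg, np.random.default_rng(12))
    mean_agg.proj.weight.data = agg.scale_projs[0].weight.data.copy()
    mean_agg.proj.bias.data = agg.scale_projs[0].bias.data.copy()
    seq = Tensor(RNG.normal(size=(4, 5, cfg.encoder_dim)).astype(np.float32))
    np.testing.assert_allclose(agg(seq)[0].data, mean_agg(seq)[0].data,
                               atol=1e-5)


# -- fusion ------------------------------------------------------------------

def test_zeroed_head_outputs_one_half_everywhere():
    cfg = ModelConfig.tiny()
    head = FusionClassifier(cfg, np.random.default_rng(13))
    head.eval()
    for p in head.parameters():
        p.data[:] = 0.0
    vs = [Tensor(RNG.normal(size=(2, cfg.embed_dim)).astype(np.float32))
          for _ in range(3)]
    logits = head(vs).data
    np.testing.assert_allclose(1.0 / (1.0 + np.exp(-logits)), 0.5)


def test_probabilities_strictly_inside_unit_interval_and_eval_deterministic(
        small_splits):
    model = ExamClassifier(ModelConfig.tiny(), S=8, seed=14)
    p1 = model.predict_proba(small_splits.test.X[:4])
    p2 = model.predict_proba(small_splits.test.X[:4])
    assert np.all((p1 > 0) & (p1 < 1))
    np.testing.assert_array_equal(p1, p2)


def test_fusion_rejects_wrong_view_count():
    head = FusionClassifier(ModelConfig.tiny(), np.random.default_rng(15))
    with pytest.raises(ContractError):
        head([Tensor(np.zeros((1, 32), dtype=np.float32))] * 2)


def test_learned_fusion_is_view_order_sensitive():
    cfg = ModelConfig.tiny()
    head = FusionClassifier(cfg, np.random.default_rng(16))
    head.eval()
    vs = [Tensor(RNG.normal(size=(1, cfg.embed_dim)).astype(np.float32))
          for _ in range(3)]
    base = head(vs).data
    swapped = head([vs[1], vs[0], vs[2]]).data
    assert not np.allclose(base, swapped, atol=1e-6)


def test_view_averaging_fusion_is_exchangeable():
    cfg = ModelConfig.tiny(fusion="average")
    head = FusionClassifier(cfg, np.random.default_rng(17))
    head.eval()
    vs = [Tensor(RNG.normal(size=(1, cfg.embed_dim)).astype(np.float32))
          for _ in range(3)]
    np.testing.assert_allclose(head(vs).data,
                               head([vs[2], vs[0], vs[1]]).data, atol=1e-6)


# -- losses ------------------------------------------------------------------

def test_bce_closed_forms():
    assert abs(bce_loss([0.5], [1]).item() - np.log(2)) < 1e-9
    assert bce_loss([1.0], [1]).item() <= 1.001e-7   # clamp bound
    batch = bce_loss([0.9, 0.2], [1, 0]).item()
    np.testing.assert_allclose(batch, (-np.log(0.9) - np.log(0.8)) / 2,
                               atol=1e-9)
    np.testing.assert_allclose(batch, 0.1643, atol=5e-5)


def test_bce_shape_mismatch_raises():
    with pytest.raises(ContractError):
        bce_loss([0.5, 0.5], [1])


def test_bce_with_logits_matches_probability_form():
    rng = np.random.default_rng(18)
    logits = rng.normal(scale=3, size=(8, 3))
    y = rng.integers(0, 2, size=(8, 3))
    via_logits = bce_with_logits(Tensor(logits), y).item()
    via_probs = bce_loss(1.0 / (1.0 + np.exp(-logits)), y).item()
    np.testing.assert_allclose(via_logits, via_probs, atol=1e-9)


def test_gradients_reach_every_parameter(small_splits):
    model = ExamClassifier(ModelConfig.tiny(), S=8, seed=19)
    model.train()
    out = model.forward(small_splits.train.X[:6])
    loss = bce_with_logits(out["logits"], small_splits.train.y[:6])
    model.zero_grad()
    loss.backward()
    dead = [name for name, p in model.named_parameters()
            if p.grad is None or not np.any(p.grad)]
    assert dead == []
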