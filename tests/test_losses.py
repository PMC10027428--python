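"""The nine distillation objectives: worked examples, loop-oracle equivalence,
zero-at-equality, linearity in the weights, and finite-difference gradients."""

import numpy as np
import pytest

import oracles
from conftest import micro_outputs
from biodistil.autodiff import Tensor
from biodistil.encoders import build_encoder, EncoderConfig
from biodistil.errors import ConfigurationError, ValidationError
from biodistil.losses import (DistillationRecipe, combined_loss, compact_combined_loss,
                              compact_loss, cosine_alignment_loss, distil_combined_loss,
                              embedding_loss, layer_distill_loss, make_projection,
                              make_uniform_layer_map, mlm_loss, output_ce_loss,
                              output_kl_loss, tiny_combined_loss)
from biodistil.masking import IGNORE_INDEX, MaskedBatch


def make_batch(labels):
    labels = np.asarray(labels)
    ids = np.where(labels == IGNORE_INDEX, 5, 4)
    return MaskedBatch(input_ids=ids, labels=labels,
                       attention_mask=np.ones_like(labels),
                       mask_weights=(labels != IGNORE_INDEX).astype(int))


# ---------------------------------------------------------------------------
# MLM loss
# ---------------------------------------------------------------------------

def test_mlm_loss_is_zero_for_one_hot_correct_predictions():
    logits = np.full((1, 3, 4), -1000.0)
    labels = np.array([[1, 2, IGNORE_INDEX]])
    logits[0, 0, 1] = logits[0, 1, 2] = 0.0
    assert float(mlm_loss(Tensor(logits), make_batch(labels))) == pytest.approx(0.0, abs=1e-9)


def test_mlm_loss_at_uniform_logits_is_log_vocab():
    logits = np.zeros((1, 5, 4))
    labels = np.array([[0, 3, IGNORE_INDEX, 2, 1]])
    assert float(mlm_loss(Tensor(logits), make_batch(labels))) == pytest.approx(np.log(4), rel=1e-9)


def test_mlm_loss_single_token_with_half_probability_is_log_two():
    logits = np.zeros((1, 1, 2))  # softmax -> (0.5, 0.5)
    labels = np.array([[0]])
    assert float(mlm_loss(Tensor(logits), make_batch(labels))) == pytest.approx(np.log(2), rel=1e-9)


def test_mlm_loss_without_masked_positions_is_zero_by_convention():
    logits = np.zeros((1, 3, 4))
    labels = np.full((1, 3), IGNORE_INDEX)
    assert float(mlm_loss(Tensor(logits), make_batch(labels))) == 0.0


# ---------------------------------------------------------------------------
# output KL / CE
# ---------------------------------------------------------------------------

def test_output_kl_is_zero_for_identical_logits_and_for_no_masked_tokens():
    logits = np.random.default_rng(0).normal(size=(1, 4, 6))
    labels = np.array([[1, IGNORE_INDEX, 2, IGNORE_INDEX]])
    assert float(output_kl_loss(Tensor(logits), Tensor(logits.copy()),
                                make_batch(labels))) == pytest.approx(0.0, abs=1e-12)
    no_mask = np.full((1, 4), IGNORE_INDEX)
    other = logits + 1.7
    assert float(output_kl_loss(Tensor(logits), Tensor(other), make_batch(no_mask))) == 0.0


def test_output_kl_hand_example_student_first():
    # student probs (0.9, 0.1), teacher (0.5, 0.5)
    s = np.log(np.array([[[0.9, 0.1]]]))
    t = np.zeros((1, 1, 2))
    labels = np.array([[0]])
    want = 0.9 * np.log(0.9 / 0.5) + 0.1 * np.log(0.1 / 0.5)
    got = float(output_kl_loss(Tensor(s), Tensor(t), make_batch(labels)))
    assert got == pytest.approx(want, rel=1e-6)
    assert got == pytest.approx(0.3681, abs=5e-4)
    flipped = float(output_kl_loss(Tensor(s), Tensor(t), make_batch(labels),
                                   teacher_first=True))
    assert flipped == pytest.approx(0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1), rel=1e-6)


def test_output_ce_hand_examples():
    labels = np.array([[0]])
    t = np.log(np.array([[[0.5, 0.5]]]))
    s = np.log(np.array([[[0.25, 0.75]]]))
    want = -0.5 * np.log(0.25) - 0.5 * np.log(0.75)
    assert float(output_ce_loss(Tensor(s), Tensor(t), make_batch(labels))) == \
        pytest.approx(want, rel=1e-6)
    # CE attains its floor, the teacher entropy, at s == t
    assert float(output_ce_loss(Tensor(t), Tensor(t.copy()), make_batch(labels))) == \
        pytest.approx(np.log(2), rel=1e-6)
    one_hot_t = np.array([[[1000.0, 0.0]]])
    assert float(output_ce_loss(Tensor(one_hot_t), Tensor(one_hot_t.copy()),
                                make_batch(labels))) == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# cosine alignment
# ---------------------------------------------------------------------------

def test_cosine_alignment_identical_zero_antiparallel_two():
    h = np.random.default_rng(1).normal(size=(1, 3, 4))
    assert float(cosine_alignment_loss(Tensor(h), Tensor(h.copy()))) == \
        pytest.approx(0.0, abs=1e-9)
    assert float(cosine_alignment_loss(Tensor(h), Tensor(-h))) == pytest.approx(2.0, abs=1e-9)


def test_cosine_alignment_hand_example():
    s = np.tile([1.0, 0.0], (1, 4, 1))
    t = np.tile([1.0, 1.0], (1, 4, 1))
    assert float(cosine_alignment_loss(Tensor(s), Tensor(t))) == \
        pytest.approx(1 - 1 / np.sqrt(2), rel=1e-6)


def test_zero_norm_row_contributes_one_to_the_alignment_loss():
    s = np.array([[[0.0, 0.0], [1.0, 0.0]]])
    t = np.array([[[1.0, 1.0], [1.0, 0.0]]])
    assert float(cosine_alignment_loss(Tensor(s), Tensor(t))) == pytest.approx(0.5, abs=1e-5)


def test_cosine_alignment_rejects_width_mismatch():
    with pytest.raises(ConfigurationError):
        cosine_alignment_loss(Tensor(np.zeros((1, 2, 3))), Tensor(np.zeros((1, 2, 4))))


# ---------------------------------------------------------------------------
# layer map
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("s, t, want", [
    (4, 12, {1: 3, 2: 6, 3: 9, 4: 12}),
    (6, 12, {l: 2 * l for l in range(1, 7)}),
    (3, 3, {1: 1, 2: 2, 3: 3}),
])
def test_uniform_layer_map(s, t, want):
    assert make_uniform_layer_map(s, t) == want


def test_layer_map_rejects_student_deeper_than_teacher():
    with pytest.raises(ConfigurationError):
        make_uniform_layer_map(4, 2)


# ---------------------------------------------------------------------------
# layer-to-layer MSE and embedding loss
# ---------------------------------------------------------------------------

def _outputs_pair(seed, **kw):
    _, s_out, _ = micro_outputs(seed, **kw)
    _, t_out, _ = micro_outputs(seed + 50, **kw)
    return s_out, t_out


def test_layer_distill_loss_zero_at_equality_and_hand_mse():
    _, out, _ = micro_outputs(3)
    rec = DistillationRecipe(variant="tiny", layer_map={1: 1, 2: 2})
    assert float(layer_distill_loss(out, out, rec)) == 0.0
    # one layer, student hidden all zeros vs teacher all ones, same attention
    attn = np.full((1, 1, 2, 2), 0.5)
    s = [Tensor(np.zeros((1, 2, 3))), Tensor(np.zeros((1, 2, 3)))]
    t = [Tensor(np.ones((1, 2, 3))), Tensor(np.ones((1, 2, 3)))]
    from biodistil.encoders import EncoderOutputs
    s_out = EncoderOutputs(None, s, [Tensor(attn)])
    t_out = EncoderOutputs(None, t, [Tensor(attn.copy())])
    rec1 = DistillationRecipe(variant="tiny", layer_map={1: 1})
    assert float(layer_distill_loss(s_out, t_out, rec1)) == pytest.approx(1.0, rel=1e-12)


def test_layer_distill_loss_matches_loop_oracle():
    s_out, t_out = _outputs_pair(7)
    rec = DistillationRecipe(variant="tiny", layer_map={1: 1, 2: 2},
                             layer_lambdas=[0.5, 2.0])
    got = float(layer_distill_loss(s_out, t_out, rec))
    want = oracles.layer_loss_loop(
        [h.data for h in s_out.hidden_states], [h.data for h in t_out.hidden_states],
        [a.data for a in s_out.attentions], [a.data for a in t_out.attentions],
        {1: 1, 2: 2}, layer_lambdas=[0.5, 2.0])
    assert got == pytest.approx(want, abs=1e-10)


def test_layer_distill_with_projection_matches_oracle_and_requires_projection():
    _, s_out, _ = micro_outputs(9, hidden=4, heads=2)
    _, t_out, _ = micro_outputs(60, hidden=6, heads=2)
    proj = make_projection(4, 6, seed=1)
    rec = DistillationRecipe(variant="tiny", layer_map={1: 2}, projection=proj)
    got = float(layer_distill_loss(s_out, t_out, rec))
    want = oracles.layer_loss_loop(
        [h.data for h in s_out.hidden_states], [h.data for h in t_out.hidden_states],
        [a.data for a in s_out.attentions], [a.data for a in t_out.attentions],
        {1: 2}, projection=proj.data)
    assert got == pytest.approx(want, abs=1e-10)
    bare = DistillationRecipe(variant="tiny", layer_map={1: 2})
    with pytest.raises(ConfigurationError, match="Wp"):
        layer_distill_loss(s_out, t_out, bare)


def test_embedding_loss_examples_and_oracle():
    ident = Tensor(np.eye(3))
    e = np.random.default_rng(4).normal(size=(1, 2, 3))
    assert float(embedding_loss(Tensor(e), Tensor(e.copy()), ident)) == \
        pytest.approx(0.0, abs=1e-12)
    zeros, ones = np.zeros((2, 4, 3)), np.ones((2, 4, 3))
    assert float(embedding_loss(Tensor(zeros), Tensor(ones), Tensor(np.eye(3)))) == 1.0
    s = np.random.default_rng(5).normal(size=(1, 3, 2))
    t = np.random.default_rng(6).normal(size=(1, 3, 4))
    proj = make_projection(2, 4, seed=2)
    got = float(embedding_loss(Tensor(s), Tensor(t), proj))
    assert got == pytest.approx(oracles.mse_loop(s @ proj.data, t), abs=1e-10)
    with pytest.raises(ConfigurationError):
        embedding_loss(Tensor(s), Tensor(t), None)


# ---------------------------------------------------------------------------
# compact loss
# ---------------------------------------------------------------------------

def test_compact_loss_zero_at_equality_and_cosine_bound():
    _, out, _ = micro_outputs(11)
    rec = DistillationRecipe(variant="compact", layer_map={1: 1, 2: 2})
    assert float(compact_loss(out, out, rec)) == pytest.approx(0.0, abs=1e-12)
    # antiparallel hidden rows, identical attentions -> cosine term 2, KL 0
    from biodistil.encoders import EncoderOutputs
    h = np.random.default_rng(12).normal(size=(1, 2, 4))
    attn = np.full((1, 1, 2, 2), 0.5)
    s_out = EncoderOutputs(None, [Tensor(h), Tensor(h)], [Tensor(attn)])
    t_out = EncoderOutputs(None, [Tensor(-h), Tensor(-h)], [Tensor(attn.copy())])
    rec1 = DistillationRecipe(variant="compact", layer_map={1: 1})
    assert float(compact_loss(s_out, t_out, rec1)) == pytest.approx(2.0, abs=1e-8)


def test_compact_loss_attention_kl_hand_example():
    from biodistil.encoders import EncoderOutputs
    h = np.ones((1, 1, 4))
    s_attn = np.array([[[[0.9, 0.1]]]])  # one head, one query row of length 2
    t_attn = np.array([[[[0.5, 0.5]]]])
    # pad hidden to sequence length 1: shapes (B=1, N=1, d)
    s_out = EncoderOutputs(None, [Tensor(h), Tensor(h)], [Tensor(s_attn)])
    t_out = EncoderOutputs(None, [Tensor(h.copy()), Tensor(h.copy())], [Tensor(t_attn)])
    rec = DistillationRecipe(variant="compact", layer_map={1: 1})
    want = 0.9 * np.log(0.9 / 0.5) + 0.1 * np.log(0.1 / 0.5)
    assert float(compact_loss(s_out, t_out, rec)) == pytest.approx(want, rel=1e-5)


def test_compact_loss_matches_loop_oracle():
    s_out, t_out = _outputs_pair(13)
    rec = DistillationRecipe(variant="compact", layer_map={1: 1, 2: 2})
    got = float(compact_loss(s_out, t_out, rec))
    want = oracles.compact_loss_loop(
        [h.data for h in s_out.hidden_states], [h.data for h in t_out.hidden_states],
        [a.data for a in s_out.attentions], [a.data for a in t_out.attentions],
        {1: 1, 2: 2})
    assert got == pytest.approx(want, abs=1e-8)


def test_compact_loss_rejects_unnormalised_attention():
    from biodistil.encoders import EncoderOutputs
    h = np.ones((1, 1, 4))
    bad = np.array([[[[0.9, 0.9]]]])
    s_out = EncoderOutputs(None, [Tensor(h), Tensor(h)], [Tensor(bad)])
    t_out = EncoderOutputs(None, [Tensor(h), Tensor(h)], [Tensor(bad.copy())])
    rec = DistillationRecipe(variant="compact", layer_map={1: 1})
    with pytest.raises(ValidationError):
        compact_loss(s_out, t_out, rec)


# ---------------------------------------------------------------------------
# combined losses: selectors, component oracles, linearity
# ---------------------------------------------------------------------------

def _distill_setup(seed=17):
    model, s_out, ids = micro_outputs(seed)
    _, t_out, _ = micro_outputs(seed + 50)
    rng = np.random.default_rng(seed + 3)
    labels = np.where(rng.random(ids.shape) < 0.4, ids, IGNORE_INDEX)
    labels[0, 0] = ids[0, 0]  # at least one masked token
    return s_out, t_out, make_batch(labels)


def test_distil_combined_is_the_weighted_sum_of_its_components():
    s_out, t_out, batch = _distill_setup()
    a = float(mlm_loss(s_out.logits, batch))
    b = float(output_kl_loss(s_out.logits, t_out.logits, batch))
    c = float(cosine_alignment_loss(s_out.hidden_states[-1], t_out.hidden_states[-1],
                                    attention_mask=batch.attention_mask))
    rec = DistillationRecipe(variant="distil", lambda_mlm=1, lambda_output=2, lambda_align=3)
    assert float(distil_combined_loss(s_out, t_out, batch, rec)) == \
        pytest.approx(a + 2 * b + 3 * c, rel=1e-10)
    only_mlm = DistillationRecipe(variant="distil", lambda_mlm=1, lambda_output=0,
                                  lambda_align=0)
    assert float(distil_combined_loss(s_out, t_out, batch, only_mlm)) == pytest.approx(a)
    only_align = DistillationRecipe(variant="distil", lambda_mlm=0, lambda_output=0,
                                    lambda_align=1)
    assert float(distil_combined_loss(s_out, s_out, batch, only_align)) == \
        pytest.approx(0.0, abs=1e-12)


def test_tiny_combined_selector_and_component_oracle():
    s_out, t_out, batch = _distill_setup(21)
    lmap = {1: 1, 2: 2}
    bare = DistillationRecipe(variant="tiny", layer_map=lmap, lambda_embed=0,
                              lambda_out_star=0)
    assert float(tiny_combined_loss(s_out, t_out, batch, bare)) == \
        pytest.approx(float(layer_distill_loss(s_out, t_out, bare,
                                               attention_mask=batch.attention_mask)))
    rec = DistillationRecipe(variant="tiny", layer_map=lmap, lambda_embed=0.7,
                             lambda_out_star=1.3)
    want = (float(layer_distill_loss(s_out, t_out, rec, attention_mask=batch.attention_mask))
            + 0.7 * float(embedding_loss(s_out.hidden_states[0], t_out.hidden_states[0]))
            + 1.3 * float(output_ce_loss(s_out.logits, t_out.logits, batch)))
    assert float(tiny_combined_loss(s_out, t_out, batch, rec)) == pytest.approx(want, rel=1e-10)


def test_tiny_combined_at_equality_leaves_only_the_ce_floor():
    s_out, _, batch = _distill_setup(23)
    rec = DistillationRecipe(variant="tiny", layer_map={1: 1, 2: 2},
                             lambda_embed=0.9, lambda_out_star=2.0)
    got = float(tiny_combined_loss(s_out, s_out, batch, rec))
    # only the soft-CE floor (the teacher's own entropy) remains
    floor = 2.0 * float(output_ce_loss(s_out.logits, s_out.logits, batch))
    assert got == pytest.approx(floor, rel=1e-10)
    assert floor > 0


def test_compact_combined_selector_and_component_oracle():
    s_out, t_out, batch = _distill_setup(25)
    lmap = {1: 1, 2: 2}
    only_mlm = DistillationRecipe(variant="compact", layer_map=lmap, lambda_mlm=1,
                                  lambda_compact=0, lambda_output=0)
    assert float(compact_combined_loss(s_out, t_out, batch, only_mlm)) == \
        pytest.approx(float(mlm_loss(s_out.logits, batch)))
    only_compact = DistillationRecipe(variant="compact", layer_map=lmap, lambda_mlm=0,
                                      lambda_compact=1, lambda_output=0)
    assert float(compact_combined_loss(s_out, s_out, batch, only_compact)) == \
        pytest.approx(0.0, abs=1e-12)
    rec = DistillationRecipe(variant="compact", layer_map=lmap)
    want = (float(mlm_loss(s_out.logits, batch))
            + float(compact_loss(s_out, t_out, rec, attention_mask=batch.attention_mask))
            + float(output_kl_loss(s_out.logits, t_out.logits, batch)))
    assert float(compact_combined_loss(s_out, t_out, batch, rec)) == \
        pytest.approx(want, rel=1e-10)


@pytest.mark.parametrize("variant", ["distil", "tiny", "compact"])
def test_combined_losses_are_linear_in_their_weights(variant):
    s_out, t_out, batch = _distill_setup(29)
    lmap = {1: 1, 2: 2}

    def loss_at(scale):
        rec = DistillationRecipe(
            variant=variant, layer_map=lmap,
            lambda_mlm=1.0 * scale, lambda_output=0.5 * scale, lambda_align=2.0 * scale,
            lambda_compact=1.5 * scale, lambda_embed=0.25 * scale,
            lambda_out_star=0.75 * scale,
            layer_lambdas=[scale, scale])
        return float(combined_loss(s_out, t_out, batch, rec))

    l1, l2, l3 = loss_at(1.0), loss_at(2.0), loss_at(3.0)
    assert l2 == pytest.approx(2 * l1, rel=1e-9)
    assert l3 == pytest.approx(l1 + l2, rel=1e-9)


def test_negative_weights_are_rejected():
    with pytest.raises(ConfigurationError):
        DistillationRecipe(variant="distil", lambda_mlm=-1.0)


def test_non_monotone_layer_map_is_rejected():
    with pytest.raises(ConfigurationError):
        DistillationRecipe(variant="tiny", layer_map={1: 3, 2: 1})


# ---------------------------------------------------------------------------
# oracle equivalence on real micro forward passes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [101, 102, 103])
def test_pointwise_losses_match_loop_oracles_on_micro_instances(seed):
    s_out, t_out, batch = _distill_setup(seed)
    s_logits, t_logits = s_out.logits.data, t_out.logits.data
    assert float(mlm_loss(s_out.logits, batch)) == \
        pytest.approx(oracles.mlm_loss_loop(s_logits, batch.labels), abs=1e-10)
    assert float(output_kl_loss(s_out.logits, t_out.logits, batch)) == \
        pytest.approx(oracles.output_kl_loop(s_logits, t_logits, batch.labels), abs=1e-10)
    assert float(output_ce_loss(s_out.logits, t_out.logits, batch)) == \
        pytest.approx(oracles.output_ce_loop(s_logits, t_logits, batch.labels), abs=1e-10)
    assert float(cosine_alignment_loss(s_out.hidden_states[-1], t_out.hidden_states[-1])) == \
        pytest.approx(oracles.cosine_align_loop(s_out.hidden_states[-1].data,
                                                t_out.hidden_states[-1].data), abs=1e-10)


# ---------------------------------------------------------------------------
# gradient correctness
# ---------------------------------------------------------------------------

def finite_difference_check(loss_fn, model, n_probes=6, eps=1e-5, seed=0):
    """Central-difference check of d(loss)/d(param) on random entries.

    The denominator floor gives near-zero gradients an absolute rather than
    relative tolerance (the usual gradcheck convention: central differences
    carry O(eps^2) truncation plus roundoff noise of the loss itself)."""
    loss = loss_fn()
    loss.backward()
    rng = np.random.default_rng(seed)
    names = [n for n, p in model.params.items() if p.grad is not None]
    worst = 0.0
    for _ in range(n_probes):
        name = names[rng.integers(len(names))]
        p = model.params[name]
        idx = tuple(rng.integers(s) for s in p.data.shape)
        analytic = p.grad[idx]
        orig = p.data[idx]
        p.data[idx] = orig + eps
        hi = float(loss_fn())
        p.data[idx] = orig - eps
        lo = float(loss_fn())
        p.data[idx] = orig
        numeric = (hi - lo) / (2 * eps)
        denom = max(abs(analytic), abs(numeric), 1e-4)
        worst = max(worst, abs(analytic - numeric) / denom)
    return worst


@pytest.mark.parametrize("variant", ["distil", "tiny", "compact"])
def test_combined_loss_gradients_pass_finite_difference_check(variant):
    cfg = EncoderConfig(num_layers=2, hidden_size=6, num_heads=2, ffn_size=12,
                        vocab_size=8, max_positions=16)
    student = build_encoder(cfg, seed=31)
    teacher = build_encoder(cfg, seed=32)
    teacher.set_trainable(False)
    ids = np.array([[5, 6, 7, 5]])
    labels = np.array([[5, IGNORE_INDEX, 7, IGNORE_INDEX]])
    batch = make_batch(labels)
    rec = DistillationRecipe(variant=variant, layer_map={1: 1, 2: 2})
    t_out = teacher.forward(ids)

    def loss_fn():
        s_out = student.forward(ids)
        return combined_loss(s_out, t_out, batch, rec)

    assert finite_difference_check(loss_fn, student, seed=hash(variant) % 1000) < 1e-4


def test_mlm_gradient_through_the_tied_decoder():
    cfg = EncoderConfig(num_layers=1, hidden_size=6, num_heads=2, ffn_size=12,
                        vocab_size=8, max_positions=16)
    model = build_encoder(cfg, seed=33)
    ids = np.array([[5, 6, 7]])
    batch = make_batch(np.array([[5, IGNORE_INDEX, 7]]))

    def loss_fn():
        return mlm_loss(model.forward(ids).logits, batch)

    assert finite_difference_check(loss_fn, model, seed=77) < 1e-4
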