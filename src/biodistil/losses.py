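"""Task-agnostic distillation objectives.

Three loss families are implemented as pure functions of the student's and
teacher's :class:`~biodistil.encoders.EncoderOutputs` on one masked batch:

* the *distil* recipe — masked-LM cross-entropy, a KL divergence between the
  student's and teacher's output distributions at masked positions, and a
  cosine alignment of the two models' last hidden states, combined with
  weights (lambda_mlm, lambda_output, lambda_align);
* the *tiny* recipe — layer-to-layer mean-squared alignment of hidden states
  (optionally through a learned width projection Wp) and attention maps under
  a student-to-teacher layer map g, an optional embedding-table MSE, and a
  soft cross-entropy output term;
* the *compact* recipe — per-layer cosine alignment of hidden states plus
  per-head KL between attention rows, combined with the MLM and output-KL
  terms of the distil recipe.

Conventions: losses average over masked positions (so values are
batch-size invariant; the written-sum convention is available via
``reduction="sum"``), the KL direction places the student distribution first
(flippable), logarithms receive a 1e-12 floor, and padding positions are
excluded from every token average via the attention mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Union

import numpy as np

from .autodiff import Tensor, as_tensor, parameter, softmax
from .encoders import EncoderOutputs
from .errors import ConfigurationError, ValidationError
from .masking import IGNORE_INDEX, MaskedBatch

LOG_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# recipe
# ---------------------------------------------------------------------------

def make_uniform_layer_map(student_layers: int, teacher_layers: int) -> Dict[int, int]:
    """Uniform-stride student->teacher layer assignment, 1-based, ending at the top.

    g(l) = ceil(l * T / S); for divisible depths this is the exact stride
    (e.g. S=4, T=12 -> {1:3, 2:6, 3:9, 4:12}).
    """
    if student_layers < 1 or teacher_layers < student_layers:
        raise ConfigurationError(
            f"need teacher_layers >= student_layers >= 1, got S={student_layers}, T={teacher_layers}")
    return {l: -(-l * teacher_layers // student_layers) for l in range(1, student_layers + 1)}


def make_projection(student_width: int, teacher_width: int, seed: int = 0) -> Tensor:
    """Trainable Wp mapping student width to teacher width."""
    rng = np.random.default_rng(seed)
    return parameter(rng.standard_normal((student_width, teacher_width)) * 0.02)


@dataclass
class DistillationRecipe:
    """Loss-variant selection, weights, layer map and optional projection."""

    variant: str = "distil"
    lambda_mlm: float = 1.0
    lambda_output: float = 1.0
    lambda_align: float = 1.0
    lambda_compact: float = 1.0
    layer_lambdas: Optional[Sequence[float]] = None  # per-student-layer weights, default 1
    lambda_embed: float = 1.0
    lambda_out_star: float = 1.0
    layer_map: Optional[Dict[int, int]] = None
    projection: Optional[Tensor] = None
    teacher_first_kl: bool = False
    presoftmax_attention: bool = False

    def __post_init__(self):
        if self.variant not in ("distil", "tiny", "compact"):
            raise ConfigurationError(f"unknown recipe variant {self.variant!r}")
        for name in ("lambda_mlm", "lambda_output", "lambda_align",
                     "lambda_compact", "lambda_embed", "lambda_out_star"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.layer_lambdas is not None and any(l < 0 for l in self.layer_lambdas):
            raise ConfigurationError("layer_lambdas must be non-negative")
        if self.layer_map is not None:
            keys = sorted(self.layer_map)
            vals = [self.layer_map[k] for k in keys]
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ConfigurationError("layer_map must be monotonically non-decreasing")

    def layer_weight(self, student_layer: int) -> float:
        if self.layer_lambdas is None:
            return 1.0
        return float(self.layer_lambdas[student_layer - 1])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _masked_rows(logits: Tensor, batch: MaskedBatch):
    """(masked_logits, masked_label_ids); logits may be (N,V) or (B,N,V)."""
    logits = as_tensor(logits)
    labels = np.asarray(batch.labels)
    sel = labels != IGNORE_INDEX
    return logits[sel], labels[sel]


def _log(p: Tensor) -> Tensor:
    return (p + LOG_FLOOR).log()


def _reduce(total: Tensor, count: int, reduction: str) -> Tensor:
    if reduction == "sum":
        return total
    return total * (1.0 / count)


def _masked_mean(per_position: Tensor, mask: Optional[np.ndarray]) -> Tensor:
    """Mean of a per-token quantity, ignoring padded positions."""
    if mask is None:
        return per_position.mean()
    mask = np.asarray(mask, dtype=float)
    denom = mask.sum()
    if denom == 0:
        return Tensor(0.0)
    return (per_position * Tensor(mask)).sum() * (1.0 / denom)


def _masked_mse(a: Tensor, b: Tensor, mask: Optional[np.ndarray] = None) -> Tensor:
    """Elementwise-mean squared difference; with a (B, N) mask, padded
    token rows are dropped from the average (key columns are kept)."""
    a, b = as_tensor(a), as_tensor(b)
    d = a - b
    sq = d * d
    if mask is None:
        return sq.mean()
    mask = np.atleast_2d(np.asarray(mask, dtype=float))  # (B, N)
    if a.ndim == 3:        # hidden states (B, N, d)
        w = mask[:, :, None]
    elif a.ndim == 4:      # attention maps (B, H, N_query, N_key)
        w = mask[:, None, :, None]
    else:
        raise ConfigurationError("mask rank incompatible with tensor rank")
    denom = float(np.broadcast_to(w, a.shape).sum())
    if denom == 0:
        return Tensor(0.0)
    return (sq * Tensor(np.ascontiguousarray(w))).sum() * (1.0 / denom)


def _hidden(out: Union[EncoderOutputs, Sequence], idx: int) -> Tensor:
    states = out.hidden_states if isinstance(out, EncoderOutputs) else out
    return as_tensor(states[idx])


def _attn(out: Union[EncoderOutputs, Sequence], layer_1based: int,
          presoftmax: bool = False) -> Tensor:
    if isinstance(out, EncoderOutputs):
        maps = out.attention_scores if presoftmax else out.attentions
        if maps is None:
            raise ConfigurationError("requested attention maps were not recorded in the forward pass")
        return as_tensor(maps[layer_1based - 1])
    return as_tensor(out[layer_1based - 1])


def _apply_projection(h: Tensor, projection: Optional[Tensor], teacher_width: int) -> Tensor:
    if h.shape[-1] != teacher_width:
        if projection is None:
            raise ConfigurationError(
                f"student width {h.shape[-1]} differs from teacher width {teacher_width} "
                "but the recipe has no projection Wp")
        return h @ projection
    if projection is not None:
        return h @ projection
    return h


# ---------------------------------------------------------------------------
# the distil family
# ---------------------------------------------------------------------------

def mlm_loss(student_logits, batch: MaskedBatch, reduction: str = "mean") -> Tensor:
    """Masked-LM cross-entropy: -sum_n sum_i Y_ni ln softmax(logits)_ni over
    masked positions (mean convention by default). Returns 0 when the batch
    contains no masked position."""
    rows, label_ids = _masked_rows(student_logits, batch)
    if label_ids.size == 0:
        return Tensor(0.0)
    logp = _log(softmax(rows, axis=-1))
    picked = logp[np.arange(label_ids.size), label_ids]
    return _reduce(-picked.sum(), label_ids.size, reduction)


def output_kl_loss(student_logits, teacher_logits, batch: MaskedBatch,
                   teacher_first: bool = False, reduction: str = "mean") -> Tensor:
    """KL divergence between student and teacher output distributions,
    restricted to masked positions by the 0/1 weight W_n.

    As written, the student distribution is the first KL argument;
    ``teacher_first=True`` flips the direction."""
    s_rows, _ = _masked_rows(student_logits, batch)
    t_rows, _ = _masked_rows(as_tensor(teacher_logits).detach(), batch)
    n = s_rows.shape[0] if s_rows.ndim > 1 else 0
    if n == 0:
        return Tensor(0.0)
    p_s = softmax(s_rows, axis=-1)
    p_t = softmax(t_rows, axis=-1)
    if teacher_first:
        kl = (p_t * (_log(p_t) - _log(p_s))).sum(axis=-1)
    else:
        kl = (p_s * (_log(p_s) - _log(p_t))).sum(axis=-1)
    return _reduce(kl.sum(), n, reduction)


def cosine_alignment_loss(student_hidden, teacher_hidden,
                          attention_mask=None) -> Tensor:
    """Mean over token positions of 1 - cos(h_s, h_t).

    A zero-norm row has cosine 0 by convention (contribution 1)."""
    s, t = as_tensor(student_hidden), as_tensor(teacher_hidden)
    if s.shape != t.shape:
        raise ConfigurationError(
            f"cosine alignment needs equal shapes, got {s.shape} vs {t.shape}")
    dot = (s * t).sum(axis=-1)
    ns = ((s * s).sum(axis=-1) + LOG_FLOOR).sqrt()
    nt = ((t * t).sum(axis=-1) + LOG_FLOOR).sqrt()
    cos = dot / (ns * nt)
    return _masked_mean(1.0 - cos, attention_mask)


def distil_combined_loss(student_out: EncoderOutputs, teacher_out: EncoderOutputs,
                         batch: MaskedBatch, recipe: DistillationRecipe) -> Tensor:
    """lambda_1 * L_mlm + lambda_2 * L_output + lambda_3 * L_align (last hidden states)."""
    if recipe.variant != "distil":
        raise ConfigurationError(f"recipe variant is {recipe.variant!r}, expected 'distil'")
    total = Tensor(0.0)
    if recipe.lambda_mlm:
        total = total + recipe.lambda_mlm * mlm_loss(student_out.logits, batch)
    if recipe.lambda_output:
        total = total + recipe.lambda_output * output_kl_loss(
            student_out.logits, teacher_out.logits, batch,
            teacher_first=recipe.teacher_first_kl)
    if recipe.lambda_align:
        total = total + recipe.lambda_align * cosine_alignment_loss(
            student_out.hidden_states[-1], teacher_out.hidden_states[-1].detach(),
            attention_mask=batch.attention_mask)
    return total


# ---------------------------------------------------------------------------
# the tiny family (layer-to-layer MSE)
# ---------------------------------------------------------------------------

def layer_distill_loss(student_out, teacher_out, recipe: DistillationRecipe,
                       attention_mask=None) -> Tensor:
    """sum_l lambda_l * [MSE(h_s,l Wp, h_t,g(l)) + MSE(a_s,l, a_t,g(l))]."""
    if recipe.layer_map is None:
        raise ConfigurationError("recipe.layer_map is required for layer-to-layer distillation")
    total = Tensor(0.0)
    for l, gl in sorted(recipe.layer_map.items()):
        hs = _hidden(student_out, l)
        ht = _hidden(teacher_out, gl).detach()
        hs = _apply_projection(hs, recipe.projection, ht.shape[-1])
        a_s = _attn(student_out, l, recipe.presoftmax_attention)
        a_t = _attn(teacher_out, gl, recipe.presoftmax_attention).detach()
        term = _masked_mse(hs, ht, attention_mask) + _masked_mse(a_s, a_t, attention_mask)
        total = total + recipe.layer_weight(l) * term
    return total


def embedding_loss(student_emb, teacher_emb, projection: Optional[Tensor] = None) -> Tensor:
    """MSE(e_s Wp, e_t) on the layer-0 (embedding) outputs."""
    s, t = as_tensor(student_emb), as_tensor(teacher_emb).detach()
    s = _apply_projection(s, projection, t.shape[-1])
    if s.shape != t.shape:
        raise ConfigurationError(f"projected embedding shape {s.shape} != teacher {t.shape}")
    return _masked_mse(s, t)


def output_ce_loss(student_logits, teacher_logits, batch: MaskedBatch,
                   reduction: str = "mean") -> Tensor:
    """Soft cross-entropy -sum_i softmax(t)_i ln softmax(s)_i at masked positions."""
    s_rows, _ = _masked_rows(student_logits, batch)
    t_rows, _ = _masked_rows(as_tensor(teacher_logits).detach(), batch)
    n = s_rows.shape[0] if s_rows.ndim > 1 else 0
    if n == 0:
        return Tensor(0.0)
    ce = -(softmax(t_rows, axis=-1) * _log(softmax(s_rows, axis=-1))).sum(axis=-1)
    return _reduce(ce.sum(), n, reduction)


def tiny_combined_loss(student_out, teacher_out, batch: MaskedBatch,
                       recipe: DistillationRecipe) -> Tensor:
    """lambda_0 * L_embed + L_layer + lambda_(L+1) * L_output*."""
    if recipe.variant != "tiny":
        raise ConfigurationError(f"recipe variant is {recipe.variant!r}, expected 'tiny'")
    total = layer_distill_loss(student_out, teacher_out, recipe,
                               attention_mask=batch.attention_mask)
    if recipe.lambda_embed:
        total = total + recipe.lambda_embed * embedding_loss(
            _hidden(student_out, 0), _hidden(teacher_out, 0), recipe.projection)
    if recipe.lambda_out_star:
        total = total + recipe.lambda_out_star * output_ce_loss(
            student_out.logits, teacher_out.logits, batch)
    return total


# ---------------------------------------------------------------------------
# the compact family
# ---------------------------------------------------------------------------

def compact_loss(student_out, teacher_out, recipe: DistillationRecipe,
                 attention_mask=None) -> Tensor:
    """Per-layer cosine alignment of hidden states plus per-head KL between
    attention probability rows:

    sum_l [ (1/N) sum_n (1 - cos(h_s,l,n, h_t,g(l),n))
            + (1/(H N)) sum_h sum_n KL(a_s,l,n,h || a_t,g(l),n,h) ]
    """
    if recipe.layer_map is None:
        raise ConfigurationError("recipe.layer_map is required for the compact loss")
    total = Tensor(0.0)
    for l, gl in sorted(recipe.layer_map.items()):
        hs = _hidden(student_out, l)
        ht = _hidden(teacher_out, gl).detach()
        if hs.shape[-1] != ht.shape[-1]:
            raise ConfigurationError("compact loss requires equal student/teacher widths")
        cos_term = cosine_alignment_loss(hs, ht, attention_mask)
        a_s = _attn(student_out, l)
        a_t = _attn(teacher_out, gl).detach()
        _check_row_stochastic(a_s.data, attention_mask)
        _check_row_stochastic(a_t.data, attention_mask)
        kl_rows = (a_s * (_log(a_s) - _log(a_t))).sum(axis=-1)  # (B, H, N)
        if attention_mask is not None:
            m = np.asarray(attention_mask, dtype=float)
            w = np.broadcast_to(m[:, None, :] if m.ndim == 2 else m[None, :], kl_rows.shape)
            kl_term = (kl_rows * Tensor(np.ascontiguousarray(w))).sum() * (1.0 / max(w.sum(), 1.0))
        else:
            kl_term = kl_rows.mean(axis=-1).mean()
        total = total + cos_term + kl_term
    return total


def _check_row_stochastic(a: np.ndarray, attention_mask, tol: float = 1e-3) -> None:
    sums = a.sum(axis=-1)
    if attention_mask is not None:
        m = np.asarray(attention_mask, dtype=bool)
        sums = sums[np.broadcast_to(m[:, None, :] if m.ndim == 2 else m[None, :], sums.shape)]
    if sums.size and np.max(np.abs(sums - 1.0)) > tol:
        raise ValidationError("attention rows are not normalised probability distributions")


def compact_combined_loss(student_out, teacher_out, batch: MaskedBatch,
                          recipe: DistillationRecipe) -> Tensor:
    """lambda_1 * L_mlm + lambda_2 * L_compact + lambda_3 * L_output (KL)."""
    if recipe.variant != "compact":
        raise ConfigurationError(f"recipe variant is {recipe.variant!r}, expected 'compact'")
    total = Tensor(0.0)
    if recipe.lambda_mlm:
        total = total + recipe.lambda_mlm * mlm_loss(student_out.logits, batch)
    if recipe.lambda_compact:
        total = total + recipe.lambda_compact * compact_loss(
            student_out, teacher_out, recipe, attention_mask=batch.attention_mask)
    if recipe.lambda_output:
        total = total + recipe.lambda_output * output_kl_loss(
            student_out.logits, teacher_out.logits, batch,
            teacher_first=recipe.teacher_first_kl)
    return total


def combined_loss(student_out, teacher_out, batch: MaskedBatch,
                  recipe: DistillationRecipe) -> Tensor:
    """Dispatch to the recipe's combined loss."""
    if recipe.variant == "distil":
        return distil_combined_loss(student_out, teacher_out, batch, recipe)
    if recipe.variant == "tiny":
        return tiny_combined_loss(student_out, teacher_out, batch, recipe)
    return compact_combined_loss(student_out, teacher_out, batch, recipe)


def component_losses(student_out, teacher_out, batch: MaskedBatch,
                     recipe: DistillationRecipe) -> Dict[str, float]:
    """Unweighted component values for diagnostics/logging."""
    out: Dict[str, float] = {}
    if recipe.variant in ("distil", "compact"):
        out["mlm"] = float(mlm_loss(student_out.logits, batch))
        out["output_kl"] = float(output_kl_loss(student_out.logits, teacher_out.logits, batch,
                                                teacher_first=recipe.teacher_first_kl))
    if recipe.variant == "distil":
        out["align"] = float(cosine_alignment_loss(
            student_out.hidden_states[-1], teacher_out.hidden_states[-1].detach(),
            attention_mask=batch.attention_mask))
    if recipe.variant == "tiny":
        out["layer"] = float(layer_distill_loss(student_out, teacher_out, recipe,
                                                attention_mask=batch.attention_mask))
        out["embed"] = float(embedding_loss(_hidden(student_out, 0),
                                            _hidden(teacher_out, 0), recipe.projection))
        out["output_ce"] = float(output_ce_loss(student_out.logits, teacher_out.logits, batch))
    if recipe.variant == "compact":
        out["compact"] = float(compact_loss(student_out, teacher_out, recipe,
                                            attention_mask=batch.attention_mask))
    return out
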