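"""Training loops: task-agnostic distillation and continual MLM pretraining.

Both modes share one optimizer (decoupled weight decay, linear warmup then
linear decay, global-norm gradient clipping) and one deterministic batching
scheme, so a run is a pure function of its configuration seed.  The teacher
is frozen throughout distillation; only student parameters (and the width
projection Wp, when present) receive updates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Tensor
from .encoders import EncoderModel
from .errors import ConfigurationError
from .losses import (DistillationRecipe, combined_loss, component_losses,
                     mlm_loss, output_kl_loss)
from .masking import MaskedBatch, mask_tokens

SEED_MODULUS = 2 ** 31


@dataclass
class TrainConfig:
    mode: str = "distill"                 # {"distill", "continual_mlm"}
    steps: int = 1
    batch_size: int = 8
    learning_rate: float = 5e-4
    max_seq_len: int = 128
    seed: int = 0
    recipe: Optional[DistillationRecipe] = None
    warmup_fraction: float = 0.1
    weight_decay: float = 0.01
    clip_norm: float = 1.0
    select_rate: float = 0.15
    mask_prob: float = 0.80
    mask_id: int = 4
    special_ids: Sequence[int] = (0, 1, 2, 3, 4)
    log_interval: int = 10

    def __post_init__(self):
        if self.mode not in ("distill", "continual_mlm"):
            raise ConfigurationError(f"unknown training mode {self.mode!r}")
        if self.steps < 0 or self.batch_size < 1:
            raise ConfigurationError("steps must be >= 0 and batch_size >= 1")


# The production-scale configurations are shipped as presets only; tests and the
# worked examples always use desk-scale step counts.  Assumed defaults: the
# source does not report pretraining batch size, sequence length or optimizer.
FULL_SCALE_PRESETS = {
    "distill-100k": TrainConfig(mode="distill", steps=100_000, batch_size=192,
                                learning_rate=5e-4, max_seq_len=128),
    "continual-mlm-200k": TrainConfig(mode="continual_mlm", steps=200_000, batch_size=192,
                                      learning_rate=5e-4, max_seq_len=128),
}


class AdamW:
    """Adam with decoupled weight decay over a named parameter dict."""

    def __init__(self, params: Dict[str, Tensor], lr: float, weight_decay: float = 0.01,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, lr_scale: float = 1.0) -> None:
        self.t += 1
        lr = self.lr * lr_scale
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def linear_schedule(step: int, total_steps: int, warmup_fraction: float) -> float:
    """Linear warmup to 1, then linear decay to 0 at total_steps."""
    warm = max(1, int(round(warmup_fraction * total_steps)))
    if step < warm:
        return (step + 1) / warm
    if total_steps <= warm:
        return 1.0
    return max(0.0, (total_steps - step) / (total_steps - warm))


def clip_gradients(params: Dict[str, Tensor], max_norm: float) -> float:
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = np.sqrt(total)
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale
    return norm


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

def pad_batch(sequences: Sequence[Sequence[int]], max_len: int,
              pad_id: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Truncate/pad token-id sequences into (ids, attention_mask) arrays."""
    n = min(max(len(s) for s in sequences), max_len)
    ids = np.full((len(sequences), n), pad_id, dtype=np.int64)
    mask = np.zeros((len(sequences), n), dtype=np.int64)
    for i, s in enumerate(sequences):
        s = list(s)[:n]
        ids[i, :len(s)] = s
        mask[i, :len(s)] = 1
    return ids, mask


def sample_masked_batch(corpus: Sequence[Sequence[int]], cfg: TrainConfig,
                        step: int, vocab_size: int) -> MaskedBatch:
    """Deterministic per-step batch: sequences drawn by a step-derived seed,
    then masked with an independent step-derived seed (logged for replay)."""
    batch_seed = (cfg.seed * 1_000_003 + step) % SEED_MODULUS
    rng = np.random.default_rng(batch_seed)
    idx = rng.integers(0, len(corpus), size=cfg.batch_size)
    ids, mask = pad_batch([corpus[i] for i in idx], cfg.max_seq_len)
    return mask_tokens(ids, select_rate=cfg.select_rate, mask_prob=cfg.mask_prob,
                       rng_seed=(batch_seed + 1) % SEED_MODULUS,
                       special_ids=cfg.special_ids, mask_id=cfg.mask_id,
                       vocab_size=vocab_size, attention_mask=mask)


# ---------------------------------------------------------------------------
# runs
# ---------------------------------------------------------------------------

def _trainable(student: EncoderModel, recipe: Optional[DistillationRecipe]) -> Dict[str, Tensor]:
    params = dict(student.params)
    if recipe is not None and recipe.projection is not None:
        params["recipe.projection"] = recipe.projection
    return params


def _validate_recipe_shapes(teacher: EncoderModel, student: EncoderModel,
                            recipe: DistillationRecipe) -> None:
    if teacher.config.vocab_size != student.config.vocab_size:
        raise ConfigurationError("teacher and student must share a vocabulary")
    widths_differ = teacher.config.hidden_size != student.config.hidden_size
    if widths_differ and recipe.projection is None and recipe.variant != "distil":
        raise ConfigurationError(
            "student/teacher widths differ: the recipe needs a projection Wp")
    if recipe.variant == "distil" and widths_differ:
        raise ConfigurationError(
            "the distil recipe aligns last hidden states without projection; widths must match")
    if recipe.layer_map is not None:
        if max(recipe.layer_map.values()) > teacher.config.num_layers:
            raise ConfigurationError("layer_map points beyond the teacher's depth")
        if max(recipe.layer_map) > student.config.num_layers:
            raise ConfigurationError("layer_map points beyond the student's depth")
    if recipe.variant == "compact" and widths_differ:
        raise ConfigurationError("the compact loss requires equal hidden widths")


def distill_run(teacher: EncoderModel, student: EncoderModel,
                corpus: Sequence[Sequence[int]], cfg: TrainConfig
                ) -> Tuple[EncoderModel, List[dict]]:
    """Distil ``student`` against a frozen ``teacher``; returns the student
    and a per-interval trace of total and component losses."""
    if cfg.recipe is None:
        raise ConfigurationError("distill mode requires cfg.recipe")
    _validate_recipe_shapes(teacher, student, cfg.recipe)
    if cfg.steps == 0:
        return student, []
    teacher.set_trainable(False)
    params = _trainable(student, cfg.recipe)
    opt = AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    vocab = student.config.vocab_size
    trace: List[dict] = []
    for step in range(cfg.steps):
        batch = sample_masked_batch(corpus, cfg, step, vocab)
        t_out = teacher.forward(batch.input_ids, attention_mask=batch.attention_mask)
        s_out = student.forward(batch.input_ids, attention_mask=batch.attention_mask)
        loss = combined_loss(s_out, t_out, batch, cfg.recipe)
        opt.zero_grad()
        loss.backward()
        clip_gradients(params, cfg.clip_norm)
        opt.step(lr_scale=linear_schedule(step, cfg.steps, cfg.warmup_fraction))
        if step % cfg.log_interval == 0 or step == cfg.steps - 1:
            rec = {"step": step, "total": float(loss)}
            rec.update(component_losses(s_out, t_out, batch, cfg.recipe))
            trace.append(rec)
    return student, trace


def continual_mlm_run(model: EncoderModel, corpus: Sequence[Sequence[int]],
                      cfg: TrainConfig) -> Tuple[EncoderModel, List[dict]]:
    """Continue pretraining ``model`` with the MLM objective alone."""
    if cfg.mode != "continual_mlm":
        raise ConfigurationError("cfg.mode must be 'continual_mlm'")
    if cfg.steps == 0:
        return model, []
    model.set_trainable(True)
    params = model.trainable_params()
    opt = AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    vocab = model.config.vocab_size
    trace: List[dict] = []
    for step in range(cfg.steps):
        batch = sample_masked_batch(corpus, cfg, step, vocab)
        out = model.forward(batch.input_ids, attention_mask=batch.attention_mask)
        loss = mlm_loss(out.logits, batch)
        opt.zero_grad()
        loss.backward()
        clip_gradients(params, cfg.clip_norm)
        opt.step(lr_scale=linear_schedule(step, cfg.steps, cfg.warmup_fraction))
        if step % cfg.log_interval == 0 or step == cfg.steps - 1:
            trace.append({"step": step, "total": float(loss), "mlm": float(loss)})
    return model, trace


# ---------------------------------------------------------------------------
# held-out evaluation helpers
# ---------------------------------------------------------------------------

def held_out_mlm_loss(model: EncoderModel, batch: MaskedBatch) -> float:
    out = model.forward(batch.input_ids, attention_mask=batch.attention_mask)
    return float(mlm_loss(out.logits, batch))


def held_out_output_kl(student: EncoderModel, teacher: EncoderModel,
                       batch: MaskedBatch) -> float:
    s = student.forward(batch.input_ids, attention_mask=batch.attention_mask)
    t = teacher.forward(batch.input_ids, attention_mask=batch.attention_mask)
    return float(output_kl_loss(s.logits, t.logits, batch))
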