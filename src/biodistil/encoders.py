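"""BERT-style and MobileBERT-style encoders with exposed internals.

Two encoder families are implemented natively on numpy:

* ``bert`` — the standard post-layer-norm transformer encoder with learned
  absolute positions, token-type embeddings and a tied-decoder MLM head.
* ``mobilebert`` — the bottleneck design: 128-dimensional word embeddings
  combined into trigrams and linearly up-projected to a 512-wide inter-block
  stream; each of the (typically 24) blocks down-projects to a 128-wide
  intra-block bottleneck for attention and stacked feed-forward sub-blocks,
  then up-projects back, with elementwise-affine "NoNorm" in place of
  layer normalisation.

Every forward pass returns the per-layer hidden states (the embedding output
counts as layer 0) and the post-softmax, row-stochastic attention maps of
every layer — the quantities the layer-to-layer distillation losses align.
Pre-softmax attention scores can be requested as well.

Parameter shapes are a pure function of the configuration, so exact
parameter counts are available without allocating a model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .autodiff import Tensor, concat, embedding, layer_norm, parameter, softmax
from .errors import ConfigurationError

IGNORE_INDEX = -100
MLM_HEAD_PREFIX = "mlm."


@dataclass(frozen=True)
class MobileExtras:
    """Bottleneck-specific sizes; defaults follow the original MobileBERT."""

    inter_block_size: int = 512
    bottleneck_size: int = 128
    num_stacked_ffn: int = 4


@dataclass(frozen=True)
class EncoderConfig:
    num_layers: int
    hidden_size: int
    num_heads: int
    ffn_size: int
    vocab_size: int
    max_positions: int = 512
    num_token_types: int = 2
    embedding_size: Optional[int] = None
    family: str = "bert"
    mobile_extras: Optional[MobileExtras] = None

    def __post_init__(self):
        if self.family not in ("bert", "mobilebert"):
            raise ConfigurationError(f"unknown encoder family {self.family!r}")
        emb = self.embedding_size
        if emb is None:
            emb = self.hidden_size if self.family == "bert" else 128
            object.__setattr__(self, "embedding_size", emb)
        for name in ("hidden_size", "num_heads", "ffn_size", "vocab_size",
                     "max_positions", "num_token_types", "embedding_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.num_layers < 0:
            raise ConfigurationError("num_layers must be non-negative")
        if self.hidden_size % self.num_heads != 0:
            raise ConfigurationError(
                f"hidden_size ({self.hidden_size}) not divisible by num_heads ({self.num_heads})")
        if self.family == "bert" and self.embedding_size != self.hidden_size:
            raise ConfigurationError("bert family requires embedding_size == hidden_size")
        if self.family == "mobilebert":
            extras = self.mobile_extras or MobileExtras()
            object.__setattr__(self, "mobile_extras", extras)
            if extras.inter_block_size != self.hidden_size:
                raise ConfigurationError(
                    "mobile_extras.inter_block_size must equal hidden_size "
                    f"({extras.inter_block_size} != {self.hidden_size})")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @staticmethod
    def from_dict(d: dict) -> "EncoderConfig":
        d = dict(d)
        if d.get("mobile_extras"):
            d["mobile_extras"] = MobileExtras(**d["mobile_extras"])
        return EncoderConfig(**d)


# ---------------------------------------------------------------------------
# parameter shapes
# ---------------------------------------------------------------------------

def _bert_shapes(cfg: EncoderConfig) -> dict:
    H, F, V = cfg.hidden_size, cfg.ffn_size, cfg.vocab_size
    shapes = {
        "embeddings.word": (V, H),
        "embeddings.position": (cfg.max_positions, H),
        "embeddings.token_type": (cfg.num_token_types, H),
        "embeddings.ln.weight": (H,),
        "embeddings.ln.bias": (H,),
    }
    for i in range(cfg.num_layers):
        p = f"layer{i}."
        for name in ("q", "k", "v", "o"):
            shapes[p + f"attn.{name}.weight"] = (H, H)
            shapes[p + f"attn.{name}.bias"] = (H,)
        shapes[p + "attn.ln.weight"] = (H,)
        shapes[p + "attn.ln.bias"] = (H,)
        shapes[p + "ffn.in.weight"] = (H, F)
        shapes[p + "ffn.in.bias"] = (F,)
        shapes[p + "ffn.out.weight"] = (F, H)
        shapes[p + "ffn.out.bias"] = (H,)
        shapes[p + "ffn.ln.weight"] = (H,)
        shapes[p + "ffn.ln.bias"] = (H,)
    shapes.update({
        "mlm.dense.weight": (H, H),
        "mlm.dense.bias": (H,),
        "mlm.ln.weight": (H,),
        "mlm.ln.bias": (H,),
        "mlm.decoder.bias": (V,),  # decoder weight tied to embeddings.word
    })
    return shapes


def _mobilebert_shapes(cfg: EncoderConfig) -> dict:
    ex = cfg.mobile_extras
    H = cfg.hidden_size          # inter-block width (512)
    B = ex.bottleneck_size       # intra-block width (128)
    E = cfg.embedding_size       # 128
    F = cfg.ffn_size             # intermediate width (512)
    V = cfg.vocab_size
    shapes = {
        "embeddings.word": (V, E),
        "embeddings.position": (cfg.max_positions, H),
        "embeddings.token_type": (cfg.num_token_types, H),
        "embeddings.transform.weight": (3 * E, H),  # trigram concat up-projection
        "embeddings.transform.bias": (H,),
        "embeddings.norm.weight": (H,),
        "embeddings.norm.bias": (H,),
    }
    for i in range(cfg.num_layers):
        p = f"layer{i}."
        # shared key/query bottleneck plus the residual-input bottleneck
        for name in ("bottleneck.in", "bottleneck.attn"):
            shapes[p + name + ".weight"] = (H, B)
            shapes[p + name + ".bias"] = (B,)
            shapes[p + name + ".norm.weight"] = (B,)
            shapes[p + name + ".norm.bias"] = (B,)
        shapes[p + "attn.q.weight"] = (B, B)
        shapes[p + "attn.q.bias"] = (B,)
        shapes[p + "attn.k.weight"] = (B, B)
        shapes[p + "attn.k.bias"] = (B,)
        shapes[p + "attn.v.weight"] = (H, B)  # values read the 512-d block input
        shapes[p + "attn.v.bias"] = (B,)
        shapes[p + "attn.o.weight"] = (B, B)
        shapes[p + "attn.o.bias"] = (B,)
        shapes[p + "attn.norm.weight"] = (B,)
        shapes[p + "attn.norm.bias"] = (B,)
        for j in range(ex.num_stacked_ffn - 1):  # extra stacked FFN sub-blocks
            q = p + f"ffn{j}."
            shapes[q + "in.weight"] = (B, F)
            shapes[q + "in.bias"] = (F,)
            shapes[q + "out.weight"] = (F, B)
            shapes[q + "out.bias"] = (B,)
            shapes[q + "norm.weight"] = (B,)
            shapes[q + "norm.bias"] = (B,)
        shapes[p + "intermediate.weight"] = (B, F)
        shapes[p + "intermediate.bias"] = (F,)
        shapes[p + "output.weight"] = (F, B)
        shapes[p + "output.bias"] = (B,)
        shapes[p + "output.norm.weight"] = (B,)
        shapes[p + "output.norm.bias"] = (B,)
        shapes[p + "output.bottleneck.weight"] = (B, H)
        shapes[p + "output.bottleneck.bias"] = (H,)
        shapes[p + "output.bottleneck.norm.weight"] = (H,)
        shapes[p + "output.bottleneck.norm.bias"] = (H,)
    shapes.update({
        "mlm.dense.weight": (H, E),
        "mlm.dense.bias": (E,),
        "mlm.ln.weight": (E,),
        "mlm.ln.bias": (E,),
        "mlm.decoder.bias": (V,),
    })
    return shapes


def parameter_shapes(cfg: EncoderConfig) -> dict:
    """Name -> shape for every trainable array, a pure function of config."""
    if cfg.family == "bert":
        return _bert_shapes(cfg)
    return _mobilebert_shapes(cfg)


# ---------------------------------------------------------------------------
# outputs and model
# ---------------------------------------------------------------------------

@dataclass
class EncoderOutputs:
    """Per-layer internals of one forward pass.

    ``hidden_states`` has ``num_layers + 1`` entries (index 0 is the embedding
    output); ``attentions`` holds one row-stochastic ``(B, H, N, N)`` map per
    layer.  All entries are autodiff tensors; call ``.data`` for raw arrays.
    """

    logits: Optional[Tensor]
    hidden_states: list
    attentions: list
    attention_scores: Optional[list] = None


class EncoderModel:
    def __init__(self, config: EncoderConfig, params: dict):
        self.config = config
        self.params = params

    def __getitem__(self, name: str) -> Tensor:
        return self.params[name]

    def set_trainable(self, trainable: bool) -> None:
        for p in self.params.values():
            p.requires_grad = trainable

    def trainable_params(self) -> dict:
        return {k: v for k, v in self.params.items() if v.requires_grad}

    # -- forward passes -------------------------------------------------------
    def forward(self, input_ids, attention_mask=None, token_type_ids=None,
                compute_logits: bool = True, keep_scores: bool = False) -> EncoderOutputs:
        input_ids = np.atleast_2d(np.asarray(input_ids, dtype=np.int64))
        Bsz, N = input_ids.shape
        if N > self.config.max_positions:
            raise ConfigurationError(
                f"sequence length {N} exceeds max_positions {self.config.max_positions}")
        if attention_mask is None:
            attention_mask = np.ones_like(input_ids)
        attention_mask = np.atleast_2d(np.asarray(attention_mask))
        if token_type_ids is None:
            token_type_ids = np.zeros_like(input_ids)
        # additive bias: large negative at padded key positions
        bias = np.where(attention_mask[:, None, None, :] > 0, 0.0, -1e9)
        if self.config.family == "bert":
            return self._forward_bert(input_ids, token_type_ids, bias, compute_logits, keep_scores)
        return self._forward_mobile(input_ids, token_type_ids, bias, compute_logits, keep_scores)

    def _attention(self, q, k, v, bias, num_heads, head_dim, keep_scores):
        Bsz, N, _ = q.shape
        def split(t):
            return t.reshape(Bsz, N, num_heads, head_dim).transpose(0, 2, 1, 3)
        qh, kh, vh = split(q), split(k), split(v)
        scores = qh @ kh.swapaxes(-1, -2) * (1.0 / np.sqrt(head_dim)) + Tensor(bias)
        probs = softmax(scores, axis=-1)
        ctx = (probs @ vh).transpose(0, 2, 1, 3).reshape(Bsz, N, num_heads * head_dim)
        return ctx, probs, (scores if keep_scores else None)

    def _forward_bert(self, input_ids, token_type_ids, bias, compute_logits, keep_scores):
        cfg, P = self.config, self.params
        Bsz, N = input_ids.shape
        x = (embedding(P["embeddings.word"], input_ids)
             + P["embeddings.position"][np.arange(N)]
             + embedding(P["embeddings.token_type"], token_type_ids))
        x = layer_norm(x, P["embeddings.ln.weight"], P["embeddings.ln.bias"])
        hidden, attns, score_list = [x], [], []
        head_dim = cfg.hidden_size // cfg.num_heads
        for i in range(cfg.num_layers):
            p = f"layer{i}."
            q = x @ P[p + "attn.q.weight"] + P[p + "attn.q.bias"]
            k = x @ P[p + "attn.k.weight"] + P[p + "attn.k.bias"]
            v = x @ P[p + "attn.v.weight"] + P[p + "attn.v.bias"]
            ctx, probs, scores = self._attention(q, k, v, bias, cfg.num_heads, head_dim, keep_scores)
            attn_out = ctx @ P[p + "attn.o.weight"] + P[p + "attn.o.bias"]
            x = layer_norm(x + attn_out, P[p + "attn.ln.weight"], P[p + "attn.ln.bias"])
            h = _gelu(x @ P[p + "ffn.in.weight"] + P[p + "ffn.in.bias"])
            h = h @ P[p + "ffn.out.weight"] + P[p + "ffn.out.bias"]
            x = layer_norm(x + h, P[p + "ffn.ln.weight"], P[p + "ffn.ln.bias"])
            hidden.append(x)
            attns.append(probs)
            if keep_scores:
                score_list.append(scores)
        logits = self._mlm_logits(x) if compute_logits else None
        return EncoderOutputs(logits, hidden, attns, score_list if keep_scores else None)

    def _forward_mobile(self, input_ids, token_type_ids, bias, compute_logits, keep_scores):
        cfg, P = self.config, self.params
        ex = cfg.mobile_extras
        Bsz, N = input_ids.shape
        w = embedding(P["embeddings.word"], input_ids)  # (B, N, 128)
        zeros = Tensor(np.zeros((Bsz, 1, cfg.embedding_size)))
        left = concat([w[:, 1:], zeros], axis=1)    # next token
        right = concat([zeros, w[:, :-1]], axis=1)  # previous token
        tri = concat([left, w, right], axis=-1)
        x = tri @ P["embeddings.transform.weight"] + P["embeddings.transform.bias"]
        x = x + P["embeddings.position"][np.arange(N)] \
              + embedding(P["embeddings.token_type"], token_type_ids)
        x = _no_norm(x, P["embeddings.norm.weight"], P["embeddings.norm.bias"])
        hidden, attns, score_list = [x], [], []
        head_dim = ex.bottleneck_size // cfg.num_heads
        for i in range(cfg.num_layers):
            p = f"layer{i}."
            narrowed = _no_norm(x @ P[p + "bottleneck.in.weight"] + P[p + "bottleneck.in.bias"],
                                P[p + "bottleneck.in.norm.weight"], P[p + "bottleneck.in.norm.bias"])
            shared = _no_norm(x @ P[p + "bottleneck.attn.weight"] + P[p + "bottleneck.attn.bias"],
                              P[p + "bottleneck.attn.norm.weight"], P[p + "bottleneck.attn.norm.bias"])
            q = shared @ P[p + "attn.q.weight"] + P[p + "attn.q.bias"]
            k = shared @ P[p + "attn.k.weight"] + P[p + "attn.k.bias"]
            v = x @ P[p + "attn.v.weight"] + P[p + "attn.v.bias"]
            ctx, probs, scores = self._attention(q, k, v, bias, cfg.num_heads, head_dim, keep_scores)
            a = ctx @ P[p + "attn.o.weight"] + P[p + "attn.o.bias"]
            a = _no_norm(a + narrowed, P[p + "attn.norm.weight"], P[p + "attn.norm.bias"])
            for j in range(ex.num_stacked_ffn - 1):
                q_ = p + f"ffn{j}."
                h = (a @ P[q_ + "in.weight"] + P[q_ + "in.bias"]).relu()
                h = h @ P[q_ + "out.weight"] + P[q_ + "out.bias"]
                a = _no_norm(a + h, P[q_ + "norm.weight"], P[q_ + "norm.bias"])
            h = (a @ P[p + "intermediate.weight"] + P[p + "intermediate.bias"]).relu()
            h = h @ P[p + "output.weight"] + P[p + "output.bias"]
            a = _no_norm(a + h, P[p + "output.norm.weight"], P[p + "output.norm.bias"])
            up = a @ P[p + "output.bottleneck.weight"] + P[p + "output.bottleneck.bias"]
            x = _no_norm(up + x, P[p + "output.bottleneck.norm.weight"],
                         P[p + "output.bottleneck.norm.bias"])
            hidden.append(x)
            attns.append(probs)
            if keep_scores:
                score_list.append(scores)
        logits = self._mlm_logits(x) if compute_logits else None
        return EncoderOutputs(logits, hidden, attns, score_list if keep_scores else None)

    def _mlm_logits(self, x: Tensor) -> Tensor:
        P = self.params
        h = _gelu(x @ P["mlm.dense.weight"] + P["mlm.dense.bias"])
        h = layer_norm(h, P["mlm.ln.weight"], P["mlm.ln.bias"])
        return h @ P["embeddings.word"].swapaxes(0, 1) + P["mlm.decoder.bias"]


def _gelu(x: Tensor) -> Tensor:
    return x * 0.5 * ((x * (1.0 / np.sqrt(2.0))).erf() + 1.0)


def _no_norm(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """MobileBERT's normalisation-free elementwise affine."""
    return x * weight + bias


# ---------------------------------------------------------------------------
# construction, counting, student initialisation
# ---------------------------------------------------------------------------

def build_encoder(config: EncoderConfig, seed: int = 0) -> EncoderModel:
    """Build a freshly initialised encoder.

    Weights are truncated-normal (std 0.02, clipped at two standard
    deviations); biases and norm offsets start at zero, norm gains at one.
    Initialisation is fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    params = {}
    for name, shape in parameter_shapes(config).items():
        if name.endswith(("ln.weight", "norm.weight")):
            data = np.ones(shape)
        elif name.endswith("bias"):
            data = np.zeros(shape)
        else:
            data = _truncated_normal(rng, shape, std=0.02)
        params[name] = parameter(data)
    return EncoderModel(config, params)


def _truncated_normal(rng, shape, std: float, clip: float = 2.0) -> np.ndarray:
    out = rng.standard_normal(shape)
    while True:
        bad = np.abs(out) > clip
        if not bad.any():
            break
        out[bad] = rng.standard_normal(bad.sum())
    return out * std


def count_parameters(model_or_config, include_mlm_head: bool = False) -> int:
    """Exact trainable-parameter count.

    The decoder of the MLM head is tied to the word-embedding table and is
    therefore never double-counted; with ``include_mlm_head=False`` the head's
    transform and bias are excluded as well (backbone-only count).
    """
    if isinstance(model_or_config, EncoderModel):
        items = {k: v.data.shape for k, v in model_or_config.params.items()}
    else:
        items = parameter_shapes(model_or_config)
    total = 0
    for name, shape in items.items():
        if not include_mlm_head and name.startswith(MLM_HEAD_PREFIX):
            continue
        total += int(np.prod(shape))
    return total


def millions(n_params: int, nearest: int = 1) -> int:
    """Round a parameter count to the nearest ``nearest`` million."""
    return nearest * round(n_params / (nearest * 1e6))


def init_student_from_teacher(teacher: EncoderModel, student_config: EncoderConfig,
                              offset: int = 0) -> EncoderModel:
    """Initialise a shallower student by copying a strided subset of teacher layers.

    Embedding tables and the MLM head are copied verbatim.  With a teacher of
    T layers and a student of S (T a multiple of S), student layer i receives
    teacher layer ``offset + i * (T // S)`` — the "every other layer" scheme
    when T = 2S and offset = 0.  The student's widths must match the
    teacher's, which is exactly the restriction this scheme imposes.
    """
    tcfg = teacher.config
    if student_config.family != tcfg.family:
        raise ConfigurationError("student and teacher must share the encoder family")
    for f in ("hidden_size", "embedding_size", "vocab_size", "ffn_size", "num_heads"):
        if getattr(student_config, f) != getattr(tcfg, f):
            raise ConfigurationError(
                f"student {f} ({getattr(student_config, f)}) must equal teacher's "
                f"({getattr(tcfg, f)}): strided initialisation cannot change widths")
    S, T = student_config.num_layers, tcfg.num_layers
    if S == 0 or T % S != 0:
        raise ConfigurationError(f"teacher depth {T} is not a multiple of student depth {S}")
    stride = T // S
    if offset < 0 or offset + (S - 1) * stride >= T:
        raise ConfigurationError(f"offset {offset} leaves the teacher's layer range")
    params = {}
    for name, shape in parameter_shapes(student_config).items():
        if name.startswith("layer"):
            idx, rest = name.split(".", 1)
            src = f"layer{offset + int(idx[5:]) * stride}.{rest}"
        else:
            src = name
        params[name] = parameter(teacher.params[src].data.copy())
    return EncoderModel(student_config, params)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: EncoderModel, path: str) -> None:
    """Write ``<path>.npz`` (named arrays) and ``<path>.json`` (config sidecar)."""
    path = Path(path)
    np.savez(str(path) + ".npz", **{k: v.data for k, v in model.params.items()})
    Path(str(path) + ".json").write_text(json.dumps(model.config.to_dict(), indent=1))


def load_checkpoint(path: str) -> EncoderModel:
    cfg = EncoderConfig.from_dict(json.loads(Path(str(path) + ".json").read_text()))
    with np.load(str(path) + ".npz") as arrays:
        params = {k: parameter(arrays[k]) for k in arrays.files}
    expected = parameter_shapes(cfg)
    if set(params) != set(expected):
        raise ConfigurationError("checkpoint arrays do not match the sidecar config")
    return EncoderModel(cfg, params)


# ---------------------------------------------------------------------------
# named architectures
# ---------------------------------------------------------------------------

PRESETS = {
    # 6-layer distilled student / its 12-layer biomedical teacher (cased vocab)
    "distil-student": EncoderConfig(num_layers=6, hidden_size=768, num_heads=12,
                                    ffn_size=3072, vocab_size=28996),
    "base-teacher": EncoderConfig(num_layers=12, hidden_size=768, num_heads=12,
                                  ffn_size=3072, vocab_size=28996),
    # 4-layer width-312 student
    "tiny-student": EncoderConfig(num_layers=4, hidden_size=312, num_heads=12,
                                  ffn_size=1200, vocab_size=28996),
    # 24-layer bottleneck encoder
    "mobile": EncoderConfig(num_layers=24, hidden_size=512, num_heads=4,
                            ffn_size=512, vocab_size=30522, embedding_size=128,
                            family="mobilebert", mobile_extras=MobileExtras()),
}
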