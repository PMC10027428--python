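"""Fine-tuning heads, label plumbing and metrics for NER, RE and extractive QA.

NER sentences carry word-level BIO tags; because the encoders operate on
WordPiece sub-words, each word's label is propagated to all of its
sub-words before fine-tuning, and evaluation can be run either at sub-word
level on the propagated labels or at word level through each word's first
sub-word.  RE is sentence-pair classification scored with binary or
macro-averaged F1.  QA is extractive span prediction scored with the
factoid metrics strict accuracy (gold at rank 1), lenient accuracy (gold in
the top-k window, k=5) and mean reciprocal rank over that window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import f1_score as _sk_f1

from .autodiff import Tensor, parameter, softmax
from .encoders import EncoderModel
from .errors import EvaluationError, ValidationError
from .masking import IGNORE_INDEX
from .tokenization import WordPieceTokenizer
from .training import AdamW, clip_gradients

logger = logging.getLogger(__name__)

LENIENT_WINDOW = 5  # top-k window for lenient accuracy and MRR

# benchmark-protocol presets for full-size models; desk-scale runs override lr
FINETUNE_PRESETS = {
    "ner": {"epochs": 5, "batch_size": 16, "learning_rate": 5e-5},
    "ner-alt": {"epochs": 5, "batch_size": 32, "learning_rate": 3e-5},
    "re": {"epochs": 3, "batch_size": 16, "learning_rate": 5e-5},
    "re-alt": {"epochs": 3, "batch_size": 16, "learning_rate": 3e-5},
    "qa": {"epochs": 3, "batch_size": 16, "learning_rate": 5e-5},
    "qa-alt": {"epochs": 3, "batch_size": 16, "learning_rate": 3e-5},
}


# ---------------------------------------------------------------------------
# task examples
# ---------------------------------------------------------------------------

def _check_bio(tags: Sequence[str]) -> None:
    prev = "O"
    for t in tags:
        if t == "O":
            prev = t
            continue
        if "-" not in t or t.split("-", 1)[0] not in ("B", "I"):
            raise ValidationError(f"malformed BIO tag {t!r}")
        kind, etype = t.split("-", 1)
        if kind == "I":
            if prev == "O" or prev.split("-", 1)[1] != etype:
                raise ValidationError(f"orphan I- tag {t!r} (previous tag {prev!r})")
        prev = t


@dataclass
class TaggedSentence:
    words: List[str]
    tags: List[str]

    def __post_init__(self):
        if len(self.words) != len(self.tags):
            raise ValidationError(
                f"{len(self.words)} words but {len(self.tags)} tags")
        _check_bio(self.tags)


@dataclass
class REExample:
    sentence: str
    label: str

    def validate_label(self, label_set) -> None:
        if label_set is not None and self.label not in label_set:
            raise ValidationError(f"label {self.label!r} outside the task label set")


@dataclass
class QAExample:
    question: str
    context: str
    answer_spans: List[Tuple[int, int]]  # 0-based half-open character offsets

    def __post_init__(self):
        for k, (a, b) in enumerate(self.answer_spans):
            if not (0 <= a < b <= len(self.context)):
                raise ValidationError(
                    f"answer span {k} ({a}, {b}) does not lie inside the context "
                    f"(length {len(self.context)})")

    @property
    def answers(self) -> List[str]:
        return [self.context[a:b] for a, b in self.answer_spans]


# ---------------------------------------------------------------------------
# label plumbing
# ---------------------------------------------------------------------------

def propagate_labels_to_subwords(sentence: TaggedSentence,
                                 tokenization: Sequence[Sequence[str]]) -> List[str]:
    """Assign each word's tag verbatim to every one of its sub-words."""
    if len(tokenization) != len(sentence.words):
        raise ValidationError("tokenization does not cover every word")
    out: List[str] = []
    for word, tag, pieces in zip(sentence.words, sentence.tags, tokenization):
        if len(pieces) == 0:
            raise ValidationError(f"word {word!r} tokenized to zero sub-words")
        out.extend([tag] * len(pieces))
    return out


def repair_bio(tags: Sequence[str]) -> List[str]:
    """Promote orphan I- tags to B- (conlleval-style repair of predictions)."""
    out, prev = [], "O"
    for t in tags:
        if t.startswith("I-") and (prev == "O" or prev[2:] != t[2:]):
            t = "B-" + t[2:]
        out.append(t)
        prev = t
    return out


def extract_entities(tags: Sequence[str]) -> List[Tuple[int, int, str]]:
    """(start, end_exclusive, type) spans from a repaired BIO sequence."""
    tags = repair_bio(tags)
    spans, start, etype = [], None, None
    for i, t in enumerate(tags):
        if t.startswith("B-"):
            if start is not None:
                spans.append((start, i, etype))
            start, etype = i, t[2:]
        elif t.startswith("I-") and start is not None and t[2:] == etype:
            continue
        else:
            if start is not None:
                spans.append((start, i, etype))
            start, etype = None, None
    if start is not None:
        spans.append((start, len(tags), etype))
    return spans


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def entity_f1(gold: Sequence[TaggedSentence],
              predicted: Sequence[Sequence[str]]) -> Tuple[float, float, float]:
    """Entity-level (exact span + type) micro-averaged precision/recall/F1, in percent."""
    if len(gold) != len(predicted):
        raise EvaluationError(f"{len(gold)} gold sentences but {len(predicted)} predictions")
    tp = n_pred = n_gold = 0
    for g, p in zip(gold, predicted):
        if len(g.tags) != len(p):
            raise EvaluationError("prediction length differs from sentence length")
        gset = set(extract_entities(g.tags))
        pset = set(extract_entities(p))
        tp += len(gset & pset)
        n_pred += len(pset)
        n_gold += len(gset)
    prec = tp / n_pred if n_pred else 0.0
    rec = tp / n_gold if n_gold else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return 100 * prec, 100 * rec, 100 * f1


def re_f1(gold: Sequence[str], predicted: Sequence[str], averaging: str = "binary",
          positive_label: Optional[str] = None,
          label_set: Optional[Sequence[str]] = None) -> float:
    """Relation-classification F1 in percent: positive-class (binary) or
    unweighted macro average over classes."""
    if len(gold) != len(predicted):
        raise EvaluationError("gold/prediction length mismatch")
    labels = set(label_set) if label_set is not None else set(gold)
    unknown = (set(gold) | set(predicted)) - labels
    if unknown:
        raise EvaluationError(f"unknown labels: {sorted(unknown)}")
    if averaging == "binary":
        if positive_label is None:
            cands = sorted(labels - {"0", "false", "negative", "no_relation", "O"})
            if not cands:
                raise EvaluationError("cannot infer a positive label")
            positive_label = cands[0]
        return 100 * _sk_f1(list(gold), list(predicted), pos_label=positive_label,
                            average="binary", zero_division=0)
    if averaging == "macro":
        return 100 * _sk_f1(list(gold), list(predicted), labels=sorted(labels),
                            average="macro", zero_division=0)
    raise EvaluationError(f"unknown averaging mode {averaging!r}")


def _normalise_answer(s: str) -> str:
    return " ".join(s.strip().casefold().split())


def qa_metrics(ranked_candidates: Sequence[Sequence[str]],
               gold_answers: Sequence[Sequence[str]],
               k: int = LENIENT_WINDOW) -> Tuple[float, float, float]:
    """(strict accuracy, lenient accuracy, MRR) over the top-k window."""
    if len(ranked_candidates) != len(gold_answers):
        raise EvaluationError("candidate/gold length mismatch")
    strict = lenient = mrr = 0.0
    n = len(gold_answers)
    if n == 0:
        return 0.0, 0.0, 0.0
    for cands, golds in zip(ranked_candidates, gold_answers):
        if len(cands) == 0:
            logger.warning("question with empty candidate list counted as a miss")
            continue
        gset = {_normalise_answer(g) for g in golds}
        window = [_normalise_answer(c) for c in cands[:k]]
        rank = next((i + 1 for i, c in enumerate(window) if c in gset), None)
        if rank is not None:
            mrr += 1.0 / rank
            lenient += 1.0
            if rank == 1:
                strict += 1.0
    return strict / n, lenient / n, mrr / n


def extract_best_span(start_scores, end_scores, max_span_len: int,
                      top_n: int = LENIENT_WINDOW):
    """Rank candidate (start, end) spans (inclusive indices) by
    ``start_score + end_score`` subject to start <= end and span length
    <= max_span_len.  Ties break to the lowest start, then lowest end.

    Returns ``(best_span, ranked_spans)``."""
    s = np.asarray(start_scores, dtype=float)
    e = np.asarray(end_scores, dtype=float)
    if s.shape != e.shape or s.ndim != 1 or s.size == 0:
        raise EvaluationError("start/end scores must be equal-length non-empty vectors")
    cands = [(i, j, s[i] + e[j])
             for i in range(s.size)
             for j in range(i, min(i + max_span_len, s.size))]
    cands.sort(key=lambda t: (-t[2], t[0], t[1]))
    ranked = [(i, j) for i, j, _ in cands[:max(top_n, 1)]]
    return ranked[0], ranked


def split_gad(examples: Sequence, test_fraction: float = 0.1,
              seed: int = 0) -> Tuple[list, list]:
    """Seeded random train/test partition; |test| = round(fraction * n)."""
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction must lie strictly between 0 and 1")
    n = len(examples)
    if n < 2:
        raise ValidationError("need at least 2 examples to split")
    k = int(round(test_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    test_idx = set(perm[:k].tolist())
    train = [examples[i] for i in range(n) if i not in test_idx]
    test = [examples[i] for i in range(n) if i in test_idx]
    return train, test


# ---------------------------------------------------------------------------
# fine-tuning heads
# ---------------------------------------------------------------------------

def _softmax_ce(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over rows whose label != IGNORE_INDEX."""
    keep = labels != IGNORE_INDEX
    if not keep.any():
        return Tensor(0.0)
    rows = logits[keep]
    ids = labels[keep]
    logp = (softmax(rows, axis=-1) + 1e-12).log()
    return -logp[np.arange(ids.size), ids].sum() * (1.0 / ids.size)


def _encode_tagged(tok: WordPieceTokenizer, sent: TaggedSentence, tag_ids: Dict[str, int],
                   max_len: int):
    ids, word_idx = tok.encode_words(sent.words)
    sub_tags = propagate_labels_to_subwords(sent, tok.tokenize(sent.words))
    labels, t = [], 0
    for wi in word_idx:
        labels.append(IGNORE_INDEX if wi < 0 else tag_ids[sub_tags[t]])
        if wi >= 0:
            t += 1
    return ids[:max_len], word_idx[:max_len], labels[:max_len]


class _FinetuneBase:
    """Shared optimisation loop over (ids, mask, label) batches."""

    def _train(self, batches, params, epochs, lr, seed, loss_fn):
        opt = AdamW(params, lr=lr, weight_decay=0.01)
        order_rng = np.random.default_rng(seed)
        n_total = max(1, epochs * len(batches))
        step = 0
        for _ in range(epochs):
            for bi in order_rng.permutation(len(batches)):
                loss = loss_fn(batches[bi])
                opt.zero_grad()
                loss.backward()
                clip_gradients(params, 1.0)
                scale = max(0.05, (n_total - step) / n_total)  # linear decay
                opt.step(lr_scale=scale)
                step += 1


class NerTagger(_FinetuneBase):
    """Token classifier: encoder top hidden states -> linear -> BIO tags."""

    def __init__(self, model: EncoderModel, tokenizer: WordPieceTokenizer,
                 label_list: Sequence[str], seed: int = 0):
        self.model = model
        self.tok = tokenizer
        self.labels = list(label_list)
        self.tag_ids = {t: i for i, t in enumerate(self.labels)}
        rng = np.random.default_rng(seed)
        d = model.config.hidden_size
        self.head_w = parameter(rng.standard_normal((d, len(self.labels))) * 0.02)
        self.head_b = parameter(np.zeros(len(self.labels)))

    def _batchify(self, sentences, batch_size, max_len):
        enc = [_encode_tagged(self.tok, s, self.tag_ids, max_len) for s in sentences]
        batches = []
        for i in range(0, len(enc), batch_size):
            chunk = enc[i:i + batch_size]
            n = max(len(c[0]) for c in chunk)
            ids = np.zeros((len(chunk), n), dtype=np.int64)
            mask = np.zeros((len(chunk), n), dtype=np.int64)
            lab = np.full((len(chunk), n), IGNORE_INDEX, dtype=np.int64)
            for r, (cid, _, clab) in enumerate(chunk):
                ids[r, :len(cid)] = cid
                mask[r, :len(cid)] = 1
                lab[r, :len(clab)] = clab
            batches.append((ids, mask, lab))
        return batches

    def _logits(self, ids, mask) -> Tensor:
        out = self.model.forward(ids, attention_mask=mask, compute_logits=False)
        return out.hidden_states[-1] @ self.head_w + self.head_b

    def fit(self, sentences: Sequence[TaggedSentence], epochs: int = 5,
            batch_size: int = 16, lr: float = 5e-5, seed: int = 0,
            max_len: int = 64) -> "NerTagger":
        batches = self._batchify(sentences, batch_size, max_len)
        self.model.set_trainable(True)
        params = dict(self.model.trainable_params(),
                      **{"head.w": self.head_w, "head.b": self.head_b})
        self._train(batches, params, epochs, lr, seed,
                    lambda b: _softmax_ce(self._logits(b[0], b[1]), b[2]))
        return self

    def predict(self, sentences: Sequence[TaggedSentence],
                granularity: str = "word", max_len: int = 64) -> List[List[str]]:
        """Word-level tags (each word's first sub-word decides, the protocol's
        inverse of label propagation) or sub-word-level propagated tags."""
        preds = []
        for s in sentences:
            ids, word_idx = self.tok.encode_words(s.words)
            ids, word_idx = ids[:max_len], word_idx[:max_len]
            logits = self._logits(np.array([ids]), np.ones((1, len(ids)), dtype=np.int64))
            best = np.argmax(logits.data[0], axis=-1)
            if granularity == "subword":
                preds.append(repair_bio([self.labels[b] for b, wi in zip(best, word_idx)
                                         if wi >= 0]))
                continue
            word_tags = ["O"] * len(s.words)
            seen = set()
            for b, wi in zip(best, word_idx):
                if wi >= 0 and wi not in seen:
                    word_tags[wi] = self.labels[b]
                    seen.add(wi)
            preds.append(repair_bio(word_tags))
        return preds


class ReClassifier(_FinetuneBase):
    """Sentence classifier on the [CLS] position's top hidden state."""

    def __init__(self, model: EncoderModel, tokenizer: WordPieceTokenizer,
                 label_list: Sequence[str], seed: int = 0):
        self.model = model
        self.tok = tokenizer
        self.labels = list(label_list)
        self.label_ids = {l: i for i, l in enumerate(self.labels)}
        rng = np.random.default_rng(seed)
        d = model.config.hidden_size
        self.head_w = parameter(rng.standard_normal((d, len(self.labels))) * 0.02)
        self.head_b = parameter(np.zeros(len(self.labels)))

    def _batchify(self, examples, batch_size, max_len):
        enc = [(self.tok.encode_text(ex.sentence, add_specials=True)[:max_len],
                self.label_ids[ex.label]) for ex in examples]
        batches = []
        for i in range(0, len(enc), batch_size):
            chunk = enc[i:i + batch_size]
            n = max(len(c[0]) for c in chunk)
            ids = np.zeros((len(chunk), n), dtype=np.int64)
            mask = np.zeros((len(chunk), n), dtype=np.int64)
            lab = np.array([c[1] for c in chunk], dtype=np.int64)
            for r, (cid, _) in enumerate(chunk):
                ids[r, :len(cid)] = cid
                mask[r, :len(cid)] = 1
            batches.append((ids, mask, lab))
        return batches

    def _logits(self, ids, mask) -> Tensor:
        out = self.model.forward(ids, attention_mask=mask, compute_logits=False)
        return out.hidden_states[-1][:, 0] @ self.head_w + self.head_b

    def fit(self, examples: Sequence[REExample], epochs: int = 3, batch_size: int = 16,
            lr: float = 5e-5, seed: int = 0, max_len: int = 64) -> "ReClassifier":
        batches = self._batchify(examples, batch_size, max_len)
        self.model.set_trainable(True)
        params = dict(self.model.trainable_params(),
                      **{"head.w": self.head_w, "head.b": self.head_b})
        self._train(batches, params, epochs, lr, seed,
                    lambda b: _softmax_ce(self._logits(b[0], b[1]), b[2]))
        return self

    def predict(self, examples: Sequence[REExample], max_len: int = 64) -> List[str]:
        out = []
        for ex in examples:
            ids = self.tok.encode_text(ex.sentence, add_specials=True)[:max_len]
            logits = self._logits(np.array([ids]), np.ones((1, len(ids)), dtype=np.int64))
            out.append(self.labels[int(np.argmax(logits.data[0]))])
        return out


def _word_offsets(text: str) -> List[Tuple[str, int, int]]:
    """Whitespace words with their half-open character offsets."""
    out, i = [], 0
    for w in text.split():
        start = text.index(w, i)
        out.append((w, start, start + len(w)))
        i = start + len(w)
    return out


class QaSpanPredictor(_FinetuneBase):
    """Extractive QA: per-token start/end scores over the context segment."""

    def __init__(self, model: EncoderModel, tokenizer: WordPieceTokenizer, seed: int = 0):
        self.model = model
        self.tok = tokenizer
        rng = np.random.default_rng(seed)
        d = model.config.hidden_size
        self.head_w = parameter(rng.standard_normal((d, 2)) * 0.02)
        self.head_b = parameter(np.zeros(2))

    def _encode(self, ex: QAExample, max_len: int):
        """[CLS] question [SEP] context [SEP]; returns ids and, for each
        position, the context-word char span it belongs to (None otherwise)."""
        ids = [self.tok.ids["[CLS]"]]
        spans: List[Optional[Tuple[int, int]]] = [None]
        for w in ex.question.split():
            for p in self.tok.tokenize_word(w):
                ids.append(self.tok.ids.get(p, self.tok.ids["[UNK]"]))
                spans.append(None)
        ids.append(self.tok.ids["[SEP]"])
        spans.append(None)
        for w, a, b in _word_offsets(ex.context):
            for p in self.tok.tokenize_word(w):
                ids.append(self.tok.ids.get(p, self.tok.ids["[UNK]"]))
                spans.append((a, b))
        ids.append(self.tok.ids["[SEP]"])
        spans.append(None)
        return ids[:max_len], spans[:max_len]

    def _scores(self, ids, mask) -> Tensor:
        out = self.model.forward(ids, attention_mask=mask, compute_logits=False)
        return out.hidden_states[-1] @ self.head_w + self.head_b  # (B, N, 2)

    def fit(self, examples: Sequence[QAExample], epochs: int = 3, batch_size: int = 16,
            lr: float = 5e-5, seed: int = 0, max_len: int = 96) -> "QaSpanPredictor":
        encoded = []
        for ex in examples:
            ids, spans = self._encode(ex, max_len)
            a, b = ex.answer_spans[0]
            tok_pos = [i for i, sp in enumerate(spans) if sp and sp[0] < b and a < sp[1]]
            if not tok_pos:
                continue  # answer truncated away
            encoded.append((ids, tok_pos[0], tok_pos[-1]))
        batches = []
        for i in range(0, len(encoded), batch_size):
            chunk = encoded[i:i + batch_size]
            n = max(len(c[0]) for c in chunk)
            ids = np.zeros((len(chunk), n), dtype=np.int64)
            mask = np.zeros((len(chunk), n), dtype=np.int64)
            st = np.array([c[1] for c in chunk], dtype=np.int64)
            en = np.array([c[2] for c in chunk], dtype=np.int64)
            for r, (cid, _, _) in enumerate(chunk):
                ids[r, :len(cid)] = cid
                mask[r, :len(cid)] = 1
            batches.append((ids, mask, st, en))
        self.model.set_trainable(True)
        params = dict(self.model.trainable_params(),
                      **{"head.w": self.head_w, "head.b": self.head_b})

        def loss_fn(b):
            ids, mask, st, en = b
            sc = self._scores(ids, mask)
            return _softmax_ce(sc[:, :, 0], st) + _softmax_ce(sc[:, :, 1], en)

        self._train(batches, params, epochs, lr, seed, loss_fn)
        return self

    def predict(self, examples: Sequence[QAExample], max_span_len: int = 8,
                max_len: int = 96) -> List[List[str]]:
        """Per question, the top-ranked candidate answer strings."""
        out = []
        for ex in examples:
            ids, spans = self._encode(ex, max_len)
            ctx = [i for i, sp in enumerate(spans) if sp is not None]
            if not ctx:
                out.append([])
                continue
            sc = self._scores(np.array([ids]), np.ones((1, len(ids)), dtype=np.int64)).data[0]
            _, ranked = extract_best_span(sc[ctx, 0], sc[ctx, 1], max_span_len)
            answers = []
            for i, j in ranked:
                a = spans[ctx[i]][0]
                b = spans[ctx[j]][1]
                answers.append(ex.context[a:b])
            out.append(answers)
        return out
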