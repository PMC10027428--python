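"""Seeded synthetic data: corpora, tiny warm teachers and toy task datasets.

The generators stand in for large biomedical resources so every part of the
toolkit is exercisable offline at desk scale:

* ``generate_corpus`` — token-id sequences with Zipf-distributed frequencies
  (real text is heavy-tailed; a uniform corpus makes the MLM loss flat) and
  one planted bigram rule (a trigger token followed by a fixed target with
  high probability) that gives masked-LM training something learnable.
* ``make_tiny_teacher`` — a small encoder briefly MLM-trained on that corpus
  so its predictions are informative enough to distil from.
* ``generate_toy_tasks`` — NER sentences whose entities come from a fixed
  sub-vocabulary of multi-piece words, RE sentence pairs whose label is a
  deterministic function of the template verb, and QA contexts whose answer
  is a verbatim span.

Every generator is a pure function of its spec (identical re-runs are
byte-identical).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple

import numpy as np

from .dataio import write_conll, write_corpus, write_qa_json, write_re_tsv
from .encoders import EncoderConfig, EncoderModel, build_encoder
from .errors import ConfigurationError
from .finetune import QAExample, REExample, TaggedSentence, split_gad
from .tokenization import SPECIAL_TOKENS, WordPieceTokenizer, write_vocab
from .training import TrainConfig, continual_mlm_run

N_SPECIALS = len(SPECIAL_TOKENS)

_HEAD_STEM = "prot"    # mention-initial entity words
_TAIL_STEM = "gene"    # mention-continuation entity words
_ENTITY_SUFFIXES = list("abcdefghij")
_POSITIVE_VERBS = ["activates", "inhibits"]
_NEGATIVE_VERBS = ["near", "mentions"]
_QA_WORDS = ["the", "answer", "is", "what", ".", "?"]
_RE_MARKERS = ["@GENE$", "@DISEASE$"]


@dataclass
class SyntheticSpec:
    vocab_size: int = 64          # specials + filler tokens used by the MLM corpus
    n_sequences: int = 400
    min_len: int = 8
    max_len: int = 32
    zipf_exponent: float = 1.1
    bigram_prob: float = 0.9      # P(target | trigger) for the planted rule
    n_entities: int = 8
    n_ner_sentences: int = 120
    n_re_examples: int = 120
    n_qa_examples: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.vocab_size < N_SPECIALS + 2:
            raise ConfigurationError("vocab_size leaves no room for content tokens")
        if self.n_entities > len(_ENTITY_SUFFIXES):
            raise ConfigurationError(f"at most {len(_ENTITY_SUFFIXES)} entity words supported")
        if not 0 <= self.bigram_prob <= 1:
            raise ConfigurationError("bigram_prob must be a fraction")
        if self.min_len < 2 or self.max_len < self.min_len:
            raise ConfigurationError("degenerate length distribution")

    # planted rule: the two most frequent content tokens
    @property
    def bigram_trigger(self) -> int:
        return N_SPECIALS

    @property
    def bigram_target(self) -> int:
        return N_SPECIALS + 1

    @property
    def filler_words(self) -> List[str]:
        return [f"w{i}" for i in range(N_SPECIALS, self.vocab_size)]

    @property
    def entity_head_words(self) -> List[str]:
        return [_HEAD_STEM + s for s in _ENTITY_SUFFIXES[:self.n_entities]]

    @property
    def entity_tail_words(self) -> List[str]:
        return [_TAIL_STEM + s for s in _ENTITY_SUFFIXES[:self.n_entities]]

    @property
    def entity_words(self) -> List[str]:
        return self.entity_head_words + self.entity_tail_words


def build_vocab(spec: SyntheticSpec) -> List[str]:
    """Full WordPiece vocabulary: specials, corpus fillers, entity pieces
    (stem + ``##`` suffixes, so entity words split into two sub-words) and
    the task template words."""
    vocab = list(SPECIAL_TOKENS) + spec.filler_words
    vocab.extend([_HEAD_STEM, _TAIL_STEM])
    vocab.extend("##" + s for s in _ENTITY_SUFFIXES[:spec.n_entities])
    vocab.extend(_POSITIVE_VERBS + _NEGATIVE_VERBS + _QA_WORDS + _RE_MARKERS)
    return vocab


def generate_corpus(spec: SyntheticSpec) -> Tuple[List[List[int]], List[str]]:
    """Token-id sequences over the filler sub-vocabulary plus the vocabulary.

    Filler token i (by frequency rank) is drawn with probability
    proportional to 1 / (i+1)^zipf_exponent; whenever the trigger token is
    emitted, the next token is the target with probability ``bigram_prob``.
    """
    rng = np.random.default_rng(spec.seed)
    content = np.arange(N_SPECIALS, spec.vocab_size)
    ranks = np.arange(1, content.size + 1, dtype=float)
    probs = ranks ** -spec.zipf_exponent
    probs /= probs.sum()
    # after a trigger, the non-rule branch excludes the target so that
    # P(target | trigger) is exactly bigram_prob
    no_target = probs.copy()
    no_target[content == spec.bigram_target] = 0.0
    no_target /= no_target.sum()
    corpus: List[List[int]] = []
    for _ in range(spec.n_sequences):
        n = int(rng.integers(spec.min_len, spec.max_len + 1))
        seq: List[int] = []
        for _ in range(n):
            if seq and seq[-1] == spec.bigram_trigger:
                if rng.random() < spec.bigram_prob:
                    seq.append(spec.bigram_target)
                else:
                    seq.append(int(rng.choice(content, p=no_target)))
            else:
                seq.append(int(rng.choice(content, p=probs)))
        corpus.append(seq)
    return corpus, build_vocab(spec)


def make_tiny_teacher(config: EncoderConfig, corpus: List[List[int]],
                      warm_steps: int, seed: int = 0) -> EncoderModel:
    """A small encoder briefly MLM-trained on the corpus so its masked-token
    predictions carry signal (held-out MLM loss below the ln|V| uniform
    baseline).  ``warm_steps=0`` returns the random initialisation."""
    model = build_encoder(config, seed=seed)
    if warm_steps == 0:
        return model
    cfg = TrainConfig(mode="continual_mlm", steps=warm_steps, batch_size=8,
                      learning_rate=5e-3, max_seq_len=min(32, config.max_positions),
                      seed=seed)
    model, _ = continual_mlm_run(model, corpus, cfg)
    return model


def generate_toy_tasks(spec: SyntheticSpec
                       ) -> Tuple[List[TaggedSentence], List[REExample], List[QAExample]]:
    """Toy NER/RE/QA datasets with planted learnable patterns.

    NER: entities are drawn from the fixed entity sub-vocabulary (one- or
    two-word mentions, valid BIO runs); the entity/filler distinction is a
    deterministic function of the token, so a bag-of-tokens baseline can
    solve the task — the point is that signal is present, not that it is
    hard.  RE: the label is a deterministic function of the template verb.
    QA: the answer is always a verbatim, non-empty span of the context.
    """
    rng = np.random.default_rng(spec.seed + 1)
    fillers = spec.filler_words
    # disjoint initial/continuation sub-vocabularies (distinct stems) keep each
    # token's tag a deterministic function of the token itself, so the planted
    # signal is learnable even from the first sub-word alone
    heads, tails = spec.entity_head_words, spec.entity_tail_words

    ner: List[TaggedSentence] = []
    for _ in range(spec.n_ner_sentences):
        words, tags = [], []
        for _ in range(int(rng.integers(5, 11))):
            if rng.random() < 0.3:
                words.append(str(rng.choice(heads)))
                tags.append("B-ENT")
                if rng.random() < 0.4:
                    words.append(str(rng.choice(tails)))
                    tags.append("I-ENT")
            else:
                words.append(str(rng.choice(fillers)))
                tags.append("O")
        ner.append(TaggedSentence(words, tags))

    re_examples: List[REExample] = []
    for _ in range(spec.n_re_examples):
        positive = bool(rng.random() < 0.5)
        verb = str(rng.choice(_POSITIVE_VERBS if positive else _NEGATIVE_VERBS))
        tail = " ".join(str(rng.choice(fillers)) for _ in range(int(rng.integers(2, 5))))
        sentence = f"{_RE_MARKERS[0]} {verb} {_RE_MARKERS[1]} {tail}"
        re_examples.append(REExample(sentence, "positive" if positive else "negative"))

    qa: List[QAExample] = []
    for _ in range(spec.n_qa_examples):
        answer = str(rng.choice(spec.entity_words))
        pre = " ".join(str(rng.choice(fillers)) for _ in range(int(rng.integers(2, 5))))
        post = " ".join(str(rng.choice(fillers)) for _ in range(int(rng.integers(2, 5))))
        context = f"{pre} the answer is {answer} . {post}"
        start = len(pre) + len(" the answer is ")
        qa.append(QAExample(question="what is the answer ?", context=context,
                            answer_spans=[(start, start + len(answer))]))
    return ner, re_examples, qa


def corpus_to_documents(corpus: List[List[int]], vocab: List[str]) -> List[str]:
    return [" ".join(vocab[i] for i in seq) for seq in corpus]


def write_fixture_tree(spec: SyntheticSpec, out_dir) -> dict:
    """Write the complete fixture tree (corpus, vocabulary, task files);
    deterministic given the spec, so identical seeds give byte-identical trees."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus, vocab = generate_corpus(spec)
    write_vocab(vocab, out / "vocab.txt")
    write_corpus(corpus_to_documents(corpus, vocab), out / "corpus.txt")
    ner, re_examples, qa = generate_toy_tasks(spec)
    cut = max(1, len(ner) * 4 // 5)
    write_conll(ner[:cut], out / "ner_train.conll")
    write_conll(ner[cut:], out / "ner_test.conll")
    re_train, re_test = split_gad(re_examples, test_fraction=0.1, seed=spec.seed)
    write_re_tsv(re_train, out / "re_train.tsv")
    write_re_tsv(re_test, out / "re_test.tsv")
    cut_qa = max(1, len(qa) * 4 // 5)
    write_qa_json(qa[:cut_qa], out / "qa_train.json")
    write_qa_json(qa[cut_qa:], out / "qa_test.json")
    return {"n_ner": len(ner), "n_re": len(re_examples), "n_qa": len(qa),
            "vocab_size": len(vocab)}
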