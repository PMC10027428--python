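"""Readers and writers for the on-disk formats, run configs and manifests.

Formats: CoNLL token-per-line files with BIO tags (NER), tab-separated
``sentence<TAB>label`` files (RE), SQuAD-style JSON with character-offset
answers (QA), plain-text corpora (one document per line) and WordPiece
vocabulary files.  Readers validate and reject malformed records rather
than coercing them; writers round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .finetune import QAExample, REExample, TaggedSentence
from .tokenization import WordPieceTokenizer


# ---------------------------------------------------------------------------
# CoNLL (NER)
# ---------------------------------------------------------------------------

def read_conll(path) -> List[TaggedSentence]:
    """Blank-line-separated sentences, one ``token<TAB>tag`` (or
    space-separated) pair per line; the dialect is auto-detected."""
    sentences: List[TaggedSentence] = []
    words: List[str] = []
    tags: List[str] = []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line.strip():
            if words:
                sentences.append(TaggedSentence(words, tags))
                words, tags = [], []
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 'token<TAB>tag', got {line!r}")
        words.append(parts[0])
        tags.append(parts[1])
    if words:
        sentences.append(TaggedSentence(words, tags))
    return sentences


def write_conll(sentences: Sequence[TaggedSentence], path) -> None:
    lines = []
    for s in sentences:
        lines.extend(f"{w}\t{t}" for w, t in zip(s.words, s.tags))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# RE (TSV)
# ---------------------------------------------------------------------------

def read_re_tsv(path, label_set: Optional[Sequence[str]] = None) -> List[REExample]:
    examples: List[REExample] = []
    labels = set(label_set) if label_set is not None else None
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 'sentence<TAB>label'")
        ex = REExample(sentence=parts[0], label=parts[1])
        if labels is not None and ex.label not in labels:
            raise ValidationError(f"{path}:{lineno}: label {ex.label!r} outside the label set")
        examples.append(ex)
    return examples


def write_re_tsv(examples: Sequence[REExample], path) -> None:
    Path(path).write_text(
        "\n".join(f"{ex.sentence}\t{ex.label}" for ex in examples) + "\n",
        encoding="utf-8")


# ---------------------------------------------------------------------------
# QA (SQuAD-style JSON)
# ---------------------------------------------------------------------------

def read_qa_json(path) -> List[QAExample]:
    """SQuAD-style records: ``answer_start`` is a 0-based *character* offset;
    spans are validated against the context (multi-byte characters count as
    one position each)."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    examples: List[QAExample] = []
    for k, rec in enumerate(doc["examples"]):
        spans = []
        for ans in rec["answers"]:
            a = int(ans["answer_start"])
            b = a + len(ans["text"])
            if not (0 <= a < b <= len(rec["context"])):
                raise ValidationError(f"record {k}: answer span ({a}, {b}) out of bounds")
            if rec["context"][a:b] != ans["text"]:
                raise ValidationError(f"record {k}: answer text does not match its offsets")
            spans.append((a, b))
        try:
            examples.append(QAExample(question=rec["question"], context=rec["context"],
                                      answer_spans=spans))
        except ValidationError as err:
            raise ValidationError(f"record {k}: {err}") from err
    return examples


def write_qa_json(examples: Sequence[QAExample], path) -> None:
    doc = {"examples": [
        {"question": ex.question, "context": ex.context,
         "answers": [{"text": ex.context[a:b], "answer_start": a}
                     for a, b in ex.answer_spans]}
        for ex in examples]}
    Path(path).write_text(json.dumps(doc, ensure_ascii=False, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

def read_corpus(path, tokenizer: WordPieceTokenizer) -> List[List[int]]:
    """One document per line, streamed through the WordPiece tokenizer."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(tokenizer.encode_text(line))
    return out


def write_corpus(documents: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(documents) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# run configuration and manifests
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    mode: str = "distill"
    teacher: Optional[str] = None
    student: Optional[str] = None
    model: Optional[str] = None
    recipe: dict = field(default_factory=dict)
    steps: int = 100
    batch_size: int = 8
    learning_rate: float = 5e-4
    max_seq_len: int = 128
    seed: int = 0
    corpus: Optional[str] = None
    vocab: Optional[str] = None
    train_file: Optional[str] = None
    test_file: Optional[str] = None
    out_dir: str = "runs"

    @staticmethod
    def load(path, **overrides) -> "RunConfig":
        """YAML/JSON config file; keyword overrides (CLI flags) win."""
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return RunConfig(**data)


def write_manifest(out_dir, config: dict, seed: int) -> Path:
    """Record everything needed to replay a run bit-for-bit."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "seed": seed,
        "versions": {"python": platform.python_version(), "numpy": np.__version__},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str), encoding="utf-8")
    return path
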