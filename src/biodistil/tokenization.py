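"""WordPiece vocabulary handling and greedy sub-word tokenization.

The vocabulary file is plain text, one token per line; the line number is
the token id.  Continuation pieces carry the ``##`` prefix.  Tokenization is
greedy longest-match-first, the standard WordPiece inference algorithm.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence

SPECIAL_TOKENS = ["[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"]
PAD_ID, UNK_ID, CLS_ID, SEP_ID, MASK_ID = range(5)


def read_vocab(path) -> List[str]:
    return Path(path).read_text(encoding="utf-8").splitlines()


def write_vocab(tokens: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(tokens) + "\n", encoding="utf-8")


class WordPieceTokenizer:
    def __init__(self, vocab: Sequence[str], unk_token: str = "[UNK]",
                 max_word_chars: int = 100):
        self.vocab: List[str] = list(vocab)
        self.ids: Dict[str, int] = {tok: i for i, tok in enumerate(self.vocab)}
        self.unk_token = unk_token
        self.max_word_chars = max_word_chars

    @classmethod
    def from_file(cls, path) -> "WordPieceTokenizer":
        return cls(read_vocab(path))

    def tokenize_word(self, word: str) -> List[str]:
        """Greedy longest-match split of one word into pieces."""
        if len(word) > self.max_word_chars:
            return [self.unk_token]
        pieces, start = [], 0
        while start < len(word):
            end = len(word)
            piece = None
            while start < end:
                cand = word[start:end]
                if start > 0:
                    cand = "##" + cand
                if cand in self.ids:
                    piece = cand
                    break
                end -= 1
            if piece is None:
                return [self.unk_token]
            pieces.append(piece)
            start = end
        return pieces

    def tokenize(self, words: Sequence[str]) -> List[List[str]]:
        """Per-word piece lists (the word -> sub-word expansion used when
        propagating labels)."""
        return [self.tokenize_word(w) for w in words]

    def convert_tokens_to_ids(self, tokens: Sequence[str]) -> List[int]:
        unk = self.ids[self.unk_token]
        return [self.ids.get(t, unk) for t in tokens]

    def encode_words(self, words: Sequence[str], add_specials: bool = True):
        """Returns (ids, word_index_per_piece); specials get word index -1."""
        ids: List[int] = []
        word_idx: List[int] = []
        if add_specials:
            ids.append(self.ids["[CLS]"])
            word_idx.append(-1)
        for i, w in enumerate(words):
            for p in self.tokenize_word(w):
                ids.append(self.ids.get(p, self.ids[self.unk_token]))
                word_idx.append(i)
        if add_specials:
            ids.append(self.ids["[SEP]"])
            word_idx.append(-1)
        return ids, word_idx

    def encode_text(self, text: str, add_specials: bool = False) -> List[int]:
        """Whitespace pre-split, then WordPiece; used for corpus streaming."""
        ids: List[int] = []
        if add_specials:
            ids.append(self.ids["[CLS]"])
        for w in text.split():
            ids.extend(self.ids.get(p, self.ids[self.unk_token])
                       for p in self.tokenize_word(w))
        if add_specials:
            ids.append(self.ids["[SEP]"])
        return ids
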