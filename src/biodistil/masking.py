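"""MLM data collator.

Selects ~15% of eligible tokens for prediction and corrupts them: 80% become
the dedicated mask token and the remaining 20% a random non-special token
(an optional keep-unchanged branch, off by default, makes the classic
80/10/10 scheme reachable).  Positions never selected keep their original
ids and carry an ignore label, so only masked tokens contribute to the MLM
and output-distillation losses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Set

import numpy as np

from .errors import ConfigurationError

IGNORE_INDEX = -100

DEFAULT_SELECT_RATE = 0.15
DEFAULT_MASK_PROB = 0.80


@dataclass
class MaskedBatch:
    """A masked input/label pair.

    ``input_ids`` is the corrupted sequence; ``labels`` holds the original id
    at selected positions and ``IGNORE_INDEX`` elsewhere; ``mask_weights`` is
    the 0/1 indicator of selected positions (``labels != IGNORE_INDEX``), the
    coefficient that restricts the output losses to masked tokens.
    """

    input_ids: np.ndarray
    labels: np.ndarray
    attention_mask: np.ndarray
    mask_weights: np.ndarray

    @property
    def num_masked(self) -> int:
        return int(self.mask_weights.sum())


def mask_tokens(token_ids,
                select_rate: float = DEFAULT_SELECT_RATE,
                mask_prob: float = DEFAULT_MASK_PROB,
                rng_seed: int = 0,
                special_ids: Iterable[int] = (0, 1, 2, 3, 4),
                mask_id: int = 4,
                vocab_size: Optional[int] = None,
                keep_prob: float = 0.0,
                attention_mask=None,
                exact_count: bool = False) -> MaskedBatch:
    """Apply MLM masking to a 1-D or 2-D integer id array.

    Each eligible position (non-special, non-padding) is independently
    selected with probability ``select_rate``; with ``exact_count=True`` an
    exact ``round(select_rate * n_eligible)``-sized subset is drawn instead.
    A selected position is replaced by ``mask_id`` with probability
    ``mask_prob``, kept unchanged with probability ``keep_prob`` and
    otherwise replaced by a uniformly random non-special id below
    ``vocab_size``.  The result is a pure function of the arguments.
    """
    if not 0.0 <= select_rate <= 1.0:
        raise ConfigurationError(f"select_rate must lie in [0, 1], got {select_rate}")
    if not 0.0 <= mask_prob <= 1.0 or not 0.0 <= keep_prob <= 1.0 or mask_prob + keep_prob > 1.0:
        raise ConfigurationError("mask_prob/keep_prob must be fractions with sum <= 1")
    ids = np.asarray(token_ids, dtype=np.int64)
    if vocab_size is None:
        vocab_size = int(ids.max(initial=0)) + 1
    if mask_id >= vocab_size:
        raise ConfigurationError(f"mask_id {mask_id} outside vocabulary of size {vocab_size}")
    special: Set[int] = set(int(s) for s in special_ids)
    if attention_mask is None:
        attention_mask = np.ones_like(ids)
    attention_mask = np.asarray(attention_mask)

    labels = np.full_like(ids, IGNORE_INDEX)
    input_ids = ids.copy()
    if ids.size == 0:
        return MaskedBatch(input_ids, labels, attention_mask, np.zeros_like(ids))

    rng = np.random.default_rng(rng_seed)
    eligible = (attention_mask > 0) & ~np.isin(ids, sorted(special))
    if exact_count:
        flat_idx = np.flatnonzero(eligible.reshape(-1))
        k = round(select_rate * flat_idx.size)
        chosen = rng.choice(flat_idx, size=k, replace=False) if k else np.array([], dtype=np.int64)
        selected = np.zeros(ids.size, dtype=bool)
        selected[chosen] = True
        selected = selected.reshape(ids.shape)
    else:
        selected = eligible & (rng.random(ids.shape) < select_rate)

    labels[selected] = ids[selected]
    u = rng.random(ids.shape)
    to_mask = selected & (u < mask_prob)
    to_keep = selected & ~to_mask & (u < mask_prob + keep_prob)
    to_random = selected & ~to_mask & ~to_keep
    input_ids[to_mask] = mask_id
    n_random = int(to_random.sum())
    if n_random:
        candidates = np.setdiff1d(np.arange(vocab_size), sorted(special))
        if candidates.size == 0:
            raise ConfigurationError("no non-special ids available for random replacement")
        input_ids[to_random] = rng.choice(candidates, size=n_random)

    mask_weights = (labels != IGNORE_INDEX).astype(np.int64)
    return MaskedBatch(input_ids, labels, attention_mask, mask_weights)
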