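import numpy as np
import pytest

from biodistil.encoders import EncoderConfig, build_encoder
from biodistil.synthetic import SyntheticSpec, generate_corpus, make_tiny_teacher
from biodistil.training import TrainConfig, sample_masked_batch

TINY_VOCAB = 64  # matches SyntheticSpec default


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=123)


@pytest.fixture(scope="session")
def corpus_and_vocab(spec):
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def teacher_config(spec):
    return EncoderConfig(num_layers=2, hidden_size=16, num_heads=2, ffn_size=32,
                         vocab_size=spec.vocab_size, max_positions=64)


@pytest.fixture(scope="session")
def student_config(spec):
    return EncoderConfig(num_layers=1, hidden_size=16, num_heads=2, ffn_size=32,
                         vocab_size=spec.vocab_size, max_positions=64)


@pytest.fixture(scope="session")
def warm_teacher(teacher_config, corpus_and_vocab):
    corpus, _ = corpus_and_vocab
    return make_tiny_teacher(teacher_config, corpus, warm_steps=300, seed=0)


@pytest.fixture(scope="session")
def held_out_batch(spec, corpus_and_vocab):
    corpus, _ = corpus_and_vocab
    cfg = TrainConfig(mode="continual_mlm", steps=1, batch_size=16,
                      max_seq_len=32, seed=20_000)
    return sample_masked_batch(corpus, cfg, 0, spec.vocab_size)


def micro_outputs(seed: int, vocab: int = 8, n_layers: int = 2, hidden: int = 6,
                  heads: int = 2, seq: int = 4, batch: int = 1):
    """A real forward pass of a micro encoder, for oracle comparisons."""
    cfg = EncoderConfig(num_layers=n_layers, hidden_size=hidden, num_heads=heads,
                        ffn_size=hidden * 2, vocab_size=vocab, max_positions=16)
    model = build_encoder(cfg, seed=seed)
    rng = np.random.default_rng(seed + 1)
    ids = rng.integers(5, vocab, size=(batch, seq))
    return model, model.forward(ids), ids
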