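"""Shared fixtures: vocabularies, tiny configs and toy labeled data."""

import numpy as np
import pytest

from condphage import build_vocabulary
from condphage.model import ClassifierConfig, ConditionalEncoder, EncoderConfig, SegmentClassifier
from condphage.seqio import Segment


@pytest.fixture(scope="session")
def vocab6():
    return build_vocabulary(6)


@pytest.fixture(scope="session")
def vocab3():
    """Small vocabulary (4^3 + 7 = 71 tokens) for fast model tests."""
    return build_vocabulary(3)


def make_segment(sequence: str, label=None, parent="test", start=0) -> Segment:
    return Segment(parent_id=parent, start=start, end=start + len(sequence),
                   sequence=sequence, label=label)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def micro_config(vocab3):
    """A very small encoder for fast unit tests (short sequences, k=3)."""
    return EncoderConfig(vocab_size=vocab3.size, num_layers=2, hidden_size=32,
                         num_heads=2, ff_size=64, max_positions=64, dropout=0.0)


@pytest.fixture()
def micro_encoder(micro_config):
    return ConditionalEncoder(micro_config, np.random.default_rng(0))


@pytest.fixture()
def micro_classifier(micro_config):
    encoder = ConditionalEncoder(micro_config, np.random.default_rng(0))
    return SegmentClassifier(encoder, ClassifierConfig(lstm_hidden=8, mlp_hidden=8),
                             np.random.default_rng(1))
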