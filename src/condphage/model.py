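"""Conditional encoder and classifier models.

Two model objects are exposed:

* :class:`ConditionalEncoder` — a BERT-style transformer over k-mer tokens
  whose position-0 input is a class token ([BAC]/[PHA], or [CLS] in the
  unconditional ablation), with a masked-language-modeling output head used
  during pre-training.
* :class:`SegmentClassifier` — the fine-tuned classifier: the encoder's
  per-position representations feed a bidirectional LSTM whose pooled final
  states go through a small MLP emitting class probabilities over
  (bacteria, phage, paradox) — or (bacteria, phage) in the no-paradox
  ablation.

Checkpoints are single ``.npz`` files holding the config, the k-mer size
and all weights; save → load reproduces bit-identical inference outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from . import nn
from .tokenizer import EncodedSegment, KmerVocabulary, build_vocabulary, stack_encoded

CHECKPOINT_FORMAT = 1


def trim_to_content(ids: np.ndarray, attention_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop all-pad trailing columns of a batch (outputs at non-pad positions
    are unaffected because padded keys are masked out of attention)."""
    n = int(attention_mask.sum(axis=1).max())
    if n >= ids.shape[1]:
        return ids, attention_mask
    return ids[:, :n], attention_mask[:, :n]


@dataclass(frozen=True)
class EncoderConfig:
    """Transformer encoder hyperparameters.

    Presets: ``"published"`` mirrors the full-scale genomic-BERT setting
    (12 layers, hidden 768, 12 heads); ``"tiny"`` (2 layers, hidden 64,
    4 heads) runs every stage on a desktop CPU and is the default for
    tests and examples.
    """

    vocab_size: int
    num_layers: int = 2
    hidden_size: int = 64
    num_heads: int = 4
    ff_size: int = 256
    max_positions: int = 512
    dropout: float = 0.0

    def __post_init__(self):
        if self.hidden_size % self.num_heads != 0:
            raise ValueError("hidden_size must be divisible by num_heads")

    @classmethod
    def preset(cls, name: str, vocab_size: int) -> "EncoderConfig":
        if name == "published":
            return cls(vocab_size=vocab_size, num_layers=12, hidden_size=768,
                       num_heads=12, ff_size=3072, max_positions=512, dropout=0.1)
        if name == "tiny":
            return cls(vocab_size=vocab_size)
        raise ValueError(f"unknown preset {name!r}; choose 'published' or 'tiny'")


@dataclass(frozen=True)
class ClassifierConfig:
    """BiLSTM + MLP head hyperparameters. ``num_classes`` is 3 for the
    paradox-augmented scheme, 2 for the no-paradox ablation."""

    lstm_hidden: int = 32
    mlp_hidden: int = 32
    num_classes: int = 3
    dropout: float = 0.0

    def __post_init__(self):
        if self.num_classes not in (2, 3):
            raise ValueError("num_classes must be 3 (paradox scheme) or 2 (ablation)")


@dataclass
class TokenRepresentations:
    """Last-layer hidden vectors for the non-pad positions of one segment."""

    hidden: np.ndarray  # [n_tokens, hidden]
    attention_mask: np.ndarray

    @property
    def label_token_vector(self) -> np.ndarray:
        """The position-0 (class token) vector — the conditioning summary."""
        return self.hidden[0]


class ConditionalEncoder(nn.Module):
    """Transformer encoder + MLM head over the k-mer vocabulary."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.config = config
        self.dtype = dtype
        self.encoder = self.child(
            "encoder",
            nn.TransformerEncoder(
                vocab_size=config.vocab_size,
                max_positions=config.max_positions,
                hidden=config.hidden_size,
                n_layers=config.num_layers,
                n_heads=config.num_heads,
                ff=config.ff_size,
                dropout=config.dropout,
                rng=rng,
                dtype=dtype,
            ),
        )
        self.mlm_head = self.child(
            "mlm_head", nn.Dense(config.hidden_size, config.vocab_size, rng, dtype)
        )

    # -- array-level API used by training loops -------------------------------
    def hidden_states(self, ids, attention_mask, train=False, rng=None) -> np.ndarray:
        """Last-layer hidden states, [B, L, hidden]."""
        return self.encoder.forward(ids, attention_mask, train=train, rng=rng)

    # -- segment-level API -----------------------------------------------------
    def encode_tokens(self, encoded: EncodedSegment) -> TokenRepresentations:
        """Deterministic inference representations for one encoded segment."""
        ids = encoded.ids[None, :]
        mask = encoded.attention_mask[None, :]
        self._check_vocab(ids)
        hidden = self.hidden_states(ids, mask)[0]
        n = encoded.n_tokens
        return TokenRepresentations(hidden=hidden[:n], attention_mask=mask[0, :n])

    def mlm_logits(self, reps: TokenRepresentations) -> np.ndarray:
        """Per-position scores over the vocabulary, [n_tokens, vocab]."""
        return self.mlm_head.forward(reps.hidden)

    def mlm_probabilities(self, reps: TokenRepresentations) -> np.ndarray:
        """Per-position probability distributions over the vocabulary."""
        return nn.softmax(self.mlm_logits(reps), axis=-1)

    def _check_vocab(self, ids: np.ndarray) -> None:
        if ids.max() >= self.config.vocab_size:
            raise ValueError(
                f"token id {int(ids.max())} out of range for vocab_size="
                f"{self.config.vocab_size}: vocabulary/config mismatch"
            )


class SegmentClassifier(nn.Module):
    """Encoder + BiLSTM + MLP emitting per-class probabilities."""

    def __init__(
        self,
        encoder: ConditionalEncoder,
        clf_config: ClassifierConfig,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        super().__init__()
        self.clf_config = clf_config
        self.cond_encoder = self.child("cond_encoder", encoder)
        hidden = encoder.config.hidden_size
        self.bilstm = self.child("bilstm", nn.BiLSTMPool(hidden, clf_config.lstm_hidden, rng, dtype))
        self.mlp1 = self.child("mlp1", nn.Dense(self.bilstm.out_dim, clf_config.mlp_hidden, rng, dtype))
        self.mlp2 = self.child("mlp2", nn.Dense(clf_config.mlp_hidden, clf_config.num_classes, rng, dtype))
        self.drop = self.child("drop", nn.Dropout(clf_config.dropout))

    @property
    def num_classes(self) -> int:
        return self.clf_config.num_classes

    def logits(self, ids, attention_mask, train=False, rng=None) -> np.ndarray:
        """Class logits [B, num_classes] from token-id arrays."""
        ids, attention_mask = trim_to_content(ids, attention_mask)
        h = self.cond_encoder.hidden_states(ids, attention_mask, train=train, rng=rng)
        pooled = self.bilstm.forward(h, attention_mask)
        self._pre = self.mlp1.forward(pooled)
        z = self.drop.forward(nn.relu(self._pre), train, rng)
        return self.mlp2.forward(z)

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        dz = self.mlp2.backward(dlogits)
        dpooled = self.mlp1.backward(self.drop.backward(dz) * nn.relu_grad(self._pre))
        dh = self.bilstm.backward(dpooled)
        self.cond_encoder.encoder.backward(dh)

    def probabilities(self, ids, attention_mask) -> np.ndarray:
        """Class probabilities [B, num_classes] (inference mode)."""
        return nn.softmax(self.logits(ids, attention_mask), axis=-1)

    def classify(self, encoded: EncodedSegment) -> np.ndarray:
        """Probability vector for one encoded segment."""
        p = self.probabilities(encoded.ids[None, :], encoded.attention_mask[None, :])
        return p[0]

    def classify_batch(self, encoded: list[EncodedSegment], batch_size: int = 16) -> np.ndarray:
        """Probabilities [N, num_classes] for a list of encoded segments."""
        ids, mask = stack_encoded(encoded)
        out = []
        for i in range(0, len(encoded), batch_size):
            out.append(self.probabilities(ids[i : i + batch_size], mask[i : i + batch_size]))
        return np.concatenate(out, axis=0)


# -- checkpoints ---------------------------------------------------------------


def save_checkpoint(model: nn.Module, path, *, k: int, kind: str,
                    extra: Optional[dict] = None) -> None:
    """Serialize a model, its config and the k-mer size to one ``.npz``."""
    if kind == "encoder":
        config = asdict(model.config)
        clf_config = None
    elif kind == "classifier":
        config = asdict(model.cond_encoder.config)
        clf_config = asdict(model.clf_config)
    else:
        raise ValueError(f"unknown checkpoint kind {kind!r}")
    meta = {
        "format": CHECKPOINT_FORMAT,
        "kind": kind,
        "k": k,
        "encoder_config": config,
        "classifier_config": clf_config,
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[nn.Module, KmerVocabulary, dict]:
    """Load a checkpoint; returns (model, vocabulary, meta).

    The model is reconstructed with a throwaway init rng and then
    overwritten with the stored weights, so loading is deterministic.
    """
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    if meta["format"] != CHECKPOINT_FORMAT:
        raise ValueError(f"unsupported checkpoint format {meta['format']}")
    vocab = build_vocabulary(meta["k"])
    enc_config = EncoderConfig(**meta["encoder_config"])
    rng = np.random.default_rng(0)
    encoder = ConditionalEncoder(enc_config, rng)
    if meta["kind"] == "encoder":
        model: nn.Module = encoder
    else:
        model = SegmentClassifier(encoder, ClassifierConfig(**meta["classifier_config"]), rng)
    model.load_state_dict(state)
    return model, vocab, meta
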