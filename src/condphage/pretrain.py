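"""Label-constrained masked language modeling.

Pre-training corrupts 15% of the non-special token positions of each
encoded segment (80% to [MASK], 10% to a random k-mer token, 10% left
unchanged) and trains the encoder to restore the original tokens from the
surrounding context *and* the class token at position 0. Because bacterial
segments carry [BAC] and phage segments carry [PHA], the encoder learns
label-conditioned context statistics rather than a single mixture — the
point of conditioning, and the reason the class-token representations of
the two classes separate after pre-training.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.metrics import silhouette_score

from . import nn
from .model import ConditionalEncoder, EncoderConfig
from .seqio import Segment
from .tokenizer import (
    CLS,
    EncodedSegment,
    KmerVocabulary,
    encode,
    encode_with_class_token,
    stack_encoded,
)

#: Target value marking positions that do not contribute to the MLM loss.
IGNORE_INDEX = -100


@dataclass
class MaskedBatch:
    """Encoded segments after MLM corruption.

    ``targets`` holds the original token id exactly at corrupted positions
    and :data:`IGNORE_INDEX` everywhere else; ``mask_positions`` is the
    boolean corruption map.
    """

    corrupted_ids: np.ndarray
    targets: np.ndarray
    mask_positions: np.ndarray
    attention_mask: np.ndarray

    @property
    def n_masked(self) -> int:
        return int(self.mask_positions.sum())


def _as_rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def mask_token_arrays(
    ids: np.ndarray,
    attention_mask: np.ndarray,
    vocab: KmerVocabulary,
    rng: np.random.Generator,
    mask_rate: float = 0.15,
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> MaskedBatch:
    """Array-level MLM corruption (the collator core).

    Each non-special position (not the class token, not [SEP], not padding)
    is selected independently with probability ``mask_rate``; selected
    positions are replaced with [MASK] / a random non-special token / left
    unchanged according to ``proportions``. Unchanged-but-selected
    positions still carry a target. Fully reproducible from ``rng``.
    """
    if not 0.0 <= mask_rate <= 1.0:
        raise ValueError("mask_rate must be in [0, 1]")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    maskable = attention_mask.astype(bool).copy()
    maskable[:, 0] = False  # class token
    maskable &= ids != vocab.sep_id
    u = rng.random(ids.shape)
    selected = maskable & (u < mask_rate)
    r = rng.random(ids.shape)
    p_mask, p_rand, _ = proportions
    to_mask = selected & (r < p_mask)
    to_rand = selected & (r >= p_mask) & (r < p_mask + p_rand)
    corrupted = ids.copy()
    corrupted[to_mask] = vocab.mask_id
    n_rand = int(to_rand.sum())
    if n_rand:
        # replacement pool excludes special tokens so no spurious label signal
        corrupted[to_rand] = rng.integers(vocab.n_specials, vocab.size, size=n_rand)
    targets = np.where(selected, ids, IGNORE_INDEX).astype(np.int64)
    return MaskedBatch(
        corrupted_ids=corrupted,
        targets=targets,
        mask_positions=selected,
        attention_mask=attention_mask,
    )


def apply_mlm_mask(
    batch: Sequence[EncodedSegment],
    vocab: KmerVocabulary,
    mask_rate: float = 0.15,
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    rng_seed: Union[int, np.random.Generator] = 0,
) -> MaskedBatch:
    """Corrupt a batch of encoded segments for masked language modeling."""
    ids, mask = stack_encoded(list(batch))
    return mask_token_arrays(ids, mask, vocab, _as_rng(rng_seed), mask_rate, proportions)


@dataclass(frozen=True)
class PretrainConfig:
    """Optimization schedule for pre-training.

    The ``"published"`` preset carries the published large-scale schedule
    (lr 4e-4, batch 2048, 10,000 warmup steps, weight decay 0.01); the
    default desk preset is sized so a tiny encoder trains on one CPU in a
    couple of minutes.
    """

    steps: int = 80
    batch_size: int = 8
    lr: float = 1e-3
    warmup_steps: int = 20
    weight_decay: float = 0.01
    mask_rate: float = 0.15
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    log_every: int = 10

    @classmethod
    def preset(cls, name: str) -> "PretrainConfig":
        if name == "desk":
            return cls()
        if name == "published":
            return cls(steps=100_000, batch_size=2048, lr=4e-4,
                       warmup_steps=10_000, weight_decay=0.01, log_every=100)
        raise ValueError(f"unknown preset {name!r}; choose 'desk' or 'published'")

    @classmethod
    def from_yaml(cls, path) -> "PretrainConfig":
        """Load a schedule from a YAML mapping; a ``preset`` key supplies
        defaults that explicit keys then override."""
        import yaml

        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        base = cls.preset(raw.pop("preset", "desk"))
        if "proportions" in raw:
            raw["proportions"] = tuple(raw["proportions"])
        return dataclasses.replace(base, **raw)


@dataclass
class PretrainResult:
    encoder: ConditionalEncoder
    history: list[dict] = field(default_factory=list)

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


def encode_corpus(
    segments: Sequence[Segment],
    vocab: KmerVocabulary,
    max_len: int,
    conditional: bool = True,
) -> list[EncodedSegment]:
    """Encode a labeled corpus with class tokens (or [CLS] in ablation mode)."""
    encoded = []
    for seg in segments:
        if conditional:
            if seg.label is None:
                raise ValueError(
                    f"segment {seg.parent_id}[{seg.start}:{seg.end}] has no label; "
                    "conditional pre-training requires labeled segments"
                )
            encoded.append(encode_with_class_token(seg, vocab, max_len))
        else:
            encoded.append(encode(seg, CLS, vocab, max_len))
    return encoded


def pretrain(
    segments: Sequence[Segment],
    vocab: KmerVocabulary,
    encoder_config: Optional[EncoderConfig] = None,
    config: Optional[PretrainConfig] = None,
    rng_seed: int = 0,
    conditional: bool = True,
) -> PretrainResult:
    """Train an encoder with label-constrained masked language modeling.

    ``conditional=True`` attaches each segment's own class token;
    ``conditional=False`` is the unconditional ablation that attaches
    [CLS] to every segment. Reproducible for a fixed seed on fixed
    hardware.
    """
    if encoder_config is None:
        encoder_config = EncoderConfig.preset("tiny", vocab.size)
    if encoder_config.vocab_size != vocab.size:
        raise ValueError("encoder_config.vocab_size does not match the vocabulary")
    if config is None:
        config = PretrainConfig()
    if len(segments) == 0:
        raise ValueError("empty pre-training corpus")

    seeds = np.random.SeedSequence(rng_seed).spawn(4)
    init_rng, mask_rng, shuffle_rng, drop_rng = (np.random.default_rng(s) for s in seeds)

    encoded = encode_corpus(segments, vocab, encoder_config.max_positions, conditional)
    ids, attn = stack_encoded(encoded)

    encoder = ConditionalEncoder(encoder_config, init_rng)
    opt = nn.Adam(dict(encoder.named_parameters()), lr=config.lr,
                  weight_decay=config.weight_decay)

    n = len(encoded)
    order = shuffle_rng.permutation(n)
    cursor = 0
    history: list[dict] = []
    for step in range(config.steps):
        if cursor + config.batch_size > n:
            order = shuffle_rng.permutation(n)
            cursor = 0
        idx = order[cursor : cursor + config.batch_size]
        cursor += config.batch_size

        batch = mask_token_arrays(ids[idx], attn[idx], vocab, mask_rng,
                                  config.mask_rate, config.proportions)
        loss, acc = _mlm_step(encoder, batch, opt, drop_rng,
                              lr=nn.linear_warmup_decay(step, config.lr,
                                                        config.warmup_steps, config.steps))
        if step % config.log_every == 0 or step == config.steps - 1:
            history.append({"step": step, "loss": loss, "masked_accuracy": acc})
    return PretrainResult(encoder=encoder, history=history)


def _mlm_step(encoder, batch: MaskedBatch, opt, drop_rng, lr: float) -> tuple[float, float]:
    """One forward/backward/update pass; returns (loss, masked accuracy)."""
    encoder.zero_grad()
    n = int(batch.attention_mask.sum(axis=1).max())
    corrupted = batch.corrupted_ids[:, :n]
    attn = batch.attention_mask[:, :n]
    targets_arr = batch.targets[:, :n]
    hidden = encoder.hidden_states(corrupted, attn, train=True, rng=drop_rng)
    rows, cols = np.nonzero(targets_arr != IGNORE_INDEX)
    gathered = hidden[rows, cols]  # [M, hidden]
    logits = encoder.mlm_head.forward(gathered)
    targets = targets_arr[rows, cols]
    loss, dlogits = nn.softmax_cross_entropy(logits, targets)
    acc = float((logits.argmax(axis=-1) == targets).mean()) if len(targets) else float("nan")
    dgathered = encoder.mlm_head.backward(dlogits)
    dhidden = np.zeros_like(hidden)
    dhidden[rows, cols] = dgathered
    encoder.encoder.backward(dhidden)
    opt.step(lr)
    return loss, acc


# -- representation separation -------------------------------------------------


def silhouette_of(vectors: np.ndarray, labels: Sequence[str]) -> float:
    """Two-class silhouette score; identical vectors give 0 by convention."""
    vectors = np.asarray(vectors, dtype=np.float64)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("silhouette requires at least two classes")
    if np.allclose(vectors, vectors[0]):
        return 0.0
    return float(silhouette_score(vectors, labels))


def label_token_vectors(
    encoder: ConditionalEncoder,
    segments: Sequence[Segment],
    vocab: KmerVocabulary,
    attach: str = "label",
    batch_size: int = 16,
) -> np.ndarray:
    """Position-0 last-hidden-state vectors for each segment.

    ``attach="label"`` uses each segment's true class token (conditional
    encoder); ``attach="cls"`` uses [CLS] for all (ablation encoder).
    """
    max_len = encoder.config.max_positions
    if attach == "label":
        encoded = [encode_with_class_token(s, vocab, max_len) for s in segments]
    elif attach == "cls":
        encoded = [encode(s, CLS, vocab, max_len) for s in segments]
    else:
        raise ValueError("attach must be 'label' or 'cls'")
    ids, mask = stack_encoded(encoded)
    vecs = []
    for i in range(0, len(encoded), batch_size):
        h = encoder.hidden_states(ids[i : i + batch_size], mask[i : i + batch_size])
        vecs.append(h[:, 0, :])
    return np.concatenate(vecs, axis=0)


def representation_separation(
    encoder: ConditionalEncoder,
    segments: Sequence[Segment],
    vocab: KmerVocabulary,
    attach: str = "label",
    batch_size: int = 16,
) -> float:
    """Silhouette of the 2-class partition of class-token representations.

    A quantitative surrogate for visual embedding-separation plots: higher
    values mean bacterial and phage class-token vectors form better
    separated clusters.
    """
    labels = [s.label for s in segments]
    if any(l is None for l in labels):
        raise ValueError("all segments must be labeled")
    counts = {l: labels.count(l) for l in set(labels)}
    if len(counts) < 2 or min(counts.values()) < 2:
        raise ValueError("need at least 2 segments per class in both classes")
    vecs = label_token_vectors(encoder, segments, vocab, attach, batch_size)
    return silhouette_of(vecs, labels)
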