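"""Paradox augmentation and classifier fine-tuning.

At prediction time the true class of a query segment is unknown, so a
conditional encoder would have a 50% chance of receiving the wrong class
token. Fine-tuning therefore tokenizes every labeled training segment
*twice* — once with [BAC], once with [PHA] — and assigns a third target
class, "paradox", to the copy whose attached token contradicts the true
label. The classifier thus learns to recognize label/content mismatch,
which the prediction-time aggregation rule converts back into a binary
phage-vs-bacteria score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .model import ClassifierConfig, ConditionalEncoder, SegmentClassifier
from .seqio import Segment
from .tokenizer import (
    BAC,
    CLS,
    PHA,
    EncodedSegment,
    KmerVocabulary,
    TOKEN_TO_CLASS,
    encode,
    stack_encoded,
)

#: Target classes of the paradox-augmented scheme, in output-index order.
CLASS_ORDER = ("bacteria", "phage", "paradox")

#: Target classes of the no-paradox ablation.
BINARY_CLASS_ORDER = ("bacteria", "phage")


@dataclass
class ParadoxSample:
    """One tokenization of a labeled segment with its fine-tuning target.

    ``target_class`` equals the true label when the attached token matches
    it, and "paradox" when it contradicts it.
    """

    encoded: EncodedSegment
    target_class: str


def paradox_augment(
    segments: Sequence[Segment],
    vocab: KmerVocabulary,
    max_len: int = 512,
) -> list[ParadoxSample]:
    """Tokenize every segment twice, once per label token.

    Output order is deterministic: segment order, [BAC] before [PHA].
    Exactly ``len(segments)`` of the ``2 * len(segments)`` outputs carry
    the "paradox" target.
    """
    samples: list[ParadoxSample] = []
    for seg in segments:
        if seg.label is None:
            raise ValueError(
                f"segment {seg.parent_id}[{seg.start}:{seg.end}] has no label; "
                "paradox augmentation requires labeled segments"
            )
        for token in (BAC, PHA):
            target = TOKEN_TO_CLASS[token] if TOKEN_TO_CLASS[token] == seg.label else "paradox"
            samples.append(ParadoxSample(encoded=encode(seg, token, vocab, max_len), target_class=target))
    return samples


def cls_binary_samples(
    segments: Sequence[Segment],
    vocab: KmerVocabulary,
    max_len: int = 512,
) -> list[ParadoxSample]:
    """No-paradox ablation: every segment once, [CLS] attached, binary target."""
    samples = []
    for seg in segments:
        if seg.label is None:
            raise ValueError("ablation fine-tuning requires labeled segments")
        samples.append(ParadoxSample(encoded=encode(seg, CLS, vocab, max_len), target_class=seg.label))
    return samples


@dataclass(frozen=True)
class FinetuneConfig:
    """Optimization schedule for fine-tuning.

    The published work states no fine-tuning hyperparameters; the
    ``"published"`` preset uses the customary BERT fine-tuning rate (2e-5),
    the desk default is sized for the tiny CPU model.
    """

    epochs: int = 4
    batch_size: int = 8
    lr: float = 1e-3
    warmup_steps: int = 10
    weight_decay: float = 0.01

    @classmethod
    def preset(cls, name: str) -> "FinetuneConfig":
        if name == "desk":
            return cls()
        if name == "published":
            return cls(epochs=5, batch_size=64, lr=2e-5, warmup_steps=500)
        raise ValueError(f"unknown preset {name!r}; choose 'desk' or 'published'")

    @classmethod
    def from_yaml(cls, path) -> "FinetuneConfig":
        """Load a schedule from a YAML mapping; a ``preset`` key supplies
        defaults that explicit keys then override."""
        import dataclasses

        import yaml

        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        base = cls.preset(raw.pop("preset", "desk"))
        return dataclasses.replace(base, **raw)


@dataclass
class FinetuneResult:
    classifier: SegmentClassifier
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


def _targets_to_indices(samples: Sequence[ParadoxSample], classes: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([index[s.target_class] for s in samples], dtype=np.int64)
    except KeyError as err:
        raise ValueError(f"target class {err} not in class set {tuple(classes)}") from None


def copy_encoder(encoder: ConditionalEncoder) -> ConditionalEncoder:
    """Independent copy with identical weights (the original stays frozen
    in place, so one pre-trained encoder can seed several fine-tunes)."""
    clone = ConditionalEncoder(encoder.config, np.random.default_rng(0), dtype=encoder.dtype)
    clone.load_state_dict(encoder.state_dict())
    return clone


def finetune(
    train: Sequence[ParadoxSample],
    valid: Sequence[ParadoxSample],
    encoder: ConditionalEncoder,
    clf_config: Optional[ClassifierConfig] = None,
    config: Optional[FinetuneConfig] = None,
    rng_seed: int = 0,
) -> FinetuneResult:
    """Fine-tune encoder + BiLSTM + MLP on (paradox-)augmented samples.

    Encoder weights are updated jointly with the head (the passed-in
    encoder object itself is left untouched; it is copied first). The
    returned classifier carries the weights of the best-validation-loss
    epoch. 3-class cross-entropy with ``num_classes=3``; the no-paradox
    ablation passes ``ClassifierConfig(num_classes=2)`` and
    [CLS]-attached binary samples.
    """
    if clf_config is None:
        clf_config = ClassifierConfig()
    if config is None:
        config = FinetuneConfig()
    classes = CLASS_ORDER if clf_config.num_classes == 3 else BINARY_CLASS_ORDER
    y_train = _targets_to_indices(train, classes)
    y_valid = _targets_to_indices(valid, classes)
    present = set(np.unique(y_train).tolist())
    if present != set(range(len(classes))):
        missing = [classes[i] for i in range(len(classes)) if i not in present]
        raise ValueError(f"degenerate task: class(es) {missing} absent from training targets")

    seeds = np.random.SeedSequence(rng_seed).spawn(3)
    init_rng, shuffle_rng, drop_rng = (np.random.default_rng(s) for s in seeds)

    classifier = SegmentClassifier(copy_encoder(encoder), clf_config, init_rng)
    opt = nn.Adam(dict(classifier.named_parameters()), lr=config.lr,
                  weight_decay=config.weight_decay)

    ids_tr, attn_tr = stack_encoded([s.encoded for s in train])
    ids_va, attn_va = stack_encoded([s.encoded for s in valid])

    n = len(train)
    steps_per_epoch = math.ceil(n / config.batch_size)
    total_steps = steps_per_epoch * config.epochs
    history: list[dict] = []
    best_loss = np.inf
    best_state = classifier.state_dict()
    best_epoch = -1
    step = 0
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            lr = nn.linear_warmup_decay(step, config.lr, config.warmup_steps, total_steps)
            classifier.zero_grad()
            logits = classifier.logits(ids_tr[idx], attn_tr[idx], train=True, rng=drop_rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, y_train[idx])
            classifier.backward_from_logits(dlogits)
            opt.step(lr)
            epoch_losses.append(loss)
            step += 1
        val_loss, val_acc = _evaluate(classifier, ids_va, attn_va, y_valid, config.batch_size)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "valid_loss": val_loss,
                "valid_accuracy": val_acc,
            }
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = classifier.state_dict()
            best_epoch = epoch
    classifier.load_state_dict(best_state)
    return FinetuneResult(classifier=classifier, history=history, best_epoch=best_epoch)


def _evaluate(classifier, ids, attn, y, batch_size) -> tuple[float, float]:
    losses = []
    correct = 0
    for start in range(0, len(y), batch_size):
        sl = slice(start, start + batch_size)
        logits = classifier.logits(ids[sl], attn[sl])
        loss, _ = nn.softmax_cross_entropy(logits, y[sl])
        losses.append(loss * len(y[sl]))
        correct += int((logits.argmax(axis=-1) == y[sl]).sum())
    n = len(y)
    return float(np.sum(losses) / n), correct / n
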