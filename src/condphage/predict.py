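"""Contig scoring: dual tokenization, label aggregation, averaging.

A query contig is split into 500-bp segments; each segment is tokenized
twice (once with [BAC], once with [PHA]) and classified into
(bacteria, phage, paradox) probabilities. Because "paradox" means "the
attached label is wrong", the three-class triple collapses to a binary
score: with [PHA] attached the paradox score counts as bacteria, with
[BAC] attached it counts as phage. All binary phage scores — two per
segment — are averaged with equal weight, and the contig is called a
phage iff the mean phage score strictly exceeds the threshold (0.5 by
default; an exact tie is called bacteria).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import SegmentClassifier
from .seqio import DEFAULT_MIN_TAIL, DEFAULT_SEGMENT_LENGTH, SequenceRecord, segment_sequence
from .tokenizer import BAC, CLS, PHA, KmerVocabulary, encode


@dataclass(frozen=True)
class ClassScores:
    """Three-class probabilities for one tokenization of one segment."""

    attached_label: str  # [BAC] or [PHA]
    p_bac: float
    p_pha: float
    p_par: float

    def __post_init__(self):
        total = self.p_bac + self.p_pha + self.p_par
        if not np.isclose(total, 1.0, atol=1e-5):
            raise ValueError(f"class scores must sum to 1 (got {total:.6f})")


@dataclass(frozen=True)
class BinaryScores:
    """Aggregated (bacteria, phage) scores for one tokenization."""

    b_bac: float
    b_pha: float


@dataclass
class ContigPrediction:
    """Final call for one contig plus its per-segment score table."""

    contig_id: str
    length: int
    n_segments: int
    phage_score: float
    call: str
    segment_scores: list[ClassScores] = field(default_factory=list)


def aggregate_scores(scores: ClassScores) -> BinaryScores:
    """Collapse a three-class triple to binary scores.

    With [PHA] attached, predicting "paradox" means the segment is *not*
    a phage, so the paradox score is added to bacteria; with [BAC]
    attached it is added to phage. The sum b_bac + b_pha always equals
    p_bac + p_pha + p_par exactly.
    """
    if scores.attached_label == PHA:
        return BinaryScores(b_bac=scores.p_bac + scores.p_par, b_pha=scores.p_pha)
    if scores.attached_label == BAC:
        return BinaryScores(b_bac=scores.p_bac, b_pha=scores.p_pha + scores.p_par)
    raise ValueError(
        f"aggregation is undefined for attached label {scores.attached_label!r}; "
        "the [CLS] ablation path bypasses aggregation"
    )


def call_from_score(phage_score: float, threshold: float = 0.5) -> str:
    """Phage iff the score strictly exceeds the threshold; ties → bacteria."""
    return "phage" if phage_score > threshold else "bacteria"


def _classify_encoded(classifier, encoded, batch_size: int) -> np.ndarray:
    """Classify encodings in length-sorted batches (short segments then cost
    less), restoring input order in the result."""
    order = np.argsort([-e.n_tokens for e in encoded], kind="stable")
    probs = np.empty((len(encoded), classifier.num_classes), dtype=np.float64)
    for i in range(0, len(order), batch_size):
        sel = order[i : i + batch_size]
        ids = np.stack([encoded[j].ids for j in sel])
        mask = np.stack([encoded[j].attention_mask for j in sel])
        probs[sel] = classifier.probabilities(ids, mask)
    return probs


def _score_segments(segments, classifier, vocab, batch_size):
    """Encode and classify segments; returns (triples, per-score phage list).

    3-class classifier: two tokenizations per segment, aggregated to binary.
    2-class ablation: single [CLS] tokenization, phage probability direct.
    """
    max_len = classifier.cond_encoder.config.max_positions
    if classifier.num_classes == 3:
        encoded = [encode(seg, token, vocab, max_len) for seg in segments for token in (BAC, PHA)]
        probs = _classify_encoded(classifier, encoded, batch_size)
        triples = [
            ClassScores(attached_label=e.attached_label, p_bac=float(p[0]),
                        p_pha=float(p[1]), p_par=float(p[2]))
            for e, p in zip(encoded, probs)
        ]
        return triples, [aggregate_scores(t).b_pha for t in triples]
    encoded = [encode(seg, CLS, vocab, max_len) for seg in segments]
    probs = _classify_encoded(classifier, encoded, batch_size)
    return [], [float(p[1]) for p in probs]


def predict_contig(
    record: SequenceRecord,
    classifier: SegmentClassifier,
    vocab: KmerVocabulary,
    threshold: float = 0.5,
    seg_len: int = DEFAULT_SEGMENT_LENGTH,
    min_tail: int = DEFAULT_MIN_TAIL,
    batch_size: int = 16,
) -> ContigPrediction:
    """Score one contig with the fine-tuned classifier.

    For the 3-class (paradox) classifier, every segment contributes two
    aggregated binary scores (one per attached label), all averaged with
    equal weight. A 2-class ablation classifier is scored with a single
    [CLS] tokenization per segment.
    """
    if not isinstance(classifier, SegmentClassifier):
        raise TypeError(
            "prediction requires a fine-tuned SegmentClassifier checkpoint; "
            "this model has no classifier head — fine-tune it first"
        )
    segments = segment_sequence(record, seg_len=seg_len, min_tail=min_tail)
    if not segments:
        raise ValueError(
            f"contig {record.id!r} ({len(record)} bp) yields no segments "
            f"(min_tail={min_tail})"
        )
    triples, phage_scores = _score_segments(segments, classifier, vocab, batch_size)
    phage_score = float(np.mean(phage_scores))
    return ContigPrediction(
        contig_id=record.id,
        length=len(record),
        n_segments=len(segments),
        phage_score=phage_score,
        call=call_from_score(phage_score, threshold),
        segment_scores=triples,
    )


def predict_batch(
    records: Sequence[SequenceRecord],
    classifier: SegmentClassifier,
    vocab: KmerVocabulary,
    threshold: float = 0.5,
    seg_len: int = DEFAULT_SEGMENT_LENGTH,
    min_tail: int = DEFAULT_MIN_TAIL,
    batch_size: int = 16,
    path=None,
) -> pd.DataFrame:
    """Score many contigs; order-preserving; optionally write a TSV report.

    Per-record failures (e.g. a contig too short to segment) become rows
    with ``call == "error"`` instead of aborting the batch. Segments of
    all contigs are classified together in large batches; scores are
    identical to scoring each contig alone.
    """
    if not isinstance(classifier, SegmentClassifier):
        raise TypeError(
            "prediction requires a fine-tuned SegmentClassifier checkpoint; "
            "this model has no classifier head — fine-tune it first"
        )
    per_record: list[tuple[SequenceRecord, list]] = []
    all_segments = []
    for rec in records:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # too-short contigs become error rows
            segs = segment_sequence(rec, seg_len=seg_len, min_tail=min_tail)
        per_record.append((rec, segs))
        all_segments.extend(segs)
    if all_segments:
        _, phage_scores = _score_segments(all_segments, classifier, vocab, batch_size)
        scores_per_seg = 2 if classifier.num_classes == 3 else 1
    else:
        phage_scores = []
        scores_per_seg = 1
    rows = []
    offset = 0
    for rec, segs in per_record:
        n_scores = len(segs) * scores_per_seg
        chunk = phage_scores[offset : offset + n_scores]
        offset += n_scores
        if not segs:
            rows.append(
                {
                    "contig_id": rec.id,
                    "length": len(rec),
                    "n_segments": 0,
                    "phage_score": float("nan"),
                    "call": "error",
                }
            )
            continue
        phage_score = float(np.mean(chunk))
        rows.append(
            {
                "contig_id": rec.id,
                "length": len(rec),
                "n_segments": len(segs),
                "phage_score": phage_score,
                "call": call_from_score(phage_score, threshold),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["contig_id", "length", "n_segments", "phage_score", "call"]
    )
    if path is not None:
        frame.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return frame
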