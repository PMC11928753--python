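"""Overlapped k-mer vocabulary with label-class special tokens.

A nucleotide segment is decomposed into all overlapping k-mers (stride 1),
a class token is prepended and a separator appended. Unlike a conventional
encoder that prepends the same [CLS] token to every sample, the conditional
encoder prepends a *label* token — [BAC] for bacterial segments, [PHA] for
phage segments — so that masked-token prediction is conditioned on the
class of the sequence. [CLS] is retained only for the unconditional
ablation baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Optional

import numpy as np

from .seqio import Segment

PAD = "[PAD]"
UNK = "[UNK]"
SEP = "[SEP]"
MASK = "[MASK]"
BAC = "[BAC]"
PHA = "[PHA]"
CLS = "[CLS]"

#: Fixed special-token order; ids 0..6 precede the k-mer block.
SPECIAL_TOKENS = (PAD, UNK, SEP, MASK, BAC, PHA, CLS)

#: Class tokens accepted at position 0 of an encoded segment.
LABEL_TOKENS = (BAC, PHA, CLS)

#: Map between biological class names and their label tokens.
CLASS_TO_TOKEN = {"bacteria": BAC, "phage": PHA}
TOKEN_TO_CLASS = {BAC: "bacteria", PHA: "phage"}

_BASES = "ACGT"
_MAX_K = 8


@dataclass(frozen=True)
class KmerVocabulary:
    """All 4^k ACGT k-mers plus special tokens, with stable contiguous ids.

    Ids are deterministic for a given ``k``: specials occupy 0..6 in
    :data:`SPECIAL_TOKENS` order, followed by k-mers in lexicographic order.
    """

    k: int
    tokens: tuple[str, ...]
    token_to_id: dict[str, int] = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def n_specials(self) -> int:
        return len(SPECIAL_TOKENS)

    def id(self, token: str) -> int:
        return self.token_to_id[token]

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    @property
    def sep_id(self) -> int:
        return self.token_to_id[SEP]

    @property
    def mask_id(self) -> int:
        return self.token_to_id[MASK]

    def is_special_id(self, token_id: int) -> bool:
        return token_id < self.n_specials

    def save(self, path) -> None:
        """Serialize as one token per line; id equals the line number."""
        with open(path, "w") as handle:
            for token in self.tokens:
                handle.write(token + "\n")

    @classmethod
    def load(cls, path) -> "KmerVocabulary":
        tokens = tuple(Path(path).read_text().split())
        k = len(tokens[-1])
        vocab = build_vocabulary(k)
        if vocab.tokens != tokens:
            raise ValueError(f"{path}: token list is not a valid k={k} vocabulary")
        return vocab


def build_vocabulary(k: int) -> KmerVocabulary:
    """Build the deterministic vocabulary for k-mer size ``k`` (1 ≤ k ≤ 8)."""
    if not 1 <= k <= _MAX_K:
        raise ValueError(f"k must be in 1..{_MAX_K}, got {k}")
    kmers = ["".join(p) for p in product(_BASES, repeat=k)]
    tokens = tuple(SPECIAL_TOKENS) + tuple(kmers)
    return KmerVocabulary(k=k, tokens=tokens, token_to_id={t: i for i, t in enumerate(tokens)})


def kmerize(sequence: str, k: int) -> list[str]:
    """All overlapping k-mers of ``sequence`` (stride 1).

    Returns ``len(sequence) - k + 1`` tokens; any window containing a letter
    outside {A,C,G,T} becomes ``[UNK]`` (the window count is unchanged, so
    positional structure is preserved).
    """
    n = len(sequence)
    if n < k:
        raise ValueError(f"sequence length {n} shorter than k={k}")
    acgt = frozenset(_BASES)
    out = []
    for i in range(n - k + 1):
        token = sequence[i : i + k]
        out.append(token if acgt.issuperset(token) else UNK)
    return out


@dataclass
class EncodedSegment:
    """Token ids for one segment with an attached class token.

    Layout: ``[label token] [k-mer tokens...] [SEP] [PAD]...`` out to
    ``max_len`` positions; ``attention_mask`` is 1 exactly on the non-pad
    prefix.
    """

    ids: np.ndarray
    attention_mask: np.ndarray
    attached_label: str
    true_label: Optional[str] = None
    segment: Optional[Segment] = None

    @property
    def n_tokens(self) -> int:
        """Non-pad length (label token + k-mers + separator)."""
        return int(self.attention_mask.sum())


def encode(
    segment: Segment,
    attached_label: str,
    vocab: KmerVocabulary,
    max_len: int = 512,
) -> EncodedSegment:
    """Tokenize a segment and attach a class token at position 0."""
    if attached_label not in LABEL_TOKENS:
        raise ValueError(f"attached_label must be one of {LABEL_TOKENS}, got {attached_label!r}")
    kmers = kmerize(segment.sequence, vocab.k)
    n = len(kmers) + 2
    if n > max_len:
        raise ValueError(
            f"segment spans {n} token positions but max_len={max_len}; "
            "re-segment the input into shorter windows"
        )
    ids = np.full(max_len, vocab.pad_id, dtype=np.int32)
    ids[0] = vocab.id(attached_label)
    ids[1 : n - 1] = [vocab.token_to_id[t] for t in kmers]
    ids[n - 1] = vocab.sep_id
    mask = np.zeros(max_len, dtype=np.int32)
    mask[:n] = 1
    return EncodedSegment(
        ids=ids,
        attention_mask=mask,
        attached_label=attached_label,
        true_label=segment.label,
        segment=segment,
    )


def encode_with_class_token(
    segment: Segment, vocab: KmerVocabulary, max_len: int = 512
) -> EncodedSegment:
    """Encode with the label token matching the segment's own class."""
    if segment.label is None:
        raise ValueError("segment has no label; pass attached_label explicitly")
    return encode(segment, CLASS_TO_TOKEN[segment.label], vocab, max_len)


def decode(encoded: EncodedSegment, vocab: KmerVocabulary) -> str:
    """Reconstruct the nucleotide segment by overlap-merging its k-mers.

    The first k-mer is taken verbatim; each subsequent k-mer must overlap
    its predecessor by k−1 bases and contributes its last base. Encodings
    containing ``[UNK]`` k-mers are not invertible and raise.
    """
    n = encoded.n_tokens
    kmer_ids = encoded.ids[1 : n - 1]
    if np.any(kmer_ids == vocab.unk_id):
        raise ValueError("encoded segment contains [UNK] k-mers; cannot decode")
    kmers = [vocab.tokens[i] for i in kmer_ids]
    seq = kmers[0]
    for prev, cur in zip(kmers, kmers[1:]):
        if prev[1:] != cur[:-1]:
            raise ValueError(f"non-adjacent k-mers {prev!r} -> {cur!r}: inconsistent overlap")
        seq += cur[-1]
    return seq


def stack_encoded(encoded: list[EncodedSegment]) -> tuple[np.ndarray, np.ndarray]:
    """Stack encodings into (ids, attention_mask) arrays of shape [B, max_len]."""
    ids = np.stack([e.ids for e in encoded])
    mask = np.stack([e.attention_mask for e in encoded])
    return ids, mask
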