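"""Synthetic bacterial/phage sequence populations.

Two Markov chains over {A,C,G,T} with divergent transition structure stand
in for bacterial and phage genomes: k-mer composition is exactly the signal
an overlapped-k-mer encoder can exploit, so recovering the class labels
from chain-generated sequences is a fair desk-scale test of the framework
without external genome databases. The ``divergence`` dial interpolates the
second chain's transition vectors between the first chain's (0 = identical
populations) and an independently drawn table (1 = maximally divergent).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .seqio import SequenceRecord, write_fasta

_BASES = "ACGT"
_MAX_ORDER = 4
_BURN_IN = 100


@dataclass(frozen=True)
class MarkovSequenceModel:
    """Order-``order`` Markov chain over {A,C,G,T}.

    ``transition`` has shape [4^order, 4]: one probability vector over the
    next base per context (contexts indexed lexicographically; order 0 has
    a single context).
    """

    order: int
    transition: np.ndarray
    label: str

    def __post_init__(self):
        if not 0 <= self.order <= _MAX_ORDER:
            raise ValueError(f"order must be in 0..{_MAX_ORDER}")
        expected = (4**self.order, 4)
        if self.transition.shape != expected:
            raise ValueError(f"transition must have shape {expected}, got {self.transition.shape}")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every transition vector must sum to 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the desk-scale conditions used throughout the tests:
    1000 training and 400 test sequences per class, lengths uniform in
    500–2000 bp, order-2 chains at divergence 0.8.
    """

    n_train: int = 1000
    n_test: int = 400
    length_range: tuple[int, int] = (500, 2000)
    order: int = 2
    divergence: float = 0.8
    rng_seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid length_range")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")


def make_model_pair(
    order: int,
    divergence: float,
    rng_seed: Union[int, np.random.Generator] = 0,
) -> tuple[MarkovSequenceModel, MarkovSequenceModel]:
    """Draw a (bacteria, phage) pair of chains with controlled divergence.

    The base table is Dirichlet(1,1,1,1) per context; the second table is
    the per-context mixture ``(1-d) * base + d * independent draw``, so
    ``d=0`` gives identical chains and larger ``d`` gives larger expected
    k-mer divergence.
    """
    if not 0 <= order <= _MAX_ORDER:
        raise ValueError(f"order must be in 0..{_MAX_ORDER}")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n_ctx = 4**order
    base = rng.dirichlet(np.ones(4), size=n_ctx)
    other = rng.dirichlet(np.ones(4), size=n_ctx)
    mixed = (1.0 - divergence) * base + divergence * other
    mixed /= mixed.sum(axis=1, keepdims=True)
    return (
        MarkovSequenceModel(order=order, transition=base, label="bacteria"),
        MarkovSequenceModel(order=order, transition=mixed, label="phage"),
    )


def sample_sequences(
    model: MarkovSequenceModel,
    n: int,
    lengths: Union[int, tuple[int, int], Sequence[int]],
    rng_seed: Union[int, np.random.Generator] = 0,
    id_prefix: str = "seq",
) -> list[SequenceRecord]:
    """Draw ``n`` independent sequences from the chain.

    ``lengths`` is a fixed length, an inclusive (min, max) uniform range,
    or an explicit per-sequence length list. The initial context is
    approximately stationary: each sequence starts from a uniformly drawn
    context followed by a 100-base burn-in that is discarded.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    if isinstance(lengths, int):
        lens = np.full(n, lengths, dtype=np.int64)
    elif isinstance(lengths, tuple) and len(lengths) == 2:
        lens = rng.integers(lengths[0], lengths[1] + 1, size=n)
    else:
        lens = np.asarray(list(lengths), dtype=np.int64)
        if len(lens) != n:
            raise ValueError("explicit lengths list must have n entries")

    order = model.order
    n_ctx = 4**order
    cum = np.cumsum(model.transition, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    total = int(lens.max()) + _BURN_IN
    ctx = rng.integers(0, n_ctx, size=n)
    emitted = np.empty((n, total), dtype=np.int8)
    for t in range(total):
        u = rng.random(n)
        nxt = (u[:, None] > cum[ctx]).sum(axis=1)
        emitted[:, t] = nxt
        if order > 0:
            ctx = (ctx * 4 + nxt) % n_ctx
    base_arr = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    records = []
    for i in range(n):
        body = emitted[i, _BURN_IN : _BURN_IN + int(lens[i])]
        seq = base_arr[body].tobytes().decode()
        records.append(SequenceRecord(id=f"{id_prefix}_{i:05d}", sequence=seq, label=model.label))
    return records


def generate_records(config: SimulationConfig) -> dict[str, list[SequenceRecord]]:
    """Draw the full labeled dataset in memory.

    Returns four balanced record lists keyed ``train_bacteria``,
    ``train_phage``, ``test_bacteria``, ``test_phage``; deterministic for
    a fixed config.
    """
    root = np.random.SeedSequence(config.rng_seed)
    pair_seed, *draw_seeds = root.spawn(5)
    bac_model, pha_model = make_model_pair(config.order, config.divergence,
                                           np.random.default_rng(pair_seed))
    jobs = [
        ("train", bac_model, config.n_train),
        ("train", pha_model, config.n_train),
        ("test", bac_model, config.n_test),
        ("test", pha_model, config.n_test),
    ]
    out: dict[str, list[SequenceRecord]] = {}
    for (split, model, count), seed in zip(jobs, draw_seeds):
        prefix = f"{model.label}_{split}"
        out[f"{split}_{model.label}"] = sample_sequences(
            model, count, config.length_range, np.random.default_rng(seed), id_prefix=prefix
        )
    return out


def emit_dataset(config: SimulationConfig, outdir, force: bool = False) -> dict[str, Path]:
    """Write a balanced train/test FASTA bundle plus a truth table.

    Produces ``train_bacteria.fasta``, ``train_phage.fasta``,
    ``test_bacteria.fasta``, ``test_phage.fasta`` and ``truth.tsv``
    (columns: id, split, class). Byte-identical for a fixed config;
    refuses a non-empty output directory unless ``force``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is non-empty; pass force=True to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)

    datasets = generate_records(config)
    paths: dict[str, Path] = {}
    truth_rows = []
    for key, records in datasets.items():
        split, label = key.split("_")
        path = outdir / f"{key}.fasta"
        write_fasta(records, path)
        paths[key] = path
        truth_rows.extend((rec.id, split, label) for rec in records)

    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as handle:
        handle.write("id\tsplit\tclass\n")
        for row in truth_rows:
            handle.write("\t".join(row) + "\n")
    paths["truth"] = truth_path
    return paths
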