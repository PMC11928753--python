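"""Masking collator statistics and the pre-training loop."""

import numpy as np
import pytest

from condphage.model import EncoderConfig
from condphage.pretrain import (
    IGNORE_INDEX,
    PretrainConfig,
    apply_mlm_mask,
    encode_corpus,
    mask_token_arrays,
    pretrain,
    representation_separation,
    silhouette_of,
)
from condphage.tokenizer import BAC, CLS, PHA, build_vocabulary, encode
from conftest import make_segment, random_dna


@pytest.fixture()
def small_batch(vocab3):
    rng = np.random.default_rng(0)
    segs = [make_segment(random_dna(rng, 30), label="bacteria") for _ in range(4)]
    return [encode(s, BAC, vocab3, 40) for s in segs]


class TestMaskingCollator:
    def test_rate_zero_masks_nothing(self, small_batch, vocab3):
        batch = apply_mlm_mask(small_batch, vocab3, mask_rate=0.0, rng_seed=1)
        assert batch.n_masked == 0
        assert (batch.targets == IGNORE_INDEX).all()
        ids = np.stack([e.ids for e in small_batch])
        assert np.array_equal(batch.corrupted_ids, ids)

    def test_special_positions_never_masked(self, small_batch, vocab3):
        for seed in range(20):
            batch = apply_mlm_mask(small_batch, vocab3, mask_rate=1.0, rng_seed=seed)
            assert not batch.mask_positions[:, 0].any()  # label token
            ids = np.stack([e.ids for e in small_batch])
            assert not batch.mask_positions[ids == vocab3.sep_id].any()
            assert not batch.mask_positions[ids == vocab3.pad_id].any()

    def test_targets_exactly_at_masked_positions(self, small_batch, vocab3):
        batch = apply_mlm_mask(small_batch, vocab3, rng_seed=3)
        assert np.array_equal(batch.targets != IGNORE_INDEX, batch.mask_positions)
        ids = np.stack([e.ids for e in small_batch])
        assert (batch.targets[batch.mask_positions] == ids[batch.mask_positions]).all()

    def test_seed_reproducibility(self, small_batch, vocab3):
        a = apply_mlm_mask(small_batch, vocab3, rng_seed=7)
        b = apply_mlm_mask(small_batch, vocab3, rng_seed=7)
        assert np.array_equal(a.corrupted_ids, b.corrupted_ids)
        assert np.array_equal(a.targets, b.targets)
        assert np.array_equal(a.mask_positions, b.mask_positions)

    def test_random_replacements_exclude_specials(self, small_batch, vocab3):
        # rate 1 with all-random replacement: every corrupted token is a k-mer
        batch = apply_mlm_mask(small_batch, vocab3, mask_rate=1.0,
                               proportions=(0.0, 1.0, 0.0), rng_seed=5)
        replaced = batch.corrupted_ids[batch.mask_positions]
        assert (replaced >= vocab3.n_specials).all()

    def test_invalid_arguments(self, small_batch, vocab3):
        with pytest.raises(ValueError):
            apply_mlm_mask(small_batch, vocab3, mask_rate=1.5)
        with pytest.raises(ValueError):
            apply_mlm_mask(small_batch, vocab3, proportions=(0.5, 0.2, 0.2))

    def test_montecarlo_statistics_match_bernoulli_scheme(self, vocab6):
        """10,000 segments of 495 maskable tokens: empirical masked fraction
        and 80/10/10 replacement proportions match the corruption rule."""
        rng = np.random.default_rng(123)
        n, n_kmers = 10_000, 495
        ids = np.empty((n, n_kmers + 2), dtype=np.int32)
        ids[:, 0] = vocab6.id(BAC)
        ids[:, 1:-1] = rng.integers(vocab6.n_specials, vocab6.size, size=(n, n_kmers))
        ids[:, -1] = vocab6.sep_id
        mask = np.ones_like(ids)
        batch = mask_token_arrays(ids, mask, vocab6, np.random.default_rng(9))
        frac = batch.n_masked / (n * n_kmers)
        assert abs(frac - 0.15) < 0.01
        sel = batch.mask_positions
        corrupted = batch.corrupted_ids[sel]
        original = ids[sel]
        p_mask = (corrupted == vocab6.mask_id).mean()
        p_keep = (corrupted == original).mean()
        p_rand = 1.0 - p_mask - p_keep
        assert abs(p_mask - 0.80) < 0.02
        assert abs(p_rand - 0.10) < 0.02
        assert abs(p_keep - 0.10) < 0.02
        assert not sel[:, 0].any() and not sel[:, -1].any()

    def test_expected_masked_count_scales_with_maskable_tokens(self, vocab3):
        """Binomial mean: a segment with c maskable tokens gets ~0.15c masks."""
        rng = np.random.default_rng(0)
        c = 40
        seg = [encode(make_segment(random_dna(rng, c + 2)), BAC, vocab3, 64)]
        total = 0
        reps = 400
        for seed in range(reps):
            total += apply_mlm_mask(seg, vocab3, rng_seed=seed).n_masked
        assert abs(total / reps - 0.15 * c) < 1.0


class TestConfig:
    def test_from_yaml_overrides_preset(self, tmp_path):
        path = tmp_path / "schedule.yaml"
        path.write_text("preset: desk\nsteps: 12\nlr: 0.002\n")
        config = PretrainConfig.from_yaml(path)
        assert config.steps == 12
        assert config.lr == 0.002
        assert config.batch_size == PretrainConfig().batch_size  # untouched default

    def test_published_preset_schedule(self):
        pub = PretrainConfig.preset("published")
        assert (pub.lr, pub.batch_size, pub.warmup_steps, pub.weight_decay) == (
            4e-4, 2048, 10_000, 0.01)


class TestEncodeCorpus:
    def test_conditional_attaches_true_class_tokens(self, vocab3):
        segs = [make_segment("ACGTACG", label="bacteria"),
                make_segment("TTTTTTT", label="phage")]
        enc = encode_corpus(segs, vocab3, 32, conditional=True)
        assert enc[0].ids[0] == vocab3.id(BAC)
        assert enc[1].ids[0] == vocab3.id(PHA)

    def test_ablation_attaches_cls_to_all(self, vocab3):
        segs = [make_segment("ACGTACG", label="bacteria"),
                make_segment("TTTTTTT", label="phage")]
        enc = encode_corpus(segs, vocab3, 32, conditional=False)
        assert all(e.ids[0] == vocab3.id(CLS) for e in enc)

    def test_unlabeled_segment_rejected_in_conditional_mode(self, vocab3):
        with pytest.raises(ValueError, match="label"):
            encode_corpus([make_segment("ACGTACG")], vocab3, 32, conditional=True)


class TestPretrainLoop:
    def test_overfits_single_repeated_segment(self, vocab3, micro_config):
        """Memorization smoke test: repeated exposure to one segment drives
        masked-token recovery accuracy near 1."""
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 40)
        segs = [make_segment(seq, label="phage")] * 50
        result = pretrain(
            segs, vocab3, micro_config,
            PretrainConfig(steps=200, batch_size=8, warmup_steps=20, log_every=50),
            rng_seed=0,
        )
        encoder = result.encoder
        encoded = [encode(make_segment(seq, label="phage"), PHA, vocab3, 64)]
        hits = total = 0
        for seed in range(20):
            batch = apply_mlm_mask(encoded, vocab3, rng_seed=seed)
            if batch.n_masked == 0:
                continue
            h = encoder.hidden_states(batch.corrupted_ids, batch.attention_mask)
            r, c = np.nonzero(batch.mask_positions)
            pred = encoder.mlm_head.forward(h[r, c]).argmax(axis=-1)
            hits += int((pred == batch.targets[r, c]).sum())
            total += len(pred)
        assert hits / total > 0.9

    def test_loss_history_recorded_and_decreasing(self, vocab3, micro_config):
        rng = np.random.default_rng(4)
        segs = [make_segment(random_dna(rng, 40), label="bacteria") for _ in range(20)]
        result = pretrain(segs, vocab3, micro_config,
                          PretrainConfig(steps=40, batch_size=8, warmup_steps=5, log_every=5),
                          rng_seed=1)
        losses = [h["loss"] for h in result.history]
        assert losses[-1] < losses[0]

    def test_unlabeled_corpus_rejected(self, vocab3, micro_config):
        with pytest.raises(ValueError):
            pretrain([make_segment("ACGTACGTAC")], vocab3, micro_config,
                     PretrainConfig(steps=1, batch_size=1), rng_seed=0)

    def test_vocab_size_mismatch_rejected(self, vocab6, micro_config):
        with pytest.raises(ValueError, match="vocab"):
            pretrain([make_segment("ACGTACGTAC", label="phage")], vocab6,
                     micro_config, PretrainConfig(steps=1, batch_size=1), rng_seed=0)


class TestSeparationStatistic:
    def test_identical_vectors_give_zero(self):
        vecs = np.ones((8, 4))
        assert silhouette_of(vecs, ["bacteria"] * 4 + ["phage"] * 4) == 0.0

    def test_far_separated_clouds_near_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((50, 6)) * 0.1
        b = rng.standard_normal((50, 6)) * 0.1 + 50.0
        labels = ["bacteria"] * 50 + ["phage"] * 50
        assert silhouette_of(np.vstack([a, b]), labels) > 0.9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            silhouette_of(np.ones((4, 2)), ["phage"] * 4)

    def test_representation_separation_requires_two_per_class(self, micro_encoder, vocab3):
        segs = [make_segment("ACGTACG", label="bacteria"),
                make_segment("TTTTACG", label="phage")]
        with pytest.raises(ValueError):
            representation_separation(micro_encoder, segs, vocab3)

    def test_conditional_encoder_separates_label_tokens_even_untrained(self, micro_encoder, vocab3):
        """With distinct class tokens at position 0, the class-token vectors
        of the two classes differ already at initialization."""
        rng = np.random.default_rng(2)
        segs = [make_segment(random_dna(rng, 30), label="bacteria") for _ in range(5)]
        segs += [make_segment(random_dna(rng, 30), label="phage") for _ in range(5)]
        sil_label = representation_separation(micro_encoder, segs, vocab3, attach="label")
        sil_cls = representation_separation(micro_encoder, segs, vocab3, attach="cls")
        assert sil_label > sil_cls
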