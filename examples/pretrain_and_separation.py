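"""Pre-train a tiny conditional encoder and measure label-token separation.

Conditional pre-training attaches [BAC]/[PHA] class tokens during
tokenization, so masked-token prediction is conditioned on the class of
the sequence. After pre-training, the last-hidden-state vectors of the
class tokens cluster by class; the silhouette score (−1..1) quantifies
that separation. The [CLS]-ablation encoder — same data, one shared class
token — shows what is lost without conditioning.

Runs in a couple of minutes on one CPU.
"""

import numpy as np

from condphage import (
    EncoderConfig,
    PretrainConfig,
    SimulationConfig,
    build_vocabulary,
    generate_records,
    pretrain,
    representation_separation,
    segment_records,
)

vocab = build_vocabulary(6)
data = generate_records(SimulationConfig(n_train=100, n_test=10, rng_seed=7))
segments = segment_records(data["train_bacteria"] + data["train_phage"])
print(f"pre-training corpus: {len(segments)} segments of <=500 bp")

config = EncoderConfig.preset("tiny", vocab.size)
schedule = PretrainConfig(steps=40, batch_size=8)
sample = segments[:50] + segments[-50:]  # 50 per class for the silhouette

cond = pretrain(segments, vocab, config, schedule, rng_seed=0, conditional=True)
sil_cond = representation_separation(cond.encoder, sample, vocab, attach="label")
print(f"conditional encoder: final MLM loss {cond.history[-1]['loss']:.3f}, "
      f"silhouette {sil_cond:.3f}")

ablation = pretrain(segments, vocab, config, schedule, rng_seed=0, conditional=False)
sil_cls = representation_separation(ablation.encoder, sample, vocab, attach="cls")
print(f"[CLS] ablation:      final MLM loss {ablation.history[-1]['loss']:.3f}, "
      f"silhouette {sil_cls:.3f}")

print("\nA silhouette near 1 means bacterial and phage class-token vectors")
print("form well-separated clusters; the ablation's near-zero value shows the")
print("shared [CLS] token cannot carry class identity.")
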