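"""Full pipeline on a small simulated dataset: pre-train, paradox
fine-tune, score held-out contigs, evaluate.

Every labeled training segment is tokenized twice (once per label token);
the copy with the wrong token gets the third target class "paradox". At
prediction time each query segment is also tokenized twice, the 3-class
scores are aggregated to binary phage scores, averaged across segments,
and thresholded at 0.5.

Takes a few minutes on one CPU.
"""

import numpy as np

from condphage import (
    ClassifierConfig,
    EncoderConfig,
    FinetuneConfig,
    PretrainConfig,
    SimulationConfig,
    build_vocabulary,
    compute_metrics,
    finetune,
    generate_records,
    paradox_augment,
    predict_batch,
    pretrain,
    segment_records,
)

vocab = build_vocabulary(6)
data = generate_records(SimulationConfig(n_train=150, n_test=50, rng_seed=7))
test = data["test_bacteria"] + data["test_phage"]
truth = [r.label for r in test]
segments = segment_records(data["train_bacteria"] + data["train_phage"])

pt = pretrain(segments, vocab, EncoderConfig.preset("tiny", vocab.size),
              PretrainConfig(), rng_seed=0)
print(f"pre-trained on {len(segments)} segments")

rng = np.random.default_rng(0)
idx = rng.permutation(len(segments))
train_pool = [segments[i] for i in idx[:200]]
valid_pool = [segments[i] for i in idx[200:240]]
ft = finetune(paradox_augment(train_pool, vocab), paradox_augment(valid_pool, vocab),
              pt.encoder, ClassifierConfig(), FinetuneConfig(), rng_seed=0)
best = ft.history[ft.best_epoch]
print(f"fine-tuned: best epoch {ft.best_epoch}, "
      f"3-class validation accuracy {best['valid_accuracy']:.3f}")

frame = predict_batch(test, ft.classifier, vocab)
print("\nfirst prediction rows:")
print(frame.head(3).to_string(index=False))

report = compute_metrics(frame["phage_score"], frame["call"], truth)
print("\nheld-out contig metrics (phage = positive class):")
print(report.to_frame().to_string(index=False))
print("\nMCC near 1 means the simulated compositional split was recovered")
print("almost perfectly; AUROC/AUPRC are threshold-free ranking quality.")
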