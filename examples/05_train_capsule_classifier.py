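"""Train a scaled-down CNN + capsule classifier on the binary task.

The full published configuration (512-channel extractor, Adam lr 0.001,
500 epochs, batch 128) is desk-scaled here: conv channels / 8, 30 epochs,
batch 32.  Inputs are standardized (the best-performing condition).
"""

from capseeg.architectures import ArchitectureSpec, build_model, train
from capseeg.data import SynthConfig, stratified_split, synth_generate, \
    to_binary
from capseeg.evaluation import confusion, metrics
from capseeg.preprocessing import condition_pipeline

data = to_binary(synth_generate(SynthConfig(n_per_class=100, seed=3)))
train_set, test_set = stratified_split(data, test_frac=0.25, seed=0)
(train_set, test_set), _ = condition_pipeline("scaling", train_set, test_set)

spec = ArchitectureSpec.for_variant("cnn_caps", n_classes=2,
                                    batch_size=32, seed=0).scaled(8)
model = build_model(spec)
model, history = train(model, train_set, spec, epochs=30)

pred = model.predict(test_set.signals)
fr = metrics(confusion(pred, test_set.labels))
print(f"loss: {history['loss'][0]:.3f} -> {history['loss'][-1]:.3f} "
      f"over {len(history['loss'])} epochs")
print(f"test accuracy: {100 * fr.accuracy:.2f}%")
for lab, p, r in zip(fr.labels, fr.precision, fr.recall):
    name = "seizure" if lab == 1 else "non-seizure"
    print(f"  {name:12s} precision {100 * p:.1f}%  recall {100 * r:.1f}%")
# class-capsule lengths act as existence probabilities; the longest capsule
# wins the prediction.
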