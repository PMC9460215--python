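# bowelwarn

Defecation pre-warning from bowel sounds with a semi-supervised GAN.

Fecal incontinence management for bed-bound and elderly patients improves
dramatically if an upcoming defecation can be predicted a few minutes
ahead. Bowel sounds — short acoustic bursts of gas and luminal contents
moving through the intestine, with energy concentrated around 100–500 Hz —
carry that signal: the rate and amplitude of colonic motility rise before
defecation. `bowelwarn` classifies 2.5 s bowel-sound segments (10,000
samples at 4 kHz) as *no defecation tendency* (0) or *defecation tendency*
(1) and raises a recording-level warning when enough segments are flagged.

The classifier is the discriminator of a semi-supervised GAN: a 1-D
convolutional network (kernel 8, stride 4 ×4 layers, LeakyReLU 0.2) whose
softmax head has K + 1 = 3 outputs — the two real classes plus a
"generated" class fed by an adversarial generator. Training minimizes

    Loss = L1 + L2
    L1   = −E_{x,y} log p(y | x)                      (labeled real data)
    L2   = −E_x log(1 − q(x)) − E_z log q(G(z))       (real vs. fake)

with `q` the fake-class probability, while the generator minimizes
`−E log(1 − q(G(z)))`. The unsupervised term lets unlabeled recordings
shape the features, which matters because labeled pre-defecation data is
scarce. Evaluation uses the standard confusion-matrix rates — accuracy,
specificity `TN/(TN+FP)` and sensitivity `TP/(TP+FN)` with "tendency" as
the positive class — macro-averaged over test sets.

Because clinical recordings of this kind are generally unpublishable, the
package includes a parameterized simulator (Poisson bursts of damped
sinusoids in the 100–500 Hz band over a noise floor; class 1 with elevated
rate and amplitude) that serves as data source for experiments and tests.

## Worked example

```python
from bowelwarn import evaluate, preprocess, synth, train

config = synth.SynthConfig.separable()
recordings = [synth.generate_recording(config, label, 100 * label + i)
              for label in (0, 1) for i in range(5)]
split = preprocess.build_dataset(recordings, labeled_fraction=0.5, rng_seed=0)
result = train.train(split.labeled_frames, split.labeled_labels,
                     split.unlabeled_frames, train.TrainConfig(epochs=5, seed=1))

frames, labels = synth.generate_fixture_set(config, 200, 60, rng_seed=99)
preds = evaluate.predict_segments(result.classifier, frames)
report = evaluate.aggregate_tasks([evaluate.confusion(preds, labels)], ["demo"])
print(report.to_dataframe().to_string(index=False))
```

Output of `python examples/04_train_and_evaluate.py` (which runs exactly
this):

```
96 labeled / 96 unlabeled training frames
epoch 0: Loss 2.684 (L1 1.113 + L2 1.570), G 0.511
epoch 1: Loss 2.391 (L1 0.887 + L2 1.505), G 0.408
epoch 2: Loss 2.363 (L1 0.813 + L2 1.551), G 0.429
epoch 3: Loss 2.254 (L1 0.837 + L2 1.418), G 0.704
epoch 4: Loss 1.978 (L1 0.950 + L2 1.029), G 1.271
   task   TP    TN   FP  FN  accuracy_pct  specificity_pct  sensitivity_pct
   demo 60.0 101.0 39.0 0.0          80.5             72.1            100.0
Average 60.0 101.0 39.0 0.0          80.5             72.1            100.0
```

Of the 200 test segments (60 pre-defecation), all 60 positives are caught
(sensitivity 100%) but 39 of the 140 quiescent segments are false alarms
(specificity 72.1%) — typical for a run this short: the network learns
"bursts present ⇒ warn" quickly and needs more epochs and data to refine
the amplitude/density boundary. Accuracy is (TP+TN)/200; the Average row
equals the single task here. Under the scaled conditions in the test suite
(20 epochs, ~500 frames) held-out accuracy reaches ≥ 0.90 averaged over
seeds.

There is also a CLI for shell use — `bowelwarn synth | preprocess | train |
evaluate | predict | run-experiment` — and an `examples/` directory with
one narrative script per capability.

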