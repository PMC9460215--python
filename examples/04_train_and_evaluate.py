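"""Train the semi-supervised GAN on simulated data and score it.

A deliberately small run (a few recordings, 5 epochs) so it finishes in a
couple of minutes on a laptop CPU; accuracy improves further with the
scaled conditions used in the test suite (20 epochs, ~500 frames).
"""

from bowelwarn import evaluate, preprocess, synth, train

config = synth.SynthConfig.separable()
recordings = [synth.generate_recording(config, label, 100 * label + i)
              for label in (0, 1) for i in range(5)]
split = preprocess.build_dataset(recordings, labeled_fraction=0.5,
                                 rng_seed=0)
print(f"{len(split.labeled_frames)} labeled / "
      f"{len(split.unlabeled_frames)} unlabeled training frames")

result = train.train(split.labeled_frames, split.labeled_labels,
                     split.unlabeled_frames,
                     train.TrainConfig(epochs=5, seed=1))
for rec in result.history:
    print(f"epoch {rec.epoch}: Loss {rec.loss:.3f} "
          f"(L1 {rec.L1:.3f} + L2 {rec.L2:.3f}), G {rec.generator_loss:.3f}")

frames, labels = synth.generate_fixture_set(config, 200, 60, rng_seed=99)
preds = evaluate.predict_segments(result.classifier, frames)
counts = evaluate.confusion(preds, labels)
report = evaluate.aggregate_tasks([counts], ["demo"])
print(report.to_dataframe().to_string(index=False))
# accuracy_pct is (TP+TN)/200 as a percentage; specificity and sensitivity
# are the class-conditional rates with "defecation tendency" positive.
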