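"""Monte-Carlo-dropout uncertainty and the full decision cascade.

Loads the checkpoint from example 01, calibrates the dropout rate p*, the
entropy cutoff alpha, and the saliency-intensity threshold D on a
mixed-difficulty validation split, then runs the cascade on a test split.
Low-entropy predictions are accepted (or, rarely, flipped by the saliency
rule); high-entropy ones are flagged for expert review.  Accuracy on the
retained subset should be at or above the accuracy over all images — the
point of selective classification.

Run examples/01_train_on_phantoms.py first.
"""

import numpy as np

import trustnet as tn

net = tn.load_checkpoint("scratch_example_model.ckpt")

mixed = tn.generate_dataset(n=240, seed=7, image_size=48,
                            split_fractions=(0.25, 0.45, 0.30))

thresholds = tn.fit_cascade(net, mixed.split("validation"),
                            p_grid=(0.01, 0.1, 0.3), n_passes=8, seed=0)
print(f"calibrated: p* = {thresholds.p_star}, "
      f"alpha = {thresholds.alpha.alpha:.4f}, "
      f"D = {thresholds.msi_threshold.D:.4f}")
print("entropy separation per dropout rate:",
      {p: round(s, 3) for p, s in
       ((float(k), v) for k, v in thresholds.provenance["separation"].items())})

test = mixed.split("test")
results = tn.run_cascade(net, thresholds, test, seed=0)
frame = tn.results_to_frame(results)
print("\ncascade outcomes:", frame.status.value_counts().to_dict())

labels = [img.label for img in test]
baseline_acc = np.mean([r.baseline_label == t for r, t in zip(results, labels)])
kept = [(r.final_label, t) for r, t in zip(results, labels)
        if r.final_label is not None]
retained_acc = np.mean([p == t for p, t in kept])
print(f"baseline accuracy over all {len(test)} images: {baseline_acc:.3f}")
print(f"accuracy over the {len(kept)} retained images: {retained_acc:.3f}")
print("flagged images are handed to an expert instead of being auto-labelled")
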