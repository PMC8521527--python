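"""Planted-mixture recovery through the full pipeline.

Simulates a 60-neuron population with a known class mixture (55%
non-linear multisensory, 15% linear, 5% auditory, 25% visual), runs the
complete analysis, and compares the recovered class proportions with the
planted truth. With the default signal-to-noise the pipeline should land
within a few percentage points of the planted mixture.
"""

import avmod

cfg = avmod.af_like_config(seed=5, n_neurons=60)
ds = avmod.simulate_population(cfg)
bundle = avmod.analyze(ds)

truth = ds.truth["true_class"].value_counts(normalize=True)
got = bundle.summaries["all"].class_proportions
print(f"{'class':26s} {'planted':>8s} {'recovered':>10s}")
for cls in avmod.NEURON_CLASSES:
    print(f"{cls:26s} {truth.get(cls, 0.0):8.3f} {got[cls]:10.3f}")

s = bundle.summaries["all"]
print(f"\nmultisensory proportion: {s.multisensory_proportion:.3f}")
print(f"median collapsed modulation index: {s.median_collapsed_index:.3f}")
if s.index_t_test:
    print(f"one-sample t vs 0: t({s.index_t_test.df}) = "
          f"{s.index_t_test.t:.2f}, p = {s.index_t_test.p:.2g}")
print("\nA positive median index with a significant t-test reflects the "
      "predominance of planted enhancement over suppression.")
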