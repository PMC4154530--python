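"""Compare knowledge-based features against the whole-epoch PSD baseline.

Computes the Fisher separability criteria J1 = tr(Sb)/tr(Sw) and
J2 = tr(Sw^-1 Sb) for both feature sets on the same simulated cohort
(features z-scored first, as the classifier sees them), plus a 2-component
PCA projection. Larger J values mean the five stages form better-separated
clusters in feature space.
"""

import numpy as np

import somnoscore as ss

cfg = ss.SimulationConfig(n_subjects=4, epochs_per_subject=60, seed=5)
cohort = ss.simulate_cohort(cfg)

for mode in ("knowledge", "conventional"):
    ds = ss.cohort_to_dataset(cohort, feature_mode=mode)
    sep = ss.feature_set_separability(ds)
    X = np.vstack([ds[s][0] for s in ds])
    scores, evr = ss.pca_project(X)
    print(f"{mode:>12}: J1 = {sep.J1:6.2f}  J2 = {sep.J2:7.2f}  "
          f"(first two PCs explain {100 * evr.sum():.0f}% of variance)")

print("\nThe sorted segment statistics isolate transient scoring cues "
      "(spindles, K-complexes, slow waves) that a single 30-s Fourier "
      "transform smears into the background, so the knowledge features "
      "separate the stages more cleanly than the raw PSD profile.")
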