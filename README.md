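# somnoscore

Automatic sleep staging from **two forehead EEG channels** (FP1, FP2 at
128 Hz). Clinical sleep studies score each 30-second epoch of a night into
one of five stages — W, N1, N2, N3, REM — by visually applying AASM rules
("more than 50% of the epoch shows alpha rhythm", "a spindle or K-complex
occurred", "high-amplitude slow waves cover over 20% of the epoch").
Full polysomnography needs a lab, gel electrodes and a technician; the
hairless forehead sites can be self-applied at home, at the cost of a much
weaker, eye-movement-contaminated signal. `somnoscore` is for researchers
and engineers prototyping such home staging pipelines.

## Method

**Knowledge-based spectral features.** Each band-passed (0.5–50 Hz) 30-s
epoch is cut into 59 half-overlapping 1-s segments (1-s Hamming window,
0.5-s step). Each segment's power spectral density is normalized to unit
total power — removing between-subject amplitude differences — and summed
into the classical bands ↓δ (1–2 Hz), δ (1–4), θ (5–7), α (8–12),
σ (12–14), β (15–30), γ (30–50). Statistics over the 59 per-segment band
proportions encode the scoring rules: means of the sorted upper/lower 80%
(↓δ, slow waves) or 50% (θ, α, β — the "more than half the epoch"
rules), max-among-59 plus mean-of-the-rest (σ for spindles, δ for
K-complexes), and the overall γ mean — 13 features per channel, 26 total.
A conventional baseline uses the whole-epoch periodogram in fifty 1-Hz
bands per channel.

**Sparse Bayesian classification.** A from-scratch relevance vector
machine: y(x) = σ(Σᵢ wᵢ K(x, xᵢ) + b) with an independent Gaussian prior
of precision αᵢ on each weight, Bernoulli likelihood via Laplace
approximation (IRLS), and type-II re-estimation αᵢ ← γᵢ/μᵢ² with
γᵢ = 1 − αᵢΣᵢᵢ. Most αᵢ diverge and their basis functions are pruned;
the few surviving training points are the relevance vectors. Five
stage-vs-rest RVMs form a one-against-all ensemble (argmax probability).
LDA, k-NN (k = 13) and an SVM (C = 50) sit behind the same interface.

**Evaluation.** Leave-one-subject-out cross-validation; overall accuracy,
per-stage sensitivity, Cohen's κ = (p₀ − pₑ)/(1 − pₑ), Fisher
separability J1 = tr(S_b)/tr(S_w) and J2 = tr(S_w⁻¹S_b), and 2-component
PCA projections.

**Synthetic cohorts.** Real overnight recordings cannot ship with the
package, so `somnoscore.simulate` generates seeded stage-labeled epochs
whose spectral content realizes the scoring rules above (alpha-dominant W,
theta N1, spindles/K-complexes in N2, >75 µV slow waves in N3,
anti-correlated eye movements in REM, broadband artifact bursts
everywhere), with overnight stage prevalences W 18.4 / N1 13.1 / N2 37.8 /
N3 15.6 / REM 15.1%.

## Worked example

```bash
python examples/02_rvm_sparsity.py
```

```
separable blobs (n=40, linear kernel): 17 relevance vectors, training accuracy 1.00
  probability range on training data: 0.000 .. 0.999
XOR (n=80, RBF gamma=0.5): 5 relevance vectors, training accuracy 1.00
```

The RVM keeps 17 of 40 (and 5 of 80) training points while fitting
perfectly — the sparsity that distinguishes it from an SVM — and returns
calibrated-looking probabilities rather than margins.

```bash
python examples/03_loso_evaluation.py   # 4 subjects x 60 epochs, ~1 min
```

```
S01: accuracy  96.7%  kappa 0.96
...
mean accuracy 93.3% +/- 5.3 (SD), mean kappa 0.91 +/- 0.07
```

Each subject is scored by a model trained only on the other subjects;
the pooled confusion matrix shows the residual confusions (REM vs N2/N1),
the same boundary human scorers disagree on. Synthetic cohorts are
cleaner than real sleep EEG, so these numbers sit above what forehead
recordings achieve in practice.

The command-line interface mirrors the library:

```bash
somnoscore simulate --out-dir cohort --n-subjects 3 --epochs-per-subject 40 --seed 202
somnoscore extract --edf cohort/S01.edf --hypnogram cohort/S01.hypnogram.csv --out feats.csv
somnoscore train --features feats.csv --out model.json
somnoscore predict --model model.json --edf cohort/S02.edf --out predicted.csv
somnoscore evaluate-loso --manifest cohort/manifest.json --out report.json
```

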