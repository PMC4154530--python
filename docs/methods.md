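# Methods

This note records the models and numerical choices behind `somnoscore`,
what the synthetic generator does and does not emulate, and the design
decisions taken where more than one reasonable option existed.

## Signal model and preprocessing

The scoring unit is a 30-s, two-channel (FP1/FP2) epoch at 128 Hz
(3840 samples/channel). Epochs are band-passed to 0.5–50 Hz with a
4th-order Butterworth applied forward–backward (`sosfiltfilt`), i.e. zero
phase with squared magnitude response. The filter family and order are not
dictated by the problem; 4th-order Butterworth is the conventional EEG
choice and both are configurable (`FilterSpec`). Edge transients are
suppressed by `sosfiltfilt`'s default odd-reflection padding; we rely on
the library default rather than a hand-rolled pad length since the
difference is confined to a few samples at the epoch edges. Filtering is
applied per epoch (the pipeline treats each epoch independently end to
end). No artifact rejection is applied anywhere — deliberately, since the
target setting is unedited self-applied forehead recordings.

## Feature extraction

**Knowledge-based set (13/channel).** STFT with a periodic (DFT-even)
1-s Hamming window and 0.5-s step gives `floor((3840−128)/64)+1 = 59`
segments; each segment's one-sided density periodogram is divided by its
total power, so every downstream quantity is a power *proportion* in
[0, 1] and the whole feature vector is invariant to scaling the raw
signal — the mechanism that removes inter-individual amplitude
differences. Band sums use 1-Hz bins with both edges inclusive. The
statistics per band:

| band | Hz | statistics | encodes |
|---|---|---|---|
| lower delta | 1–2 | upper-80% mean, lower-80% mean | slow-wave occupancy (N3) |
| delta | 1–4 | max of 59, mean of remaining 58 | K-complex (N2) |
| theta | 5–7 | upper/lower-50% means | light sleep (N1/N2/REM) |
| alpha | 8–12 | upper/lower-50% means | wake |
| sigma | 12–14 | max of 59, mean of remaining 58 | spindle (N2) |
| beta | 15–30 | upper/lower-50% means | wake |
| gamma | 30–50 | mean of 59 | movement/EMG |

Sorted-fraction means take k = max(1, floor(fraction·59)) values — 47
for 80%, 29 for 50% (the median segment belongs to neither half); the
rounding convention is ours. The lower-delta band is 1–2 Hz: a 0.5-Hz
edge cannot be represented on the 1-Hz bin grid of a 1-s window, and the
band is configurable for other grids. The amplitude half of the visual
slow-wave rule (">75 µV") is unrepresentable after per-segment
normalization — normalization deliberately discards amplitude — so N3 is
carried by relative lower-delta power alone.

**Conventional baseline (50/channel).** The whole-epoch Hamming
periodogram aggregated into fifty 1-Hz bands centered at 1…50 Hz and
normalized per channel to unit sum, making the baseline scale-invariant
and commensurate with the knowledge set (a `normalize=False` switch
retains raw PSD).

Before classification, features are z-scored with training-fold
means/SDs only; constant features pass through unscaled.

## Relevance vector machine

The classification variant of sparse Bayesian learning over the kernel
basis Φ = [1, K(X, X)]: Bernoulli likelihood, independent zero-mean
Gaussian weight priors with precisions α, posterior mode by IRLS/Newton
with backtracking (penalized-likelihood never decreased), Laplace
covariance Σ = (ΦᵀBΦ + A)⁻¹, and MacKay updates αᵢ ← γᵢ/μᵢ²,
γᵢ = 1 − αᵢΣᵢᵢ. Defaults: αᵢ = 10⁻², prune at α > 10⁹ (pruned bases
never re-enter), stop when max |Δ log α| < 10⁻³, IRLS capped at 25 inner
steps, outer cap 20 000. The large outer cap matters only for degenerate
inputs: on *linearly separable* data the Laplace approximation saturates
(B → 0) and the α dynamics traverse a slow manifold, so sparsification of
a collinear (e.g. linear-kernel) basis takes thousands of cheap
iterations; on overlapping data — all realistic staging folds — the fit
converges in a few hundred. Non-convergence is reported in model metadata,
not raised. There is no penalty parameter to tune; the per-weight
regularization is estimated from the data, and the output is a posterior
class probability.

Multiclass staging trains one stage-vs-rest RVM per stage in the fixed
order (W, N1, N2, N3, REM) and predicts the argmax probability, ties going
to the earlier stage. A training set missing any stage is an error.
Baselines behind the same fit/predict interface: LDA (shared-covariance
Gaussian discriminant; ridge 10⁻⁶·tr(S)/d added only when the pooled
covariance is near-singular), k-NN (Euclidean, k = 13, vote ties broken by
the nearest neighbor among tied classes), and scikit-learn's SVC (C = 50)
for margin-classifier comparisons. The RBF kernel is exp(−γ‖x−z‖²) with
γ = 0.5 by default, matching the γ-parameterization; a σ-style value can
be converted by γ = 1/(2σ²).

## Evaluation

Fisher criteria J1 = tr(S_b)/tr(S_w) and J2 = tr(S_w⁻¹S_b) with the
standard scatter definitions. J2 is invariant to invertible linear feature
maps; J1 is not, so *cross-feature-set comparisons* (`feature_set_separability`)
z-score the features first — the representation the classifier actually
consumes — otherwise J1 merely ranks the sets by their largest raw
variances. Cohen's κ is unweighted. Sensitivity for a stage absent from a
subject's night is reported as missing (NaN/null), not zero. LOSO reports
per-subject accuracy/κ, across-subject mean ± SD, and the pooled
confusion matrix, since both conventions are common and they answer
different questions (subject-level generalization vs epoch-level
agreement). PCA projections fix component signs by making each loading's
largest-magnitude entry positive.

## Synthetic data

The generator produces what the feature extractor is entitled to assume
and nothing more: stage-conditional *spectral* structure. Per stage, a
dominant band-noise carrier is gated to a contiguous occupancy window
(raised-cosine edges), continuous secondary carriers and a per-channel
1/f + white floor are added, and transient events are inserted at
Poisson-random onsets with raised-cosine envelopes: spindles (12–14 Hz,
0.5–1.5 s, ~every 2nd N2 epoch), K-complexes (negative-then-positive
biphasic, ≥0.5 s, ~every 2nd N2 epoch), slow waves (N3: 0.75–2 Hz
carrier at 50 µV RMS — peaks above the 75 µV visual criterion — over
~35% of the epoch), and eye movements (REM: 0.5–1.5 s monophasic
deflections, anti-correlated across the two frontal channels; their rate,
3/epoch, is a free parameter with no published criterion to anchor it).
Realism mechanisms, frozen as the package's study conditions:

* per-epoch occupancy jitter (±0.15) and log-amplitude jitter (SD 0.3),
  so epochs straddle the ">50% of the epoch" scoring thresholds;
* broadband 0.5–50 Hz artifact bursts (4/epoch, ~25 µV, 0.3–1.5 s) in
  every stage, emulating frontalis EMG/movement in unedited forehead
  recordings — these corrupt whole-epoch spectra while the sorted
  segment statistics remain robust, which is precisely the contrast the
  knowledge features exist to exploit;
* a per-subject multiplicative amplitude gain exp(N(0, 0.2)), the
  between-subject difference the per-segment normalization cancels.

Stage labels are drawn i.i.d. from the overnight mixture
(18.4/13.1/37.8/15.6/15.1%); a sticky-Markov option (repeat the previous
stage with probability s) adds realistic stage runs without changing the
stationary mixture, and is off by default. Subject streams derive from
the master seed via `SeedSequence(seed).spawn`, so cohorts are
bit-reproducible from the seed alone.

What the generator does **not** emulate: true EEG microstructure
(waveform morphology, phase coupling), EOG/EMG as separate channels,
arousals and apnea events, stage-transition dynamics, or scorer label
noise. Synthetic stages are therefore *more* separable than real ones:
LOSO accuracies here (~0.9 on default cohorts) say the pipeline is
correct and that the knowledge features beat the whole-epoch baseline
under these conditions; they do not predict field accuracy on real
forehead recordings.

## Problem sizes and determinism

The acceptance script and the heavyweight tests use a 10-subject ×
100-epoch cohort for the LOSO comparison: large enough that every
training fold contains all five stages with near-certainty and the
knowledge-vs-conventional ordering is stable across seeds, while the
two-pipeline comparison (100 binary RVM fits on ~900-point kernels)
completes in a few minutes on one CPU. All fixtures use explicit seeds
recorded in the code; identical epochs yield bit-identical features.

## I/O conventions

Recordings travel as plain 16-bit EDF (1-s records, µV, symmetric
physical range; round-trip error ≤ half a digital step). Reading uses
`mne`; writing is a compact in-repo encoder since no installed library
writes EDF. Hypnograms are a separate `epoch,stage` CSV side-car
(0-based, aligned to the recording start, `?` = unscored); unscored
epochs are excluded from training and from every reported metric.
Trailing partial epochs are dropped with a log message. EDF+ annotations,
other PSG channels, and montage re-referencing are out of scope.

## Known limitations

* The Laplace-approximate RVM is O(n·m²) per iteration in the active
  basis size m; cohorts beyond a few thousand epochs per fold call for
  the sequential marginal-likelihood variants, which this package
  intentionally does not implement.
* The generator's stage recipes are spectral caricatures; claims about
  real-data performance require real recordings.
* N1 is intrinsically under-determined in this feature space (it shares
  theta dominance with N2/REM backgrounds); its sensitivity is the
  weakest in every configuration, as it is for human scorers.
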