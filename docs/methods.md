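# Methods

## The problem and the model

Stress leaves a spectral signature in resting EEG: frontal-midline theta
(4–7 Hz) rises, frontal alpha (8–13 Hz) falls and its left/right balance
shifts, central beta (14–30 Hz) rises, and high-beta (23–36 Hz)
fronto-central coupling strengthens. `earattn` decodes the post-stressor
vs. post-relaxation resting state from just the two preauricular ear
channels, a montage sparse enough for wearables but too sparse for
conventional spatial filtering. The classifier therefore models the one
spatial relation the montage does offer — the interaction between the left
and right ear signals.

**DeepAttNet.** Each 60-s, 125-Hz epoch (2 × 7500 samples) is split into a
left and a right stream. Every stream passes four temporal blocks
(1-D convolution → batch normalization → ELU, average pooling after blocks
1–3). Kernel lengths shrink from 125 to 20 samples (1 s down to 0.16 s), so
early blocks capture slow rhythms and later blocks fine structure; pooling
with lengths 5, 6, 7 reduces 7500 samples to exactly 35 temporal tokens.
A 1×1 pointwise convolution compresses the final feature maps to a single
scalar token sequence per stream, preserving band energy while collapsing
the feature dimension. Learned linear maps lift the scalar tokens to
queries/keys (d_k = 8) and values (d_v = 1), and scaled dot-product
attention softmax(QKᵀ/√d_k)V is applied twice: left tokens query right
keys/values, and vice versa, so each ear conditions on the other. The two
attended length-35 sequences are concatenated (70 features) and classified
by linear(70→64) → batch norm → ELU → dropout(0.5) → linear(64→2), with
stress as class 1. The full model has ≈ 6 × 10⁴ trainable parameters.

Design points that were genuinely open, and how they were fixed:

* **Encoder widths** — filters (8, 16, 16, 32), same-padding, stride 1:
  chosen to satisfy the 125→20 kernel schedule and the 35-token budget with
  a parameter count near 0.07 M.
* **Streams are not weight-shared** (a `share_streams` switch exists):
  hemispheric asymmetry is the signal of interest, so each ear gets its own
  encoder.
* **Q/K/V are learned projections** of the compressed tokens rather than the
  tokens themselves; with d_v = 1 the attended output stays a 35-vector per
  direction, keeping the classifier input at 70.
* **"Two cross-attention heads"** are realized as the two directions, one
  single-head attention per direction.
* **Key projections carry no bias**: a key bias shifts every attention score
  in a row equally and is exactly inert under the row softmax.
* **Ablation wiring**: `no_cross_attention` concatenates the two compressed
  token sequences directly; `no_pointwise` replaces the learned 1×1
  compression with a uniform mean over feature maps so the token count stays
  35; `self_attention` applies within-stream single-head attention
  (d_v = 8) followed by temporal averaging; `lightweight_transformer` lifts
  the concatenated 70-token sequence to d_model = 32, adds learned
  positional and channel embeddings, and applies one two-head Transformer
  encoder layer (feed-forward width 128). The Transformer variant has more
  parameters than the full cross-attention model, mirroring the compactness
  ordering of the attention baselines.

**Implementation.** No deep-learning framework is used: layers, attention,
backpropagation and AdamW are a small NumPy (float32) stack. Convolutions
run as circular FFT correlations at one transform length n ≥ L + K − 1; the
output windows needed by the forward pass and by both gradients are free of
circular aliasing at that length, which allows the input spectrum to be
cached and reused for the kernel gradient. Analytic gradients are verified
against central differences (float64) and a naive direct convolution in the
test suite. Gradients that are exactly zero by construction (e.g. a
convolution bias feeding batch normalization in training mode) are excluded
from those checks explicitly.

## Training and evaluation protocol

Eight-fold subject-level cross-validation: subjects are shuffled once with
the root seed and partitioned into eight disjoint test groups (4 of 32
subjects each); each fold's remaining subjects are split 6:1 — at the
subject level, so early stopping never sees a test or validation subject's
data — into 24 training and 4 validation subjects. Training uses AdamW
(lr 10⁻³ constant, β = (0.9, 0.999), ε = 10⁻⁸, weight decay 0.01 — the
optimizer's customary default, since no value was pinned), cross-entropy on
logits, mini-batches of 16 (validation 8, test full batch), at most 200
epochs with early stopping after 30 epochs without a strictly lower
validation loss; the best-validation parameters are restored. Metrics are
accuracy and macro-F1 (unweighted mean of per-class F1, via scikit-learn);
fold-wise model comparisons use the paired Wilcoxon test with
Benjamini–Hochberg correction across comparisons. All randomness (fold
assignment, parameter initialization, batch order, dropout) derives from the
run seed; runs are bit-reproducible per platform.

## Marker statistics

Welch spectra use 2-s Hamming segments with 50% overlap at 125 Hz (0.5 Hz
resolution, ~59 averages per 60-s epoch); band power is the trapezoidal
integral of the PSD over the closed band, and coherence is magnitude-squared
coherence averaged over bins with center frequency in [23, 36] Hz, using the
same segmentation. Band edges follow the conventional definitions (θ 4–7,
α 8–13, β 14–30, high-β 23–36 Hz; β and high-β overlap deliberately).

The Wilcoxon signed-rank test drops zero differences, uses the exact
permutation distribution of W⁺ for n ≤ 25 without ties (dynamic-programming
enumeration, validated against full enumeration and scipy), and otherwise a
normal approximation with continuity and tie correction. The signed z
statistic is always reported, and Rosenthal's r = |z|/√n uses the original
pair count. BH adjustment is statsmodels' step-up (q(i) = min over suffixes
of m·p(j)/j, capped at 1); q-values are rounded to 4 decimals in written
reports only. On the seven published marker p-values this reproduces the
0.0228 → 0.0319 adjustment and a six-of-seven rejection count; the published
FAA and α-power q-values do not follow from the printed (rounded) p-values
under the step-up rule and are therefore not used as checks.

## The synthetic generator

The generator emulates what the downstream analyses assume about the data,
not a biophysical head model. Each recording is 60 s at 500 Hz in
microvolts: per-channel 1/f background noise (frequency-domain synthesis,
amplitude ∝ f^(−exponent/2), flattened below 1 Hz, unit RMS) plus
narrowband-filtered white-noise oscillators (not pure sines, so Welch
estimates carry realistic variance): θ strongest at Fpz (3 μV RMS), left and
right α at AF7/AF8 (4 μV), β at Cz (2 μV), and one shared high-β source
(1.5 μV) mixed into AF7, C3, AF8, C4, Fpz and Cz, which creates the
fronto-central coherence. Ear channels receive lagged hemispheric mixtures
of θ, the ipsilateral α, β, the shared source and an ear-specific broadband
component, delayed by an integer-sample interaural lag (default 4 ms,
shifted +6 ms under stress).

Stress multiplies oscillator amplitudes only — θ ×2.5, α ×0.6 with an
asymmetric factor exp(±faa_shift/4) realizing a +0.5 FAA log-power shift,
Cz β ×2.2, shared high-β ×2.0 — and never changes which random substream is
drawn, so the null configuration (all gains 1, shifts 0) makes the two
conditions i.i.d. The published analysis reports no quantitative effect
sizes (and none at all for the ear channels), so these defaults were chosen
once as a deliberately large-effect regime in which every dosed marker is
detectable and the ear channels carry a clearly learnable condition
signature; the ear-channel effect in particular is an assumption exposed as
configuration. Per-subject log-normal amplitude factors (sd 0.3, shared
across conditions) make subject identity a confound that subject-level CV
must overcome. Seeding is hierarchical — root seed → (subject, condition,
component) substreams via stable CRC-32 keys — so adding channels or effects
never perturbs existing draws, and a fixed seed gives bit-identical output.

What the generator does **not** emulate: EMG/EOG/motion artifacts, electrode
impedance drift, volume-conduction mixing beyond the explicit weights,
nonstationarity within an epoch, or any cohort-fitted effect magnitude.
Passing tests therefore show that the pipeline recovers the structure it
assumes, under favorable signal-to-noise; they do not certify real-data
performance.

## Preprocessing choices

Filtering is zero-phase (forward–backward) by default, doubling the
effective magnitude order; a causal switch exists. The notch is a
second-order IIR at 60 Hz with quality factor 30. Down-sampling 500 → 125 Hz
keeps every 4th sample, the 40 Hz low-pass having already removed content
above the new Nyquist; non-integer ratios fall back to polyphase
resampling. Filtering precedes resampling. Epochs are the first 60 s of a
recording (half-open sample windows, 0-based); multi-epoch slicing exists
as an opt-in augmentation mode and longer-duration simulation plus
multi-epoch slicing is the supported way to enlarge datasets.

## Explainability

Row entropy uses natural log on renormalized rows (0·log 0 := 0), so values
lie in [0, ln 35 ≈ 3.555]; an optional normalized variant divides by ln T′.
Occlusion windows convert seconds to samples by flooring (62-sample window,
12-sample step at 125 Hz → 620 positions on 7500 samples); windows that
would cross the epoch edge are dropped, the occlusion baseline is exactly
0 μV on the post-filter scale, and window time is reported at the window
center. Fold summaries average per-sample statistics within label first,
then difference (stress − relax), then average deltas across folds.

## Problem sizes used by the automated checks

The simulation-based acceptance tests run the 32-subject cohort with
training capped at 45 epochs (patience 30) for the three-seed CV accuracy
check, a 16-subject cohort with 4 folds and a 40-epoch cap for the ablation
ordering, 50 ten-subject replicates for marker detection power, and 25
eight-subject replicates for null false-positive control; marker replicates
are evaluated directly on the generator output, since linear filtering
barely affects in-band power. These sizes are the package's chosen test
conditions and are deliberately smaller than a full study.

## Known limitations

* The NumPy training stack is CPU-only and single-threaded; it is built for
  correctness and small cohorts, not large-scale training.
* EDF files can be read (via mne) but not written; the native interchange
  format is delimited text plus a TSV manifest.
* Exact Wilcoxon p-values switch to a normal approximation in the presence
  of tied |differences| at any n.
* The lightweight-Transformer and self-attention baselines follow the
  published description at the block level; their internal widths are this
  package's choices and only the parameter-count *ordering* against the full
  model is asserted.
* Bit-level reproducibility is promised per platform only (FFT and BLAS
  kernels differ across builds).
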