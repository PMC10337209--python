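# Methods

## Problem and model

In motor-imagery (MI) brain-computer interfaces the class information is
carried by event-related desynchronization/synchronization (ERD/ERS):
task-locked changes of band-limited oscillatory power in sensorimotor
EEG. The informative frequency band differs between subjects, which
hurts multisubject (calibration-free) decoders trained on pooled data
with a single broadband input.

The framework implemented here decomposes each trial with an ordered
bank of N bandpass filters F_1..F_N, trains one compact CNN M_n per band
on the band-filtered (then standardized) trials with cross-entropy loss,
and fuses the member outputs at test time by an unweighted probability
sum:

    Ê_n = F_n(E),    O_n = M_n(Ê_n),    L = argmax_c Σ_n O_n[c]

Four bank schemes are provided: *fixed* low-cut (nested bands 0–8,
0–12, …, 0–36 Hz), *sliding* (constant width translated upward),
*nonoverlapping* (contiguous 4 Hz tiles, the classical FBCSP-style
decomposition) and *broadband* (a single band; the no-bank baseline).
The fixed scheme gives every member a wide, information-rich passband
while still forcing different members to emphasize different bands —
narrow 4 Hz bands starve a CNN of discriminative signal and invite
overfitting, which is why the nonoverlapping bank underperforms.

Ties in the argmax resolve to the lowest class index (measure-zero in
practice; pinned for reproducibility). Argmax-of-sum equals
argmax-of-mean, so the fusion is invariant to member count rescaling; a
weighted sum is available behind a non-default option but is not used
anywhere.

## Filtering

Bandpass filtering is a 4th-order Butterworth applied forward and
backward (`sosfiltfilt`), i.e. zero-phase with 8th-order magnitude
response. Trials are reflect-padded by 1 s before filtering and cropped
after, because forward–backward IIR transients are material on 4–4.5 s
trials. A 0 Hz low edge is realized as a pure low-pass (a 0 Hz bandpass
edge is ill-posed). Bands are validated against Nyquist at application
time. Band construction treats frequencies as exact up to a 1e-9
relative divisibility tolerance.

## Standardization

Channelwise exponential running standardization with smoothing factor
alpha = 1e-3 and variance floor eps = 1e-4 (the configuration standard
in CNN EEG-decoding toolboxes):

    m_t = (1−α) m_{t−1} + α x_t      (m_0 = x_0)
    v_t = (1−α) v_{t−1} + α (x_t − m_t)²   (v_0 = 0)
    y_t = (x_t − m_t) / max(√v_t, eps)

Initialization m_0 = x_0, v_0 = 0 avoids an arbitrary warm-up constant;
the first output sample is exactly 0. State resets at each trial
boundary (trials are stored independently). Standardization is applied
*after* bandpass filtering, and the identical code path
(`band_preprocess`) is used at training and prediction time, so
train/serve skew is impossible by construction. Note a limiting
behavior: as α → 1 both the residual and √v shrink proportionally, so
outputs saturate near ±1 rather than vanishing.

## Backbones

Implemented in a small numpy network engine with hand-written
forward/backward passes (gradients verified against central
differences to ~1e-10) and an Adam optimizer. Single precision is the
working dtype; runs are bit-reproducible for a fixed seed because all
randomness (initialization, dropout, batch order) derives from
`numpy.random.default_rng(seed)`.

* **shallow** — temporal convolution (kernel 25 samples at 250 Hz, 40
  filters), spatial convolution spanning all channels (40 filters),
  batch norm, squaring, average pooling (75, stride 15), log, dropout
  0.5, dense softmax. The square→pool→log chain makes the network a
  trainable log-bandpower feature extractor.
* **eegnet** — temporal convolution (kernel 64, F1 = 8), depthwise
  spatial convolution (D = 2), separable convolution (depthwise kernel
  16 + pointwise F2 = 16), each block with batch norm / ELU / average
  pooling / dropout, dense softmax. Convolutions are "valid" (no
  padding); the depthwise max-norm constraint of the original is
  omitted.
* **deep** — temporal+spatial block followed by up to three
  conv/max-pool blocks with doubling widths (25/50/100/200), ELU,
  dropout; blocks that no longer fit the time axis are skipped, so the
  architecture degrades gracefully on short trials.

All backbones accept arbitrary (channels, samples) input and compute
the dense-layer size from the shape. The registry accepts third-party
builders satisfying the same contract. Attention-based architectures
are out of scope.

## Training protocol

One model per band, trained independently with Adam (lr 1e-3 default,
batch 64 default) and cross-entropy for a fixed number of epochs — no
early stopping. Band n uses seed `seed + n` for initialization and
batching, so per-band results do not depend on which other bands are
trained (verified by a band-independence test). When a test set is
supplied, accuracy/macro-F1/macro-AUC are recorded every epoch per band
and for the fused ensemble (from the stored per-band probability
traces).

## Evaluation

Metrics are summarized over the *final window* of evaluated epochs:
window means damp epoch-to-epoch fluctuation, and the *population*
variance (ddof = 0) of window accuracy serves as a convergence/stability
measure (reported in human-readable output in the conventional 1e-5
scaling, stored unscaled). F1 and AUC use macro (unweighted
one-vs-rest) averaging — classes are balanced by construction here, and
macro is the conventional default; AUC ties use midranks, and a class
absent from the truth is excluded from the macro AUC with a warning.
Paired accuracy comparisons use a one-sided Student's t test,
t = mean(d)/(sd(d)/√n) with the sample (n−1) standard deviation and the
upper-tail p from t_{n−1}; all-equal differences raise a degenerate-case
error rather than fabricating a p-value. Its type-I error calibration is
checked by simulation. The default pairing unit is per-epoch accuracies
of a matched run pair within the evaluation window.

## Synthetic data

The generator reproduces the statistical structure the method exploits,
not the biophysics. Per subject: a smooth random channel-mixing matrix
(identity plus smoothed Gaussian noise, shared within subject) mixes
source-space 1/f^k background noise (k = 1 by default, spectrum
flattened below 1 Hz); one narrowband rhythm per class —
amplitude-modulated bandpass-filtered noise, not a pure sinusoid, to
avoid trivially separable phase artifacts — is projected through a
smooth spatial pattern peaking on a class-specific channel group. In a
trial of class c, rhythm c's envelope drops by a factor √(1−erd_depth)
after the cue (200 ms raised-cosine transition), an ERD-style power
decrease of `erd_depth`; the other rhythms stay at baseline. The rhythm
mixture is scaled so its channel-level RMS is `snr` times the
background's.

Defaults (the study conditions of every test): 2 subjects with band
centers 10 and 24 Hz, 4 classes, 22 channels, 250 Hz, 4.5 s trials with
the cue at 0.5 s, 25 train + 15 test trials per class per subject, band
width 4 Hz, erd_depth 0.75, snr 1.0. A bandpower-LDA oracle confirms
that discriminability is real and band-localized: on the default
dataset its accuracy profile across 4 Hz bands peaks at 8–12 Hz and
20–28 Hz — exactly the configured subject bands — and a pooled
all-band LDA reaches ≈0.54 against 0.25 chance.

What the generator does **not** emulate: volume-conduction head models,
artifacts (EMG/EOG), inter-session nonstationarity, 50/60 Hz line
noise, heavy-tailed amplitude distributions. Passing tests therefore
show that the pipeline recovers band-localized, subject-varying ERD
structure from realistic noise — not that it matches any particular
real-data accuracy level.

## Desk-scale recovery experiment

`ofbcnn.experiments` compares the fixed bank (0–8 … 0–36 Hz, 8 members),
the nonoverlapping bank (0–4 … 32–36 Hz, 9 members) and the broadband
baseline (0–36 Hz) under identical budgets on the default simulation.
Problem sizes were chosen so the whole comparison runs in minutes on
one CPU: trials are decimated 250 → 125 Hz after generation
(anti-aliased integer-factor decimation; all bands end ≤ 36 Hz, well
below the 62.5 Hz Nyquist), the shallow backbone is narrowed to 8
temporal + 8 spatial filters with kernel/pooling rescaled to 125 Hz
(13 / 38 / stride 8) and dropout 0.25, and training runs 12 epochs with
Adam at lr 3e-3, batch 32. The summary window is the final 20% of
epochs (minimum 3). Five simulation seeds are run; the expected pattern
is the ordering fixed ≥ broadband > nonoverlapping, with the fixed
ensemble far above the 0.25 chance level.

## Numerical choices and edge cases

* Probability rows are renormalized in float64 after the float32
  forward pass; simplex deviations are < 1e-6.
* `SafeLog` clips at 1e-6 before the logarithm.
* Filter design is cached per (band, fs).
* The running-variance recursion is clipped at 0 to absorb float
  round-off before the square root.
* Degenerate banks (single band) are first-class: the broadband scheme
  *is* the N = 1 ensemble, and the framework provably reduces to the
  plain backbone there.

## Known limitations

* CPU-only, minutes-scale training; the full-size shallow/eegnet/deep
  configurations train but are not fast.
* No GPU, no learned fusion weights, no per-subject band selection, no
  transfer learning.
* The EDF ingest hook for real recordings is not provided; the on-disk
  container (float32 array + JSON sidecar) is the supported input.
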