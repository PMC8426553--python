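# Methods

This note records what `attnspeech` computes, the assumptions behind each
stage, and the choices made where the design was genuinely open.

## Problem setting

Binary classification of speech segments (depression vs. healthy
control) from frame-level acoustic descriptors, with variable-length
segments of roughly 3–20 s. Clinical corpora of this kind (clinical
interviews, reading tasks) are access-restricted, so the package ships a
synthetic-data module that reproduces the *structure* of the problem —
two classes, variable lengths, a time-localized discriminative region —
with known ground truth, making every stage testable.

## Feature extraction

All descriptors are computed per 25 ms frame at a 10 ms hop (Hamming
taper for spectral analysis, rectangular frames for correlation-based
pitch measures). Framing is configurable; the defaults follow the
ComParE/openSMILE low-level-descriptor convention. The full schema is
77 columns, zero-padded to 80 so the feature width divides evenly for
1, 2, 4 or 8 attention heads.

* **F0** — normalized autocorrelation, search range 55–500 Hz, voicing
  threshold 0.45 on the peak height. All integer multiples of the true
  period produce near-equal autocorrelation peaks, so the tracker picks
  the *shortest* lag whose local maximum lies within 0.08 of the global
  maximum; the peak is parabolic-interpolated for sub-sample lag
  resolution. Silent frames (RMS < 1e-6) are unvoiced; unvoiced frames
  carry F0 = 0, never NaN.
* **Jitter / shimmer** — cycle-level statistics. One amplitude peak per
  pitch period is located by walking each voiced run at the local
  expected period (search window 0.7–1.3 periods) with parabolic
  refinement of both position and amplitude; jitter is
  mean |T_k − T_{k+1}| / mean T and shimmer the analogue on peak
  amplitudes, over a 100 ms window centred on each frame, requiring at
  least three valid cycles (else 0). Sub-sample peak positions matter:
  a 2% period perturbation at 220 Hz is ~1.5 samples per cycle at
  16 kHz. Frame-level F0 differences alone cannot resolve cycle-to-cycle
  perturbation — the 25 ms frame averages ~5 cycles — which is why these
  two extractors work from the waveform's cycle marks rather than from
  the F0 track.
* **Spectral** — MFCC as the first 13 orthonormal DCT-II coefficients of
  log Mel-band energies (26 triangular HTK-scale filters, FFT size =
  next power of two above the frame length); Δ-features by ±2-frame
  regression with edge replication (so a constant track has zero delta
  everywhere); loudness as the sum of Mel-band energies compressed with
  a 0.3 power law; LPC(8) by the autocorrelation method via a Toeplitz
  solve, with zero-coefficient fallback (and a logged warning) on
  degenerate or unstable frames; LSP frequencies from the roots of the
  sum/difference polynomials, falling back to the flat-spectrum grid
  when root-finding degenerates, so the strictly-ascending invariant
  holds unconditionally.
* **Harmonicity** — the harmonic fraction r of frame power is the
  normalized autocorrelation at the pitch-period lag
  (parabolic-interpolated); harmonicERMS = rms·√r,
  noiseERMS = rms·√(1−r), HNR = 10·log10(r/(1−r)) clipped to ±40 dB.
  Unvoiced frames are treated as all-noise (HNR at the lower clip);
  their voicing probability is still reported as the best candidate
  peak. The clip keeps pure tones and silence finite.

Per-feature z-normalization is a pipeline step (train-set statistics
only, std floor 1e-8), not part of extraction, and is flag-controlled.

## Model

Two stacked forget-gate LSTM layers (standard cell: input/forget/cell/
output gates, forget bias 1.0, Glorot input weights, orthogonal
recurrent blocks) encode the padded batch; hidden and cell states are
zeroed at padded steps, so padding cannot leak into any valid output,
and `o_last` is read at each sequence's last *valid* index. Attention
variants:

* `none` — classifier on `o_last` (plain LSTM baseline);
* `single` — `s = softmax(o_last (o_all W_t)^H)`, context `s·o_all`;
* `multi` — per-head affine projections of `o_all` (keys, values) and
  `o_last` (query) into `Z/n`-wide subspaces, masked softmax over valid
  steps, per-head contexts concatenated.

Attention logits are **unscaled** by default; the `1/√(Z/n)` scaling of
the transformer convention is available behind `scale_scores` but off,
matching the unscaled form of the time-dimension attention equations.
The classifier head is 128 → 12 → 2 with ReLU between layers and a
softmax output; the `[128, 12]` hidden sizes are read as two hidden
layers ahead of the 2-way output. With a single head and identity
projections the multi-head path reduces exactly to the single-head
equations with `W_t = I`; this identity is asserted in the tests.

Everything — forward pass, cross-entropy loss, backpropagation through
time, Adam — is implemented in NumPy with hand-derived gradients,
checked against central finite differences for all three attention
variants. Gradient norms are clipped at 5; a non-finite loss aborts
training with a diagnostic rather than continuing silently.

## Training pipeline

Segments outside the inclusive [3 s, 20 s] duration band are discarded
with a logged reason (the band boundaries are kept, reading "<3 s … or
larger than 20 s discarded" as a closed interval). Splits are seeded
and stratified by class; when speaker ids are present the split is
grouped by speaker (no speaker on both sides) with a segment-level
escape hatch, since speaker leakage inflates segment-level scores. A
stratified 10% validation set is carved from the train split for early
stopping on validation UAR; the best-validation checkpoint is restored
at the end, with ties resolved in favour of the later epoch (among
equally valid models, prefer the one trained longer — on easily
separable data validation UAR saturates early while attention keeps
sharpening). Batches are bucketed by length before padding to limit
padding waste. Normalization statistics and early stopping depend only
on train/validation data; the test suite asserts that retraining with
different test labels yields bit-identical parameters.

## Synthetic data

`gen_sequences` emits class-0 sequences as stationary Gaussian AR(1)
frames (lag-1 coefficient 0.6, unit marginal std, independent feature
columns) and class-1 sequences as the same plus a mean shift of
`effect_size`·std on the first quarter of the feature columns, only
inside a salient window given as a fraction-of-length interval. Lengths
are uniform over the configured range. The reference study conditions
are 200 sequences per class, 16 features, lengths 30–100 frames,
effect size 3, salient window (0.4, 0.6) — the central 20%. A
sliding-window t-statistic over time bins recovers the window location
without any model, serving as the oracle for the attention-salience
test.

`gen_waveform` synthesizes a glottal-like pulse train: Hann-windowed
harmonic bursts (8 harmonics, 1/h amplitude roll-off) placed at
continuous sub-sample times, with per-period Gaussian perturbations of
period length (jitter) and amplitude (shimmer) and white noise scaled
to an exact target SNR. Sub-sample placement means the injected
perturbations are not quantized by the sampling grid. Perturbations are
Gaussian with std equal to the requested fraction; the local
jitter/shimmer statistic of such a sequence has expectation
(2/√π) ≈ 1.13 × that fraction, which sits inside the ±30% recovery
tolerance the DSP tests use.

What the generators deliberately do not emulate: formant structure,
coarticulation, prosodic phrasing, channel/recording variability, and
any correlation between features. Passing tests therefore demonstrate
the pipeline's correctness and the attention mechanism's ability to
localize a time-confined signal — not clinical validity on real speech.

## Scaled study conditions

The reference experiments (`attnspeech.study`) use sequence lengths of
30–100 frames, 16 features, LSTM hidden sizes (32, 16), 4 heads, Adam
at 1e-3 and a 40-epoch budget with patience equal to the budget. The
corpus-scale defaults — hidden sizes (512, 256), learning rate 1e-4,
batch 64 — remain the `ModelConfig` defaults; they are sized for
hour-scale corpora with ~80-dimensional features and thousands of
segments, which is two orders of magnitude more data than the synthetic
study, where a model of that size would be severely over-parameterized.
The null control (effect size 0, shuffled labels) uses the identical
configuration and lands at chance-level UAR.

## Numerical choices and degenerate inputs

* Masked softmax excludes invalid positions from normalization (the
  −∞ convention); every sequence has length ≥ 1 by construction, so a
  fully masked row cannot occur.
* Silence: all features finite; HNR at the lower clip, voicing 0.
* Autocorrelation-method LPC is stable up to round-off; instability or
  non-finite coefficients fall back to zeros with a warning.
* WAV input: mono only (multi-channel is rejected, not downmixed,
  because channel mixing changes amplitude-based descriptors);
  polyphase resampling to 16 kHz on rate mismatch.
* All seeds are explicit; a run is reproducible bit for bit.

## Known limitations

* Jitter and shimmer need reliable cycle marks; on heavily aperiodic or
  low-SNR voiced speech the marker can skip cycles, which deflates the
  local statistics toward 0 (never NaN).
* The harmonicity estimate uses a single autocorrelation lag per frame;
  clean periodic signals measure ~20 dB rather than +∞ because frame
  boundaries truncate pulses (pure sines, unaffected by truncation,
  reach the +40 dB clip).
* The attention-mass margin over the uniform baseline is modest on the
  synthetic task because the LSTM state itself already separates the
  classes; attention sharpens with continued training after accuracy
  saturates, which is why the study trains past convergence.
* Training is single-threaded NumPy: appropriate for the shipped study
  sizes, not for corpus-scale replication.
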