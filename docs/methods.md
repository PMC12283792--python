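# Methods

## Problem and pipeline

`ecogflex` decodes continuous finger flexion from multichannel
electrocorticography (ECoG). The inputs are a cortical potential matrix
(channels × time, 1 kHz) and a dataglove trace (5 fingers × time, 25 Hz);
the output is a predicted flexion trajectory for each finger, scored by the
Pearson correlation *r* against the recorded trace.

The pipeline, in execution order:

1. **Normalization.** Each channel is z-scored (subtract mean, divide by
   SD), then the median of the standardized trace is removed, so every
   channel has median exactly 0. The sentence order of the source recipe is
   ambiguous about whether the median step precedes the z-score; we follow
   z-score → median removal.
2. **Filtering.** Zero-phase 4th-order Butterworth band-pass 40–300 Hz,
   then a zero-phase notch comb (quality factor 30) at 60 Hz and its
   harmonics below Nyquist. Forward–backward filtering keeps the neural
   signal aligned with the glove trace (no group delay).
3. **Morlet spectrogram.** Each channel is convolved ("same" length) with
   complex Morlet wavelets ψ_f(t) = A·exp(−t²/2σ²)·exp(2πift),
   σ(f) = n_cycles/(2πf), on a log-uniform grid of F frequencies spanning
   40–300 Hz. The amplitude |W| forms a 3-D array
   (channel, frequency, time). A is fixed by unit L2 norm of the
   discretized wavelet (support truncated at ±5σ), which makes amplitudes
   comparable across frequencies; with that convention the response of the
   bank to a unit tone at f₀ is proportional to
   √σ(f)·exp(−(2πσ(f))²(f−f₀)²/2), the identity the tests check.
   F and n_cycles are free parameters of the recipe; defaults F = 40 and
   n_cycles = 7 are standard practice for high-gamma work. Amplitude |W| is
   the default output; |W|² is available via a `power` switch.
4. **Downsampling.** The spectrogram time axis is reduced 1 kHz → 100 Hz by
   block means over consecutive 10-sample blocks (anti-aliasing the
   envelope), and the glove trace is upsampled 25 → 100 Hz by cubic
   splines; the two axes are truncated to a common length.
5. **Windowing.** Overlapping windows of length l = 256 samples with stride
   s produce N = ⌊(T−l)/s⌋ + 1 samples of shape (c·f, l) with aligned
   (5, l) targets. The (channel, frequency) axes are flattened
   channel-major; the order is recorded in the dataset metadata. l must be
   divisible by 2⁵ because the encoder pools five times.
6. **Model.** A 1-D convolutional encoder–decoder:
   feature-reduction conv (c·f → 64, kernel 3); five encoder stages
   (widths 64, 128, 256, 512, 512 by default; kernels 7, 7, 5, 5, 5;
   dilations 1, 2, 3, 1, 2) each conv → layer norm → GELU → dropout 0.1 →
   max-pool 2, saving the pooled output for the skip path; five decoder
   stages, each concatenating the length-matched skip (doubling the feature
   axis) → conv block → ×2 upsampling by a learnable transposed conv
   (kernel 2, stride 2); a 1×1 conv head to 5 outputs. "Same" padding
   everywhere, so only pooling and upsampling change length and the output
   time axis equals the input's. Because skips store the *pooled* copies,
   lengths pair off such that the first decoder stage's skip is the
   bottleneck itself — a degenerate but structurally consistent
   concatenation. Decoder widths and kernels mirror the encoder in reverse;
   they are not specified by the source recipe.
7. **Loss and optimization.** L = MSE + λ·(1 − mean cosine similarity),
   cosine computed per (sample, finger) along the window's time axis;
   λ = 1 by default (the neutral reading of "combines" the two terms).
   Adam, learning rate 8.42e-5, L2 weight decay 1e-6. Training is fully
   seeded (initialization, batch order, dropout) and bitwise repeatable at
   fixed thread settings.
8. **Evaluation.** Held-out series are decoded window-by-window and
   stitched — non-overlapping tiling (stride = l, the default) or
   per-timepoint averaging of overlapping windows — then per-finger Pearson
   r is computed over the full stitched series. Fingers with zero-variance
   truth are reported NaN and excluded from the mean.

The network and its training are implemented directly on NumPy arrays with
hand-written backpropagation (convolution and transposed convolution via
per-tap matrix products, layer norm, exact-erf GELU, inverted dropout,
argmax-routed pooling); gradients are verified against central finite
differences in the test suite.

## Ablation axes

The harness can swap (a) the wavelet family — Morlet vs. Haar / Daubechies
(db4) / Symlet (sym4); (b) dilations on/off (all 1); (c) transposed-conv
vs. fixed linear-interpolation upsampling; (d) the window stride. For the
compactly supported families no continuous-transform construction is given
by the source recipe; we rescale the discrete mother wavelet (PyWavelets
`wavefun`) so its central frequency lands on each grid frequency,
L2-normalize, convolve, and rectify. This keeps the (c, f, t) contract so
the downstream model is unchanged.

## Synthetic fixture

Real competition recordings cannot be redistributed, so the test bed is a
generator that emulates their structure: a 2 s cue / 2 s rest paradigm
cycling through the five fingers, the cued finger performing 3–5
raised-cosine flexion bumps per cue (amplitudes 0.7–1.0, values clipped to
[0, 1], plus a small smooth baseline drift). Each finger owns a disjoint
high-gamma sub-band (70–88, 90–108, 110–128, 130–148, 150–168 Hz) and two
of the 16 channels; those channels carry band-limited Gaussian carrier
noise amplitude-modulated by the finger's trajectory. All channels receive
pink (1/f-amplitude) noise at unit scale, a unit-amplitude 60 Hz sinusoid
(random phase per channel) and a small shared Gaussian term (SD 0.1). The
default recording is 120 s, split 2:1 chronologically into train/test.

What the fixture does *not* emulate: volume conduction and electrode
geometry, non-stationary noise, cross-finger coupling, measurement
artifacts, or any biophysics. Passing the end-to-end checks therefore
demonstrates that the pipeline's statistical machinery recovers a planted
band-power code, not that it attains any particular accuracy on real
cortical data.

## Desk-scale problem sizes

End-to-end checks run on one CPU, so the heavy runs use a width-capped
model (64, 64, 128, 128, 128, 128), training stride 8, batch 16 and 8
epochs on the 120 s fixture (~440 Adam steps, a few minutes per run). At
these sizes the full model reaches mean test r ≈ 0.88 on the fixture;
the published-width model and dense stride-1 training are available through
the same configuration objects. The optimization sanity check uses a
smaller fixture (8 channels, 14 s, 8 frequencies) and 200 steps.

## Numerical choices and edge cases

- Zero-variance channels fail normalization with the channel index named;
  callers drop them explicitly.
- Notch harmonics at or above Nyquist are skipped with a warning.
- A wavelet whose truncated support exceeds the signal length raises,
  advising fewer cycles or a longer signal.
- Cosine similarity of a zero-norm segment is defined as 0 (with a
  warning) so the loss stays finite; Pearson r of a zero-variance series
  is an error, surfaced as NaN-and-excluded at the report level.
- Block-mean downsampling drops a trailing partial block
  (output length ⌊t/10⌋).
- Max-pool ties resolve to the first maximum; `tile` stitching requires an
  exact partition and raises on gaps.
- Parameters are float32; He-style fan-in initialization with a recorded
  seed; the per-layer parameter ledger is reported by `model-summary`
  rather than asserted against any external count.

## Known limitations

- Training on CPU in NumPy is orders of magnitude slower than a GPU
  implementation; published-scale runs (stride 1, widths to 512, tens of
  epochs) are possible but slow.
- The first decoder stage's self-concatenated skip adds parameters without
  new information; alternatives (pre-pool skips) would change the length
  bookkeeping and are not explored.
- The alternative-wavelet construction is one of several defensible
  readings for discrete families.
- Early stopping monitors mean per-window validation r, which is far
  noisier than full-series r; with short schedules it rarely triggers.
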