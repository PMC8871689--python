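# Methods

`nirsclean` implements a hybrid detection-and-correction procedure for
motion artifacts in fNIRS hemodynamic time series (Δ[HbO2]/Δ[Hb] in
µmol/L, or optical density converted first). This note documents the model,
its parameters, the numerical choices made where the design was open, what
the synthetic benchmark does and does not emulate, and the known
limitations.

## Signal model and artifact taxonomy

Resting hemodynamics are treated as a band-limited stochastic process in
0.003–0.04 Hz riding on a small broadband measurement-noise floor. Motion
contaminates the record in three ways:

* **severe oscillations** — large, fast (≈1–3 Hz) bursts from rapid head
  movement;
* **slight oscillations** — smaller, slower (≈0.06–0.12 Hz) excursions
  from gentle movement;
* **baseline shifts (BS)** — sustained level changes from a change of head
  (optode) position, co-occurring with a slow oscillation.

## Detection

1. **Moving SD.** A two-sided moving population SD `t(n)` over a window of
   `W = 2k+1` samples, `k = round(3·fs)` (6.1 s at 10 Hz). The first and
   last `k` samples replicate the nearest interior value; records shorter
   than `W` are rejected.
2. **Dynamic threshold.** `T1, T2, T3` are the maxima of the first
   30/50/70% of the sorted SD series (1-based index `max(1, ⌊qN⌋)`). The
   SD series is clipped into `[T1, T3]`, filtered with a zero-phase
   order-3 Butterworth high-pass at 0.02 Hz (a low-pass variant is
   exposed as `RunConfig.threshold_filter` for users who prefer a
   slowly-adapting threshold), floored at `T2`, and offset by
   `3(T3−T1)`, giving `A(n)`.
3. **Classification.** `t > 2A` → suspected severe; `A < t ≤ 2A` → slight
   (boundary inclusive); otherwise none. Every stage is positively
   homogeneous, so labels are invariant under amplitude rescaling; the
   moving SD is translation-invariant, so oscillation labels ignore DC
   offset.
4. **Severe confirmation.** Suspected runs (merged across gaps shorter
   than 1 s) are split at signal troughs so each piece holds one peak
   (trough plateaus resolve to their first sample); a piece whose range
   is ≥ 6× the SD of the whole suspected region is confirmed severe, the
   rest demote to slight.
5. **Baseline shifts.** An oscillation run flanked on both sides by quiet
   runs of at least 5 s (`quiet_seconds`) is marked as a BS iff the means
   of the two entire flanking quiet runs differ by more than half the
   run's range.

An acceleration strategy is provided for comparison: the RMS of the three
axes `sqrt((ax²+ay²+az²)/3)` replaces the signal, its moving SD `d(n)` is
compared against `B(n) = 2·clip(d, T/2, T)` with `T` the 30% quantile, and
the same classification applies; confirmation and BS analysis still run on
the fNIRS trace.

## Correction

Stages run in a fixed order, each stage touching only what it owns:

1. **Severe correction** (`p_severe = 0.99`): within each severe segment a
   cubic smoothing spline minimizing `p·Σ(x−f)² + (1−p)·∫(f″)²` (natural
   end conditions, unit weights, sample-index grid) is subtracted,
   flattening the burst. Samples outside severe segments are untouched.
2. **BS removal** (`p = 1/fs³`): within each BS segment the heavily
   smoothed spline trend is subtracted and the fitted value at the
   segment's first sample added back, so the segment starts where it did
   and ends at its pre-shift level. The post-segment record keeps the
   shifted level; that residual offset is deliberately left to the final
   high-pass.
3. **Dual-threshold wavelet denoising**: the signal is decomposed
   (`db4` default, symmetric boundary handling) to the deepest level whose
   approximation band still contains the hemodynamic band
   (level 6 at 10 Hz for a 0.04 Hz upper edge — deeper would push the
   band itself into detail levels, where the global σ̂ would flag it as
   outliers and the denoiser would erase genuine signal). The coefficient
   SD σ̂ is the |value| at sorted 1-based index `round(0.1587·L)` over all
   detail levels pooled (the 15.87th percentile of a zero-mean Gaussian is
   −σ, so this is a robust SD estimate that ignores heavy artifact tails).
   With `u = Φ⁻¹(1−α/2)` (α = 0.05 by default; performance is insensitive
   across 0.005–0.1), the processing threshold is `w2 = u·σ̂` and the
   detecting threshold `w1 = 1.3·w2`. Any coefficient with |w| > w1
   triggers zeroing of the whole contiguous run of same-level neighbors
   with |w| > w2; isolated coefficients between the thresholds are kept.
   The whole procedure is averaged over K = 16 unit-sample circular
   shifts (cycle spinning) to suppress shift-variant ringing. The record
   is reflect-padded before shifting: without padding, a record whose two
   ends sit at different levels (the usual situation after BS removal)
   acquires a fabricated jump at the wrap point, and zeroing that jump's
   coefficients corrupts both record ends (≈7 dB in-band loss measured on
   the benchmark).
4. **Final high-pass**: zero-phase order-3 Butterworth at 0.003 Hz
   removes the DC and the residual inter-segment offsets left by BS
   removal.

All intermediate stages (`x1`, `x2`, `x3`, `y`) are kept on the returned
`PipelineResult` for inspection.

## ΔOD conversion

The modified Beer–Lambert law maps dual-wavelength optical-density changes
to concentration changes: `Δ[HbO2] = (a1·ΔOD_λ1 + a2·ΔOD_λ2)/L`,
`Δ[Hb] = (b1·ΔOD_λ1 + b2·ΔOD_λ2)/L`. The shipped default coefficients for
735/850 nm are (330.1717, −131.3958, −127.6967, 184.5598). For other
wavelength pairs, `coefficients_from_extinction` inverts the 2×2 forward
system `ΔOD_λi = DPF_λi·(ε_HbO2,λi·Δ[HbO2] + ε_Hb,λi·Δ[Hb])·L` directly —
a linear solve rather than transcribed closed-form fractions, which keeps
the conversion exactly inverse-consistent with the forward model.

## Synthetic benchmark

No public dataset accompanies the method, so evaluation uses a parametric
generator:

* **clean signal** — white Gaussian noise FFT-masked to 0.003–0.04 Hz,
  renormalized to zero mean and unit SD, plus a 0.05-SD white
  measurement-noise floor (real recordings carry instrument/shot noise,
  and the σ̂ order statistic presumes such a floor — on a strictly
  band-limited signal σ̂ → 0 and the denoiser would zero everything).
  Optional cardiac (~1 Hz) and respiratory (~0.3 Hz) sinusoids are off by
  default.
* **artifacts** (amplitudes in multiples of the clean SD): 4 spikes of
  10 SD (2 s, Gaussian-windowed 1–3 Hz carrier peaking at the envelope
  maximum), 3 slow oscillations of 2 SD (20 s, Hann-windowed
  0.06–0.12 Hz), and 2 BS steps of 8 SD (1 s smoothstep rise, sustained
  to the end of the record), hosted on slow-oscillation events. Events
  keep ≥ 60 s gaps and 10 s edge margins. The BS height must exceed the
  co-located oscillation swing for the detection rule
  `|Δmean| > range/2` to be satisfiable at all; 8 SD is large but
  typical of optode-displacement shifts.
* **benchmark** — 20 independent segments of 600 s at 10 Hz (a
  desk-scale version of the reference design of 60 segments of 1.5 h),
  with per-segment seeds derived from one master seed.

What passing tests on this generator do **not** show: performance on real
optode-coupling noise (non-Gaussian, non-stationary), on superficial
physiological oscillations (Mayer waves), or on multi-channel data; the
artifact shapes are stylized stand-ins chosen for reproducibility.

## Numerical choices

* Smoothing splines are solved by `scipy.interpolate.make_smoothing_spline`
  with `lam = (1−p)/p`; `p = 1` and `p = 0` short-circuit to interpolation
  and the least-squares line; 4-point segments solve the tiny Reinsch
  system densely (scipy needs ≥ 5 points).
* Quantile convention: "maximum of the first q%" = sorted value at
  1-based index `max(1, ⌊qN⌋)`.
* Zero-phase filters are `scipy.signal.sosfiltfilt` with order-3
  Butterworth sections; pad length is capped at `n−1` for short records.
* SNR of a zero-residual signal is reported as the `inf` sentinel, never
  silently dropped.
* Segments shorter than 4 samples: severe correction subtracts the raw
  segment (the interpolation limit); BS removal skips them.
* Files are written with 17 significant digits and read back with
  round-trip float parsing, so signal round trips are bit-exact.

## Known limitations

* **Clean-signal false baseline shifts.** On artifact-free records the BS
  rule occasionally fires where a cluster of slight-oscillation labels
  sits inside a strong slow-drift epoch: continuous drift makes the
  flanking means differ by more than half the (short) run's range. The
  subsequent spline correction then removes a few seconds of genuine
  trend. Over 40 artifact-free 600 s records the output-to-input
  correlation (after 0.003 Hz high-pass) averaged 0.994 with a worst case
  of 0.95; about one record in six dips below 0.99. This is a property of
  the detection rule itself, not of the correction stages: the wavelet and
  high-pass stages alone stay above 0.995 on every record tested.
* **Residual post-BS offsets.** BS removal corrects only within the
  marked segment; the level change after the segment is handled by the
  0.003 Hz high-pass, which leaves a transient around the segment end on
  short records.
* **dmey reconstruction.** PyWavelets ships the discrete Meyer wavelet as
  a truncated FIR whose filter norm is 1.0022; decomposition +
  reconstruction is only accurate to ~1e-2, so the perfect-reconstruction
  guarantee holds for the other 15 supported mother wavelets but not for
  `dmey`.
* Uniform sampling is assumed throughout; gaps or irregular timestamps
  must be resolved before use.
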