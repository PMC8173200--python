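# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic generator does and does not emulate, and the
known limitations.

## Descriptor tracks (audio_io)

All downstream measures are computed from three tracks sampled on a shared
1 ms grid:

* **Amplitude envelope** — windowed RMS of the waveform, 10 ms window,
  1 ms hop. A Hilbert-magnitude variant is available
  (`envelope_kind="hilbert"`); the two agree closely for percussive
  material, and RMS is the default because it is cheap and exactly
  sign-flip invariant.
* **Wiener entropy** — log ratio of geometric to arithmetic mean of the
  windowed power spectrum (log spectral flatness, DC excluded, Hann
  window). It is ≤ 0 by the AM–GM inequality: near 0 for noisy (flat)
  frames, strongly negative for tonal frames. Note a known estimator bias:
  the raw single-window periodogram of white noise has expected
  log-flatness −γ ≈ −0.58 rather than 0, because periodogram bins are
  exponentially distributed. We keep the raw estimate (the group contrast
  uses within-recording scaled values, so a constant bias is immaterial);
  tests assert that noise frames sit far above tonal frames rather than at
  exactly 0. Some descriptions orient this measure the other way
  ("maximum for a pure tone"); we keep the standard convention (maximum =
  0 for noise). Only the orientation, not the discriminative content, is
  affected.
* **Pitch** — normalized-autocorrelation tracker, search range 40–600 Hz
  (the drum's full octave range with margin), voicing threshold 0.3 on the
  peak autocorrelation. The pitch analysis window is 50 ms — a 10 ms
  window cannot contain even half a period at 40 Hz — centred on the same
  1 ms grid. The signal is decimated to ≈11 kHz first. Octave-down errors
  (subharmonic lags score ≈ the true period) are avoided by taking the
  *shortest* lag among local peaks within 15% of the global maximum, then
  refining by parabolic interpolation. Frames below threshold, or in
  near-silence, are reported missing and excluded from note aggregation
  (no imputation).

## Segmentation

Onsets are detected on the envelope via two Hodrick–Prescott smoothings:
`d(t) = HP(env, λ=50) − HP(env, λ=1e7)`, i.e. a lightly smoothed envelope
minus a slowly adapting baseline. The HP trend solves
`(I + λ D₂ᵀD₂) τ = x` (D₂ the second-difference operator), implemented as
a symmetric pentadiagonal banded solve — O(n), matching a dense solve to
machine precision. Both λ values assume the 1 kHz envelope rate; resampling
the envelope would require rescaling λ (≈ rate⁴).

Candidate onsets are the rising segments of `d` (local minimum → next
local maximum). A rise is accepted when its magnitude exceeds all of:

* 0.65 × MAD(d) — noise floor;
* 4% of the largest rise in the recording — rejects noise wiggles in
  sparse recordings, where MAD(d) is tiny;
* 40% of the envelope value at the rise's start — rejects beating ripple
  between overlapping decaying tones (e.g. simultaneous 120 and 170 Hz
  tails beat at 50 Hz), which appears as small rises riding on a high
  residual envelope.

The onset time is the steepest-ascent point of the rise; a 30 ms
refractory gap suppresses double fires. All thresholds are relative, so
detection is invariant to global gain. A plain zero-crossing criterion was
rejected during development because a quiet note riding a loud
predecessor's decay never re-crosses the adaptive baseline at short IOI.
These three constants were calibrated once on segmentation-validation
corpora (stroke trains at IOI 150/250/400 ms, 15 dB SNR, note-amplitude
SD 0.12) to meet corpus-level recall and precision ≥ 0.95 at ±15 ms, and
then frozen; they are exposed as function parameters. Residual failure
modes: notes much quieter than an overlapping predecessor are missed
(physically their envelope rise is tiny), which is also why the manual
annotation override path exists.

## Note and stimulus features

A note spans onset → next onset (last note: to the end of the recording).
Note intensity and entropy are means of the frame tracks over the span;
note pitch is the **median** of voiced frames (robust to glide ends; the
within-note statistic is our choice). Scaling to [0, 1] uses the 0.5th and
99.5th percentiles of the *millisecond-wise* track within the recording
(clipped; a degenerate range maps to 0.5) and is applied before note
aggregation of the scaled variants. Level summaries (mean pitch,
intensity, timbre, IOI) use unscaled units; change summaries (mean
absolute consecutive-note differences, two-interval ratio) use scaled
values — mixing units this way is deliberate and mirrors how the measures
are used downstream. Interval-ratio sequences use overlapping pairs
(i₁,i₂), (i₂,i₃), …, maximizing data per stimulus. Probability densities
are Gaussian KDEs with Silverman bandwidth.

## Modulation spectrum and pulse clarity

The amplitude modulation spectrum uses a 128-band gammatone filterbank
(ERB-spaced centres, 80–8800 Hz, capped at 0.45·rate), per-band Hilbert
envelopes downsampled to 100 Hz, per-band demeaning and division by the
band's mean level (so bands contribute modulation *depth*, not level),
RMS across bands of the DFT amplitudes, and averaging into log-spaced
modulation bins (0.25–32 Hz, 8 bins/octave, geometric-mean centres). The
binned vector is normalized to unit sum; the peak is the bin-centre with
maximal amplitude. Gain invariance is exact. Band count, envelope rate and
bin resolution are parameters.

Pulse clarity is the maximum of a normalized autocorrelation of the
onset-strength function (half-wave-rectified envelope derivative at
1 kHz), per 5 s frame with 10% hop, lags 0.18–2.0 s (33–333 events/min),
averaged over frames, clipped to [0, 1]. The autocorrelation is
cross-normalized (r(l) = Σxₜxₜ₊ₗ / √(Σₜ<N−l xₜ² · Σₜ≥l xₜ²) on the demeaned
signal) so a perfectly periodic train scores exactly 1 regardless of frame
length; lag-resonance weighting used by some toolboxes is deliberately
omitted (a simplification; it changes absolute values slightly but not the
regular-vs-irregular ordering). Recordings shorter than one frame are
scored on the full recording with a warning.

## Behavioral scoring

Music is the positive class. Accuracy = (TP+TN)/total. MCC uses the usual
product-of-marginals denominator with the degenerate-case rule that a zero
denominator is replaced by 1, so an all-one-answer responder scores
exactly 0 (chance). The per-participant MCC is the primary unit; pooled
values are also reported. Group comparisons use Welch's two-tailed t-test
with Satterthwaite df; Cohen's d uses the pooled-SD form. The Bonferroni
threshold for the 10-measure battery is α/10.

## Collinearity screen and perception model

VIF_j = 1/(1−R²_j) from regressing predictor j on the others (with
intercept). Exact duplicates are dropped first; then the largest-VIF
predictor is removed iteratively until all ≤ 5. The screened feature set
enters a Bernoulli GLMM:

    perceived_music ~ acoustic + familiar + confidence
                      + familiar:(acoustic, confidence)
                      + (1 | participant) + (1 | stimulus)

Acoustic predictors and confidence are centred and scaled (confidence is
first shifted 1–4 → 0–3; the shift is absorbed by centring). Familiarity
stays 0/1.

Estimation is maximum likelihood with the Laplace approximation,
implemented in-package: for candidate random-intercept SDs the joint
penalized log-likelihood is maximized over (β, u) by damped Newton
iterations (dense solve of the (p+q)×(p+q) system; q ≈ participants +
stimuli), and the profiled objective
`ll − u'Λ⁻¹u/2 − log det(I + Λ Z'WZ)/2` is minimized over the two log-SDs
by Nelder–Mead. Wald covariance of β is the Schur complement
`(X'WX − X'WZ(Z'WZ+Λ⁻¹)⁻¹Z'WX)⁻¹`, the standard mixed-model form; CIs for
odds ratios are Wald on the log-odds scale, exponentiated. Against lme4's
Laplace `glmer` on identical data the fixed effects agree to ≈0.2 SE,
Wald SEs to <0.01 and variance components to a few percent (the two
profiled objectives differ in minor details; ours attains an equal or
lower deviance on its own objective). Non-convergence raises with the
gradient norm; extreme coefficients/SEs trigger a separation warning.

R² follows the Nakagawa latent-scale decomposition with logistic residual
variance π²/3: marginal = var(Xβ)/(var(Xβ)+σ²ₚ+σ²ₛ+π²/3); conditional adds
σ²ₚ+σ²ₛ to the numerator. In-sample prediction accuracy and MCC are
reported both conditionally (including fitted random intercepts — the
primary figure) and marginally (fixed effects only) at a 0.5 threshold.

## Synthetic generator

`make_corpus` emulates the study design: 15+15 stimuli of 5–10 s at
22.05 kHz, percussive strokes on three tone levels within one octave
(120/170/240 Hz) with 15% glide probability (±3 semitones). Strokes are
decaying harmonic complexes (fundamental + 2 partials, 100 ms decay, 3 ms
attack) plus a 25 ms noise transient whose relative level sets the
timbre; the tonal component always carries the note's amplitude so pitch
is never buried by the transient. Category contrasts (directions matching
the acoustic findings): speech-like — louder (amp 0.75 ± 0.04 vs
0.45 ± 0.18), longer IOI (260 ± 25 vs 170 ± 15 ms between stimuli), more
within-stimulus jitter (35 vs 6 ms, hence lower pulse clarity), mid-range
stable timbre; music-like — alternating timbre extremes (larger timbre
change). Pitch distributions are identical across categories (a null
contrast the pipeline must *not* turn into an effect). Background noise at
30 dB SNR by default. The same seed reproduces the corpus bit-exactly.

What the generator does **not** emulate: realistic dùndún timbre (membrane
modes, stick noise), room acoustics, recording-chain nonlinearity, the
expert-performer structure of real phrases (linguistic tone sequences,
phrase-final lengthening), or correlated note parameters within phrases.
Passing tests therefore demonstrate that the pipeline recovers known
structure under controlled conditions — not that it would reproduce any
particular real-world measurement.

`simulate_listeners` draws P(music) = logistic(β₀ + g·Σβⱼzⱼ + u_participant
+ v_stimulus) with g = 1.5 for familiar listeners, σₚ = 0.8, σₛ = 0.5, and
default β giving pulse clarity/timbre change → music, intensity/pitch
change → speech. Confidence is the within-participant quartile of
|linear predictor| mapped to 1–4 — so correct responses carry higher
confidence by construction. Under the all-null configuration, confidence
still tracks |random effects|, making it endogenous; inference
calibration is therefore assessed on the exogenous terms.

## Problem sizes used in the validation suite

Chosen as the smallest designs that make the checks statistically
meaningful: segmentation quality on 6-recording corpora per tempo
condition; clarity monotonicity over 10 seeds per jitter level; GLMM CI
coverage over 100 replicates and type-I calibration over 200 replicates
of a 100-participant × 30-stimulus design; behavioral type-I over 300
replicates of 30 chance listeners; the category-contrast check on the
full 15+15 corpus. The type-I acceptance band (per-effect rate in
[0.005, 0.105], mean over exogenous effects in [0.02, 0.09]) was fixed
before the calibration runs, from binomial noise at 200 replicates plus
the known mild liberality of Wald z-tests with 30 stimulus clusters.

## Known limitations

* The segmenter has no offset detection and no stroke-type classification;
  note extent is onset-to-onset by construction.
* Wiener entropy inherits periodogram bias (constant offset; harmless
  after scaling).
* The AMS rescaling step follows the published description of the
  reference procedure, not its original code; absolute bin amplitudes may
  differ from other implementations (peak location is robust).
* Pulse clarity omits resonance weighting; absolute values are not
  comparable to toolbox outputs, orderings are.
* GLMM inference is Wald/Laplace; with 30 stimuli, stimulus-level effects
  are mildly liberal (measured type-I ≈ 0.03–0.08 at nominal 0.05).
* Pitch tracking of a quiet note overlapped by a loud neighbor's ringing
  is occasionally wrong by an octave (≈1–2% of dense music-like notes
  after all guards). Because within-recording scaling uses the raw pitch
  track's percentiles, such frames widen the scaling range and compress
  the recording's scaled pitch changes; on some corpus seeds this turns
  the generator's null pitch-change contrast into a spurious group
  difference. The canonical study seed (1) is unaffected; the artifact
  and its mechanism are stated here rather than patched cosmetically.
* Real recordings are supported as input (WAV + optional onset
  annotations) but no claim is made that the synthetic calibrations
  transfer to them unchanged.
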