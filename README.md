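# dundun

Acoustic-feature battery and perceptual-classification pipeline for
**talking-drum speech surrogacy** studies.

The Yorùbá dùndún is an hourglass tension drum played both as a musical
instrument and as a speech surrogate: cord pressure modulates its pitch
over a full octave, letting it imitate the three tone levels of spoken
Yorùbá. Given recordings of performances intended as *music-like* or
*speech-like*, and listener judgments of the same stimuli, this package
answers two questions: **which acoustic features separate the two
performance modes**, and **which features (and how much listener
familiarity) predict what people hear**.

## What it computes

For each recording (WAV, any rate; mono or stereo):

* descriptor tracks on a 1 ms grid — RMS amplitude envelope, Wiener
  entropy (log spectral flatness, a timbre measure), and an
  autocorrelation pitch track (40–600 Hz);
* note segmentation from the envelope via the difference of two
  Hodrick–Prescott smoothings (λ = 50 vs λ = 10⁷), with a manual
  annotation override (`stimulus_id, onset_ms` CSV);
* note-level measures (pitch, intensity, timbre, inter-onset interval)
  and consecutive-note measures (absolute differences of 0–1 scaled
  tracks; two-interval ratio i₁/(i₁+i₂), where 0.5 = local isochrony);
* the amplitude modulation spectrum (128-band gammatone filterbank,
  envelope DFTs binned on a log axis, 0.25–32 Hz) and its peak, plus
  autocorrelation pulse clarity in [0, 1];
* Welch t-tests of every measure between stimulus groups with a
  Bonferroni-corrected threshold, plus per-group probability densities of
  the note-level measures (Gaussian KDE, Silverman bandwidth).

For listener response tables (participant × stimulus judgments with
confidence and familiarity):

* confusion matrices (music = positive class), accuracy, and the Matthews
  correlation coefficient

      MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

  with a zero denominator set to 1 (an all-one-answer responder scores
  exactly 0 = chance);
* a mixed-effects logistic model of perceived category:
  `perceived_music ~ acoustic features + familiarity + confidence +
  familiarity:(features, confidence) + (1|participant) + (1|stimulus)`,
  fit by maximum likelihood with the Laplace approximation, after a VIF
  collinearity screen (threshold 5) of the stimulus features; reported as
  odds ratios with Wald CIs, random-intercept variances, Nakagawa
  marginal/conditional R², and in-sample prediction accuracy/MCC.

A synthetic module generates drum-like corpora (decaying pitched strokes
on three tone levels, category contrasts in level, timing and timbre)
with ground-truth onsets, and listener populations with known logistic
coefficients — so every stage is testable without the original
recordings. See `docs/methods.md` for models, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the full synthetic study into
`results/`:

```bash
python analysis/01_simulate_corpus.py    # 15+15 recordings + ground truth
python analysis/02_acoustic_features.py  # segmentation + feature battery
python analysis/03_listener_behavior.py  # 107 simulated listeners, MCC
python analysis/04_perception_model.py   # VIF screen + mixed-effects model
```

`02_acoustic_features.py` prints the group contrasts (t is music −
speech; threshold p < 0.005 after correcting for 10 tests):

```
              feature          t        df            p         d  significant_after_correction
       mean_intensity -15.811572 27.911199 1.849021e-15 -5.773570                          True
           mean_pitch  -1.509510 25.040102 1.436849e-01 -0.551195                         False
          mean_ioi_ms -14.758872 19.077841 6.862331e-12 -5.389178                          True
mean_intensity_change  14.086147 27.999585 3.109267e-14  5.143534                          True
    mean_pitch_change  -1.103990 27.857405 2.790426e-01 -0.403120                         False
   mean_timbre_change  25.465983 24.596381 3.422901e-19  9.298862                          True
        pulse_clarity   7.521595 26.287053 5.133610e-08  2.746498                          True
```

Speech-like performances come out louder (negative t for intensity) with
longer inter-onset intervals and *less* note-to-note intensity variation;
music-like ones have a clearer pulse and larger timbre changes; pitch
does not separate the groups after correction — exactly the contrast
pattern the generator encodes. `03_listener_behavior.py` then scores 107
simulated listeners:

```
pooled accuracy: 0.891
mean per-participant MCC: 0.794
familiar vs unfamiliar MCC: delta=0.141, t(104.6)=7.76, p=6.1e-12, d=1.49
unfamiliar MCC vs chance: mean=0.727, p=2.9e-49
```

and `04_perception_model.py` fits the perception model after the VIF
screen (here the strong synthetic contrasts make the level/timing block
heavily collinear, so five predictors are removed), reporting for each
retained fixed effect an odds ratio (> 1 → pushes toward "music", < 1 →
toward "speech") with its Wald CI, e.g. pulse clarity OR 8.26
[5.44, 12.55] *** and familiar:pulse_clarity OR 3.21 [2.10, 4.91] ***,
with marginal R² 0.663, conditional R² 0.772, and conditional in-sample
prediction accuracy 0.904 / MCC 0.808.

The same stages are available as a CLI (`dundun simulate | features |
behavior | model | all`) for running on real WAV directories:

```bash
dundun features --wav-dir my_recordings/ --annotations onsets.csv --out out/
```

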