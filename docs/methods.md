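# Methods

`oscispeech` implements a single-trial analysis linking induced EEG rhythms
to speech-in-noise intelligibility: parieto-occipital alpha (7–15 Hz) and
frontal beta (13–30 Hz) power, measured per trial with a Slepian-tapered
complex-wavelet spectrogram, are related to the percent-correct keyword
score of that trial through a chain of linear, mixed, and multinomial
models; a compound-binomial null tests whether keyword outcomes within a
trial are independent. Because the experimental recordings this design
comes from are not publicly downloadable, the package includes a
first-class synthetic cohort generator with the statistical structure the
analysis assumes, and every stage is validated against that generator.

## Study design encoded in the defaults

Six subjects each perform 175 trials in each of two masking conditions
(speech-in-babble, SiB, and speech-in-speech-shaped-noise, SiSSN), giving
1050 trials per condition. Each trial is a 5.25-s epoch: 0.5 s baseline, a
visual cue at 0.5 s, masker onset at 1.5 s, target-speech onset at 2.75 s.
The *pre-stimulus* window is the 1-s cue-to-masker interval; the
*during-stimulus* window is the 3.75 s from masker onset to epoch end.
Intelligibility is scored on 5 keywords, so the trial score is one of
{0, 20, 40, 60, 80, 100}.

The montage is the 32-channel Biosemi layout (A1–A32; coordinates from
MNE's bundled standard montage) plus two earlobe references (EXG1/EXG2).
Alpha is measured over the parieto-occipital group A9–A22, beta over the
frontal group A1–A6 and A25–A31.

Sampling rate defaults to 256 Hz rather than the 4.096-kHz hardware rate:
nothing above 30 Hz is analyzed, and the lower rate keeps full-cohort
simulation tractable on one CPU. `pipeline.validate_config` reports this
and any other deviation from the reference setup as an explicit notice.

## Generative model

Each trial carries a latent state `z ~ N(0, 1)`:

* **Behavior.** The five keywords are conditionally independent Bernoulli
  draws with success probability `logistic(eta0_cond + eta1 * z)`
  (`eta0 = 0` in both conditions, i.e. ~50 % mean intelligibility, matching
  the SNRs chosen to avoid floor/ceiling; `eta1 = 1` by default).
  Marginally over `z` this makes within-trial keyword outcomes positively
  correlated; `eta1 = 0` is the exact independence regime, and a two-latent
  mode (`n_latents = 2`) gives alpha and beta *independent* behavioral
  information (each latent drives one band, and their mean drives the
  keywords).
* **Band power.** Trial log power (dB re 1 µV²) for band *b* is
  `mu_subject,b + shared_b + period noise`, where `shared_b` contains
  `gamma_b * z_b` plus extra trial-level variance. Subject means span ~5 dB
  for alpha (ascending) and ~6 dB for beta (descending, so the
  alpha-to-beta ratio crosses 1 across subjects). Defaults:
  `gamma = 1.2 dB` per unit `z` and total per-trial sd `sigma = 3 dB`,
  values in the range reported for single-trial alpha/beta variability and
  chosen jointly so reduced cohorts (50 trials/subject) retain ≥ 80 %
  power for the score effect while the per-trial spread stays large
  relative to spectral-estimation noise.
* **Pre/during structure.** The shared trial component is split between the
  pre- and during-stimulus periods so that the population squared
  correlation between the two equals `rho_period` (default 0.8). The
  during-stimulus alpha level is raised by `during_alpha_boost = 3 dB`
  (during beta unchanged), reproducing the above-diagonal alpha and
  on-diagonal beta pre/during scatter. Note `rho_period` is a
  *within-subject* quantity: pooling subjects adds the between-subject
  variance to both periods and inflates the pooled R² (which is also true
  of the pooled design-scale regression the analysis reports).
* **Waveforms.** Per channel: 1/f background (4 µV rms, exponent 1),
  a 20-µV-rms common-mode drift shared with the earlobe channels (what
  re-referencing removes), 0.5 µV sensor noise, and the two oscillations as
  narrowband-filtered Gaussian noise — alpha 10 ± 2 Hz on a
  parieto-occipital Gaussian spatial field, beta 20 ± 4 Hz on a
  fronto-medial field centered over the F/FC row. Oscillation amplitudes
  are calibrated (via a cached long-realization measurement through the
  spectrogram itself) so the *extracted* band power matches the trial's
  ground truth. Channels share each oscillation only partially
  (`osc_coherence = 0.25`): cortical rhythms are not rank-1 across the
  scalp, and partial coherence both is more realistic and lets the
  channel-group average suppress single-channel estimation noise. Blinks
  are 300-ms raised-cosine transients (100 µV) on a fixed rank-1 spatial
  pattern concentrated just anterior of the Fp row, at Poisson-distributed
  times (1/epoch).

What the generator does **not** emulate: acoustic stimuli, evoked
(phase-locked) responses, saccades or non-blink artifacts, volume-conduction
head modeling, non-stationary oscillatory bursting, or heavy-tailed power
distributions (log-normal is an assumption; the source design does not
characterize single-trial distributions). Passing tests therefore show the
*analysis chain* is correct and calibrated under a plausible generative
model — not that real EEG satisfies that model.

## Preprocessing

Re-reference to the earlobe average; signal-space projection (SSP) of the
blink pattern (1 component by default, patterns estimated as leading left
singular vectors of artifact segments, reference channels excluded);
zero-phase 4th-order Butterworth bandpass (nominally 1–400 Hz, clipped to
0.45 × fs with a logged warning at desk-scale rates). The chain is linear;
the order is fixed (re-reference first) because with signal on the
reference electrodes SSP and re-referencing differ by the common mode
projected onto the artifact pattern. SSP inevitably removes the component
of frontal oscillatory signal lying along the blink pattern; with the
default geometry this costs ~0.3 dB of measured frontal beta and nothing
measurable of parieto-occipital alpha, and the energy-accounting test
bounds the total (alpha + beta) measured-band-power loss at < 5 %.

## Time–frequency analysis

For each frequency on a 2–40-Hz, 1-Hz grid, the wavelet is a DPSS
(Slepian) taper of length 5 cycles (odd number of samples) with full
time-bandwidth product 2, multiplied by a complex exponential. The taper
count convention is `max(1, floor(TB) − 1)`, i.e. a single taper at TB = 2.
Power is the taper-mean squared magnitude of the convolution, scaled so a
stationary sinusoid of amplitude A reads A²/2 at its frequency (the scale
uses the taper's DC gain; an independent windowed-DFT oracle reproduces the
implementation to < 1e-6 relative error). Bins whose wavelet support
crosses an epoch edge are masked invalid and excluded from all averages
rather than zero-padded.

Band power is the unweighted mean over band frequencies (closed interval on
the grid — alpha [7, 15] and beta [13, 30] overlap at 13–15 Hz by design,
their channel groups differing), group channels, and valid bins of the
period window. dB conversion is `10 log10(power / 1e-12)` (dB re 1 µV²).
Pre- and during-stimulus power are combined by the arithmetic mean in the
linear power domain before further analysis; whether the reference analysis
averaged in linear power or in dB is not stated, so `combine_domain="db"`
(geometric mean) is available, with `linear` the documented default.

## Behavioral null model

With `p̂` the condition's mean proportion of keywords correct, independence
implies the keywords-correct count per sentence is Binomial(5, p̂) and the
per-bin sentence counts are Binomial(1050, q_x). `build_null` computes the
exact masses, expected counts, and per-bin 95 % envelopes. The
independence test uses a Pearson χ² (or G²; `statistic="loglik"`) against
the expected counts, calibrated by Monte Carlo: replicates draw 1050
independent Binomial(5, p̂) sentences, and each replicate's statistic is
computed against expected counts at its **own** re-estimated p̂ (a
parametric bootstrap). Re-estimation matters: comparing replicates to the
fixed plug-in p̂ is conservative (measured type-I ≈ 0.02 instead of 0.05),
so the fixed-p variant is available (`refit_p=False`) but not the default.
P-values use the add-one rule, (1 + #{MC ≥ observed}) / (n_mc + 1).

## Statistical models

All power responses enter as dB (a scaled log, leaving F/t statistics
identical to natural-log fits).

* **Score ANOVA.** OLS of log band power on percent-correct score as an
  ordered factor (orthonormal polynomial contrasts over the six equally
  spaced levels; contrasts are rebuilt on the observed levels if one is
  absent) plus condition, with Type II F tests; per-contrast t statistics
  (linear … quintic) are reported, and the score × condition interaction is
  fitted only on request. With the full design the score term is tested on
  2093 denominator df.
* **Successive differences.** Backward-difference coding gives the five
  step contrasts 20−0, 40−20, …, 100−80 adjusted for condition; for
  balanced data the step estimates telescope to the 100-vs-0 mean
  difference.
* **Alpha–beta association.** Random-intercept linear mixed model (log beta
  on log alpha + condition, intercept per subject), fitted by REML profiled
  over the variance ratio using the per-group Woodbury identity, so the fit
  is a one-dimensional optimization at any n. The slope's denominator df
  use the Satterthwaite approximation computed from the numerical Hessian
  of the REML criterion — the finite-sample stand-in for Kenward–Roger
  (every result carries that note; at n ≈ 2100 the difference is
  negligible). The implementation reproduces R's `lmerTest`
  (slope/SE/df/variance components) and `statsmodels`' MixedLM in the test
  suite. A single-subject table falls back to fixed-effects OLS with a
  logged note; `subject_mode="fixed"` forces fixed subject intercepts.
* **Individual differences.** Type II F for subject and condition on log
  alpha, log beta, or their (log) ratio.
* **Multinomial deviance.** Score as a 6-level categorical response
  (reference level 0) on standardized log alpha, log beta, and condition;
  Type II likelihood-ratio tests fit the full model and each drop-one
  model, with deviance −2 log LR referred to χ². Each dropped predictor
  spans 5 equations, so continuous terms carry 5 df; the condition factor
  likewise contributes (levels − 1) × 5 = 5 df under this construction (a
  published analysis-of-deviance table prints 2 for condition, which the
  stated drop-one construction cannot produce; this implementation reports
  the construction's own df). Deviances relative to a condition-only base
  model are also returned (the model-comparison figure construction).
  Optimization: Newton with fallback to L-BFGS/BFGS, tolerance 1e-8.
* **Pre/during regression.** OLS of during- on pre-stimulus log power
  (R², df = n − 2). `within_subject=True` demeans by subject first,
  isolating the trial-level shared variance the generator's `rho_period`
  configures (df = n − 1 − n_subjects).

## Validation experiments and problem sizes

`oscispeech.validation` (driven by `scripts/acceptance.py` and
`tests/test_acceptance.py`) re-runs the chain end to end: design df
(2093/2098, 1050 trials per condition), epoch geometry, spectrogram-oracle
agreement, null-test calibration (200 datasets × 500 MC replicates; type-I
and KS uniformity) and power at `eta1 = 1.5` (100 datasets), band-power
recovery over 200 default-noise epochs, score-effect power (100 reduced
cohorts of 50 trials/subject) and type-I (200 such cohorts), multinomial
independent-contribution rates (100 reduced cohorts, two-latent generator;
100 redundant-predictor cohorts), and pre/during shared-variance recovery
(100 single-subject cohorts of 50 epochs). Sizes were chosen so the suite
completes in a few minutes on one CPU while leaving the Monte-Carlo error
of each rate well inside its decision band. EEG-dependent experiments
restrict the frequency grid to the band(s) being extracted; grid choice
does not enter the band averages beyond that.

Two quantitative caveats the experiments themselves expose: (i) pre-window
band-power estimates carry irreducible spectral-estimation noise (a 1-s
window at alpha frequencies has ~4 time-bandwidth degrees of freedom per
channel, ~0.7 dB estimator sd after group averaging), which systematically
attenuates the extracted pre-vs-during R² by ~0.045 relative to the
generator's 0.8 — the truth-level recovery is exact (mean R² 0.80), and
both numbers are reported; (ii) SSP removes a few percent of measured
frontal beta power (see Preprocessing). Both are properties of the method,
not of the implementation.

## Numerical choices

0-based sample indexing and half-open time windows throughout; epoch length
`round(5.25 × fs)` samples (1344 at 256 Hz). Wavelet windows forced to odd
length so `mode="same"` convolution is exactly centered. REML variance
ratio optimized on a log scale over e^[−18, 18]; boundary fits (ratio → 0)
report residual df. dB conversion rejects non-positive power. The add-one
MC p-value never returns 0. HDF5 is the on-disk epoch format (datasets
`data` [trial × channel × sample], `labels`, scalar attrs for sampling rate
and timeline anchors, trial table embedded as CSV text).

## Known limitations

Kenward–Roger df are approximated by Satterthwaite. The generator's
log-normal single-trial power and Gaussian spatial fields are assumptions.
No gamma-band analysis, no phase/inter-trial-coherence measures, no
baseline normalization (absolute dB power is analyzed), no ICA or channel
interpolation, and no automated blink detection — SSP takes
artifact segments as input (here, the generator's ground truth). Real-EEG
file ingestion is limited to the documented HDF5 layout; EDF+ export is not
implemented.
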