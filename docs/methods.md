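# Methods

This note documents the models, estimators and numerical choices behind
`facegamma`, and what the synthetic-data tests do and do not establish.

## Synthetic study model

The simulator stands in for unavailable patient recordings.  Each synthetic
patient carries depth contacts in up to four temporal-lobe regions plus a
scalp Fz channel and belongs to group O (no mesial temporal seizure onset
zone) or group M (mesial temporal SOZ).  A recording is the sum of four
components per channel:

* **Background**: Gaussian noise spectrally shaped as 1/f^α with the
  spectrum flattened below 1 Hz, normalized to a target SD.  Defaults
  α = 1.5 and 20 µV are typical for mesial temporal LFP; the shelf keeps
  the variance from being dominated by unphysical sub-Hz drift, which would
  otherwise swamp epoch-SD artifact rejection.
* **Evoked deflections**: Gaussian-windowed monophasic bumps (default FWHM
  60 ms) at the nominal 110/240/360-ms latencies, identical in every
  matching trial, so they survive trial averaging.  Amplitudes are signed;
  the shipped defaults use negative values for the N-components and point
  in the directions the group comparison is meant to detect (faces >
  mosaics at N240/N360 in amygdala and fusiform, a famous-face N360
  advantage in the parahippocampal gyrus, a flat hippocampus).
* **Induced gamma bursts**: band-limited noise carriers under a Hann
  envelope with an independent realization per trial, so they cancel from
  the trial average but raise single-trial power.  The carrier spectrum
  follows the background's 1/f shape inside the burst band, which makes the
  decibel elevation flat across frequency; the amplitude is calibrated so
  that the mean in-band power over the burst window exceeds the background
  by exactly the configured decibel amount (the Hann envelope's mean-square
  is divided out).
* **Cross-regional coupling**: during post-stimulus windows of the listed
  categories, the gamma-band component of the target region is multiplied
  by `1 + depth·cos φ(t − lag)`, where φ is the source region's narrowband
  phase (brick-wall ± 1.5 Hz around the coupling frequency, Hilbert
  transform).  Gates carry 10-ms cosine ramps to avoid spectral splatter.

Contacts within a region receive the shared evoked/induced trace scaled by
a per-contact gain gradient (defaults 1.0, 0.45).  Without the gradient an
adjacent-contact bipolar derivation would cancel every injected effect
exactly; with it, bipolar channels retain a known 0.55× copy.

Event schedules draw inter-stimulus intervals uniformly from 2800–3000 ms,
with 300 ms of fixation and 1500 ms of stimulus between onsets, 6
categories (5 face categories + mosaics) × `n_per_category` stimuli in a
seeded random order, and 2 s of padding at both recording edges so the
first epoch's 1.1-s baseline exists.

**What the simulator does not emulate**: epileptiform spikes and seizures,
eye movements and other artifacts (rejection is exercised on amplitude
outliers only), realistic electrode geometry and volume conduction,
between-patient variability in effect topography, and 1/f exponent
heterogeneity.  Passing tests therefore establish that the estimators
recover known effects under realistic spectra and trial counts — not that
they are robust to every pathology of clinical recordings.

## Preprocessing

Recordings are written/read as plain 16-bit EDF (µV).  2048-Hz data are
decimated to 1024 Hz after a 255-tap linear-phase FIR low-pass (pass to
480 Hz; ~53 dB stopband), applied via symmetric same-mode convolution so no
phase shift is introduced.  Epochs span [−1.1, +1.5) s with t = 0 the first
sample at/after onset; windows are half-open throughout.  Artifact
rejection computes each epoch's SD over the full span per channel and masks
epochs with SD > 2.5 × the channel's mean epoch SD; masking (not deletion)
keeps trial indices aligned across channels.  Because the criterion is a
fixed multiple of the mean, it is scale-invariant, and it can never reject
all trials of a channel on its own (the warning path exists for epochs
already masked upstream).  The ERP band-pass is a zero-phase 4th-order
Butterworth (0.5–20 Hz, forward–backward): a linear-phase FIR sharp enough
for the 0.5-Hz edge would be longer than the epoch permits under
forward–backward filtering, and the IIR meets the ripple and attenuation
requirements with margin.

## Time–frequency analysis

Complex Morlet wavelets at 40 log-spaced frequencies from 1 to 200 Hz with
cycle counts increasing logarithmically from 3 to 10 — narrow wavelets
track the slow end's temporal dynamics, wide ones stabilize gamma
estimates.  Wavelets are normalized to unit gain for a sinusoid at their
centre frequency.  Convolution is FFT-based on reflect-padded epochs;
samples closer to an epoch edge than a wavelet half-width (3.5 σ_t) are
flagged edge-contaminated.

The decibel baseline B(f) per channel is the **geometric** mean over the
[−1.1, 0) s span of the kept-trial-averaged power.  With a geometric-mean
baseline the trial-averaged dB map averages to exactly zero over the
baseline span (an arithmetic mean leaves a Jensen gap); the two differ by
well under 0.1 dB at realistic trial counts.  Per-trial dB values share the
common B(f).  Windowed gamma rows convert the dB block back to power
ratios, average over the 45–150 Hz × window block, and re-express the mean
ratio in dB — averaging before the logarithm avoids the ~−2.5 dB
chi-square bias that per-pixel single-trial dB values carry.

## Cluster-based permutation test

One face-minus-mosaic dB map per (patient, region); pooled-variance
two-sample t per pixel (positive = group O > M); voxel threshold |t| ≥
t_{0.975, n−2}; 4-connected components (rook adjacency); cluster statistic
= sum of t over the cluster.  Each permutation randomly reassigns the
subject maps to groups of the original sizes and records the maximum
positive and minimum negative cluster sum (zero when no cluster forms, so
both null distributions always hold exactly `n_perm` entries).  Real
clusters survive at ≥ the 95th percentile of the max distribution or ≤ the
5th percentile of the min distribution — one test per tail at ~5%.  When
fewer distinct assignments than permutations exist (e.g. 252 for 5 + 5),
sampling proceeds with replacement under a warning; the test is then
slightly conservative, as the measured null rate (~4% at 5 + 5 subjects)
reflects.

## Coupling estimators

**PAC.** Phases from 4-cycle Morlets on a 3–20 Hz grid (1-Hz steps),
amplitudes from 6-cycle Morlets on a 45–200 Hz grid (5-Hz steps), both cut
to the 0–750 ms post-stimulus window and concatenated over kept trials
common to the two channels.  The modulation index is the mean vector
length |⟨A(t)·e^{iφ(t)}⟩|.  Surrogates circularly shift the concatenated
amplitude series against the phase series by one global random offset of at
least 1 s (computed for all offsets at once via FFT cross-correlation,
which is numerically identical to explicit shifting); z = (MI − μ_surr)/
σ_surr, significant at z ≥ 2.  The observed null rate of z ≥ 2 is ~2.3%
per grid pair, but pairs within one dataset are strongly correlated, so
per-dataset rates disperse widely; rate checks average over independent
realizations.

**PSI.** For each (phase frequency, amplitude frequency): x = real part of
the phase-channel Morlet coefficient, y = amplitude envelope; both demeaned
and Hann-tapered per 750-ms trial segment; complex coherency C(f) averaged
over segments; PSI = Im Σ_f conj(C(f))·C(f + δf) over f within ±2 Hz of
the phase frequency, δf one Rayleigh bin (1.33 Hz).  Positive PSI means x
leads (the phase site drives the amplitude site); the estimator is exactly
antisymmetric under exchanging x and y.  z-scores come from surrogates that
permute the trial pairing, which preserves both auto-spectra.  A sharpness
caveat discovered during validation: a 15-ms lag across a ~3-Hz-wide
coupled band amounts to only ~0.3 rad of total cross-spectral phase
advance, comparable to the coherency's endpoint phase noise at ~150
segments, so single-dataset direction calls at one grid pair carry
appreciable error probability even when the underlying envelope is
verifiably lagged.  Direction-recovery checks therefore combine z-scores
over independent simulated recordings (Stouffer), which is decisively
signed in both directions.  PSI maps are reported only inside the
PAC-significant (z ≥ 2) region, mirroring how the directionality is meant
to be read.

Channel selection for coupling takes, per region, the contact with the
fewest rejected epochs (ties broken by channel order) — an operational
stand-in for picking the least artifact-laden electrode by eye.

## Mixed-effects models

Trial-level values (ERP window amplitudes in µV, windowed gamma in dB) are
pooled over patients per region.  Model 1: group + picture (face/mosaic) +
hemisphere (+ peak for ERP) + group × picture; Model 2 drops mosaic trials
and replaces picture with the five face categories.  Fits are REML with a
random intercept per patient (statsmodels MixedLM; several optimizers are
tried and the best finite REML likelihood kept, because the default
gradient optimizers occasionally stall on a degenerate point).  The
fixed-effects covariance is computed directly from the estimated variance
components via the GLS identity — finite even when the intercept variance
sits on the boundary, and identical to lme4's `vcov`.

Degrees of freedom use a containment-style rule: terms constant within
patients are tested against n_patients − q_between df, within-patient terms
against residual df.  For balanced designs this tracks Satterthwaite
closely (between-effect p-values are mildly conservative) and gives
honest CI coverage for group effects at six patients.  Term p-values are
Holm–Bonferroni corrected (step-down with monotonicity enforcement); a
significant group × category interaction triggers pairwise
estimated-marginal-mean contrasts per group with studentized-range (Tukey)
p-values, averaging the design over the off-factors.

**Responsiveness flags** are a reconstruction — the criterion behind the
reported responsive-contact counts is not specified anywhere we could
follow, so a contact is ERP-responsive if any of the three peak-window
amplitude distributions differs from zero (two-sided one-sample t,
Holm-corrected over three windows, α = 0.05), and gamma-responsive if its
windowed gamma dB values exceed zero (one-sided t, α = 0.05).  Treat these
flags as a plausible operationalization, not a replication.

## Problem sizes and determinism

Validation runs use scaled-down sizes chosen to estimate each property
with adequate precision: calibration rates from 200 repetitions at 500
permutations, power from 50 repetitions, coupling from 150-trial
recordings (5 realizations per direction for PSI), amplitude/power
recovery from 200 trials, model recovery from 50 simulated six-patient
studies.  The pipeline's own defaults keep the full-size constants (3000
permutations, 200 surrogates).  All randomness flows from seeds:
`SimConfig.seed` for data, explicit seeds for surrogate/permutation draws,
and in the pipeline a master seed expanded into fixed per-stage spawn keys
so that toggling one stage never shifts another's draws; identical configs
reproduce outputs bit-for-bit.

## Known limitations

* The simulator's effect sizes are illustrative; no per-trial amplitude
  distributions exist to calibrate them against.
* Between-effects df are containment-based, not Satterthwaite; for heavily
  unbalanced designs the approximation degrades.
* The PSI's single-pixel direction call is intrinsically noisy for small
  lags and narrow coupled bands (see above); read it over regions, not
  pixels.
* Edge-contaminated time–frequency samples are flagged but not excluded
  from per-trial model rows; at 1024 Hz and ≥ 45 Hz the contamination is
  confined to ~35 ms at each epoch edge, outside every analysis window.
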