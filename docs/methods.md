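# Methods

`physioid` identifies subjects (1-of-N classification) from three wearable
physiological waveforms — electrocardiogram (ECG), photoplethysmogram (PPG)
and respiration (RESP) — through a feature-level fusion pipeline:
denoise → cycle segmentation → 20 features per cycle → per-modality
PCA → LDA reduction → multiset canonical correlation (MCCA) fusion → SVM.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic validation does and does not demonstrate.

## Synthetic cohort model

There is no public ground-truth dataset with beat-exact annotations for all
three modalities, so validation rests on a generative cohort model whose
event times are known exactly.

**Subjects.** Each subject is a parameter vector drawn once (uniformly,
from resting-adult ranges): mean heart rate 55–95 bpm with beat-to-beat
variability σ 0.8–3 bpm; five Gaussian ECG kernels (P, Q, R, S, T) with
subject-specific amplitudes, widths and offsets from the R peak; a
two-kernel PPG pulse (systolic wave + dicrotic wave at a delay, amplitude
ratio in 0.3–0.6) delayed from the R peak by a pulse-transit time of
0.15–0.30 s; a phase-warped sinusoidal respiration waveform at 9–22
breaths/min with an inspiration fraction of 0.30–0.45. Subject seeds derive
as `master_seed * 10007 + subject_id`, so any subject can be reconstructed
in isolation.

**Records and sessions.** The default protocol is 10 records of 60 s per
subject at 125 Hz (the sampling convention of bedside-monitor waveform
archives). Each record index models a separate acquisition *session*:
resting heart rate shifts by N(0, 2·hr_sd) and each sensor's coupling gain
by lognormal(0, 0.1) between sessions. Without session effects every
modality is a near-perfect fingerprint and single-modality identification
saturates at ~100%, which real bench campaigns do not show; with them, the
cohort lands in the empirically reported regime (single-modality accuracy
roughly 0.70–0.90, tri-modal fusion ≥ 0.99). ECG and PPG records of one
session share one RR tachogram, so cardiac timing is physically coupled
across those modalities. Beat times are quantized to the sample grid so
the discretely sampled beat template is identical beat to beat.

**Noise.** Independently switchable: white noise at a stated SNR (dB,
relative to clean-signal variance), baseline wander (one sinusoid at
0.2–0.4 Hz), and powerline interference (50 Hz). The default study noise
is 20 dB white + 0.15-amplitude baseline wander + 0.05-amplitude powerline.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: motion artifacts, arrhythmia and ectopy,
sensor detachment, morphology drift within a session, inter-lead ECG
differences, and the heavy-tailed artifact structure of ICU archives. The
generator's role is parameter recovery under controlled conditions, not
clinical realism.

## Preprocessing

**ECG/PPG.** Multi-level discrete wavelet transform (db4), default depth
L = smallest level with fs/2^(L+1) < `baseline_cut` (L = 7 at 125 Hz and
0.5 Hz). Detail coefficients are soft-thresholded at the universal
threshold σ̂·√(2 ln N), with σ̂ = median(|finest details|)/0.6745. The σ̂
estimate deliberately uses only the finest level: deeper levels are
dense in P/T-wave signal and their own MAD would annihilate it. Baseline
drift is removed by zeroing the approximation band plus every detail band
overlapping [0, `baseline_cut`): the dyadic filters' transition bands are
wide, and stopping at the nominal band edge leaves ~20% of a sub-cutoff
drift tone in the neighboring level (measured on a 0.3 Hz tone; the
overlap rule leaves ~2%).

*Known limitation (measured, and deliberately not patched):* the soft
universal rule shrinks every surviving coefficient by the full threshold,
so on a 10 dB-SNR input the shrinkage bias on QRS/T coefficients caps the
output near 7 dB — slightly *below* the input. The independent reference
implementation (scikit-image's VisuShrink, same wavelet/mode/levels) lands
at the same value, confirming this is a property of the method, not of
this implementation. Hard thresholding would reach ~11–14 dB, but soft
thresholding is this pipeline's contract. In the pipeline's actual
operating regime (structured noise: baseline wander + powerline + 20 dB
white) denoising does improve SNR and removes the drift entirely, which is
what the identification stage needs.

**RESP.** Zero-phase windowed-sinc FIR low-pass, cutoff 1.0 Hz, Hamming
window, default length 4 s of taps (odd count, integer group delay removed
exactly; edges are edge-padded). The length is chosen for a ~0.8 Hz
transition band: a short (e.g. 101-tap) filter at 125 Hz has a ~4 Hz
transition and would attenuate breathing itself. Stopband attenuation at
50 Hz exceeds 50 dB.

**Spectra.** Welch averaged periodograms (Hann, mean-detrended), used for
QC plots; total integrated power matches signal variance to within ~5%
(window loss).

## Segmentation

**ECG.** Pan–Tompkins: 5–15 Hz Butterworth band-pass (zero-phase),
five-point derivative, squaring, 150 ms moving-window integration, dual
adaptive signal/noise thresholds with a 200 ms refractory period and a
half-threshold search-back after 1.66 × the running RR average. Accepted
peaks are refined to the local ECG maximum within ±75 ms. Thresholds are
initialized robustly from percentiles of the integrated signal so the
first beats of a record are not lost. Fiducials per beat: Q/S as minima
within 50 ms before/after R; P/T as maxima inside the T1 = 0.25 s pre-R
and T2 = 0.45 s post-R windows (typical P-onset→R and R→T-offset spans);
the cycle cut is [R−T1, R+T2). Beats whose windows cross the record
boundary are dropped, not padded. Note the fixed-width cuts overlap when
RR < 0.7 s; PPG/RESP cycles below are true partitions.

**PPG.** Systolic peaks = local maxima separated by ≥ 0.4 s with
prominence ≥ 0.3 × the median candidate prominence; feet = minima between
consecutive peaks; cycles cut foot-to-foot.

**RESP.** Sign changes of a smoothed (0.25 s moving average) first
difference mark peaks/troughs; extrema closer than 1 s merge keeping the
larger excursion; cycles cut trough-to-trough.

On the clean 25-subject cohort the R detector recovers every beat within
±60 ms (sensitivity = precision = 1.0) and stays ≥ 0.95 at 10 dB SNR;
PPG/RESP cycle counts track ground truth within ±1 per 60 s record.

## Features and samples

20 features per single-cycle segment, modality-agnostic and
fiducial-light (the published pipelines in this area rarely enumerate
their feature sets; this one is config-pluggable):

* 15 time-domain: mean, median, SD, RMS, mean absolute deviation,
  skewness, excess kurtosis, min, max, peak-to-peak, total energy,
  zero crossings about the mean, Hjorth mobility, Hjorth complexity,
  cycle duration (s). Constant segments define skewness/kurtosis/
  mobility/complexity = 0.
* 5 frequency-domain, from a zero-padded periodogram (DC excluded):
  dominant frequency, spectral centroid, spectral bandwidth (2nd central
  moment), spectral entropy normalized to [0,1], and the low-band energy
  fraction E_low/(E_low+E_high) with the low/high split at 10 Hz (ECG),
  2 Hz (PPG), 0.5 Hz (RESP). The *fraction* form is used instead of a raw
  low/high quotient because the quotient is unbounded when a clean
  low-frequency cycle has an empty high band; all-zero segments define
  entropy 0 and fraction 1.

Cycles are binned by start time into 20 equal windows per subject (30 s
windows over the 600 s session timeline — two samples per record, which
is how 10 recordings yield 20 samples); each window becomes one sample as
the per-feature **median** over its cycles (robust to missed/spurious
cycles). Empty windows are dropped with a warning; a subject keeping
fewer than half its windows is dropped. 25 subjects × 20 windows give the
500-row per-modality sample set; rows are aligned across modalities on
the (subject, window) key.

## Dimensionality reduction and fusion

All statistics below are fitted on training rows only and applied to test
rows; features are z-scored (training statistics) before PCA because they
carry heterogeneous units.

* **PCA**: eigendecomposition of the covariance J = XᵀX/n of the centered
  data; default k = 10 components per modality (on the synthetic cohort
  this captures ≥ 99% cumulative contribution, mirroring the usual
  contribution-rate criterion). Component signs are fixed by making the
  largest-magnitude loading positive.
* **LDA**: top k = 6 eigenvectors of (Sw + εI)⁻¹Sb with the multi-class
  scatters Sw = Σ_c Σ_{x∈c}(x−u_c)(x−u_c)ᵀ and Sb = Σ_c n_c(u_c−u)(u_c−u)ᵀ
  and ridge ε = 10⁻⁶·trace(Sw)/d. Reported eigenvalues are the exact
  Rayleigh quotients wᵀSb w / wᵀSw w of the unridged scatters at the
  solved directions, so they remain interpretable as class-separation
  ratios independent of the ridge.
* **MCCA**: the multiset canonical criterion is solved as the symmetric-
  definite generalized eigenproblem S a = λ diag(S_ii) a where S is the
  full covariance block matrix [S_ij] (diagonal blocks included; for two
  sets the top eigenvalue is 1 + ρ with ρ the first canonical
  correlation). Each S_ii is ridge-regularized with fraction 10⁻⁸ of its
  mean diagonal — small enough that the stationarity residuals against the
  *raw* blocks stay ≤ 10⁻⁶, large enough to stabilize near-singular
  blocks; genuinely singular blocks raise an error advising a larger
  ridge. Directions are rescaled to Σ_i a_iᵀS_ii a_i = 1 exactly. The
  fused vector concatenates the three k = 6 projections (18-D);
  concatenation preserves modality-specific information, with summation
  available by config. CCA (two sets) uses the same solver; its canonical
  correlations are reported in [0, 1] and cross-checked in the tests
  against an independent whitened-SVD oracle.
* **Baselines**: serial fusion (concatenation), parallel fusion (the
  complex composite z = x + iy materialized as real/imaginary channels or
  modulus, shorter set zero-padded), CCA and PCA+CCA dual-modality
  variants.

## Identification

One-vs-one multiclass SVM (RBF kernel for fused features; polynomial,
degree 3, for raw single-modality features) with per-split grid search:
C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵, …, 2³}, 5-fold cross-validation on the
training split only, features standardized inside the model. Experiments
use stratified 7:3 splits (per-class test count = floor(0.3·n_c), so
500 samples split 350/150) repeated 10 times with paired split seeds
across designs; accuracy is the pooled fraction of correctly identified
test samples, and per-subject accuracies pool the 10 repeats' test sets.
A label-shuffling control verifies the whole pipeline collapses to chance
(1/25) when the labels carry no information.

## Numerical conventions

Eigenvector signs: largest-magnitude coefficient positive, everywhere.
Zero-variance features pass through standardization unscaled. Degenerate
inputs (constant segments, all-zero spectra, flat records) return defined
values or empty results with a warning rather than NaNs. All randomness
flows from explicit seeds through `numpy` `SeedSequence` spawning; the
same seeds give bit-identical records and identical experiment results.

## Problem sizes used in validation

The shipped test suite runs the full study scale — 25 subjects × 10 × 60 s
records × 3 modalities (≈ 5.6 M samples), 500-row sample sets, 10-repeat
experiments for the tri-modal, three single-modal and shuffled-control
designs — plus small randomized instances for the linear-algebra oracles.
`scripts/acceptance.py` regenerates the ECG arm of the cohort from scratch
and reports the retained PCA dimensionality.
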