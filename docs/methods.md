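# Methods

This note records the modeling choices behind `osasev`: what each stage
assumes, which knobs matter, and what the synthetic validation does and does
not establish.

## Signal model and preprocessing

Input is single-channel bedside audio at 8 kHz — a room microphone far from
the sleeper, so SNR is poor and the background (wideband hiss, mains hum) is
assumed *stationary* over the night. Denoising is classic magnitude-domain
spectral subtraction: the noise spectrum is the mean STFT magnitude of the
quietest `denoise.quantile` (default 10%) of frames of the recording itself,
subtracted per frame with factor `denoise.oversubtraction` (default 1.0) and
floored at `denoise.floor` (1%) of the noise magnitude, with the original
phase kept. The STFT runs at speech resolution (512-point FFT, Hanning, 50%
overlap), independent of the coarser feature framing. An outer `min` with
the input magnitude guarantees subtraction never amplifies a bin. At the
default factor the matched-noise residual is the Rayleigh tail of the
magnitude distribution (≈0.3–0.4× input RMS); oversubtraction 2–3 drives it
below 0.1×. Denoising precedes stage extraction by default
(`denoise_before_extract`), so the profile is estimated on the longest
available stretch; the order is switchable.

Analysis is restricted to N2/N3 sleep (regular breathing, minimal movement
noise). Kept intervals are concatenated by default (`concat_segments`);
whether the original workflow concatenated or processed stages separately is
not determinable, so a per-segment mode is provided in which each kept
interval is framed and analyzed on its own — no level transition or CSD
window then spans the splice between non-adjacent stages — with transition
counts pooled and the CSD running mean continued across segments. Intervals
map to half-open sample ranges `[round(start·rate), round(end·rate))` so
boundaries never double-count.

## Temporal quantization

Frames are 0.5 s Hanning windows, 80% overlap (0.1 s hop); trailing
remainders are dropped so per-frame statistics stay unbiased. Frame energy
is the mean squared weighted sample; the quantizer, however, compares the
frame's *peak* (max squared weighted sample) against the thresholds, and the
threshold reference is accordingly the modal *peak* energy: per 60 s block
(`temporal.block_s`) the mode of a 64-bin histogram of log10 peak energies
is taken and blended with the running estimate with weight
`temporal.smoothing` = 0.9 on the old value. Thresholds are
`ratio_low` = 2 and `ratio_high` = 20 times the mode. This presumes silence
(background-only frames) is the most frequent peak range — true for natural
breathing duty cycles; a recording with nearly continuous sound would defeat
the dynamic thresholds.

The ripple rule: a frame whose peak clears the lower threshold is still
level 1 unless at least `proportion_threshold` = 50% of its energy lies in
samples above a silence floor. The floor is
`silence_floor_fraction` = 0.25 of the lower threshold (≈ half the modal
peak). A much smaller floor fails the rule's purpose: diffuse background
excursions — including musical-noise residue of spectral subtraction — carry
most of their energy above a 1%-of-peak floor and would pass as breathing,
splitting long silences. At 25%, isolated background outliers fail the
proportion test while genuine breathing frames (whose per-sample energies
sit orders of magnitude above the floor) pass.

Level 4: every maximal level-1 run strictly longer than
`temporal.min_gap_s` = 20 s whose flanking frames are both in {2, 3} is
relabeled in full — "between levels 2 and 3" is read as breathing on both
sides in either order. Runs touching a recording edge are never relabeled.
The transition matrix is globally normalized (16 entries sum to 1), so the
(1,1) entry is the overall silence-dwell probability — the clinically
loaded quantity; a row-stochastic variant sits behind
`temporal.row_normalize`.

## Cyclic spectral density

The estimator evaluates the symmetric-lag instantaneous autocorrelation
`C(t, τ) = x(t + ⌈τ/2⌉) x(t − ⌊τ/2⌋)` at 107 symmetric lags
(= 2·(n_f − 1) + 1) and averages it over `n_alpha` = 889 contiguous time
blocks per 60 s window (block ≈ 67 ms, far below any breath period, so
modulation at ≲ 7 Hz is unaffected while the α ≠ 0 estimation noise drops by
≈ 1/√block). An FFT over τ gives 54 one-sided spectral bins (up to 4 kHz in
≈ 75 Hz steps); an FFT over t gives 889 cyclic-frequency bins in ≈ 1/60 Hz
steps (fftfreq order, α = 0 at index 0, magnitudes symmetric in ±α for real
input). Both step counts are config keys (`csd.n_f`, `csd.n_alpha`); the
defaults reproduce the 54 × 889 working shape. Windows shorter than 60 s at
the end of a recording are dropped from the running mean. The incremental
mean is exact: after k updates it equals the batch mean to 1e-10.

Verified detector behavior: for noise amplitude-modulated at 0.25 Hz the
α-marginal argmax lands in the bin nearest 0.25 Hz; for stationary white
noise the mean α ≠ 0 magnitude is ≈ 1.3% of the α = 0 column. Time-reversal
leaves the magnitude structure unchanged up to re-randomization of the
estimation floor (the averaging blocks realign), so the symmetry is asserted
on the α = 0 column, the peak location, and global correlation rather than
bitwise.

## Dimensionality reduction and statistics

Otsu's 256-bin threshold zeroes sub-threshold entries of the mean grid —
value suppression, not deletion, because downstream shapes are fixed. A
constant grid has no threshold and is passed through with a degenerate flag.

NMF uses multiplicative updates for the Frobenius objective: init from
seeded uniform noise scaled so E[(WH)ᵢⱼ] matches mean(V), at most
`nmf.max_iter` = 500 iterations, stopping when the relative objective change
falls below `nmf.tol` = 1e-6; the objective is non-increasing by
construction. The shared basis (rank `nmf.rank` = 45, heuristic) is fit on
the horizontally stacked *transposed* grids of all subjects — rows index
cyclic frequency, so the basis captures cohort-wide cyclic structure — and
each subject is projected with H-only updates against the frozen W.

Statistics use the sample (n−1) std/variance, biased moment skewness
g1 = m₃/m₂^1.5 and Pearson (non-excess) kurtosis m₄/m₂²; constant rows or
columns report skewness and kurtosis as 0 by convention. The mean is
available as an optional eighth statistic (`nmf.include_mean`, default off,
keeping the 693 count). Feature names are `c_<base>_<obs>_<stat>_<seq>` with
1-based sequence numbers, so a selected feature like "base α, observation f,
maximum, 40" is addressable as `c_alpha_f_max_40`.

## Classification protocol

The linear SVM uses pairwise one-vs-one decomposition, min-max scaling fit
on training data only, C = 1, and *balanced class weights*. The weights
matter: every LOOCV training fold is one subject short in the held-out
class, and an underfit pairwise machine (small scaled margins at C = 1)
otherwise degenerates into majority voting against exactly that class —
measured as 0.15 LOOCV against 0.95 k-fold CV on the same feature before the
fix.

Selection ranks every feature by stratified 5-fold CV accuracy of a
single-feature SVM, then greedily grows a subset within the top
`selection.k` = 50, stopping when no addition improves CV accuracy; ties
break toward the earlier rank, so results are deterministic under the seed.
By default selection runs once on the full cohort and the subset is reused
in every LOOCV fold — the workflow published severity studies imply. That
protocol is *optimistic*: the held-out subject influenced the subset, and on
pure noise its selection CV score sits far above the 25% chance level
(selection bias over ~709 candidates). `selection.nested` re-selects inside
every fold; in that mode LOOCV accuracy on noise or shuffled labels stays
within 3σ of chance, and an identifying feature planted on the held-out
subject cannot change its prediction. Both modes are first-class; reported
numbers should state which was used.

Binary screening collapses predictions to normal vs any-OSA following the
class labels. A zero-denominator metric cell is reported as 0 with a flag,
never NaN.

## Synthetic data: what it emulates

One subject = band-passed (300–1500 Hz) noise gated by a single
inspiratory-dominant burst per `breath_period_s` = 4 s cycle (a single burst
keeps the envelope's fundamental cyclic frequency at exactly the breath
rate); snoring breaths swap the carrier for a 1.6× louder harmonic train at
`snore_f0_hz` = 80 Hz; apnea gaps have durations uniform in [15, 40] s —
straddling the 20 s rule on purpose — inserted at a Poisson rate matching
the target AHI, kept ≥ 8 s apart and ≥ 20 s from the edges so every gap is
breathing-flanked; background is white noise plus 60/120/180 Hz hum at
`noise_snr_db` = 15 dB against the breathing RMS. Cohorts draw target AHIs
uniformly per class band (severe capped at 60/h) and regenerate any subject
whose realized (quantized) AHI leaves its band; snore fraction rises with
severity (0.15/0.35/0.50/0.65), reflecting the higher snoring prevalence of
more severe OSA. Realized AHI is quantized to one event per recording hour,
so recordings must be long enough for a band to be realizable (10 min ⇒ 6/h
steps); shorter requests fail fast with a clear message.

Not emulated: real snore acoustics and inter-subject voice variability,
position changes, arousals and movement noise, hypopneas (partial events),
REM-stage physiology, room reverberation. Passing the synthetic study
therefore shows the pipeline recovers severity structure *of the kind it
assumes* — silence statistics and breath-rate cyclostationarity — under
realistic noise; it does not certify clinical performance, which the source
study established at 79.52%/92.78% on 83 patients whose audio is not
available.

## Problem sizes and numerics

The shipped study runs 5 subjects per class at 10 minutes each — small
enough for a laptop CPU in minutes while leaving every class band
realizable and 10 CSD windows per subject. LOOCV needs ≥ `folds` subjects
per class for the inner selection CV. The NMF stack for 20 subjects is
889 × 1080. All randomness fans out from a single pipeline seed via
CRC-keyed `SeedSequence` children (one per stage), so stages are
independently reproducible and derived seeds stay below 2³¹. Degenerate
inputs (all-zero blocks, constant matrices, zero grids) are handled
explicitly rather than propagating NaN.

## Known limitations

* The dynamic-threshold quantizer assumes silence is the modal peak range;
  continuous-sound recordings break it (documented failure mode, see the
  burst construction used in tests).
* The level-4 rule counts silences, not clinically scored events; adjacent
  breath pauses can pad a silence run by up to one pause per side, so gap
  counts from natural-pause audio are exact only outside a ±pause band
  around 20 s.
* The CSD grid's step counts are working defaults that reproduce the target
  shape; the underlying window/lag parameters are not uniquely determined by
  that shape.
* Pooled-selection LOOCV numbers are optimistic by construction; use the
  nested mode for unbiased estimates.
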