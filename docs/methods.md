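# Methods

This note documents the models, numerical choices, and limitations behind
`somnostage`, in the order data flows through the pipeline.

## Data model and conventions

All timestamps are seconds relative to lights off (t = 0); epoch *k* covers
the half-open window [30k, 30(k+1)). Stage tokens are W, N1, N2, SWS, REM
(NREM1/NREM2 accepted as read aliases). Recording directories hold one
RFC-4180 CSV per channel (`t_s,v` or `t_s,x,y,z`), a `manifest.json` with
channel locations, modalities, rates and units, and a `hypnogram.csv`;
numeric fields are serialized to 9 significant digits, so a read-write
round trip is stable to ~5 parts in 10⁹.

Sleep metrics follow the standard definitions: SOL is lights-off to the
first non-wake epoch; TST is 0.5 min per non-wake epoch; efficiency is
TST over total recording time; WASO counts wake after the first sleep epoch
*including* terminal wake before lights on (the definition "before lights
on" is taken literally); LPS is the start of the first run of ≥ 20
consecutive non-wake epochs (≥ 10 contiguous minutes, any stage), undefined
if no such run exists. Stage percentages partition non-wake epochs.

## Synthetic cohort generator

The generator produces the study conditions the analysis assumes; it is a
forward model with full ground truth, not a fit to any dataset.

**Hypnogram.** A first-order Markov chain on the five stages per 30-s
epoch. `calibrate_transition_matrix` receives target stage percentages
(over sleep), target sleep efficiency, and mean bout lengths per stage. The
diagonal comes from the geometric bout identity p_stay = 1 − 1/bout. Off-
diagonal mass is found by balancing the jump-chain flow matrix (row and
column sums proportional to π·(1 − p_stay)) with an RAS/Sinkhorn iteration
after assigning forced entries, under a structural-zero pattern in which
REM is enterable only from N2 — a crude mimic of sleep cycling, and
configurable. The resulting stationary distribution matches the targets to
better than 1e-9; printed stage tables that sum to 99.9 rather than 100 are
renormalized. Default mean bouts (W 2, N1 2, N2 6, SWS 10, REM 10 epochs)
encode a plausible degree of night fragmentation: one-minute awakenings and
N1 visits, three-minute N2 bouts, five-minute SWS/REM bouts.

Nights begin with a forced wake prefix whose length is drawn from
N(15.1, 11.4²) min truncated at zero — the target cohort's onset-latency
distribution — after which the chain starts in N1. Because that prefix adds
wake beyond the chain's stationary share, the calibration compensates the
stationary wake mass for the *expected* prefix length (the truncated-normal
mean, ≈ 17.2 min over an 8-h night) so whole-night sleep efficiency hits
the target. Passing `expected_onset_min=0` gives the uncompensated chain
(stationary wake exactly 1 − SE/100). First-order dynamics understate the
long-range memory of real sleep (no explicit ~90-min cycles); they are
sufficient to exercise a clip-level classifier and to calibrate marginal
architecture.

**Cardiac chain.** Within an epoch of stage s, successive RR intervals are
60000/HR(s) + LF(s)·sin(2π·0.1 t) + HF(s)·sin(2π·0.25 t) + ε,
ε ~ N(0, σ(s)) with σ mapped from bpm to ms, clipped inside (300, 2000) ms.
Default stage means (W 70, N1 62, N2 58, SWS 55, REM 68 bpm) and
modulation amplitudes encode textbook autonomic physiology — NREM lowers
heart rate with vagal (HF) dominance deepening into SWS, REM raises rate
and low-frequency variability. These are documented assumptions, not cohort
claims. ECG channels are a symmetric QRS-like template train (Gaussian R
wave, 8 ms width, small Q/S side lobes; per-channel gains 0.8/1.0/1.2 mV)
plus sinusoidal baseline drift, white noise (0.02 mV), and Poisson artifact
windows (2/h, 2–10 s) in which noise is multiplied by 20. No P/T waves are
modelled; the morphology is sufficient for R-peak work, not for
morphological ECG analysis.

**Motion.** Wrist acceleration is a slowly reorienting gravity vector plus
Poisson bursts of 3–8 Hz band-limited oscillation; burst rates are
stage-dependent (W 3/min ≫ N2 0.1/min ≥ SWS 0.02/min), amplitude 0.3 g,
sensor noise 0.003 g. The actigraph channel applies the same count
transform the aligner uses (below), adds 5 % multiplicative count noise,
and reports its epochs under a deliberately wrong clock
(`actigraph_offset`, default 37 s), recorded in ground truth.

**Temperature.** Distal sites (hands, ankles) relax with a 20-min time
constant toward base + 2.5 °C while asleep and back while awake, so the
distal-to-proximal gradient (DPG) rises after sleep onset; proximal sites
follow a slow deterministic decline over the first three quarters of the
night and partial recovery after. Sampling is 1/60 Hz with 0.05 °C noise.

**Cohorts.** Per-subject seeds derive from the master seed; subjects also
receive a heart-rate offset (SD 2 bpm), temperature offset (SD 0.2 °C), and
movement-rate scale (log-normal, SD 0.2) so leave-one-subject-out folds
face genuine between-subject shift. The default configuration is
intentionally favourable to staging (clean stage-conditional signals);
passing tests on it demonstrates the pipeline's correctness and internal
consistency, not expected performance on clinical recordings, where
inter-subject variability, arousals, and artifact structure are far richer.

## Cleaning

ECG and acceleration are linearly interpolated onto uniform grids after
collapsing duplicate timestamps by averaging. Noisy-clip rejection computes
per-channel SDs over 10-s clips (the trailing partial clip treated like any
other) and rejects clips whose SD strictly exceeds twice the mean of the
lowest ⌈0.15·n⌉ SDs; the ceiling guarantees a non-empty reference set, and
strict inequality means exact-tie SDs survive. Outlier excision is
one-sided (> mean + 10 SD within each retained clip) with a ⌈0.005·rate⌉-
sample buffer on each side and merged overlapping spans. The three chest
channels are summed with masked samples contributing zero; timepoints
masked on all three are flagged missing and later drop any overlapping
clip. Filtering is zero-phase (forward–backward) Butterworth so R-peak
timing is not skewed; the effective amplitude response is |H|².

## Synchronization

Lag sign convention: lag > 0 means the second series lags the first;
correcting a channel adds the estimated lag to its timestamps. The
actigraph is aligned by Pearson-correlating its per-epoch counts against a
1 Hz rolling 30-s sum of the wearable's per-second movement residuals over
integer-second candidate lags — sub-epoch resolution that plain epoch-level
correlation (quantized to 30 s) cannot reach. The ECG chain is aligned by
FFT cross-correlation of a mid-night 15-min segment against a smoothed
impulse train at the reference R-peak times, at one-sample resolution.
Estimates with peak correlation below 0.3 are flagged unconfident — this
threshold is the automated stand-in for the visual inspection a human
analyst would apply. Clock drift (time-varying lag) is out of scope.

The activity-count transform (band-pass 3–11 Hz, per-second peak of the
filtered magnitude, 0.017 g dead-band, residuals summed per 30-s epoch)
follows the published wrist-count emulation. The g→count scale is an open
constant in that recipe; it is set to 1 g = 100 count units so that the
weighted-epoch scorer's "medium" threshold of 40 separates quiet wake from
brief sleep movements on the device's own scale.

## Cardiac analysis

QRS enhancement uses the stationary (undecimated) wavelet transform with
sym4 — a wavelet shaped like the QRS complex — reconstructing only detail
levels whose dyadic passbands intersect 5–30 Hz, then squaring. Level
selection by passband intersection adapts automatically to sampling rate
(levels 3–5 at 250 Hz, 5–7 at 1000 Hz), so the 250 Hz desk-scale path and
the 1000 Hz device path run identical code.

Detection thresholds each 10-s block at median + 4·MAD, linearly
interpolated between block centres (an O(N) surrogate for a rolling
window), with a secondary relative-amplitude floor of 0.05 × the block's
99th percentile: the robust spread of a mostly-baseline *squared* trace is
orders of magnitude below QRS energy, and without the floor baseline-noise
maxima leak through. Peaks keep a 250 ms refractory separation and are
refined to the raw-trace maximum within ±25 ms. All detector constants are
config-exposed standard practice. On the default simulator the detector
achieves sensitivity/precision 1.000/0.999 (noisy) and 1.0/1.0 (noiseless,
45–120 bpm).

RR intervals between consecutive peaks are kept only inside [300, 2000] ms
(a physiologic-bounds choice of this package), and a discarded interval
breaks the pair chain so nothing spans a discard. The 14 ECG features per
clip are mean heart rate; mean/min/max/SD of RR; RMSSD; NN50/PNN50 and
NN20/PNN20 with *strict* inequality ("differ by more than x ms"); and
VLF/LF/HF (0.003–0.04, 0.04–0.15, 0.15–0.40 Hz) with LF/HF. The canonical
feature table enumerates thirteen named HRV quantities while the canonical
count is fourteen; this package reads the fourteenth as mean heart rate,
the one "measure of heart rate" not redundant with the listed statistics.
Band powers come from the Lomb–Scargle periodogram of the mean-subtracted
RR tachogram — RR samples are inherently uneven and 2-min clips are short,
so spectral estimation without resampling is preferable — integrated over
each band by the trapezoid rule, scaled so a pure tone contributes on the
order of its A²/2 variance. Note the VLF band completes less than one
cycle in 120 s; VLF is computed as defined but is not a reliable estimate
at clip length and should be treated as a nuisance column.

## Feature extraction

Epochs whose label differs from either neighbour are removed (stage scoring
is ambiguous around transitions), and each maximal run of retained,
identically-labeled, contiguous epochs is tiled into non-overlapping
4-epoch clips anchored at the run start; leftover epochs are discarded, as
are clips overlapping a missing-data window. Accelerometer features are 11
per axis on the high-pass-filtered signal: mean, min, max, range, IQR, SD
(n−1 denominator), kurtosis as the non-excess fourth standardized moment
(Gaussian → 3, biased estimator, matching the original analysis
environment's convention), RMS, variance, and a Pearson correlation with
p-value assigned cyclically to axis pairs (x: corr(x,y); y: corr(y,z);
z: corr(z,x)) — the cyclic reading honours the 11-per-axis bookkeeping
when the correlate is otherwise unspecified. Zero-variance axes emit NaN
sentinels for kurtosis and correlations.

Temperature features (mean, min, max, range over the clip) are computed on
a mode-dependent source series: the DPG (mean of 4 distal − mean of 4
proximal) with the full sensor set, the group mean with only distal or only
proximal sensors, a named distal−proximal pair difference, or a single
sensor's raw series. At 1/60 Hz a 2-min clip holds about two samples; the
window extends to the nearest sample before its start when fewer than two
fall inside.

The canonical matrix is 51 columns — 33 accelerometer (one device) + 14
ECG + 4 temperature; selecting both wrists yields 66 + 14 + 4. The printed
51-count implies a single accelerometer, which therefore defines the
canonical schema. Missing sentinels are imputed by the per-subject column
median (never across subjects, so no information crosses a
leave-one-subject-out boundary), falling back to the global median.

## Staging and evaluation

Each of the 130 trees is fit on a draw of minority-count rows sampled with
replacement within every class — bootstrap and under-sampling in one step,
re-drawn independently per tree so the ensemble sees diverse majority
subsets. With under-sampling off, trees see plain bootstraps. Scores are
vote fractions; argmax ties break toward the fixed class order
Wake < Light/NREM < Deep < REM for determinism. ROC and AUROC are
one-vs-rest on the vote fractions — the natural bagging score when no
probability model is specified.

LOSO gives one fold per held-out subject; fold metrics are aggregated as
mean and SD, with a pooled row-normalized confusion matrix as primary and
the mean of per-fold normalized matrices as secondary (both are emitted
because pooling versus averaging is a genuine reporting choice). Personal
models use stratified k-fold (default 20) within one subject, dealing each
class round-robin across folds so every training split retains every class;
classes with fewer than two rows are dropped with a warning. The learning
curve draws, for each n from 2 to N−1, ten random n-subject training sets
evaluated on one held-out subject each. The actigraphy baseline scores
epoch k wake iff 0.04c(k−2) + 0.2c(k−1) + c(k) + 0.2c(k+1) + 0.04c(k+2)
strictly exceeds 40 (edges zero-padded) — the published weighted-epoch
algorithm, standing in for the wrist device's proprietary scorer.

## Problem sizes and determinism

Desk-scale runs use 250 Hz ECG and cohorts of 2–6 subjects at 0.5–8 h;
all parameters are in physical units so the 1000 Hz device path is the same
code. The end-to-end evaluation in the test suite uses six 8-h subjects at
250 Hz. Every stochastic component draws from a generator keyed by a
configuration seed and a fixed stream tag, so identical configurations
reproduce byte-identical numeric outputs; the pipeline writes a config hash
into its log lines for provenance.

## Known limitations

First-order hypnogram dynamics; template-level ECG morphology; no non-wear
or electrode-pop artifact classes beyond noise-gain windows; no clock
drift; VLF unreliable at clip length; personal-model folds can lack a class
in their test split when a stage is rare within a night. The simulator's
separability is by construction — results on it validate the machinery,
not clinical performance.
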