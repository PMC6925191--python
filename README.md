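# somnostage

Sleep stage classification from wearable multimodal overnight signals:
wrist acceleration, chest ECG, and distal/proximal skin temperature.

Laboratory polysomnography (PSG) is the gold standard for scoring sleep in
30-s epochs, but it is obtrusive and expensive; wrist actigraphy is cheap but
blind to quiet wakefulness and to stage structure. `somnostage` implements
the middle path for researchers in digital sleep medicine: a full analysis
pipeline from raw wearable sensor streams to epoch-level sleep staging,

* **cleaning** — resampling to a uniform grid, rejection of noisy 10-s ECG
  clips (SD > 2 × mean of the lowest 15 % of clip SDs), one-sided outlier
  excision (> mean + 10 SD, ± 5 ms buffer), composite ECG summation, and
  zero-phase Butterworth high-pass filtering (1 Hz; 1st order for ECG, 5th
  for acceleration);
* **synchronization** — cross-correlation recovery of inter-device clock
  offsets, at 1-s resolution for the actigraph (via emulated activity
  counts) and one-sample resolution for the ECG chain;
* **cardiac analysis** — sym4 stationary-wavelet QRS enhancement, adaptive
  R-peak detection, RR series with physiologic bounds, and 14
  heart-rate/HRV features per 2-minute clip (time domain plus Lomb–Scargle
  VLF/LF/HF band powers);
* **feature extraction** — transition-epoch removal, 2-minute clip tiling,
  and the canonical 51-feature matrix (33 accelerometer + 14 ECG + 4 skin
  temperature, the latter computed on the distal-to-proximal gradient, a
  group average, or a single sensor depending on the sensor subset);
* **staging** — a bagged ensemble of 130 decision trees with per-tree
  random under-sampling to the minority class, scored by vote fractions;
  leave-one-subject-out and within-subject 20-fold evaluation, per-class
  recall/confusion/ROC/AUROC, sensor-subset ablation, learning curves, and
  a weighted-epoch actigraphy baseline;
* **a synthetic-cohort simulator** — ground-truthed overnight recordings
  with a Markov hypnogram calibratable to a target sleep architecture,
  stage-dependent RR dynamics rendered to three-channel ECG, stage-dependent
  movement bursts, thermoregulatory distal/proximal temperature dynamics,
  and deliberately injected clock errors and artifacts, so the whole
  pipeline is exercisable without access to a private clinical dataset.

## Model summary

Stages are the AASM labels W, N1, N2, SWS, REM, mapped onto three staging
resolutions (wake/sleep; wake/NREM/REM; wake/light/deep/REM). Each retained
2-minute clip *i* yields features **x**ᵢ ∈ ℝ⁵¹ and a label; each of the 130
trees is fit on a bootstrap draw re-balanced by random under-sampling to the
minority-class count, and the ensemble score for class *c* is the fraction
of trees voting *c*. Evaluation is leave-one-subject-out: recall (true
positive rate) per class and one-vs-rest AUROC from the vote fractions.

The simulator's hypnogram is a first-order Markov chain on the five stages
at the 30-s epoch level. `calibrate_transition_matrix` fixes the diagonal
from mean bout lengths (p_stay = 1 − 1/bout) and balances the off-diagonal
flow so the stationary distribution reproduces target stage percentages and
sleep efficiency exactly (default targets: N2 51.6 %, SWS 27.0 %, REM
16.9 % of sleep; efficiency 88.9 %; onset latency ~N(15.1, 11.4²) min
truncated at zero).

## Worked example

```bash
python examples/01_simulate_night_and_sleep_metrics.py
```

```
epochs scored: 960 (30 s each)
total sleep time:          429.5 min
sleep efficiency:           89.5 %
sleep onset latency:        19.0 min
latency persistent sleep:   31.5 min
wake after sleep onset:     31.5 min
    N1:   2.9 % of sleep
    N2:  48.2 % of sleep
   SWS:  26.7 % of sleep
   REM:  22.2 % of sleep
```

One simulated 8-hour night: 429.5 of 480 min asleep (efficiency 89.5 %),
sleep onset 19 min after lights off, and a stage composition dominated by
N2 — single-night draws scatter around the calibrated architecture, and the
across-night means converge to it (see
`examples/02_calibrate_sleep_architecture.py`). The remaining examples walk
one capability each: HRV extraction from raw ECG, clock-offset recovery,
and LOSO staging versus the actigraphy baseline.

The same pipeline runs from the shell:

```bash
somnostage simulate --subjects 6 --out cohort/ --seed 1
somnostage run --config examples/pipeline.yaml
```

writing `features.csv`, row-normalized confusion tables, per-class ROC
curves, an AUROC summary, and `report.md` into the configured output
directory.

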