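"""Clip segmentation and the 51-feature matrix.

Epochs bordering a stage transition are removed (scoring is ambiguous
there), the remaining runs of identically-staged epochs are tiled into
non-overlapping 2-minute clips (four 30-s epochs), and each clip yields:

* 33 accelerometer features (11 per axis, time domain): mean, min, max,
  range, interquartile range, SD, kurtosis, RMS, variance, plus a Pearson
  correlation coefficient and its p-value assigned cyclically to axis pairs
  (x: corr(x,y); y: corr(y,z); z: corr(z,x));
* 14 ECG features (see :mod:`somnostage.cardiac`);
* 4 skin-temperature features (mean, min, max, range) of a source series
  chosen by the sensor subset's temperature rule: the distal-to-proximal
  gradient (DPG) with all sensors, the group average with only distal or
  only proximal sensors, a named distal-proximal pair difference, or the
  raw series of a single sensor.

The canonical single-accelerometer full set is exactly 51 columns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from . import cardiac, preprocess
from .io_model import (
    DISTAL_TEMP_LOCATIONS,
    PROXIMAL_TEMP_LOCATIONS,
    ChannelSeries,
    Hypnogram,
    Recording,
    StageLabel,
    ValidationError,
)

__all__ = [
    "Clip",
    "SensorSubset",
    "FeatureMatrix",
    "ProcessedRecording",
    "remove_transition_epochs",
    "segment_clips",
    "accel_features",
    "temp_features",
    "process_recording",
    "build_feature_matrix",
    "ACCEL_STAT_NAMES",
    "CLIP_EPOCHS",
]

CLIP_EPOCHS = 4  # 2-minute clips of four 30-s epochs

ACCEL_STAT_NAMES = (
    "mean",
    "min",
    "max",
    "range",
    "iqr",
    "sd",
    "kurtosis",
    "rms",
    "variance",
    "pearson_r",
    "pearson_p",
)

#: cyclic axis-pair bookkeeping for the Pearson features
_AXIS_PAIRS = {0: (0, 1), 1: (1, 2), 2: (2, 0)}
_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class Clip:
    """A 2-minute analysis window with a single stage label."""

    subject_id: str
    window: tuple[float, float]
    stage: StageLabel
    epoch_indices: tuple[int, ...]


@dataclass(frozen=True)
class SensorSubset:
    """Which sensors feed the feature matrix.

    ``temp_mode`` is one of ``dpg_all``, ``distal_avg``, ``proximal_avg``,
    ``pair:<distal>:<proximal>``, ``single:<location>``, or ``none``.
    """

    accel_locations: tuple[str, ...] = ("wrist_nd",)
    use_ecg: bool = True
    temp_mode: str = "dpg_all"

    def __post_init__(self) -> None:
        if not self.accel_locations and not self.use_ecg and self.temp_mode == "none":
            raise ValidationError("sensor subset must select at least one modality")
        mode = self.temp_mode.split(":")[0]
        if mode not in {"dpg_all", "distal_avg", "proximal_avg", "pair", "single", "none"}:
            raise ValidationError(f"unknown temp_mode {self.temp_mode!r}")

    @property
    def n_features(self) -> int:
        n = 33 * len(self.accel_locations)
        if self.use_ecg:
            n += 14
        if self.temp_mode != "none":
            n += 4
        return n


def remove_transition_epochs(hyp: Hypnogram) -> np.ndarray:
    """Boolean mask of epochs retained after transition removal.

    Epoch ``k`` is removed iff its label differs from either neighbour —
    i.e. every epoch immediately before or after a stage transition drops.
    """
    labels = hyp.as_array()
    n = len(labels)
    keep = np.ones(n, dtype=bool)
    if n > 1:
        diff = labels[1:] != labels[:-1]
        keep[1:] &= ~diff
        keep[:-1] &= ~diff
    return keep


def segment_clips(
    rec: Recording,
    mask: np.ndarray,
    missing_windows: Sequence[tuple[float, float]] = (),
) -> list[Clip]:
    """Tile retained epoch runs into non-overlapping 4-epoch clips.

    Clips are anchored at the start of each maximal run of retained,
    identically-labeled, contiguous epochs; leftover epochs at run ends are
    discarded, as are clips overlapping a missing-data window.
    """
    hyp = rec.hypnogram
    labels = hyp.epoch_labels
    n = hyp.epoch_count
    clips: list[Clip] = []
    k = 0
    while k < n:
        if not mask[k]:
            k += 1
            continue
        run_start = k
        while (
            k + 1 < n
            and mask[k + 1]
            and labels[k + 1] is labels[run_start]
        ):
            k += 1
        run_end = k  # inclusive
        run_len = run_end - run_start + 1
        for c in range(run_len // CLIP_EPOCHS):
            k0 = run_start + c * CLIP_EPOCHS
            w = (hyp.epoch_start(k0), hyp.epoch_start(k0) + CLIP_EPOCHS * hyp.epoch_length)
            if any(a < w[1] and b > w[0] for a, b in missing_windows):
                continue
            clips.append(
                Clip(
                    subject_id=rec.subject_id,
                    window=w,
                    stage=labels[k0],
                    epoch_indices=tuple(range(k0, k0 + CLIP_EPOCHS)),
                )
            )
        k = run_end + 1
    return clips


def _axis_stats(x: np.ndarray) -> dict[str, float]:
    constant = float(x.max() - x.min()) == 0.0
    sd = 0.0 if constant or len(x) < 2 else float(x.std(ddof=1))
    out = {
        "mean": float(x.mean()),
        "min": float(x.min()),
        "max": float(x.max()),
        "range": float(x.max() - x.min()),
        "iqr": 0.0 if constant else float(np.percentile(x, 75) - np.percentile(x, 25)),
        "sd": sd,
        "rms": float(np.sqrt(np.mean(x**2))),
        "variance": sd**2,
    }
    if sd > 0:
        out["kurtosis"] = float(spstats.kurtosis(x, fisher=False, bias=True))
    else:
        out["kurtosis"] = float("nan")
    return out


def accel_features(values: np.ndarray, prefix: str) -> dict[str, float]:
    """The 33 per-clip accelerometer features for one tri-axial slice.

    Kurtosis is the non-excess fourth standardized moment (Gaussian -> 3).
    Zero-variance axes emit NaN sentinels for kurtosis and the correlation
    pair; those are imputed at matrix assembly.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValidationError("accel features require an (n, 3) slice")
    out: dict[str, float] = {}
    for ax in range(3):
        stats = _axis_stats(v[:, ax])
        a, b = _AXIS_PAIRS[ax]
        if np.ptp(v[:, a]) > 0 and np.ptp(v[:, b]) > 0 and len(v) > 2:
            r, p = spstats.pearsonr(v[:, a], v[:, b])
            stats["pearson_r"], stats["pearson_p"] = float(r), float(p)
        else:
            stats["pearson_r"] = stats["pearson_p"] = float("nan")
        for name in ACCEL_STAT_NAMES:
            out[f"{prefix}_{_AXES[ax]}_{name}"] = stats[name]
    return out


def _temp_source(
    temp_channels: dict[str, ChannelSeries], mode: str
) -> tuple[np.ndarray, np.ndarray, str]:
    """(times, values, name prefix) of the mode's source series."""
    parts = mode.split(":")
    kind = parts[0]

    def stack(locs: Iterable[str]) -> np.ndarray:
        return np.mean([temp_channels[l].values for l in locs], axis=0)

    any_ch = next(iter(temp_channels.values()))
    t = any_ch.timestamps
    if kind == "dpg_all":
        vals = stack(DISTAL_TEMP_LOCATIONS) - stack(PROXIMAL_TEMP_LOCATIONS)
        return t, vals, "dpg"
    if kind == "distal_avg":
        return t, stack(DISTAL_TEMP_LOCATIONS), "avg"
    if kind == "proximal_avg":
        return t, stack(PROXIMAL_TEMP_LOCATIONS), "avg"
    if kind == "pair":
        vals = temp_channels[parts[1]].values - temp_channels[parts[2]].values
        return t, vals, "dpg"
    if kind == "single":
        return t, temp_channels[parts[1]].values, "raw"
    raise ValidationError(f"unknown temp mode {mode!r}")


def temp_features(
    temp_channels: dict[str, ChannelSeries],
    window: tuple[float, float],
    mode: str,
) -> dict[str, float]:
    """Mean/min/max/range of the mode's temperature source over a clip.

    Skin temperature samples arrive once a minute, so the clip window is
    extended to the nearest sample before its start when fewer than two
    samples fall inside; fewer than two usable samples yields NaNs.
    """
    t, vals, tag = _temp_source(temp_channels, mode)
    lo, hi = window
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 2:
        before = np.nonzero(t < lo)[0]
        if len(before):
            sel[before[-1]] = True
    names = [f"temp_{tag}_{s}" for s in ("mean", "min", "max", "range")]
    if sel.sum() < 2:
        return {n: float("nan") for n in names}
    x = vals[sel]
    return dict(
        zip(names, [float(x.mean()), float(x.min()), float(x.max()), float(x.max() - x.min())])
    )


@dataclass
class ProcessedRecording:
    """Cleaned signals and detection products for one subject-night."""

    subject_id: str
    hypnogram: Hypnogram
    accel: dict[str, ChannelSeries]  # location -> filtered tri-axial series
    r_peaks: np.ndarray
    missing_windows: list[tuple[float, float]]
    temp: dict[str, ChannelSeries]


def process_recording(
    rec: Recording,
    *,
    accel_rate: Optional[float] = None,
    ecg_rate: Optional[float] = None,
) -> ProcessedRecording:
    """Run the cleaning + detection chain once per recording.

    Acceleration is regularized and high-pass filtered (5th order, 1 Hz);
    the three chest ECG channels are regularized, noise-clip rejected,
    outlier-excised, summed into the composite, high-pass filtered
    (1st order, 1 Hz), wavelet-enhanced, and peak-detected.  Timepoints
    masked on all three ECG channels become missing windows that later drop
    overlapping clips.
    """
    accel: dict[str, ChannelSeries] = {}
    for loc in ("wrist_nd", "wrist_d"):
        if rec.has_channel(loc, "accel"):
            ch = rec.channel(loc, "accel")
            reg = preprocess.regularize_sampling(ch, accel_rate or ch.nominal_rate)
            accel[loc] = preprocess.highpass_filter(reg, cutoff=1.0, order=5)

    r_peaks = np.empty(0)
    missing_windows: list[tuple[float, float]] = []
    ecgs = rec.ecg_channels()
    if ecgs:
        rate = ecg_rate or ecgs[0].nominal_rate
        regs = [preprocess.regularize_sampling(ch, rate) for ch in ecgs]
        masks = [preprocess.reject_noisy_ecg_clips(ch) for ch in regs]
        masks = [preprocess.remove_ecg_outliers(ch, m) for ch, m in zip(regs, masks)]
        composite, missing = preprocess.composite_ecg(regs, masks)
        if missing.any():
            # contiguous missing-sample runs -> time windows
            idx = np.nonzero(missing)[0]
            splits = np.nonzero(np.diff(idx) > 1)[0]
            for seg in np.split(idx, splits + 1):
                missing_windows.append(
                    (composite.timestamps[seg[0]], composite.timestamps[seg[-1]])
                )
        filtered = preprocess.highpass_filter(composite, cutoff=1.0, order=1)
        enhanced = cardiac.wavelet_qrs_enhance(filtered)
        r_peaks = cardiac.detect_r_peaks(enhanced, raw=filtered)

    temp = {
        c.location: c for c in rec.channels if c.modality == "temp"
    }
    return ProcessedRecording(
        subject_id=rec.subject_id,
        hypnogram=rec.hypnogram,
        accel=accel,
        r_peaks=r_peaks,
        missing_windows=missing_windows,
        temp=temp,
    )


@dataclass
class FeatureMatrix:
    """Clips x named features, with stage labels and subject ids."""

    df: pd.DataFrame
    labels: pd.Series  # stage token per row
    subjects: pd.Series
    clip_starts: pd.Series

    @property
    def n_clips(self) -> int:
        return len(self.df)

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    def rows_for_subject(self, subject_id: str) -> np.ndarray:
        return (self.subjects == subject_id).to_numpy()


def _slice(ch: ChannelSeries, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    sel = (ch.timestamps >= lo) & (ch.timestamps < hi)
    return ch.values[sel]


_ACCEL_PREFIX = {"wrist_nd": "acc_nd", "wrist_d": "acc_d"}


def build_feature_matrix(
    cohort: Sequence[Recording] | Sequence[ProcessedRecording],
    subset: SensorSubset = SensorSubset(),
    *,
    accel_rate: Optional[float] = None,
    ecg_rate: Optional[float] = None,
) -> FeatureMatrix:
    """Assemble the feature matrix for a cohort under a sensor subset.

    Accepts raw recordings (processed on the fly) or pre-processed ones
    (e.g. when several subsets are built from the same cohort).  Missing
    sentinels are imputed by the per-subject column median, so no
    information crosses subjects into a leave-one-subject-out fold.
    """
    if len(cohort) == 0:
        raise ValidationError("empty cohort")
    processed = [
        r
        if isinstance(r, ProcessedRecording)
        else process_recording(r, accel_rate=accel_rate, ecg_rate=ecg_rate)
        for r in cohort
    ]

    rows = []
    labels = []
    subjects = []
    starts = []
    for pr in processed:
        mask = remove_transition_epochs(pr.hypnogram)
        rec_stub = Recording(
            subject_id=pr.subject_id,
            channels=[],
            hypnogram=pr.hypnogram,
        )
        clips = segment_clips(rec_stub, mask, pr.missing_windows)
        for clip in clips:
            feats: dict[str, float] = {}
            for loc in subset.accel_locations:
                if loc not in pr.accel:
                    raise ValidationError(f"{pr.subject_id}: no accel channel at {loc}")
                feats.update(
                    accel_features(_slice(pr.accel[loc], clip.window), _ACCEL_PREFIX[loc])
                )
            if subset.use_ecg:
                rr = cardiac.build_rr(pr.r_peaks, clip.window)
                feats.update(
                    {f"ecg_{k}": v for k, v in cardiac.hrv_features(rr).items()}
                )
            if subset.temp_mode != "none":
                feats.update(temp_features(pr.temp, clip.window, subset.temp_mode))
            rows.append(feats)
            labels.append(clip.stage.value)
            subjects.append(pr.subject_id)
            starts.append(clip.window[0])

    if not rows:
        raise ValidationError("cohort produced no clips")
    df = pd.DataFrame(rows)
    subjects_s = pd.Series(subjects, name="subject")

    # per-subject median imputation of missing sentinels
    for col in df.columns[df.isna().any()]:
        med = df.groupby(subjects_s)[col].transform("median")
        df[col] = df[col].fillna(med)
    df = df.fillna(df.median()).fillna(0.0)

    return FeatureMatrix(
        df=df,
        labels=pd.Series(labels, name="stage"),
        subjects=subjects_s,
        clip_starts=pd.Series(starts, name="clip_start_s"),
    )
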