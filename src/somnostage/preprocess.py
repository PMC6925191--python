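"""Signal cleaning: resampling, ECG noise rejection, composite ECG, filtering.

The ECG cleaning chain follows the wearable-study recipe: per-channel
standard deviations over 10-s clips flag noisy segments (SD more than twice
the mean of the lowest 15 % of clip SDs), individual outliers above
mean + 10 SD are excised with a 5 ms buffer, and the three chest channels are
summed into a composite trace.  Drift is removed with zero-phase Butterworth
high-pass filters (1 Hz cutoff; 1st order for ECG, 5th for acceleration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io_model import ChannelSeries, ValidationError

__all__ = [
    "CleanMask",
    "regularize_sampling",
    "reject_noisy_ecg_clips",
    "remove_ecg_outliers",
    "composite_ecg",
    "highpass_filter",
]


@dataclass
class CleanMask:
    """Per-channel exclusion bookkeeping on the regularized sample grid."""

    n_samples: int
    clip_samples: int  # samples per 10-s clip
    rejected_clip_indices: set[int] = field(default_factory=set)
    removed_sample_spans: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_clips(self) -> int:
        return max(1, math.ceil(self.n_samples / self.clip_samples))

    def clip_bounds(self, c: int) -> tuple[int, int]:
        return c * self.clip_samples, min((c + 1) * self.clip_samples, self.n_samples)

    def sample_excluded(self) -> np.ndarray:
        """Boolean array: True where a sample is rejected or removed."""
        out = np.zeros(self.n_samples, dtype=bool)
        for c in self.rejected_clip_indices:
            a, b = self.clip_bounds(c)
            out[a:b] = True
        for a, b in self.removed_sample_spans:
            out[a:b] = True
        return out


def regularize_sampling(series: ChannelSeries, target_rate: float) -> ChannelSeries:
    """Resample onto a uniform grid at ``target_rate`` over the original span.

    Duplicate timestamps are collapsed by averaging their values before
    linear interpolation, correcting occasional duplicated or missing points.
    """
    t = series.timestamps
    v = series.values
    if len(t) < 2:
        raise ValidationError("cannot regularize a series with < 2 samples")

    # ChannelSeries enforces strictly increasing timestamps, but raw streams
    # arrive as plain arrays too; collapse exact duplicates defensively.
    t = np.asarray(t, dtype=float)
    uniq, inverse, counts = np.unique(t, return_inverse=True, return_counts=True)
    if len(uniq) != len(t):
        if v.ndim == 1:
            sums = np.zeros(len(uniq))
            np.add.at(sums, inverse, v)
            v = sums / counts
        else:
            sums = np.zeros((len(uniq), v.shape[1]))
            np.add.at(sums, inverse, v)
            v = sums / counts[:, None]
        t = uniq
    if len(t) < 2:
        raise ValidationError("cannot regularize a series with < 2 distinct times")

    n_out = int(math.floor((t[-1] - t[0]) * target_rate)) + 1
    grid = t[0] + np.arange(n_out) / target_rate
    if v.ndim == 1:
        out = np.interp(grid, t, v)
    else:
        out = np.column_stack([np.interp(grid, t, v[:, j]) for j in range(v.shape[1])])
    return series.copy_with(timestamps=grid, values=out, nominal_rate=target_rate)


def _clip_sds(values: np.ndarray, clip_samples: int) -> np.ndarray:
    n = len(values)
    n_clips = max(1, math.ceil(n / clip_samples))
    return np.array(
        [np.std(values[c * clip_samples : (c + 1) * clip_samples]) for c in range(n_clips)]
    )


def reject_noisy_ecg_clips(series: ChannelSeries, clip_len: float = 10.0) -> CleanMask:
    """Flag noisy 10-s clips of an ECG channel.

    A clip is rejected when its standard deviation strictly exceeds twice the
    mean of the lowest ``ceil(0.15 * n_clips)`` clip standard deviations.  The
    trailing partial clip is assessed like any other.
    """
    rate = series.nominal_rate
    clip_samples = int(round(clip_len * rate))
    if series.n_samples < 1:
        raise ValidationError("empty series")
    sds = _clip_sds(series.values, clip_samples)
    k = math.ceil(0.15 * len(sds))
    threshold = 2.0 * np.sort(sds)[:k].mean()
    rejected = {int(c) for c in np.nonzero(sds > threshold)[0]}
    return CleanMask(
        n_samples=series.n_samples,
        clip_samples=clip_samples,
        rejected_clip_indices=rejected,
    )


def remove_ecg_outliers(series: ChannelSeries, mask: CleanMask) -> CleanMask:
    """Excise extreme samples within each retained clip.

    A sample more than 10 standard deviations above the clip mean (one-sided)
    is removed together with a 5 ms buffer on each side; overlapping removal
    spans are merged.  Returns a new mask; the input is not modified.
    """
    v = series.values
    rate = series.nominal_rate
    buffer = math.ceil(0.005 * rate)
    spans: list[tuple[int, int]] = list(mask.removed_sample_spans)
    for c in range(mask.n_clips):
        if c in mask.rejected_clip_indices:
            continue
        a, b = mask.clip_bounds(c)
        clip = v[a:b]
        mu, sd = clip.mean(), clip.std()
        idx = np.nonzero(clip > mu + 10.0 * sd)[0]
        for i in idx:
            spans.append((max(a, a + i - buffer), min(b, a + i + buffer + 1)))
    spans.sort()
    merged: list[tuple[int, int]] = []
    for s in spans:
        if merged and s[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], s[1]))
        else:
            merged.append(s)
    return CleanMask(
        n_samples=mask.n_samples,
        clip_samples=mask.clip_samples,
        rejected_clip_indices=set(mask.rejected_clip_indices),
        removed_sample_spans=merged,
    )


def composite_ecg(
    channels: list[ChannelSeries], masks: list[CleanMask]
) -> tuple[ChannelSeries, np.ndarray]:
    """Sum ECG channels into a composite trace, honouring exclusion masks.

    Masked samples contribute zero to the sum.  Returns the composite series
    and a boolean array marking timepoints masked on *all* channels; those
    propagate to clip exclusion downstream.
    """
    if len(channels) < 1:
        raise ValidationError("composite requires at least one channel")
    ref = channels[0]
    for ch in channels[1:]:
        if ch.n_samples != ref.n_samples or not np.allclose(
            ch.timestamps, ref.timestamps, atol=1e-9
        ):
            raise ValidationError("ECG channels must share the regularized grid")
    total = np.zeros(ref.n_samples)
    n_masked = np.zeros(ref.n_samples, dtype=int)
    for ch, m in zip(channels, masks):
        excl = m.sample_excluded()
        vals = np.where(excl, 0.0, ch.values)
        total += vals
        n_masked += excl
    missing = n_masked >= len(channels)
    out = ref.copy_with(values=total, location="chest_1", modality="ecg")
    return out, missing


def highpass_filter(
    series: ChannelSeries, cutoff: float = 1.0, order: int = 1
) -> ChannelSeries:
    """Zero-phase Butterworth high-pass (forward-backward) to remove drift."""
    rate = series.nominal_rate
    if cutoff >= rate / 2:
        raise ValidationError(
            f"cutoff {cutoff} Hz is at or above Nyquist ({rate / 2} Hz)"
        )
    sos = sps.butter(order, cutoff, btype="highpass", fs=rate, output="sos")
    v = series.values
    if v.ndim == 1:
        out = sps.sosfiltfilt(sos, v)
    else:
        out = np.column_stack([sps.sosfiltfilt(sos, v[:, j]) for j in range(v.shape[1])])
    return series.copy_with(values=out)
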