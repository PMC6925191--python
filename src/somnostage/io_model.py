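"""Core domain types, recording I/O, stage-resolution mapping, and sleep metrics.

The data model mirrors an overnight multi-device sleep study: a subject wears
wrist accelerometers, chest ECG sensors, and distal/proximal skin-temperature
loggers while a hypnogram (one AASM stage label per 30-s epoch, scored from
lights off to lights on) provides ground truth.  A recording directory on disk
holds one CSV per sensor channel, a ``manifest.json`` describing the channels,
and a ``hypnogram.csv``.

Time convention: all in-memory timestamps are seconds relative to lights off
(t = 0); epoch ``k`` covers the half-open window ``[30k, 30(k+1))``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "StageLabel",
    "Hypnogram",
    "ChannelSeries",
    "GroundTruth",
    "Recording",
    "SleepMetrics",
    "FormatError",
    "ValidationError",
    "map_stage_resolution",
    "resolution_classes",
    "compute_sleep_metrics",
    "read_recording",
    "write_recording",
]

EPOCH_SECONDS = 30.0

#: Body-site tags a channel may carry.
LOCATIONS = frozenset(
    {
        "wrist_nd",
        "wrist_d",
        "chest_1",
        "chest_2",
        "chest_3",
        "hand_nd",
        "hand_d",
        "ankle_nd",
        "ankle_d",
        "forehead",
        "chest",
        "abdomen",
        "thigh",
        "actigraph",
    }
)

MODALITIES = frozenset({"accel", "ecg", "temp", "counts"})

DISTAL_TEMP_LOCATIONS = ("hand_nd", "hand_d", "ankle_nd", "ankle_d")
PROXIMAL_TEMP_LOCATIONS = ("forehead", "chest", "abdomen", "thigh")


class FormatError(ValueError):
    """A file on disk does not match the expected layout."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


class StageLabel(str, Enum):
    """AASM sleep stage of a 30-s epoch."""

    W = "W"
    N1 = "N1"
    N2 = "N2"
    SWS = "SWS"
    REM = "REM"

    @classmethod
    def parse(cls, token: str) -> "StageLabel":
        """Parse a stage token; NREM1/NREM2 are accepted read-aliases."""
        tok = token.strip()
        aliases = {"NREM1": "N1", "NREM2": "N2", "N3": "SWS"}
        tok = aliases.get(tok, tok)
        try:
            return cls(tok)
        except ValueError:
            raise ValidationError(
                f"unknown sleep stage token {token!r}; expected one of "
                f"W, N1, N2, SWS, REM"
            ) from None


SLEEP_STAGES = (StageLabel.N1, StageLabel.N2, StageLabel.SWS, StageLabel.REM)

_RESOLUTION_MAPS = {
    2: {
        StageLabel.W: "Wake",
        StageLabel.N1: "Sleep",
        StageLabel.N2: "Sleep",
        StageLabel.SWS: "Sleep",
        StageLabel.REM: "Sleep",
    },
    3: {
        StageLabel.W: "Wake",
        StageLabel.N1: "NREM",
        StageLabel.N2: "NREM",
        StageLabel.SWS: "NREM",
        StageLabel.REM: "REM",
    },
    4: {
        StageLabel.W: "Wake",
        StageLabel.N1: "Light",
        StageLabel.N2: "Light",
        StageLabel.SWS: "Deep",
        StageLabel.REM: "REM",
    },
}

#: Fixed class order per staging resolution, used for deterministic
#: tie-breaking and report layout.
_RESOLUTION_CLASSES = {
    2: ("Wake", "Sleep"),
    3: ("Wake", "NREM", "REM"),
    4: ("Wake", "Light", "Deep", "REM"),
}


def resolution_classes(resolution: int) -> tuple[str, ...]:
    """Ordered coarse class names for a staging resolution (2, 3 or 4)."""
    try:
        return _RESOLUTION_CLASSES[resolution]
    except KeyError:
        raise ValidationError(f"resolution must be 2, 3 or 4, got {resolution}") from None


def map_stage_resolution(label: StageLabel, resolution: int) -> str:
    """Map a five-stage label onto the 2-, 3-, or 4-class staging scheme.

    2-stage: Wake vs Sleep; 3-stage: Wake vs NREM vs REM; 4-stage:
    Wake vs Light (N1+N2) vs Deep (SWS) vs REM.  Wake always maps to Wake.
    """
    if resolution not in _RESOLUTION_MAPS:
        raise ValidationError(f"resolution must be 2, 3 or 4, got {resolution}")
    return _RESOLUTION_MAPS[resolution][StageLabel(label)]


@dataclass(frozen=True)
class Hypnogram:
    """Scored stage labels, one per 30-s epoch, from lights off to lights on."""

    epoch_labels: tuple[StageLabel, ...]
    epoch_length: float = EPOCH_SECONDS
    lights_off: float = 0.0

    def __post_init__(self) -> None:
        if len(self.epoch_labels) < 1:
            raise ValidationError("hypnogram needs at least one epoch")
        object.__setattr__(
            self, "epoch_labels", tuple(StageLabel(s) for s in self.epoch_labels)
        )

    @property
    def epoch_count(self) -> int:
        return len(self.epoch_labels)

    @property
    def lights_on(self) -> float:
        return self.lights_off + self.epoch_count * self.epoch_length

    @property
    def duration_s(self) -> float:
        return self.epoch_count * self.epoch_length

    def epoch_start(self, k: int) -> float:
        return self.lights_off + k * self.epoch_length

    def as_array(self) -> np.ndarray:
        """Labels as an object array of stage tokens."""
        return np.array([s.value for s in self.epoch_labels], dtype=object)


@dataclass
class ChannelSeries:
    """One sensor stream: timestamps (s relative to lights off) and samples.

    ``values`` is shape (n,) for scalar modalities (ecg mV, temp degC,
    counts) or (n, 3) for tri-axial acceleration in g.
    """

    timestamps: np.ndarray
    values: np.ndarray
    nominal_rate: float
    location: str
    modality: str
    units: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.location not in LOCATIONS:
            raise ValidationError(f"unknown body location {self.location!r}")
        if len(self.timestamps) != len(self.values):
            raise ValidationError("timestamps and values must have equal length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError(
                f"channel ({self.location}, {self.modality}): timestamps must be "
                "strictly increasing"
            )

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def is_triaxial(self) -> bool:
        return self.values.ndim == 2 and self.values.shape[1] == 3

    def copy_with(self, **kw) -> "ChannelSeries":
        base = dict(
            timestamps=self.timestamps,
            values=self.values,
            nominal_rate=self.nominal_rate,
            location=self.location,
            modality=self.modality,
            units=self.units,
        )
        base.update(kw)
        return ChannelSeries(**base)


@dataclass
class GroundTruth:
    """Simulator provenance attached to a synthetic recording."""

    r_peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    artifact_windows: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    injected_lags: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r_peak_times = np.asarray(self.r_peak_times, dtype=float)
        if len(self.r_peak_times) > 1:
            gaps = np.diff(self.r_peak_times)
            if not np.all(gaps > 0):
                raise ValidationError("r_peak_times must be strictly increasing")


@dataclass
class Recording:
    """A subject-night: sensor channels plus the scored hypnogram."""

    subject_id: str
    channels: list[ChannelSeries]
    hypnogram: Hypnogram
    ground_truth: Optional[GroundTruth] = None
    start_iso: str = "2026-01-01T22:00:00"
    applied_corrections: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(c.location, c.modality) for c in self.channels]
        if len(keys) != len(set(keys)):
            raise ValidationError("at most one channel per (location, modality)")

    def channel(self, location: str, modality: str) -> ChannelSeries:
        for c in self.channels:
            if c.location == location and c.modality == modality:
                return c
        raise KeyError(f"no channel at ({location}, {modality})")

    def has_channel(self, location: str, modality: str) -> bool:
        return any(
            c.location == location and c.modality == modality for c in self.channels
        )

    def ecg_channels(self) -> list[ChannelSeries]:
        return [c for c in self.channels if c.modality == "ecg"]


@dataclass
class SleepMetrics:
    """Hypnogram-derived summary measures of overnight sleep quality."""

    total_sleep_time: float  # min
    sleep_efficiency: float  # percent of recording time
    sleep_onset_latency: Optional[float]  # min; None if no sleep
    latency_persistent_sleep: Optional[float]  # min; None if no 10-min run
    waso: float  # min of wake after sleep onset
    stage_percent: dict[str, float]  # percent of sleep time per sleep stage


def compute_sleep_metrics(hyp: Hypnogram) -> SleepMetrics:
    """Standard PSG summary metrics from a hypnogram.

    * SOL: lights off to the first non-wake epoch.
    * TST: 0.5 min per non-wake epoch between lights off and lights on.
    * SE: TST over total recording time, as a percent.
    * WASO: wake time after the first sleep epoch (terminal wake included).
    * LPS: lights off to the start of the first run of >= 20 consecutive
      non-wake epochs (>= 10 contiguous minutes of sleep, any stage);
      None if no such run exists.
    * stage %: share of each sleep stage among non-wake epochs.
    """
    labels = hyp.epoch_labels
    n = hyp.epoch_count
    epoch_min = hyp.epoch_length / 60.0
    is_sleep = np.array([s is not StageLabel.W for s in labels], dtype=bool)
    n_sleep = int(is_sleep.sum())
    total_min = n * epoch_min

    tst = n_sleep * epoch_min
    se = 100.0 * tst / total_min
    if n_sleep == 0:
        return SleepMetrics(
            total_sleep_time=0.0,
            sleep_efficiency=0.0,
            sleep_onset_latency=None,
            latency_persistent_sleep=None,
            waso=0.0,
            stage_percent={},
        )

    first_sleep = int(np.argmax(is_sleep))
    sol = first_sleep * epoch_min
    waso = float(np.sum(~is_sleep[first_sleep:])) * epoch_min

    # first run of >= 20 consecutive sleep epochs
    lps: Optional[float] = None
    run = 0
    for k in range(n):
        if is_sleep[k]:
            run += 1
            if run >= 20:
                lps = (k - 19) * epoch_min
                break
        else:
            run = 0

    stage_percent = {
        s.value: 100.0 * sum(1 for lab in labels if lab is s) / n_sleep
        for s in SLEEP_STAGES
    }
    return SleepMetrics(
        total_sleep_time=tst,
        sleep_efficiency=se,
        sleep_onset_latency=sol,
        latency_persistent_sleep=lps,
        waso=waso,
        stage_percent=stage_percent,
    )


# ---------------------------------------------------------------------------
# Directory I/O
#
# Layout:  manifest.json
#          hypnogram.csv            (header "epoch,stage"; 1-based epoch)
#          <channel file>.csv       (header "t_s,v" or "t_s,x,y,z")
#          ground_truth.json        (optional, synthetic recordings only)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.9g"  # numeric round-trip stable to 9 significant digits


def _channel_filename(ch: ChannelSeries) -> str:
    return f"{ch.location}_{ch.modality}.csv"


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording directory (manifest, per-channel CSVs, hypnogram)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    manifest = {
        "subject_id": rec.subject_id,
        "lights_off_iso": rec.start_iso,
        "lights_on_iso": rec.start_iso,  # informational; offsets are in t_s
        "epoch_length_s": rec.hypnogram.epoch_length,
        "channels": [
            {
                "file": _channel_filename(ch),
                "location": ch.location,
                "modality": ch.modality,
                "rate_hz": ch.nominal_rate,
                "units": ch.units,
            }
            for ch in rec.channels
        ],
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    for ch in rec.channels:
        with open(path / _channel_filename(ch), "w", newline="") as fh:
            w = csv.writer(fh)
            if ch.is_triaxial:
                w.writerow(["t_s", "x", "y", "z"])
                for t, v in zip(ch.timestamps, ch.values):
                    w.writerow(
                        [_FLOAT_FMT % t] + [_FLOAT_FMT % x for x in v]
                    )
            else:
                w.writerow(["t_s", "v"])
                for t, v in zip(ch.timestamps, ch.values):
                    w.writerow([_FLOAT_FMT % t, _FLOAT_FMT % v])

    with open(path / "hypnogram.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "stage"])
        for k, s in enumerate(rec.hypnogram.epoch_labels, start=1):
            w.writerow([k, s.value])

    if rec.ground_truth is not None:
        gt = rec.ground_truth
        with open(path / "ground_truth.json", "w") as fh:
            json.dump(
                {
                    "r_peak_times": [float(_FLOAT_FMT % t) for t in gt.r_peak_times],
                    "artifact_windows": {
                        k: [[float(a), float(b)] for a, b in v]
                        for k, v in gt.artifact_windows.items()
                    },
                    "injected_lags": {k: float(v) for k, v in gt.injected_lags.items()},
                },
                fh,
            )
    return path


def _read_channel_csv(fp: Path, meta: Mapping) -> ChannelSeries:
    with open(fp, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[0] != "t_s":
            raise FormatError(f"{fp.name}: expected header starting with 't_s'")
        rows = [[float(x) for x in row] for row in reader if row]
    arr = np.asarray(rows, dtype=float)
    if arr.size == 0:
        arr = arr.reshape(0, len(header))
    t = arr[:, 0]
    vals = arr[:, 1] if len(header) == 2 else arr[:, 1:]
    return ChannelSeries(
        timestamps=t,
        values=vals,
        nominal_rate=float(meta["rate_hz"]),
        location=meta["location"],
        modality=meta["modality"],
        units=meta.get("units", ""),
    )


def read_recording(path: str | Path) -> Recording:
    """Load a recording directory written by :func:`write_recording`."""
    path = Path(path)
    mf = path / "manifest.json"
    if not mf.exists():
        raise FormatError(f"missing manifest.json in {path}")
    try:
        with open(mf) as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError as e:
        raise FormatError(f"malformed manifest.json: {e}") from None
    for key in ("subject_id", "channels"):
        if key not in manifest:
            raise FormatError(f"manifest.json missing required key {key!r}")

    channels = []
    for meta in manifest["channels"]:
        fp = path / meta["file"]
        if not fp.exists():
            raise FormatError(f"channel file {meta['file']} listed but absent")
        channels.append(_read_channel_csv(fp, meta))

    hyp_fp = path / "hypnogram.csv"
    if not hyp_fp.exists():
        raise FormatError(f"missing hypnogram.csv in {path}")
    labels = []
    with open(hyp_fp, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "stage" not in reader.fieldnames:
            raise FormatError("hypnogram.csv: expected header 'epoch,stage'")
        for row in reader:
            labels.append(StageLabel.parse(row["stage"]))
    hyp = Hypnogram(
        epoch_labels=tuple(labels),
        epoch_length=float(manifest.get("epoch_length_s", EPOCH_SECONDS)),
    )

    gt = None
    gt_fp = path / "ground_truth.json"
    if gt_fp.exists():
        with open(gt_fp) as fh:
            raw = json.load(fh)
        gt = GroundTruth(
            r_peak_times=np.asarray(raw.get("r_peak_times", []), dtype=float),
            artifact_windows={
                k: [tuple(w) for w in v]
                for k, v in raw.get("artifact_windows", {}).items()
            },
            injected_lags=dict(raw.get("injected_lags", {})),
        )

    return Recording(
        subject_id=manifest["subject_id"],
        channels=channels,
        hypnogram=hyp,
        ground_truth=gt,
        start_iso=manifest.get("lights_off_iso", "2026-01-01T22:00:00"),
    )
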