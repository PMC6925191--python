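"""Synthetic overnight cohorts with stage-dependent physiology.

Generates subject-nights carrying the statistical structure the staging
analysis assumes, with full ground truth:

* a first-order Markov hypnogram at the 30-s epoch level, calibratable so
  its stationary distribution reproduces a target sleep architecture
  (stage percentages, sleep efficiency, mean bout lengths);
* an RR-interval process with stage-dependent mean heart rate and
  low-/high-frequency autonomic modulation, rendered into three chest ECG
  channels via a fixed QRS template plus drift, noise, and artifact bursts;
* wrist acceleration as slowly drifting gravity plus Poisson movement
  bursts whose rate is stage-dependent (wake moves, slow-wave sleep does
  not);
* eight skin-temperature channels in which distal sites relax toward an
  elevated set point after sleep onset (the distal-to-proximal gradient
  rising with sleep) while proximal sites follow a slow decline-then-rise;
* an actigraph count channel computed from the same wrist motion but with a
  deliberately injected clock offset.

Defaults reproduce the sleep architecture of a healthy young-adult cohort:
stage 2 51.6 %, SWS 27.0 %, REM 16.9 % of sleep, sleep efficiency 88.9 %,
sleep onset latency 15.1 (11.4) min.  Heart-rate and temperature parameters
are documented physiological assumptions (NREM lowers heart rate, REM raises
and destabilizes it, distal skin warms at sleep onset), not cohort claims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .align import per_second_activity
from .io_model import (
    ChannelSeries,
    GroundTruth,
    Hypnogram,
    Recording,
    StageLabel,
    ValidationError,
)

__all__ = [
    "SimConfig",
    "STAGE_ORDER",
    "REFERENCE_STAGE_PERCENT",
    "REFERENCE_SLEEP_EFFICIENCY",
    "DEFAULT_MEAN_BOUT_EPOCHS",
    "SOL_MEAN_MIN",
    "SOL_SD_MIN",
    "calibrate_transition_matrix",
    "expected_onset_latency_min",
    "simulate_hypnogram",
    "simulate_rr_series",
    "synthesize_ecg",
    "simulate_accelerometer",
    "simulate_temperature",
    "simulate_actigraph",
    "generate_cohort",
]

STAGE_ORDER = ("W", "N1", "N2", "SWS", "REM")
_IDX = {s: i for i, s in enumerate(STAGE_ORDER)}

#: Healthy young-adult sleep architecture used for default calibration.
REFERENCE_STAGE_PERCENT = {"N1": 4.4, "N2": 51.6, "SWS": 27.0, "REM": 16.9}
REFERENCE_SLEEP_EFFICIENCY = 88.9
SOL_MEAN_MIN = 15.1
SOL_SD_MIN = 11.4

#: Mean bout lengths (epochs) chosen as a plausible degree of night
#: fragmentation: ~1 min awakenings and stage-1 visits, ~3 min stage-2
#: bouts, ~5 min slow-wave and REM bouts.
DEFAULT_MEAN_BOUT_EPOCHS = {"W": 2.0, "N1": 2.0, "N2": 6.0, "SWS": 10.0, "REM": 10.0}


def expected_onset_latency_min(mean: float = SOL_MEAN_MIN, sd: float = SOL_SD_MIN) -> float:
    """Mean of the truncated-at-zero normal sleep-onset-latency draw."""
    if sd <= 0:
        return max(0.0, mean)
    alpha = -mean / sd
    phi = math.exp(-0.5 * alpha * alpha) / math.sqrt(2 * math.pi)
    Phi = 0.5 * math.erfc(-alpha / math.sqrt(2.0))
    return mean + sd * phi / (1.0 - Phi)


def _balance_flow(nu: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Flow matrix with row and column sums ``nu`` on the given support.

    Forced entries (a column whose remaining support is a single row, or
    vice versa) are assigned first, so the remaining transportation problem
    is strictly interior and RAS/Sinkhorn balancing converges geometrically.
    """
    n = len(nu)
    supply = nu.astype(float).copy()
    demand = nu.astype(float).copy()
    m = mask.copy()
    F = np.zeros((n, n))

    changed = True
    while changed:
        changed = False
        for j in range(n):
            if demand[j] <= 1e-15:
                m[:, j] = False
                continue
            rows = [i for i in range(n) if m[i, j] and supply[i] > 1e-15]
            if len(rows) == 1:
                i = rows[0]
                amt = min(supply[i], demand[j])
                F[i, j] += amt
                supply[i] -= amt
                demand[j] -= amt
                changed = True
        for i in range(n):
            if supply[i] <= 1e-15:
                m[i, :] = False
                continue
            cols = [j for j in range(n) if m[i, j] and demand[j] > 1e-15]
            if len(cols) == 1:
                j = cols[0]
                amt = min(supply[i], demand[j])
                F[i, j] += amt
                supply[i] -= amt
                demand[j] -= amt
                changed = True

    rows_left = supply > 1e-15
    cols_left = demand > 1e-15
    if rows_left.any():
        G = np.outer(supply, demand) * m
        for _ in range(50000):
            rs = G.sum(axis=1)
            G[rows_left] *= (supply[rows_left] / np.where(
                rs[rows_left] > 0, rs[rows_left], 1.0
            ))[:, None]
            cs = G.sum(axis=0)
            G[:, cols_left] *= demand[cols_left] / np.where(
                cs[cols_left] > 0, cs[cols_left], 1.0
            )
            if (
                np.abs(G.sum(axis=1) - supply)[rows_left].max() < 1e-13
                and np.abs(G.sum(axis=0) - demand)[cols_left].max() < 1e-13
            ):
                break
        F += G
    return F


def _default_allowed_jumps() -> np.ndarray:
    """Structural support of the jump chain: REM entered only from N2."""
    m = np.ones((5, 5), dtype=bool)
    np.fill_diagonal(m, False)
    rem = _IDX["REM"]
    for s in ("W", "N1", "SWS"):
        m[_IDX[s], rem] = False
    return m


def calibrate_transition_matrix(
    target_stage_percent: Mapping[str, float],
    target_sleep_efficiency: float,
    mean_bout_epochs: Mapping[str, float],
    *,
    expected_onset_min: Optional[float] = None,
    duration_h: float = 8.0,
    allowed_jumps: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Row-stochastic 5x5 epoch transition matrix hitting a sleep architecture.

    The diagonal is fixed by the geometric bout-length identity
    ``p_stay = 1 - 1/mean_bout``; off-diagonal mass is balanced (RAS
    iteration on the jump-chain flow matrix, honouring structural zeros such
    as "REM only from N2") so the chain's stationary distribution equals the
    target: sleep stages in the given proportions and a wake share derived
    from the sleep-efficiency target.

    Because the night simulator prepends a forced wake prefix of expected
    length ``expected_onset_min`` (default: the mean of the truncated-normal
    onset draw), the stationary wake share is compensated downward so the
    whole-night efficiency matches.  Pass ``expected_onset_min=0`` for a
    chain whose stationary wake share is exactly ``1 - SE/100``.
    """
    pct = {s: float(target_stage_percent.get(s, 0.0)) for s in STAGE_ORDER[1:]}
    if any(v < 0 for v in pct.values()):
        raise ValidationError("stage percentages must be nonnegative")
    total = sum(pct.values())
    # printed stage tables often sum to 99.9 or 100.1; renormalize within 0.5
    if not math.isclose(total, 100.0, abs_tol=0.5):
        raise ValidationError(f"sleep-stage percentages must sum to 100, got {total}")
    pct = {s: 100.0 * v / total for s, v in pct.items()}
    if not 0.0 < target_sleep_efficiency <= 100.0:
        raise ValidationError("sleep efficiency must be in (0, 100]")
    bouts = {s: float(mean_bout_epochs[s]) for s in STAGE_ORDER}
    if any(b < 1.0 for b in bouts.values()):
        raise ValidationError("mean bout lengths below one epoch are infeasible")

    if expected_onset_min is None:
        expected_onset_min = expected_onset_latency_min()
    d_epochs = duration_h * 120.0
    onset_epochs = min(expected_onset_min * 2.0, d_epochs)
    wake_total = d_epochs * (1.0 - target_sleep_efficiency / 100.0)
    denom = d_epochs - onset_epochs
    pi_w = max(0.0, (wake_total - onset_epochs) / denom) if denom > 0 else 0.0

    pi = np.empty(5)
    pi[0] = pi_w
    for s, v in pct.items():
        pi[_IDX[s]] = (1.0 - pi_w) * v / 100.0

    d = np.array([1.0 - 1.0 / bouts[s] for s in STAGE_ORDER])
    q = pi * (1.0 - d)  # stationary jump-chain weights
    active = q > 1e-15
    mask = _default_allowed_jumps() if allowed_jumps is None else np.asarray(
        allowed_jumps, dtype=bool
    )
    mask = mask & np.outer(active, active)

    nu = np.where(active, q, 0.0)
    nu = nu / nu.sum()
    F = _balance_flow(nu, mask)

    P = np.zeros((5, 5))
    for i in range(5):
        if active[i]:
            jump = F[i] / nu[i]
            jump_sum = jump.sum()
            if jump_sum > 0:
                jump = jump / jump_sum
            P[i] = (1.0 - d[i]) * jump
            P[i, i] = d[i]
        else:
            # state with zero stationary mass: keep the diagonal, dump the
            # rest on the first active sleep state (unreachable anyway)
            P[i, i] = d[i]
            tgt = next(j for j in range(5) if active[j] and j != i)
            P[i, tgt] = 1.0 - d[i]

    if np.abs(P.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValidationError("calibration failed: rows not stochastic")
    resid = np.abs(pi @ P - pi).max()
    if resid > 1e-9:
        raise ValidationError(
            f"calibration failed: stationary residual {resid:.2e} "
            "(targets may be infeasible under the structural-zero pattern)"
        )
    return P


_DEFAULT_P_CACHE: Optional[np.ndarray] = None


def _default_transition_matrix() -> np.ndarray:
    global _DEFAULT_P_CACHE
    if _DEFAULT_P_CACHE is None:
        _DEFAULT_P_CACHE = calibrate_transition_matrix(
            REFERENCE_STAGE_PERCENT, REFERENCE_SLEEP_EFFICIENCY, DEFAULT_MEAN_BOUT_EPOCHS
        )
    return _DEFAULT_P_CACHE.copy()


def _stage_map(**kw: float) -> dict[str, float]:
    return {s: float(kw[s]) for s in STAGE_ORDER}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    All per-stage maps are keyed by stage token (W, N1, N2, SWS, REM).
    Defaults encode the study conditions the generator emulates; the ECG
    rate defaults to 1000 Hz (the device rate) while desk-scale analyses
    typically pass 250 Hz — parameters are in physical units, so the code
    path is identical.
    """

    transition_matrix: Optional[np.ndarray] = None
    initial_stage: str = "W"
    # cardiac: NREM lowers HR, SWS most; REM raises it and its variability
    stage_hr_mean: dict[str, float] = field(
        default_factory=lambda: _stage_map(W=70.0, N1=62.0, N2=58.0, SWS=55.0, REM=68.0)
    )
    stage_hr_sd: dict[str, float] = field(
        default_factory=lambda: _stage_map(W=4.0, N1=3.0, N2=2.5, SWS=1.5, REM=5.0)
    )
    stage_lf_amp: dict[str, float] = field(  # ms at 0.1 Hz
        default_factory=lambda: _stage_map(W=25.0, N1=20.0, N2=15.0, SWS=8.0, REM=30.0)
    )
    stage_hf_amp: dict[str, float] = field(  # ms at 0.25 Hz
        default_factory=lambda: _stage_map(W=10.0, N1=15.0, N2=20.0, SWS=25.0, REM=8.0)
    )
    # motion
    movement_burst_rate: dict[str, float] = field(  # bursts/min
        default_factory=lambda: _stage_map(W=3.0, N1=0.3, N2=0.1, SWS=0.02, REM=0.05)
    )
    burst_amp: float = 0.3  # g
    accel_noise_sd: float = 0.003  # g
    # temperature
    temp_distal_base: float = 31.5  # degC
    temp_proximal_base: float = 34.5
    dpg_rise: float = 2.5  # degC distal asymptotic rise after sleep onset
    temp_tau: float = 20.0  # min
    temp_proximal_swing: float = 0.5  # degC slow proximal decline amplitude
    temp_noise_sd: float = 0.05
    # ECG rendering
    ecg_noise_sd: float = 0.02  # mV
    artifact_rate: float = 2.0  # artifacts/h
    artifact_gain: float = 20.0
    # clocks
    actigraph_offset: float = 37.0  # s, injected actigraph clock error
    ecg_offset: float = 0.0  # s, injected wearable-ECG clock error
    # rates / duration
    ecg_rate: float = 1000.0
    accel_rate: float = 62.5
    temp_rate: float = 1.0 / 60.0
    duration: float = 8.0  # h
    # sleep-onset forcing; None disables the forced wake prefix
    sol_mean_min: Optional[float] = SOL_MEAN_MIN
    sol_sd_min: float = SOL_SD_MIN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_matrix is None:
            self.transition_matrix = _default_transition_matrix()
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        for s, hr in self.stage_hr_mean.items():
            if not 30.0 < hr < 180.0:
                raise ValidationError(f"stage_hr_mean[{s}]={hr} outside (30, 180) bpm")
        for name in ("ecg_rate", "accel_rate", "temp_rate", "duration"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration * 3600.0 / 30.0))

    @property
    def duration_s(self) -> float:
        return self.duration * 3600.0

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator for one simulator stage."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


def _validate_stochastic(P: np.ndarray) -> None:
    if P.shape != (5, 5) or np.any(P < -1e-12):
        raise ValidationError("transition matrix must be 5x5 nonnegative")
    if np.abs(P.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValidationError("transition matrix rows must sum to 1")


def simulate_hypnogram(config: SimConfig) -> Hypnogram:
    """Draw one night of 30-s stage labels from the configured Markov chain.

    When onset forcing is enabled (the default) a truncated-normal
    sleep-onset latency is drawn, that many epochs are scored wake, and the
    chain starts in N1 at onset; afterwards wake can recur as scored
    awakenings.  With ``sol_mean_min=None`` the chain simply starts at
    ``initial_stage`` on epoch 0.
    """
    P = np.asarray(config.transition_matrix, dtype=float)
    _validate_stochastic(P)
    rng = config.rng(1)
    n = config.n_epochs
    cum = np.cumsum(P, axis=1)

    labels = np.empty(n, dtype=object)
    if config.sol_mean_min is not None:
        sol = -1.0
        while sol < 0.0:
            sol = rng.normal(config.sol_mean_min, config.sol_sd_min)
        onset = min(n, int(round(sol * 2.0)))
        labels[:onset] = "W"
        if onset >= n:
            return Hypnogram(tuple(StageLabel(s) for s in labels))
        state = _IDX["N1"]
        labels[onset] = "N1"
        start = onset + 1
    else:
        state = _IDX[config.initial_stage]
        labels[0] = STAGE_ORDER[state]
        start = 1

    u = rng.random(n)
    for k in range(start, n):
        state = int(np.searchsorted(cum[state], u[k]))
        labels[k] = STAGE_ORDER[state]
    return Hypnogram(tuple(StageLabel(s) for s in labels))


def _stage_of_time(hyp: Hypnogram) -> np.ndarray:
    """Stage token per epoch as an object array (helper)."""
    return hyp.as_array()


def simulate_rr_series(hyp: Hypnogram, config: SimConfig) -> np.ndarray:
    """Cumulative R-peak times (s) with stage-dependent RR dynamics.

    Within each epoch, RR(t) = 60000/HR(stage) + LF sin(2 pi 0.1 t)
    + HF sin(2 pi 0.25 t) + N(0, sd) ms, where sd is the stage heart-rate SD
    mapped onto the RR scale.  Intervals are clipped inside (300, 2000) ms so
    every generated gap is physiologic.
    """
    rng = config.rng(2)
    stages = hyp.as_array()
    dur = hyp.duration_s
    peaks = []
    t = float(rng.uniform(0.0, 0.5))
    while t < dur:
        stage = stages[min(len(stages) - 1, int(t // hyp.epoch_length))]
        hr = config.stage_hr_mean[stage]
        base = 60000.0 / hr
        sd_ms = 60000.0 * config.stage_hr_sd[stage] / hr**2
        rr = (
            base
            + config.stage_lf_amp[stage] * math.sin(2 * math.pi * 0.1 * t)
            + config.stage_hf_amp[stage] * math.sin(2 * math.pi * 0.25 * t)
            + rng.normal(0.0, sd_ms)
        )
        rr = min(max(rr, 320.0), 1990.0)
        t += rr / 1000.0
        peaks.append(t)
    if peaks and peaks[-1] >= dur:
        peaks.pop()
    return np.asarray(peaks)


def _qrs_template(tt: np.ndarray) -> np.ndarray:
    """Symmetric QRS-like shape (mV for unit amplitude), peak at t=0."""
    r = np.exp(-0.5 * (tt / 0.008) ** 2)
    q = -0.15 * np.exp(-0.5 * ((tt + 0.025) / 0.008) ** 2)
    s = -0.15 * np.exp(-0.5 * ((tt - 0.025) / 0.008) ** 2)
    return r + q + s


_ECG_LOCATIONS = ("chest_1", "chest_2", "chest_3")
_ECG_CHANNEL_GAIN = (0.8, 1.0, 1.2)


def synthesize_ecg(
    r_peaks: np.ndarray, config: SimConfig
) -> tuple[list[ChannelSeries], GroundTruth]:
    """Render three chest ECG channels from an R-peak train.

    Each channel is a per-channel-scaled QRS template train plus baseline
    drift, white noise, and Poisson artifact windows in which the noise is
    multiplied by ``artifact_gain``.  The injected wearable clock error
    (``ecg_offset``) shifts the reported timestamps; ground truth records the
    true peak times, artifact windows, and the injected lag.
    """
    rng = config.rng(3)
    rate = config.ecg_rate
    dur = config.duration_s
    n = int(round(dur * rate))
    grid = np.arange(n) / rate
    r_peaks = np.asarray(r_peaks, dtype=float)

    template_sum = np.zeros(n)
    half = int(round(0.06 * rate))
    for p in r_peaks:
        ci = int(round(p * rate))
        a, b = max(0, ci - half), min(n, ci + half + 1)
        if a >= b:
            continue
        template_sum[a:b] += _qrs_template(grid[a:b] - p)

    channels: list[ChannelSeries] = []
    artifact_windows: dict[str, list[tuple[float, float]]] = {}
    n_art_expected = config.artifact_rate * config.duration
    for loc, gain in zip(_ECG_LOCATIONS, _ECG_CHANNEL_GAIN):
        drift = 0.1 * np.sin(2 * np.pi * 0.05 * grid + rng.uniform(0, 2 * np.pi))
        drift += 0.05 * np.sin(2 * np.pi * 0.13 * grid + rng.uniform(0, 2 * np.pi))
        noise = rng.normal(0.0, config.ecg_noise_sd, n) if config.ecg_noise_sd > 0 else np.zeros(n)
        wins: list[tuple[float, float]] = []
        n_art = rng.poisson(n_art_expected) if n_art_expected > 0 else 0
        for _ in range(n_art):
            start = float(rng.uniform(0.0, dur))
            length = float(rng.uniform(2.0, 10.0))
            end = min(dur, start + length)
            a, b = int(start * rate), int(end * rate)
            noise[a:b] *= config.artifact_gain
            wins.append((start, end))
        wins.sort()
        artifact_windows[loc] = wins
        values = gain * template_sum + drift + noise
        channels.append(
            ChannelSeries(
                timestamps=grid - config.ecg_offset,
                values=values,
                nominal_rate=rate,
                location=loc,
                modality="ecg",
                units="mV",
            )
        )
    gt = GroundTruth(
        r_peak_times=r_peaks,
        artifact_windows=artifact_windows,
        injected_lags={"ecg": config.ecg_offset} if config.ecg_offset else {},
    )
    return channels, gt


def simulate_accelerometer(
    hyp: Hypnogram, config: SimConfig
) -> list[ChannelSeries]:
    """Two wrist tri-axial acceleration channels (non-dominant, dominant).

    Baseline is a slowly reorienting gravity vector; movement appears as
    Poisson bursts of 3-8 Hz band-limited oscillation whose rate depends on
    the sleep stage (wake moves far more than sleep).
    """
    rate = config.accel_rate
    dur = hyp.duration_s
    n = int(round(dur * rate))
    grid = np.arange(n) / rate
    stages = hyp.as_array()
    out = []
    for ci, loc in enumerate(("wrist_nd", "wrist_d")):
        rng = config.rng(4 + ci)
        phi = 0.3 * np.sin(2 * np.pi * grid / 5400.0 + rng.uniform(0, 2 * np.pi))
        psi = 0.2 * np.sin(2 * np.pi * grid / 7200.0 + rng.uniform(0, 2 * np.pi))
        vals = np.column_stack(
            [np.sin(phi), np.cos(phi) * np.sin(psi), np.cos(phi) * np.cos(psi)]
        )
        if config.accel_noise_sd > 0:
            vals += rng.normal(0.0, config.accel_noise_sd, (n, 3))
        for k, stage in enumerate(stages):
            lam = config.movement_burst_rate[stage] * (hyp.epoch_length / 60.0)
            for _ in range(rng.poisson(lam)):
                start = hyp.epoch_start(k) + rng.uniform(0.0, hyp.epoch_length)
                length = rng.uniform(0.3, 1.5)
                a = int(start * rate)
                b = min(n, int((start + length) * rate))
                if a >= b or a >= n:
                    continue
                tt = grid[a:b] - start
                window = np.hanning(b - a)
                for axis in range(3):
                    f = rng.uniform(3.0, 8.0)
                    amp = config.burst_amp * rng.uniform(0.5, 1.0)
                    vals[a:b, axis] += amp * window * np.sin(
                        2 * np.pi * f * tt + rng.uniform(0, 2 * np.pi)
                    )
        out.append(
            ChannelSeries(
                timestamps=grid,
                values=vals,
                nominal_rate=rate,
                location=loc,
                modality="accel",
                units="g",
            )
        )
    return out


_DISTAL = ("hand_nd", "hand_d", "ankle_nd", "ankle_d")
_PROXIMAL = ("forehead", "chest", "abdomen", "thigh")


def simulate_temperature(hyp: Hypnogram, config: SimConfig) -> list[ChannelSeries]:
    """Eight skin-temperature channels at 1/60 Hz.

    Distal sites relax with time constant ``temp_tau`` toward
    ``base + dpg_rise`` while asleep and back toward base while awake,
    so the distal-to-proximal gradient rises after sleep onset.  Proximal
    sites follow a slow deterministic decline (three quarters of the night)
    then partial rise, scaled by ``temp_proximal_swing``.
    """
    rng = config.rng(6)
    step_min = 1.0 / (config.temp_rate * 60.0)  # minutes between samples
    n = int(round(hyp.duration_s * config.temp_rate))
    times = np.arange(n) / config.temp_rate
    stages = hyp.as_array()
    asleep = np.array(
        [stages[min(len(stages) - 1, int(t // hyp.epoch_length))] != "W" for t in times]
    )

    distal = np.empty(n)
    T = config.temp_distal_base
    for i in range(n):
        target = config.temp_distal_base + (config.dpg_rise if asleep[i] else 0.0)
        T += (target - T) * (1.0 - math.exp(-step_min / config.temp_tau))
        distal[i] = T

    frac = times / max(times[-1], 1.0)
    swing = config.temp_proximal_swing
    proximal = config.temp_proximal_base - swing * np.where(
        frac < 0.75, frac / 0.75, 1.0 - 0.5 * (frac - 0.75) / 0.25
    )

    out = []
    for loc in _DISTAL:
        noise = rng.normal(0.0, config.temp_noise_sd, n) if config.temp_noise_sd > 0 else 0.0
        out.append(
            ChannelSeries(
                timestamps=times,
                values=distal + noise,
                nominal_rate=config.temp_rate,
                location=loc,
                modality="temp",
                units="degC",
            )
        )
    for loc in _PROXIMAL:
        noise = rng.normal(0.0, config.temp_noise_sd, n) if config.temp_noise_sd > 0 else 0.0
        out.append(
            ChannelSeries(
                timestamps=times,
                values=proximal + noise,
                nominal_rate=config.temp_rate,
                location=loc,
                modality="temp",
                units="degC",
            )
        )
    return out


def simulate_actigraph(
    accel_nd: ChannelSeries, config: SimConfig
) -> tuple[ChannelSeries, dict[str, float]]:
    """Actigraph counts from wrist motion, with an injected clock error.

    Counts are computed with the same per-second peak / dead-band transform
    used for alignment, summed over 30-s windows that actually start at
    ``30k + offset`` in true time while being reported with nominal
    timestamps ``30k`` — i.e. the device clock is wrong by ``offset``
    seconds.  Returns the channel and the injected-lag record.
    """
    rng = config.rng(7)
    sec_times, residuals = per_second_activity(accel_nd)
    offset = int(round(config.actigraph_offset))
    per_epoch = 30
    n_epochs = len(residuals) // per_epoch
    pad = abs(offset)
    padded = np.pad(residuals, (pad, pad))
    counts = np.empty(n_epochs)
    for k in range(n_epochs):
        a = pad + k * per_epoch + offset
        counts[k] = padded[a : a + per_epoch].sum()
    counts *= np.clip(1.0 + rng.normal(0.0, 0.05, n_epochs), 0.0, None)
    ch = ChannelSeries(
        timestamps=sec_times[0] + 30.0 * np.arange(n_epochs),
        values=counts,
        nominal_rate=1.0 / 30.0,
        location="actigraph",
        modality="counts",
        units="counts",
    )
    return ch, {"actigraph": float(config.actigraph_offset)}


@dataclass(frozen=True)
class SubjectVariation:
    """Between-subject physiological offsets drawn once per subject."""

    hr_offset_bpm: float = 0.0
    temp_offset: float = 0.0
    movement_scale: float = 1.0


def _vary_config(base: SimConfig, seed: int, var: SubjectVariation) -> SimConfig:
    cfg = replace(
        base,
        seed=int(seed),
        stage_hr_mean={k: v + var.hr_offset_bpm for k, v in base.stage_hr_mean.items()},
        temp_distal_base=base.temp_distal_base + var.temp_offset,
        temp_proximal_base=base.temp_proximal_base + var.temp_offset,
        movement_burst_rate={
            k: v * var.movement_scale for k, v in base.movement_burst_rate.items()
        },
    )
    return cfg


def generate_cohort(
    config: SimConfig,
    n_subjects: int,
    *,
    subject_variability: bool = True,
) -> list[Recording]:
    """Simulate a cohort of subject-nights with full ground truth.

    Per-subject seeds derive deterministically from the master seed.  With
    ``subject_variability`` (default) each subject receives a small
    heart-rate offset, temperature offset, and movement-rate scale so that
    leave-one-subject-out evaluation faces realistic between-subject shifts.
    """
    if n_subjects < 1:
        raise ValidationError("cohort needs at least one subject")
    master = np.random.default_rng([int(config.seed) % (2**31), 999])
    recordings = []
    for i in range(n_subjects):
        seed_i = int(master.integers(0, 2**31 - 1))
        if subject_variability:
            var = SubjectVariation(
                hr_offset_bpm=float(master.normal(0.0, 2.0)),
                temp_offset=float(master.normal(0.0, 0.2)),
                movement_scale=float(np.exp(master.normal(0.0, 0.2))),
            )
        else:
            var = SubjectVariation()
        cfg = _vary_config(config, seed_i, var)

        hyp = simulate_hypnogram(cfg)
        r_peaks = simulate_rr_series(hyp, cfg)
        ecg_channels, gt = synthesize_ecg(r_peaks, cfg)
        accel_channels = simulate_accelerometer(hyp, cfg)
        temp_channels = simulate_temperature(hyp, cfg)
        actigraph, lags = simulate_actigraph(accel_channels[0], cfg)
        gt.injected_lags.update(lags)

        recordings.append(
            Recording(
                subject_id=f"S{i + 1:02d}",
                channels=ecg_channels + accel_channels + temp_channels + [actigraph],
                hypnogram=hyp,
                ground_truth=gt,
            )
        )
    return recordings
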