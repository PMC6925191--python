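"""Shared fixtures: small synthetic cohorts and channels, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from somnostage.io_model import ChannelSeries, Hypnogram, StageLabel
from somnostage.synthetic_data import SimConfig, generate_cohort


def make_hypnogram(tokens: str | list[str]) -> Hypnogram:
    """Hypnogram from space-separated stage tokens, e.g. 'W W N1 N2'."""
    if isinstance(tokens, str):
        tokens = tokens.split()
    return Hypnogram(tuple(StageLabel.parse(t) for t in tokens))


def quiet_config(**kw) -> SimConfig:
    """A deterministic low-noise configuration for small fixtures."""
    base = dict(
        duration=0.5,
        ecg_rate=250.0,
        ecg_noise_sd=0.0,
        artifact_rate=0.0,
        accel_noise_sd=0.0,
        temp_noise_sd=0.0,
        sol_mean_min=None,
        seed=11,
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """Two short subject-nights with defaults scaled to desk size."""
    cfg = SimConfig(duration=1.0, ecg_rate=250.0, seed=5)
    return generate_cohort(cfg, 2)


def constant_series(value: float, n: int = 100, rate: float = 10.0,
                    location: str = "chest_1", modality: str = "ecg") -> ChannelSeries:
    return ChannelSeries(
        timestamps=np.arange(n) / rate,
        values=np.full(n, float(value)),
        nominal_rate=rate,
        location=location,
        modality=modality,
    )
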