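"""Shared fixtures: analytic constructions and seeded simulator runs."""

from __future__ import annotations

import numpy as np
import pytest

from ipvi import (
    AnthropometricModel,
    IPSimConfig,
    SwayTimeSeries,
    simulate_ip,
)

FS = 512.0


@pytest.fixture(scope="session")
def anthro() -> AnthropometricModel:
    return AnthropometricModel(m=70.0, h=0.9)


@pytest.fixture(scope="session")
def sinusoid_construction(anthro):
    """COP/GRF pair built to satisfy the pendulum proportionality exactly.

    True COM x*(t) = 10 sin(2 pi 0.4 t) mm over 30 s at 512 Hz;
    GRF_x = m x''* (N, mm-consistent) and p_x = x* - (I_a/(m^2 g h)) GRF_x,
    so the COP error is exactly proportional to GRF_x.
    """
    t = np.arange(int(30 * FS) + 1) / FS
    w = 2 * np.pi * 0.4
    x_true = 10.0 * np.sin(w * t)  # mm
    grf = anthro.m * (-(w**2) * x_true) / 1000.0  # N
    cop = x_true - 1000.0 * anthro.c2 * grf  # mm
    series = SwayTimeSeries(fs=FS, t0=0.0, cop_x=cop, grf_x=grf)
    return series, x_true


@pytest.fixture(scope="session")
def ip_stance():
    """One seeded 30 s inverted-pendulum trial with ground truth."""
    return simulate_ip(IPSimConfig(seed=42))


def make_series(
    cop: np.ndarray, grf: np.ndarray | None = None, fs: float = FS, t0: float = 0.0
) -> SwayTimeSeries:
    cop = np.asarray(cop, dtype=float)
    if grf is None:
        grf = np.zeros_like(cop)
    return SwayTimeSeries(fs=fs, t0=t0, cop_x=cop, grf_x=np.asarray(grf, dtype=float))
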