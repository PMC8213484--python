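"""IPVI and COP-velocity features at trial and one-second-window level.

The IP validity index (IPVI) is the Pearson correlation between the COP
error e_x and the AP ground-reaction force over a trial or window: near 1
when sway is pendulum-like, lower when non-ankle joints contribute. The
benchmark postural-steadiness feature is the mean AP COP velocity MV_AP
(path length over duration, mm/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .com_estimation import ComTrajectory
from .signal_io import SwayTimeSeries


@dataclass(frozen=True)
class TrialFeatures:
    """Trial-level feature values.

    ``ipvi`` is NaN when undefined (fewer than 2 valid samples or zero
    variance in either channel); velocities are non-negative mm/s.
    """

    ipvi: float
    mv_ap: float
    n_valid: int
    mv_ml: Optional[float] = None
    mv: Optional[float] = None


@dataclass(frozen=True)
class WindowFeatures:
    """Feature values for one non-overlapping window of a trial."""

    window_index: int
    ipvi: float  # NaN when undefined
    mv_ap: float


def ipvi(
    e_x: np.ndarray, grf_x: np.ndarray, valid_mask: Optional[np.ndarray] = None
) -> float:
    """Pearson correlation between COP error and AP GRF over valid pairs.

    Returns NaN (undefined, never fabricated) when fewer than 2 valid
    pairs remain or either channel has zero variance.
    """
    e_x = np.asarray(e_x, dtype=float)
    grf_x = np.asarray(grf_x, dtype=float)
    if e_x.shape != grf_x.shape:
        raise ValueError("e_x and grf_x must have the same length")
    if valid_mask is None:
        valid_mask = np.isfinite(e_x) & np.isfinite(grf_x)
    else:
        valid_mask = np.asarray(valid_mask, dtype=bool) & np.isfinite(e_x)
    a = e_x[valid_mask]
    b = grf_x[valid_mask]
    if len(a) < 2:
        return math.nan
    a = a - a.mean()
    b = b - b.mean()
    va = float(a @ a)
    vb = float(b @ b)
    if va == 0.0 or vb == 0.0:
        return math.nan
    return float((a @ b) / math.sqrt(va * vb))


def mv_ap(cop_x: np.ndarray, fs: float) -> float:
    """Mean AP COP velocity: total path length / duration, mm/s."""
    cop_x = np.asarray(cop_x, dtype=float)
    if len(cop_x) < 2:
        raise ValueError("need at least 2 samples")
    T = (len(cop_x) - 1) / fs
    return float(np.sum(np.abs(np.diff(cop_x))) / T)


def mv_planar(
    cop_x: np.ndarray, cop_y: np.ndarray, fs: float
) -> tuple[float, float, float]:
    """Planar mean velocity decomposition: returns (mv, mv_ml, mv_ap).

    ``mv`` uses Euclidean increments of the planar COP path; ``cop_y`` is
    the medial-lateral channel.
    """
    cop_x = np.asarray(cop_x, dtype=float)
    cop_y = np.asarray(cop_y, dtype=float)
    if cop_x.shape != cop_y.shape:
        raise ValueError("cop_x and cop_y must have the same length")
    if len(cop_x) < 2:
        raise ValueError("need at least 2 samples")
    T = (len(cop_x) - 1) / fs
    dx = np.diff(cop_x)
    dy = np.diff(cop_y)
    mv = float(np.sum(np.hypot(dx, dy)) / T)
    return mv, float(np.sum(np.abs(dy)) / T), float(np.sum(np.abs(dx)) / T)


def trial_features(series: SwayTimeSeries, traj: ComTrajectory) -> TrialFeatures:
    """IPVI and MV_AP for a whole trial."""
    r = ipvi(traj.e_x, series.grf_x, traj.valid)
    return TrialFeatures(
        ipvi=r, mv_ap=mv_ap(series.cop_x, series.fs), n_valid=traj.n_valid
    )


def windowed_features(
    series: SwayTimeSeries, traj: ComTrajectory, window_s: float = 1.0
) -> list[WindowFeatures]:
    """Per-window IPVI and MV_AP over non-overlapping windows.

    Windows are laid out on the trial clock (floor(duration / window_s)
    windows; a trailing remainder is dropped), so the window count is
    deterministic regardless of the validity mask. IPVI uses only the
    window's valid samples and is NaN when fewer than 2 remain or variance
    vanishes; MV_AP is a plain COP property and uses the full window.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    w = int(round(window_s * series.fs))
    if w < 2:
        raise ValueError("window too short for the sampling rate")
    n_windows = series.n_samples // w
    out: list[WindowFeatures] = []
    for i in range(n_windows):
        sl = slice(i * w, (i + 1) * w)
        r = ipvi(traj.e_x[sl], series.grf_x[sl], traj.valid[sl])
        out.append(
            WindowFeatures(
                window_index=i, ipvi=r, mv_ap=mv_ap(series.cop_x[sl], series.fs)
            )
        )
    return out


def ipvi_median_split(windows: Sequence[WindowFeatures]) -> tuple[float, float]:
    """Mean MV_AP of the larger-IPVI and smaller-IPVI halves of windows.

    Windows with undefined IPVI are excluded. The remaining windows are
    stably sorted by IPVI descending; the first ceil(n/2) form the larger
    half (ties keep input order). Returns
    ``(mean_mv_ap_larger_half, mean_mv_ap_smaller_half)``.
    """
    defined = [w for w in windows if not math.isnan(w.ipvi)]
    if len(defined) < 2:
        raise ValueError("need at least 2 windows with defined IPVI")
    ranked = sorted(defined, key=lambda w: -w.ipvi)  # Python sort is stable
    n_hi = math.ceil(len(ranked) / 2)
    hi = [w.mv_ap for w in ranked[:n_hi]]
    lo = [w.mv_ap for w in ranked[n_hi:]]
    return float(np.mean(hi)), float(np.mean(lo))
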