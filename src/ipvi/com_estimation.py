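"""AP centre-of-mass reconstruction by zero-point-to-zero-point double
integration.

Under the single inverted-pendulum model of quiet standing, the COP error
e_x = x - p_x (COM minus COP, AP direction) is proportional to the AP
ground-reaction force:

    x(t) - p_x(t) = e_x(t) = I_a / (m^2 g h) * GRF_x(t)

The reconstruction itself is model-free: Newton's law gives
x''(t) = GRF_x(t) / m at every instant, and whenever GRF_x crosses zero
the COM and COP projections coincide (by the proportionality above), so
between consecutive zero instants t_i < t_{i+1}

    x(t) = (1/m) * double-integral of GRF_x from t_i + C1 (t - t_i) + C0

with the constants fixed by the boundary conditions x(t_i) = p_x(t_i) and
x(t_{i+1}) = p_x(t_{i+1}). The inverted-pendulum assumption enters only
through the zero-crossing anchors and the predicted slope above — the
IPVI then measures how well that proportionality actually holds.

Unit bridge: COP enters and COM leaves in mm, GRF in N, anthropometrics in
SI; c2 * GRF is metres and is converted to mm inside this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .signal_io import SwayTimeSeries

M_TO_MM = 1000.0

#: Default merge gap between retained GRF zero crossings (s); about ten
#: samples at 512 Hz. Crossing clusters produced by residual noise around
#: zero are closer than the low-pass filter can resolve and carry no COM
#: information.
DEFAULT_MIN_GAP_S = 0.02


class DegenerateTrajectoryWarning(UserWarning):
    """Emitted when a trajectory has no valid segment."""


@dataclass(frozen=True)
class AnthropometricModel:
    """Subject constants of the sagittal inverted-pendulum model.

    Parameters
    ----------
    m : float
        Body mass excluding the feet, kg.
    h : float
        COM height above the ankle joint, m.
    I_a : float, optional
        Moment of inertia of the body about the ankle in the sagittal
        plane, kg m^2. Defaults to the point-mass value ``m * h**2``; only
        the ratio I_a/(m^2 g h) enters the reconstruction, and the
        point-mass pendulum is the conventional first approximation.
    g : float
        Gravitational acceleration, m/s^2.
    """

    m: float
    h: float
    I_a: Optional[float] = None
    g: float = 9.81

    def __post_init__(self) -> None:
        if self.I_a is None:
            object.__setattr__(self, "I_a", self.m * self.h**2)
        for name in ("m", "h", "I_a", "g"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")

    @property
    def c1(self) -> float:
        """I_a / (m g h) — COP-error per COM acceleration, s^2."""
        return self.I_a / (self.m * self.g * self.h)

    @property
    def c2(self) -> float:
        """I_a / (m^2 g h) — COP-error (m) per unit GRF_x (N)."""
        return self.I_a / (self.m**2 * self.g * self.h)

    @property
    def mgh(self) -> float:
        """Gravitational toppling stiffness m g h, N m/rad."""
        return self.m * self.g * self.h


@dataclass(frozen=True)
class ZeroCrossingSet:
    """Zero instants of GRF_x with their bracketing sample indices.

    ``times[i]`` lies in ``[time[indices[i]], time[indices[i] + 1]]``
    (equal endpoints for an exact-zero sample).
    """

    times: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "indices", idx)
        if len(t) != len(idx):
            raise ValueError("times and indices length mismatch")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("crossing times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ComTrajectory:
    """Reconstructed AP COM with COP error and validity mask.

    ``x`` and ``e_x`` are NaN outside valid samples; ``valid`` marks
    samples inside some crossing-bounded segment. ``e_x = x - cop_x``
    exactly on valid samples.
    """

    x: np.ndarray
    e_x: np.ndarray
    valid: np.ndarray

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    @property
    def valid_fraction(self) -> float:
        return self.n_valid / len(self.valid)


def find_grf_zero_crossings(
    series: SwayTimeSeries, min_gap_s: float = DEFAULT_MIN_GAP_S
) -> ZeroCrossingSet:
    """Locate every zero instant of GRF_x.

    Sign changes between adjacent samples are located by linear
    interpolation. A sample exactly at zero is a crossing at that sample
    time (runs of consecutive zeros collapse to the first). Crossings
    closer than ``min_gap_s`` to the previously retained crossing are
    dropped. An empty set is a legal result.
    """
    if min_gap_s < 0:
        raise ValueError("min_gap_s must be >= 0")
    g = series.grf_x
    t = series.time
    times: list[float] = []
    idxs: list[int] = []

    # exact zeros: first sample of each zero-run
    zero = g == 0.0
    for k in np.nonzero(zero)[0]:
        if k > 0 and zero[k - 1]:
            continue
        times.append(float(t[k]))
        idxs.append(int(k))
    # strict sign changes between adjacent nonzero samples
    prod = g[:-1] * g[1:]
    for k in np.nonzero(prod < 0)[0]:
        tk = t[k] - g[k] * (t[k + 1] - t[k]) / (g[k + 1] - g[k])
        times.append(float(tk))
        idxs.append(int(k))

    if not times:
        return ZeroCrossingSet(np.empty(0), np.empty(0, dtype=int))
    order = np.argsort(times)
    t_sorted = np.asarray(times)[order]
    i_sorted = np.asarray(idxs)[order]
    keep_t: list[float] = []
    keep_i: list[int] = []
    for tk, ik in zip(t_sorted, i_sorted):
        if keep_t and tk - keep_t[-1] < min_gap_s:
            continue
        keep_t.append(tk)
        keep_i.append(ik)
    return ZeroCrossingSet(np.asarray(keep_t), np.asarray(keep_i, dtype=int))


def _interp_at(series: SwayTimeSeries, channel: np.ndarray, t: float) -> float:
    return float(np.interp(t, series.time, channel))


def integrate_segment(
    series: SwayTimeSeries,
    anthro: AnthropometricModel,
    t_i: float,
    t_ip1: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct COM samples on one crossing-bounded segment.

    Returns ``(indices, x_mm)`` where ``indices`` are the grid samples with
    ``t_i <= t <= t_{i+1}`` and ``x_mm`` the COM there. The double integral
    of GRF_x / m is taken cumulatively (trapezoidal rule, twice) on the
    local axis made of the off-grid crossing instants plus the enclosed
    grid samples, so the partial first and last steps are handled exactly
    to trapezoid order; the integration constants pin the result to the
    (interpolated) COP at both crossing instants. Raises ValueError for
    segments under 3 grid samples (the boundary-value problem is
    numerically underdetermined there).
    """
    if not t_i < t_ip1:
        raise ValueError("segment endpoints must satisfy t_i < t_ip1")
    t = series.time
    inside = np.nonzero((t >= t_i) & (t <= t_ip1))[0]
    if len(inside) < 3:
        raise ValueError("segment shorter than 3 samples")

    # local axis: [t_i, grid..., t_ip1]; dedupe on-grid endpoints
    t_loc = t[inside]
    g_loc = series.grf_x[inside]
    pre = t_loc[0] - t_i > 0
    post = t_ip1 - t_loc[-1] > 0
    if pre:
        t_loc = np.concatenate(([t_i], t_loc))
        g_loc = np.concatenate(([_interp_at(series, series.grf_x, t_i)], g_loc))
    if post:
        t_loc = np.concatenate((t_loc, [t_ip1]))
        g_loc = np.concatenate((g_loc, [_interp_at(series, series.grf_x, t_ip1)]))

    v = cumulative_trapezoid(g_loc, t_loc, initial=0.0)  # N s
    d = cumulative_trapezoid(v, t_loc, initial=0.0)  # N s^2
    dd = d / anthro.m * M_TO_MM  # double integral of x'' = GRF_x/m, in mm

    # boundary conditions pin x to the (interpolated) COP at both crossings
    p_i = _interp_at(series, series.cop_x, t_i)
    p_ip1 = _interp_at(series, series.cop_x, t_ip1)
    T = t_ip1 - t_i
    c0 = p_i
    c1_lin = (p_ip1 - p_i - dd[-1]) / T
    x_loc = dd + c0 + c1_lin * (t_loc - t_i)

    lo = 1 if pre else 0
    hi = len(t_loc) - 1 if post else len(t_loc)
    return inside, x_loc[lo:hi]


def estimate_com(
    series: SwayTimeSeries,
    anthro: AnthropometricModel,
    min_gap_s: float = DEFAULT_MIN_GAP_S,
) -> ComTrajectory:
    """Reconstruct the AP COM over a whole trial.

    Integrates every consecutive crossing pair independently; samples
    before the first crossing, after the last, or inside a degenerate
    segment (< 3 samples) are marked invalid. With fewer than two crossings
    the result is all-invalid and a :class:`DegenerateTrajectoryWarning`
    is emitted.
    """
    n = series.n_samples
    x = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    crossings = find_grf_zero_crossings(series, min_gap_s=min_gap_s)
    if len(crossings) < 2:
        warnings.warn(
            "fewer than 2 GRF_x zero crossings: COM undetermined everywhere",
            DegenerateTrajectoryWarning,
            stacklevel=2,
        )
        return ComTrajectory(x=x, e_x=np.full(n, np.nan), valid=valid)
    for t_i, t_ip1 in zip(crossings.times[:-1], crossings.times[1:]):
        try:
            idx, x_seg = integrate_segment(series, anthro, t_i, t_ip1)
        except ValueError:
            continue
        x[idx] = x_seg
        valid[idx] = True
    e_x = np.where(valid, x - series.cop_x, np.nan)
    if not valid.any():
        warnings.warn(
            "no valid segment after degeneracy filtering",
            DegenerateTrajectoryWarning,
            stacklevel=2,
        )
    return ComTrajectory(x=x, e_x=e_x, valid=valid)
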