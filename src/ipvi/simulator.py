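"""Synthetic quiet-standing trials with ground-truth COM.

Two generative models are provided:

* a single inverted pendulum (IP) rotating about the ankle, stabilized by
  a proportional-derivative ankle torque plus low-pass-filtered Gaussian
  motor noise — sway generated this way satisfies the COP-error/GRF
  proportionality identically (small angles), so the full estimation
  pipeline can be validated against known COM;
* a two-link (ankle-hip) sagittal model whose hip stiffness controls how
  pendulum-like the sway is: in the stiff-hip limit it converges to the
  composite-body IP, while a compliant hip produces multi-segment sway
  that degrades the IP validity index.

Both integrate fixed-step classical Runge-Kutta (RK4) at the output rate
(with deterministic sub-stepping when joint stiffness demands it), so a
seed fully determines a trial. COP follows the small-angle plate equation
COP = ankle torque / (m g) with massless feet and the plate origin at the
ankle; GRF_x is total mass times the horizontal COM acceleration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as _sps

from .com_estimation import AnthropometricModel
from .signal_io import SwayTimeSeries, TrialMeta

M_TO_MM = 1000.0

#: Sway-angle magnitude treated as a fall (rad). Quiet stance stays well
#: below this; reaching it means the controller lost the pendulum.
FALL_ANGLE_RAD = 0.5

#: RK4 phase budget per substep: dt_sub * (fastest natural frequency)
#: is kept below this, far inside the RK4 stability region (~2.8).
_MAX_PHASE_PER_STEP = 0.5


class FallError(RuntimeError):
    """The simulated body exceeded the fall angle."""


class InstabilityWarning(UserWarning):
    """Configured stiffness cannot statically hold the body upright."""


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IPSimConfig:
    """Single inverted-pendulum simulation parameters.

    The ankle controller is tau = kp*theta + kd*dtheta/dt + eta(t) with
    eta low-pass-filtered Gaussian torque noise of standard deviation
    ``noise_sd`` (N m) and bandwidth ``noise_cutoff_hz``. Static stability
    requires kp above the gravitational toppling stiffness m*g*h; a config
    below it is allowed (it exercises the fall detector) but warns.
    """

    anthro: AnthropometricModel = field(
        default_factory=lambda: AnthropometricModel(m=70.0, h=0.9)
    )
    kp: float = 800.0
    kd: float = 350.0
    noise_sd: float = 0.4
    noise_cutoff_hz: float = 2.0
    duration_s: float = 30.0
    fs: float = 512.0
    seed: int = 0
    theta0: float = 0.0

    def __post_init__(self) -> None:
        if self.kd < 0 or self.noise_sd < 0:
            raise ValueError("kd and noise_sd must be >= 0")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if self.noise_cutoff_hz <= 0 or self.noise_cutoff_hz >= self.fs:
            raise ValueError("noise_cutoff_hz must lie in (0, fs)")
        if self.kp <= self.anthro.mgh:
            warnings.warn(
                f"kp={self.kp} <= toppling stiffness mgh={self.anthro.mgh:.1f}: "
                "statically unstable, expect a fall",
                InstabilityWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class SegmentParams:
    """One rigid segment: mass (kg), length (m), COM offset from the
    proximal joint (m) and inertia about its own COM (kg m^2)."""

    mass: float
    length: float
    com_offset: float
    inertia: float

    def __post_init__(self) -> None:
        for name in ("mass", "length", "com_offset", "inertia"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.com_offset > self.length:
            raise ValueError("com_offset cannot exceed segment length")


def _default_lower() -> SegmentParams:
    # legs: ~35% body mass, ankle-to-hip 0.8 m
    return SegmentParams(mass=24.5, length=0.8, com_offset=0.45, inertia=1.4)


def _default_upper() -> SegmentParams:
    # head-arms-trunk: ~65% body mass, COM 0.32 m above hip
    return SegmentParams(mass=45.5, length=0.8, com_offset=0.32, inertia=4.1)


@dataclass(frozen=True)
class DoubleLinkConfig:
    """Two-link (ankle-hip) sagittal sway model parameters.

    Joint torques are PD restoring torques plus independent filtered noise
    at each joint; ``k_hip`` sets how rigidly the trunk follows the legs.
    Construction checks the linearized closed-loop system and warns when
    it is not asymptotically stable.
    """

    lower: SegmentParams = field(default_factory=_default_lower)
    upper: SegmentParams = field(default_factory=_default_upper)
    k_ankle: float = 800.0
    c_ankle: float = 350.0
    k_hip: float = 600.0
    c_hip: float = 50.0
    noise_sd_ankle: float = 0.4
    noise_sd_hip: float = 0.25
    noise_cutoff_hz: float = 2.0
    duration_s: float = 30.0
    fs: float = 512.0
    seed: int = 0
    phi0: tuple[float, float] = (0.0, 0.0)
    hip_locked: bool = False

    def __post_init__(self) -> None:
        if min(self.k_ankle, self.k_hip) <= 0 or min(self.c_ankle, self.c_hip) < 0:
            raise ValueError("joint stiffness must be > 0 and damping >= 0")
        if min(self.noise_sd_ankle, self.noise_sd_hip) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if not self._linearized_stable():
            warnings.warn(
                "linearized two-link system is not asymptotically stable",
                InstabilityWarning,
                stacklevel=2,
            )

    # -- derived mechanics ---------------------------------------------------

    @property
    def total_mass(self) -> float:
        return self.lower.mass + self.upper.mass

    @property
    def com_height(self) -> float:
        """Composite COM height above the ankle, segments aligned (m)."""
        lo, up = self.lower, self.upper
        return (lo.mass * lo.com_offset + up.mass * (lo.length + up.com_offset)) / (
            self.total_mass
        )

    @property
    def composite_inertia(self) -> float:
        """Whole-body inertia about the ankle, segments aligned (kg m^2)."""
        lo, up = self.lower, self.upper
        return (
            lo.inertia
            + lo.mass * lo.com_offset**2
            + up.inertia
            + up.mass * (lo.length + up.com_offset) ** 2
        )

    def composite_anthro(self, g: float = 9.81) -> AnthropometricModel:
        """Equivalent single-pendulum anthropometrics (rigid-body limit)."""
        return AnthropometricModel(
            m=self.total_mass, h=self.com_height, I_a=self.composite_inertia, g=g
        )

    def _matrices(self, g: float = 9.81):
        lo, up = self.lower, self.upper
        m11 = lo.inertia + lo.mass * lo.com_offset**2 + up.mass * lo.length**2
        m22 = up.inertia + up.mass * up.com_offset**2
        m12c = up.mass * lo.length * up.com_offset  # times cos(phi1 - phi2)
        a = lo.mass * lo.com_offset + up.mass * lo.length  # gravity lever, joint 1
        b = up.mass * up.com_offset  # gravity lever, joint 2
        M0 = np.array([[m11, m12c], [m12c, m22]])
        Kg = np.diag([a * g, b * g])
        Kc = np.array(
            [[self.k_ankle + self.k_hip, -self.k_hip], [-self.k_hip, self.k_hip]]
        )
        Cc = np.array(
            [[self.c_ankle + self.c_hip, -self.c_hip], [-self.c_hip, self.c_hip]]
        )
        return M0, Kg, Kc, Cc

    def _linearized_stable(self, g: float = 9.81) -> bool:
        M0, Kg, Kc, Cc = self._matrices(g)
        Minv = np.linalg.inv(M0)
        A = np.block(
            [
                [np.zeros((2, 2)), np.eye(2)],
                [Minv @ (Kg - Kc), -Minv @ Cc],
            ]
        )
        return bool(np.all(np.linalg.eigvals(A).real < 0))

    def _substeps(self, g: float = 9.81) -> int:
        """Deterministic sub-stepping to keep RK4 stable for stiff hips."""
        M0, Kg, Kc, _ = self._matrices(g)
        w2 = np.linalg.eigvals(np.linalg.solve(M0, Kc + Kg))
        w_max = float(np.sqrt(np.max(np.abs(w2))))
        dt = 1.0 / self.fs
        return max(1, math.ceil(w_max * dt / _MAX_PHASE_PER_STEP))


@dataclass(frozen=True)
class SimulatedStance:
    """Simulator output: measured-like signals plus ground truth.

    ``series`` carries COP (mm) and GRF_x (N) as a force plate would see
    them; ``truth_com_x`` is the exact AP COM (mm) and
    ``truth_joint_angles`` the joint angles (rad), one column per joint.
    """

    series: SwayTimeSeries
    truth_com_x: np.ndarray
    truth_joint_angles: np.ndarray

    @property
    def truth_cop_error(self) -> np.ndarray:
        """Ground-truth COP error x_true - p_x (mm)."""
        return self.truth_com_x - self.series.cop_x


# ---------------------------------------------------------------------------
# Noise and integration helpers
# ---------------------------------------------------------------------------

def _filtered_torque_noise(
    rng: np.random.Generator,
    n_grid: int,
    fs: float,
    cutoff_hz: float,
    sd: float,
    eval_times: np.ndarray,
) -> np.ndarray:
    """Low-pass-filtered Gaussian torque noise sampled at ``eval_times``.

    White noise is generated on a fixed half-step grid (2*fs) regardless of
    integrator sub-stepping, so paired-seed runs of different models share
    the same noise realization; a 2nd-order Butterworth forward pass
    shapes the spectrum and the result is rescaled to the exact target SD.
    """
    fs2 = 2.0 * fs
    n2 = 2 * n_grid - 1
    warm = int(2.0 * fs2)  # discard filter start-up
    white = rng.standard_normal(n2 + warm)
    if sd == 0.0:
        return np.zeros(len(eval_times))
    sos = _sps.butter(2, cutoff_hz, btype="low", fs=fs2, output="sos")
    shaped = _sps.sosfilt(sos, white)[warm:]
    shaped *= sd / np.std(shaped)
    t_base = np.arange(n2) / fs2
    return np.interp(eval_times, t_base, shaped)


def _rk4_eval_times(n_grid: int, fs: float, substeps: int) -> np.ndarray:
    """Times of every RK4 node and midpoint: j * dt_sub / 2."""
    n_half = 2 * substeps * (n_grid - 1) + 1
    return np.arange(n_half) / (2.0 * substeps * fs)


def _integrate_pendulum(
    inertia: float,
    mgh: float,
    kp: float,
    kd: float,
    eta: np.ndarray,
    n_grid: int,
    fs: float,
    substeps: int,
    theta0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """RK4 for I*theta'' = mgh*sin(theta) - (kp*theta + kd*omega + eta).

    ``eta`` holds the noise at every half-substep node. Returns (theta,
    omega) on the output grid. Raises FallError past FALL_ANGLE_RAD.
    """
    dt = 1.0 / (fs * substeps)
    th, om = float(theta0), 0.0
    sin = math.sin
    eta_l = eta.tolist()
    theta_out = np.empty(n_grid)
    omega_out = np.empty(n_grid)
    theta_out[0], omega_out[0] = th, om
    j = 0  # half-step noise cursor
    for k in range(1, n_grid):
        for _ in range(substeps):
            e0, em, e1 = eta_l[j], eta_l[j + 1], eta_l[j + 2]
            j += 2
            a1 = (mgh * sin(th) - kp * th - kd * om - e0) / inertia
            th2 = th + 0.5 * dt * om
            om2 = om + 0.5 * dt * a1
            a2 = (mgh * sin(th2) - kp * th2 - kd * om2 - em) / inertia
            th3 = th + 0.5 * dt * om2
            om3 = om + 0.5 * dt * a2
            a3 = (mgh * sin(th3) - kp * th3 - kd * om3 - em) / inertia
            th4 = th + dt * om3
            om4 = om + dt * a3
            a4 = (mgh * sin(th4) - kp * th4 - kd * om4 - e1) / inertia
            th += dt * (om + 2 * om2 + 2 * om3 + om4) / 6.0
            om += dt * (a1 + 2 * a2 + 2 * a3 + a4) / 6.0
        if abs(th) > FALL_ANGLE_RAD:
            raise FallError(f"fall at t = {k / fs:.2f} s (|theta| > {FALL_ANGLE_RAD})")
        theta_out[k] = th
        omega_out[k] = om
    return theta_out, omega_out


# ---------------------------------------------------------------------------
# Single inverted pendulum
# ---------------------------------------------------------------------------

def simulate_ip(config: IPSimConfig) -> SimulatedStance:
    """Simulate a quiet-standing trial of the single IP model.

    Dynamics: I_a theta'' = m g h sin(theta) - tau with ankle torque
    tau = kp*theta + kd*theta' + eta(t). Outputs the small-angle plate COP
    p_x = tau / (m g), the true COM x = h sin(theta), and
    GRF_x = m * d^2/dt^2 (h sin theta). Deterministic for a fixed seed.
    """
    anthro = config.anthro
    n = int(round(config.duration_s * config.fs)) + 1
    rng = np.random.default_rng(config.seed)
    eval_t = _rk4_eval_times(n, config.fs, 1)
    eta = _filtered_torque_noise(
        rng, n, config.fs, config.noise_cutoff_hz, config.noise_sd, eval_t
    )
    theta, omega = _integrate_pendulum(
        anthro.I_a,
        anthro.mgh,
        config.kp,
        config.kd,
        eta,
        n,
        config.fs,
        1,
        config.theta0,
    )
    eta_grid = eta[::2]
    tau = config.kp * theta + config.kd * omega + eta_grid
    alpha = (anthro.mgh * np.sin(theta) - tau) / anthro.I_a  # theta''
    acc_com = anthro.h * (alpha * np.cos(theta) - omega**2 * np.sin(theta))
    series = SwayTimeSeries(
        fs=config.fs,
        t0=0.0,
        cop_x=tau / (anthro.m * anthro.g) * M_TO_MM,
        grf_x=anthro.m * acc_com,
    )
    return SimulatedStance(
        series=series,
        truth_com_x=anthro.h * np.sin(theta) * M_TO_MM,
        truth_joint_angles=theta[:, None],
    )


# ---------------------------------------------------------------------------
# Two-link (ankle-hip) model
# ---------------------------------------------------------------------------

def simulate_double_link(config: DoubleLinkConfig, g: float = 9.81) -> SimulatedStance:
    """Simulate a quiet-standing trial of the ankle-hip two-link model.

    Absolute segment angles (phi1 legs, phi2 trunk, both from vertical)
    follow the manipulator-form equations of motion with gravity, PD joint
    torques and filtered torque noise per joint. COP comes from the ankle
    torque via the plate equation with the total mass; GRF_x from the
    mass-weighted COM acceleration. With ``hip_locked`` the trunk is
    rigidly attached and the reduced (composite single-pendulum) dynamics
    are integrated instead — hip noise is internal to the rigid body and
    drops out.
    """
    lo, up = config.lower, config.upper
    n = int(round(config.duration_s * config.fs)) + 1
    fs = config.fs
    substeps = 1 if config.hip_locked else config._substeps(g)
    rng = np.random.default_rng(config.seed)
    eval_t = _rk4_eval_times(n, fs, substeps)
    eta_a = _filtered_torque_noise(
        rng, n, fs, config.noise_cutoff_hz, config.noise_sd_ankle, eval_t
    )
    eta_h = _filtered_torque_noise(
        rng, n, fs, config.noise_cutoff_hz, config.noise_sd_hip, eval_t
    )

    m_tot = config.total_mass
    a_lev = lo.mass * lo.com_offset + up.mass * lo.length
    b_lev = up.mass * up.com_offset

    if config.hip_locked:
        comp = config.composite_anthro(g)
        theta, omega = _integrate_pendulum(
            comp.I_a,
            comp.mgh,
            config.k_ankle,
            config.c_ankle,
            eta_a,
            n,
            fs,
            substeps,
            config.phi0[0],
        )
        eta_grid = eta_a[::2]
        tau_a = config.k_ankle * theta + config.c_ankle * omega + eta_grid
        alpha = (comp.mgh * np.sin(theta) - tau_a) / comp.I_a
        acc_com = comp.h * (alpha * np.cos(theta) - omega**2 * np.sin(theta))
        series = SwayTimeSeries(
            fs=fs,
            t0=0.0,
            cop_x=tau_a / (m_tot * g) * M_TO_MM,
            grf_x=m_tot * acc_com,
        )
        return SimulatedStance(
            series=series,
            truth_com_x=comp.h * np.sin(theta) * M_TO_MM,
            truth_joint_angles=np.column_stack([theta, theta]),
        )

    m11 = lo.inertia + lo.mass * lo.com_offset**2 + up.mass * lo.length**2
    m22 = up.inertia + up.mass * up.com_offset**2
    m12f = up.mass * lo.length * up.com_offset
    ka, ca = config.k_ankle, config.c_ankle
    kh, ch = config.k_hip, config.c_hip
    ag, bg = a_lev * g, b_lev * g
    sin, cos = math.sin, math.cos
    dt = 1.0 / (fs * substeps)
    ea_l, eh_l = eta_a.tolist(), eta_h.tolist()

    def deriv(p1, p2, w1, w2, na, nh):
        psi, dpsi = p2 - p1, w2 - w1
        tau_a = -(ka * p1 + ca * w1 + na)
        tau_h = -(kh * psi + ch * dpsi + nh)
        c12 = cos(p1 - p2)
        s12 = sin(p1 - p2)
        m12 = m12f * c12
        r1 = ag * sin(p1) - m12f * s12 * w2 * w2 + tau_a - tau_h
        r2 = bg * sin(p2) + m12f * s12 * w1 * w1 + tau_h
        det = m11 * m22 - m12 * m12
        al1 = (m22 * r1 - m12 * r2) / det
        al2 = (m11 * r2 - m12 * r1) / det
        return al1, al2

    p1, p2 = float(config.phi0[0]), float(config.phi0[1])
    w1 = w2 = 0.0
    phi1 = np.empty(n)
    phi2 = np.empty(n)
    om1 = np.empty(n)
    om2 = np.empty(n)
    phi1[0], phi2[0], om1[0], om2[0] = p1, p2, w1, w2
    j = 0
    for k in range(1, n):
        for _ in range(substeps):
            na0, nam, na1 = ea_l[j], ea_l[j + 1], ea_l[j + 2]
            nh0, nhm, nh1 = eh_l[j], eh_l[j + 1], eh_l[j + 2]
            j += 2
            a11, a12 = deriv(p1, p2, w1, w2, na0, nh0)
            q1 = p1 + 0.5 * dt * w1
            q2 = p2 + 0.5 * dt * w2
            v1 = w1 + 0.5 * dt * a11
            v2 = w2 + 0.5 * dt * a12
            a21, a22 = deriv(q1, q2, v1, v2, nam, nhm)
            q1b = p1 + 0.5 * dt * v1
            q2b = p2 + 0.5 * dt * v2
            v1b = w1 + 0.5 * dt * a21
            v2b = w2 + 0.5 * dt * a22
            a31, a32 = deriv(q1b, q2b, v1b, v2b, nam, nhm)
            q1c = p1 + dt * v1b
            q2c = p2 + dt * v2b
            v1c = w1 + dt * a31
            v2c = w2 + dt * a32
            a41, a42 = deriv(q1c, q2c, v1c, v2c, na1, nh1)
            p1 += dt * (w1 + 2 * v1 + 2 * v1b + v1c) / 6.0
            p2 += dt * (w2 + 2 * v2 + 2 * v2b + v2c) / 6.0
            w1 += dt * (a11 + 2 * a21 + 2 * a31 + a41) / 6.0
            w2 += dt * (a12 + 2 * a22 + 2 * a32 + a42) / 6.0
        if abs(p1) > FALL_ANGLE_RAD or abs(p2 - p1) > FALL_ANGLE_RAD:
            raise FallError(f"fall at t = {k / fs:.2f} s")
        phi1[k], phi2[k], om1[k], om2[k] = p1, p2, w1, w2

    # per-sample torques and accelerations on the output grid
    ea_g, eh_g = eta_a[:: 2 * substeps], eta_h[:: 2 * substeps]
    psi = phi2 - phi1
    dpsi = om2 - om1
    tau_a = -(ka * phi1 + ca * om1 + ea_g)
    tau_h = -(kh * psi + ch * dpsi + eh_g)
    c12 = np.cos(phi1 - phi2)
    s12 = np.sin(phi1 - phi2)
    m12 = m12f * c12
    r1 = ag * np.sin(phi1) - m12f * s12 * om2**2 + tau_a - tau_h
    r2 = bg * np.sin(phi2) + m12f * s12 * om1**2 + tau_h
    det = m11 * m22 - m12**2
    al1 = (m22 * r1 - m12 * r2) / det
    al2 = (m11 * r2 - m12 * r1) / det
    acc_sum = a_lev * (al1 * np.cos(phi1) - om1**2 * np.sin(phi1)) + b_lev * (
        al2 * np.cos(phi2) - om2**2 * np.sin(phi2)
    )  # = m_tot * xdd_com
    com_x = (a_lev * np.sin(phi1) + b_lev * np.sin(phi2)) / m_tot
    series = SwayTimeSeries(
        fs=fs,
        t0=0.0,
        cop_x=-tau_a / (m_tot * g) * M_TO_MM,
        grf_x=acc_sum,
    )
    return SimulatedStance(
        series=series,
        truth_com_x=com_x * M_TO_MM,
        truth_joint_angles=np.column_stack([phi1, phi2]),
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def default_cohort_spec(
    n_subjects: int = 20,
    trials_per_subject: int = 12,
    duration_s: float = 30.0,
    seed: int = 0,
) -> dict:
    """Demo two-group cohort mirroring the study layout.

    Both groups sway as two-link bodies. The older group gets a stiffer
    hip (more pendulum-like, hence larger IPVI) and stronger motor noise
    (larger sway velocity); the younger group a more compliant hip and
    weaker noise. This is a modelling choice producing the expected
    group ordering, not an estimate of real ageing physiology.
    """
    return {
        "seed": seed,
        "n_subjects": n_subjects,
        "trials_per_subject": trials_per_subject,
        "duration_s": duration_s,
        "fs": 512.0,
        "groups": {
            "younger": {
                # lower bound sits just above the linear stability boundary
                # (~255 N m/rad with the default segments): every drawn
                # subject can actually stand
                "k_hip": {"normal": [350.0, 60.0], "bounds": [265.0, 600.0]},
                "noise_sd_ankle": {"normal": [0.35, 0.06], "bounds": [0.2, 0.6]},
                "noise_sd_hip": {"normal": [0.25, 0.04], "bounds": [0.12, 0.4]},
            },
            "older": {
                "k_hip": {"normal": [2500.0, 400.0], "bounds": [1500.0, 4000.0]},
                "noise_sd_ankle": {"normal": [0.55, 0.08], "bounds": [0.3, 0.9]},
                "noise_sd_hip": {"normal": [0.25, 0.04], "bounds": [0.12, 0.4]},
            },
        },
    }


def _draw_param(rng: np.random.Generator, spec):
    if isinstance(spec, (int, float)):
        return float(spec)
    if "normal" in spec:
        mu, sd = spec["normal"]
        v = rng.normal(mu, sd)
        if "bounds" in spec:
            lo_b, hi_b = spec["bounds"]
            v = min(max(v, lo_b), hi_b)
        return float(v)
    if "uniform" in spec:
        lo_b, hi_b = spec["uniform"]
        return float(rng.uniform(lo_b, hi_b))
    raise ValueError(f"unrecognized parameter distribution: {spec!r}")


@dataclass(frozen=True)
class CohortTrial:
    """One synthetic trial with its metadata and generative ground truth."""

    series: SwayTimeSeries
    meta: TrialMeta
    stance: SimulatedStance
    config: DoubleLinkConfig


def synth_cohort(cohort_spec: dict) -> list[CohortTrial]:
    """Generate a reproducible synthetic cohort of quiet-standing trials.

    ``cohort_spec`` lists groups with per-parameter distributions (scalar,
    ``{"normal": [mu, sd], "bounds": [lo, hi]}`` or
    ``{"uniform": [lo, hi]}``) over :class:`DoubleLinkConfig` fields,
    plus counts, duration, rate and a master seed. Per-subject parameters
    and per-trial noise seeds derive from the master seed through a
    spawned ``SeedSequence`` tree, so a spec reproduces byte-identical
    trials. Trials are laid out as 3 per session over 4 sessions when
    ``trials_per_subject`` is divisible by 3.
    """
    for key in ("groups", "n_subjects", "trials_per_subject"):
        if key not in cohort_spec:
            raise ValueError(f"cohort spec missing {key!r}")
    if not cohort_spec["groups"]:
        raise ValueError("cohort spec lists no groups")
    n_sub = int(cohort_spec["n_subjects"])
    n_tr = int(cohort_spec["trials_per_subject"])
    if n_sub < 1 or n_tr < 1:
        raise ValueError("n_subjects and trials_per_subject must be >= 1")
    duration = float(cohort_spec.get("duration_s", 30.0))
    fs = float(cohort_spec.get("fs", 512.0))
    master = np.random.SeedSequence(int(cohort_spec.get("seed", 0)))
    trials_per_session = 3 if n_tr % 3 == 0 else n_tr

    out: list[CohortTrial] = []
    group_names = sorted(cohort_spec["groups"])
    group_seeds = master.spawn(len(group_names))
    for gname, gseq in zip(group_names, group_seeds):
        gspec = cohort_spec["groups"][gname]
        subj_seeds = gseq.spawn(n_sub)
        for s_idx, sseq in enumerate(subj_seeds):
            param_rng = np.random.default_rng(sseq)
            drawn = {k: _draw_param(param_rng, v) for k, v in gspec.items()}
            trial_seeds = sseq.spawn(n_tr)
            for t_idx, tseq in enumerate(trial_seeds):
                cfg = DoubleLinkConfig(
                    duration_s=duration,
                    fs=fs,
                    seed=int(tseq.generate_state(1)[0] % (2**31)),
                    **drawn,
                )
                stance = simulate_double_link(cfg)
                meta = TrialMeta(
                    subject_id=f"{gname[0]}{s_idx + 1:02d}",
                    group=gname if gname in ("younger", "older") else "unknown",
                    session=t_idx // trials_per_session + 1,
                    trial=t_idx % trials_per_session + 1,
                    condition="eyes_open",
                )
                out.append(
                    CohortTrial(series=stance.series, meta=meta, stance=stance, config=cfg)
                )
    return out
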