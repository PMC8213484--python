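"""Force-plate trial I/O and signal conditioning.

Trials are stored as delimited text (comma or tab) with ``#``-prefixed
header comments carrying metadata (subject, group, session, trial,
condition, units) and named data columns ``time, cop_x, grf_x[, grf_z]``.
Units are seconds, millimetres (COP) and newtons (GRF) throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import signal as _sps

#: Maximum tolerated timestamp jitter relative to a uniform grid (s).
TIME_JITTER_TOL_S = 1e-6

_GROUPS = ("younger", "older", "unknown")
_CONDITIONS = ("eyes_open", "eyes_closed")


class TrialFileError(ValueError):
    """Raised for malformed trial files (missing channels, bad cells...)."""


@dataclass(frozen=True)
class SwayTimeSeries:
    """Uniformly sampled AP COP and AP GRF signals for one trial segment.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds; sample ``k`` is at
        ``t0 + k / fs``.
    cop_x : ndarray
        AP centre-of-pressure displacement in mm.
    grf_x : ndarray
        AP ground-reaction force in N.
    grf_z : ndarray, optional
        Vertical force in N (pass-through channel).
    """

    fs: float
    t0: float
    cop_x: np.ndarray
    grf_x: np.ndarray
    grf_z: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"fs must be positive and finite, got {self.fs}")
        cop = np.asarray(self.cop_x, dtype=float)
        grf = np.asarray(self.grf_x, dtype=float)
        object.__setattr__(self, "cop_x", cop)
        object.__setattr__(self, "grf_x", grf)
        if self.grf_z is not None:
            object.__setattr__(self, "grf_z", np.asarray(self.grf_z, dtype=float))
        n = len(cop)
        if n < 2:
            raise ValueError("series needs at least 2 samples")
        for name in ("cop_x", "grf_x", "grf_z"):
            ch = getattr(self, name)
            if ch is None:
                continue
            if len(ch) != n:
                raise ValueError(f"channel {name} length {len(ch)} != {n}")
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"channel {name} contains non-finite values")
        if not np.isfinite(self.t0):
            raise ValueError("t0 must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.cop_x)

    @property
    def duration_s(self) -> float:
        """Span from first to last sample, (n-1)/fs."""
        return (self.n_samples - 1) / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times t0 + k/fs."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channels(self) -> dict[str, np.ndarray]:
        out = {"cop_x": self.cop_x, "grf_x": self.grf_x}
        if self.grf_z is not None:
            out["grf_z"] = self.grf_z
        return out


@dataclass(frozen=True)
class TrialMeta:
    """Identity of a trial within the session/trial study layout."""

    subject_id: str = "anonymous"
    group: str = "unknown"
    session: int = 1
    trial: int = 1
    condition: str = "eyes_open"

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {_GROUPS}, got {self.group!r}")
        if self.condition not in _CONDITIONS:
            raise ValueError(
                f"condition must be one of {_CONDITIONS}, got {self.condition!r}"
            )
        if self.session < 1 or self.trial < 1:
            raise ValueError("session and trial are 1-based positive integers")


# ---------------------------------------------------------------------------
# Trial file reading / writing
# ---------------------------------------------------------------------------

def write_trial(series: SwayTimeSeries, meta: TrialMeta, path: str | Path) -> None:
    """Write a trial to delimited text with a self-describing header.

    The format is lossless at 17 significant digits (round-trip exact for
    float64). Columns are tab-separated: ``time, cop_x, grf_x[, grf_z]``.
    """
    path = Path(path)
    cols = ["time"] + list(series.channels())
    data = np.column_stack([series.time] + list(series.channels().values()))
    buf = io.StringIO()
    buf.write("# ipvi trial file v1\n")
    buf.write(f"# subject: {meta.subject_id}\n")
    buf.write(f"# group: {meta.group}\n")
    buf.write(f"# session: {meta.session}\n")
    buf.write(f"# trial: {meta.trial}\n")
    buf.write(f"# condition: {meta.condition}\n")
    buf.write("# units: time=s cop=mm grf=N\n")
    buf.write(f"# fs_hz: {series.fs!r}\n")
    buf.write("\t".join(cols) + "\n")
    for row in data:
        buf.write("\t".join(repr(float(v)) for v in row) + "\n")
    path.write_text(buf.getvalue())


def read_trial(path: str | Path) -> tuple[SwayTimeSeries, TrialMeta]:
    """Read a delimited-text trial file.

    Metadata comes from ``# key: value`` comment lines; missing keys fall
    back to :class:`TrialMeta` defaults. The sampling rate is taken from a
    ``fs_hz`` header key when present, otherwise inferred from the median
    timestamp increment. Timestamps deviating from the uniform grid by more
    than ``TIME_JITTER_TOL_S`` are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_kv: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta_kv[k.strip().lower()] = v.strip()
            continue
        fields = line.replace(",", "\t").split("\t")
        fields = [f.strip() for f in fields if f.strip() != ""]
        if header is None:
            header = [f.lower() for f in fields]
            continue
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise TrialFileError(f"{path}:{lineno}: non-numeric cell") from exc
    if header is None or not rows:
        raise TrialFileError(f"{path}: no data")
    for required in ("time", "cop_x", "grf_x"):
        if required not in header:
            raise TrialFileError(f"{path}: missing channel {required!r}")
    widths = {len(r) for r in rows}
    if widths != {len(header)}:
        raise TrialFileError(f"{path}: ragged rows")
    arr = np.asarray(rows, dtype=float)
    col = {name: arr[:, i] for i, name in enumerate(header)}
    t = col["time"]
    if len(t) < 2:
        raise TrialFileError(f"{path}: fewer than 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise TrialFileError(f"{path}: non-monotone time")
    if "fs_hz" in meta_kv:
        fs = float(meta_kv["fs_hz"])
    else:
        fs = 1.0 / float(np.median(dt))
    grid = t[0] + np.arange(len(t)) / fs
    if np.max(np.abs(t - grid)) > TIME_JITTER_TOL_S:
        raise TrialFileError(f"{path}: non-uniform timestamps (jitter > 1e-6 s)")
    series = SwayTimeSeries(
        fs=fs,
        t0=float(t[0]),
        cop_x=col["cop_x"],
        grf_x=col["grf_x"],
        grf_z=col.get("grf_z"),
    )
    meta = TrialMeta(
        subject_id=meta_kv.get("subject", "anonymous"),
        group=meta_kv.get("group", "unknown"),
        session=int(meta_kv.get("session", 1)),
        trial=int(meta_kv.get("trial", 1)),
        condition=meta_kv.get("condition", "eyes_open"),
    )
    return series, meta


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------

def butterworth_lowpass(
    series: SwayTimeSeries, order: int = 6, cutoff_hz: float = 5.0
) -> SwayTimeSeries:
    """Zero-phase Butterworth low-pass filtering of all channels.

    An order-``order`` Butterworth design is applied forward and backward
    (:func:`scipy.signal.filtfilt`), giving zero phase lag and a squared
    magnitude response, so the gain at ``cutoff_hz`` is |H|^2 = 0.5.
    Reflective padding of ``3 * order`` samples suppresses edge transients.

    Zero phase matters here: a causal filter would delay COP relative to
    GRF and bias their correlation.
    """
    if order < 2 or order % 2:
        raise ValueError("order must be even and >= 2")
    if not 0 < cutoff_hz < series.fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={series.fs / 2} Hz)"
        )
    padlen = 3 * order
    if series.n_samples <= padlen:
        raise ValueError(
            f"series too short for stable filtering (need > {padlen} samples)"
        )
    sos = _sps.butter(order, cutoff_hz, btype="low", fs=series.fs, output="sos")
    filtered = {
        name: _sps.sosfiltfilt(sos, ch, padtype="even", padlen=padlen)
        for name, ch in series.channels().items()
    }
    return replace(series, **filtered)


def resample_uniform(
    series: SwayTimeSeries, target_fs: float, include_endpoints: bool = True
) -> SwayTimeSeries:
    """Linear interpolation onto a uniform grid at ``target_fs``.

    With ``include_endpoints`` the grid spans the full input interval
    including both the first and last instants (a 30 s span at 30 Hz gives
    901 points); otherwise the grid holds every multiple of ``1/target_fs``
    from ``t0`` that fits inside the span.

    Linear interpolation is appropriate because signals are low-pass
    filtered well below target rates used in practice.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    span = series.duration_s
    if include_endpoints:
        n_new = int(round(span * target_fs)) + 1
        grid = series.t0 + np.arange(n_new) * (span / (n_new - 1)) if n_new > 1 else None
    else:
        n_new = int(np.floor(span * target_fs)) + 1
        grid = series.t0 + np.arange(n_new) / target_fs if n_new > 1 else None
    if grid is None or n_new < 2:
        raise ValueError("target grid would have < 2 points")
    t_old = series.time
    new = {
        name: np.interp(grid, t_old, ch) for name, ch in series.channels().items()
    }
    fs_new = target_fs if not include_endpoints else (n_new - 1) / span
    return SwayTimeSeries(fs=fs_new, t0=series.t0, **new)


def extract_window(
    series: SwayTimeSeries, start_s: float, end_s: float
) -> SwayTimeSeries:
    """Return samples with time in ``[start_s, end_s]`` (absolute clock)."""
    if end_s <= start_s:
        raise ValueError(f"end {end_s} must exceed start {start_s}")
    t_last = series.t0 + series.duration_s
    eps = TIME_JITTER_TOL_S
    if start_s < series.t0 - eps or end_s > t_last + eps:
        raise ValueError(
            f"window [{start_s}, {end_s}] outside span [{series.t0}, {t_last}]"
        )
    t = series.time
    mask = (t >= start_s - eps) & (t <= end_s + eps)
    idx = np.nonzero(mask)[0]
    if len(idx) < 2:
        raise ValueError("window contains fewer than 2 samples")
    sel = {name: ch[idx] for name, ch in series.channels().items()}
    return SwayTimeSeries(fs=series.fs, t0=float(t[idx[0]]), **sel)
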