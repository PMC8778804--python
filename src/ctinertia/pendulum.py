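"""Trifilar-pendulum measurement model.

A trifilar pendulum — a platform hung from three parallel threads of length
``L`` attached at radius ``R`` — measures the moment of inertia of whatever
rests on it. For small torsional oscillation about the vertical axis
through the thread circle's center, the system is a one-degree-of-freedom
harmonic oscillator and its MoI about that axis follows from the period:

    I = m g R^2 tau^2 / (4 pi^2 L)

with ``m`` the total suspended mass. The period comes from fitting a damped
harmonic oscillator to the angular-velocity record of a gyroscope riding on
the platform. Angular displacement and velocity of the damped oscillator:

    x(t)  = X exp(-zeta omega_n t) sin(omega_d t + phi)
    x'(t) = X exp(-zeta omega_n t) [omega_d cos(omega_d t + phi)
                                    - zeta omega_n sin(omega_d t + phi)]

with ``omega_d = omega_n sqrt(1 - zeta^2)``. The gyroscope observes x'(t),
so the fit targets angular velocity directly.

A specimen placed with its CoM a horizontal distance ``D`` from the
platform axis still oscillates about that axis, so the raw difference
measurement overestimates its own-CoM MoI by the parallel-axis term. The
corrected dorsoventral MoI is

    I_dv = (m_b + m_p) g R^2 tau^2 / (4 pi^2 L) - I_p - m_b D^2

where ``m_b``/``m_p`` are specimen and bare-pendulum masses, ``I_p`` the
bare-pendulum MoI, ``tau`` the loaded period and ``D`` the measured offset.
At ``D = 0`` this reduces exactly to the uncorrected difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, signal

from ._util import STANDARD_GRAVITY
from .errors import DomainError, FitError, InsufficientDataError, NoOscillationError

__all__ = [
    "PendulumRig",
    "OscillationTrace",
    "DampedFit",
    "PeriodEstimate",
    "fit_damped_oscillator",
    "period_estimate",
    "rig_moi",
    "specimen_moi_corrected",
    "analytic_block_moi",
    "read_trace_csv",
]


@dataclass
class PendulumRig:
    """Geometry and mass of the bare pendulum (platform + board + gyro)."""

    m_p: float  # kg, pendulum mass without specimen
    R: float  # m, thread attachment radius from the rotation center
    L: float  # m, mean thread length
    g: float = STANDARD_GRAVITY  # m s^-2
    I_p: float | None = None  # kg m^2, bare-rig MoI once measured

    def __post_init__(self):
        for name in ("m_p", "R", "L", "g"):
            if not getattr(self, name) > 0:
                raise DomainError(f"rig parameter {name} must be strictly positive")
        if self.I_p is not None and not self.I_p > 0:
            raise DomainError("I_p must be strictly positive when given")


@dataclass
class OscillationTrace:
    """Uniformly sampled angular-velocity record (gyroscope output)."""

    t: np.ndarray  # s
    omega: np.ndarray  # rad s^-1

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float).ravel()
        self.omega = np.asarray(self.omega, dtype=float).ravel()
        if self.t.size != self.omega.size:
            raise ValueError("t and omega must have equal length")
        if self.t.size < 4:
            raise InsufficientDataError("trace too short")
        dt = np.diff(self.t)
        if np.abs(dt - dt[0]).max() > 1e-9:
            raise ValueError("trace must be uniformly sampled (to 1e-9 s)")

    @property
    def rate(self) -> float:
        """Sampling rate, Hz."""
        return 1.0 / float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class DampedFit:
    """Converged damped-harmonic-oscillator fit of an angular-velocity trace.

    ``X`` and ``phi`` are the displacement amplitude (rad) and phase at the
    start of the fit window.
    """

    zeta: float
    omega_n: float  # rad s^-1
    omega_d: float  # rad s^-1
    X: float  # rad
    phi: float  # rad
    tau: float  # s, damped period 2 pi / omega_d
    residual_rms: float  # rad s^-1

    def __post_init__(self):
        if not 0.0 <= self.zeta < 1.0:
            raise ValueError(f"damping ratio must satisfy 0 <= zeta < 1, got {self.zeta}")
        if abs(self.omega_d - self.omega_n * np.sqrt(1 - self.zeta**2)) > 1e-9 * self.omega_n:
            raise ValueError("omega_d inconsistent with omega_n and zeta")
        if abs(self.tau - 2 * np.pi / self.omega_d) > 1e-9 * self.tau:
            raise ValueError("tau inconsistent with omega_d")


@dataclass
class PeriodEstimate:
    tau: float  # s, mean over repeats
    std: float  # s, sample standard deviation (0 for a single repeat)
    n: int


def _velocity_model(t, X, phi, zeta, omega_d):
    omega_n = omega_d / np.sqrt(1.0 - zeta**2)
    env = X * np.exp(-zeta * omega_n * t)
    arg = omega_d * t + phi
    return env * (omega_d * np.cos(arg) - zeta * omega_n * np.sin(arg))


def fit_damped_oscillator(trace: OscillationTrace, fit_window: float = 60.0) -> DampedFit:
    """Nonlinear least-squares damped-oscillator fit of the trailing window.

    Fitting only the last ``fit_window`` seconds (default 60 s of a ~180 s
    record) avoids release transients. Initial guesses: the damped frequency
    from the dominant discrete-spectrum peak, the damping ratio from the
    logarithmic decrement of successive velocity extrema, and amplitude and
    phase from a linear solve at those values. Time is measured from the
    window start, so ``X``/``phi`` describe the oscillator there.
    """
    if fit_window <= 0:
        raise DomainError("fit_window must be positive")
    if trace.duration < fit_window:
        raise InsufficientDataError(
            f"trace duration {trace.duration:.1f}s shorter than fit window {fit_window}s"
        )
    sel = trace.t >= trace.t[-1] - fit_window
    t = trace.t[sel] - trace.t[sel][0]
    v = trace.omega[sel]
    dt = t[1] - t[0]

    # spectral peak -> omega_d guess; also the oscillation-presence gate
    win = np.hanning(t.size)
    spec = np.abs(np.fft.rfft((v - v.mean()) * win))
    freqs = 2 * np.pi * np.fft.rfftfreq(t.size, dt)
    k = int(np.argmax(spec[1:])) + 1
    floor = np.median(spec[1:])
    if floor > 0 and spec[k] < 10.0 * floor:
        raise NoOscillationError(
            "no dominant spectral peak above the noise floor; trace does not oscillate"
        )
    omega_d0 = freqs[k]
    if omega_d0 <= 0:
        raise NoOscillationError("spectral peak at zero frequency")
    if trace.duration * omega_d0 / (2 * np.pi) < 10:
        raise InsufficientDataError("trace shorter than 10 periods of the fitted mode")

    # log decrement of successive same-sign extrema -> zeta guess
    peaks, _ = signal.find_peaks(np.abs(v))
    zeta0 = 0.005
    if peaks.size >= 4:
        amps = np.abs(v[peaks])
        good = amps > 1e-12 * amps.max()
        amps = amps[good]
        if amps.size >= 4:
            # extrema come every half period; decrement per full cycle
            ratios = amps[:-2] / amps[2:]
            ratios = ratios[ratios > 0]
            if ratios.size:
                delta = float(np.median(np.log(ratios)))
                delta = max(delta, 0.0)
                zeta0 = float(delta / np.sqrt(4 * np.pi**2 + delta**2))
                zeta0 = min(max(zeta0, 0.0), 0.5)

    # linear solve for amplitude/phase at (zeta0, omega_d0)
    omega_n0 = omega_d0 / np.sqrt(1 - zeta0**2)
    env = np.exp(-zeta0 * omega_n0 * t)
    c1 = env * (omega_d0 * np.cos(omega_d0 * t) - zeta0 * omega_n0 * np.sin(omega_d0 * t))
    c2 = env * (-omega_d0 * np.sin(omega_d0 * t) - zeta0 * omega_n0 * np.cos(omega_d0 * t))
    (a, b), *_ = np.linalg.lstsq(np.column_stack([c1, c2]), v, rcond=None)
    x0 = float(np.hypot(a, b))
    phi0 = float(np.arctan2(b, a))

    try:
        popt, _ = optimize.curve_fit(
            _velocity_model,
            t,
            v,
            p0=[max(x0, 1e-12), phi0, zeta0, omega_d0],
            bounds=([0.0, -2 * np.pi, 0.0, 0.5 * omega_d0], [np.inf, 2 * np.pi, 0.999, 1.5 * omega_d0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(
            f"damped-oscillator fit did not converge (omega_d0={omega_d0:.4g}, "
            f"zeta0={zeta0:.4g}): {exc}"
        ) from exc
    X, phi, zeta, omega_d = (float(p) for p in popt)
    omega_n = omega_d / np.sqrt(1 - zeta**2)
    resid = v - _velocity_model(t, X, phi, zeta, omega_d)
    return DampedFit(
        zeta=zeta,
        omega_n=omega_n,
        omega_d=omega_d,
        X=X,
        phi=phi,
        tau=2 * np.pi / omega_d,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def period_estimate(fits) -> PeriodEstimate:
    """Mean period over repeated measurements (unweighted), with scatter."""
    fits = list(fits)
    if not fits:
        raise InsufficientDataError("need at least one fit to estimate a period")
    taus = np.array([f.tau for f in fits], dtype=float)
    std = float(taus.std(ddof=1)) if taus.size > 1 else 0.0
    return PeriodEstimate(tau=float(taus.mean()), std=std, n=taus.size)


def rig_moi(m: float, g: float, R: float, tau: float, L: float) -> float:
    """Small-angle trifilar MoI from the oscillation period.

    ``I = m g R^2 tau^2 / (4 pi^2 L)`` for a single-degree-of-freedom
    torsional oscillation of total suspended mass ``m`` about the vertical
    axis through the thread circle's center.
    """
    for name, val in (("m", m), ("g", g), ("R", R), ("tau", tau), ("L", L)):
        if not val > 0:
            raise DomainError(f"{name} must be strictly positive, got {val}")
    return m * g * R**2 * tau**2 / (4 * np.pi**2 * L)


def specimen_moi_corrected(
    m_b: float,
    m_p: float,
    I_p: float,
    tau_with: float,
    rig: PendulumRig,
    D: float,
) -> float:
    """Specimen MoI about its own CoM axis, corrected for CoM misalignment.

    The loaded pendulum still twists about the platform axis, so the
    combined measured MoI contains the specimen's parallel-axis term
    ``m_b D^2``; subtracting it (along with the bare-rig ``I_p``) returns
    the MoI about the axis through the specimen's own CoM, normal to the
    board. With ``D = 0`` this is exactly the uncorrected difference.
    """
    if D < 0:
        raise DomainError("CoM offset D must be >= 0")
    combined = rig_moi(m_b + m_p, rig.g, rig.R, tau_with, rig.L)
    return combined - I_p - m_b * D**2


def analytic_block_moi(a: float, b: float, c: float, mass: float, axis: int) -> float:
    """Closed-form MoI of a homogeneous rectangular block about a principal
    axis through its CoM: ``(m/12) (p^2 + q^2)`` with ``p, q`` the edge
    lengths perpendicular to ``axis`` (0 -> a, 1 -> b, 2 -> c)."""
    if min(a, b, c, mass) <= 0:
        raise DomainError("block dimensions and mass must be strictly positive")
    dims = [a, b, c]
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    p, q = (d for i, d in enumerate(dims) if i != axis)
    return mass / 12.0 * (p**2 + q**2)


_TIME_COLUMNS = ("time_s", "time", "t", "seconds", "timestamp_s", "elapsed_s")
_OMEGA_COLUMNS = (
    "omega_rad_s",
    "omega",
    "angular_velocity",
    "angular_velocity_rad_s",
    "gyro_z",
    "wz",
    "rad_s",
)


def read_trace_csv(path) -> OscillationTrace:
    """Read a gyroscope log CSV, tolerating common logger header variants.

    Looks for a time column (``time_s``, ``time``, ``t``, ...) and an
    angular-velocity column (``omega_rad_s``, ``gyro_z``, ...), matching
    case-insensitively.
    """
    df = pd.read_csv(Path(path))
    cols = {c.strip().lower(): c for c in df.columns}
    t_col = next((cols[c] for c in _TIME_COLUMNS if c in cols), None)
    w_col = next((cols[c] for c in _OMEGA_COLUMNS if c in cols), None)
    if t_col is None or w_col is None:
        raise ValueError(
            f"could not identify time/angular-velocity columns in {list(df.columns)}; "
            f"expected one of {_TIME_COLUMNS} and one of {_OMEGA_COLUMNS}"
        )
    return OscillationTrace(t=df[t_col].to_numpy(), omega=df[w_col].to_numpy())
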