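"""Filtering, integration to angular displacement, and time normalization.

Angular velocity is low-pass filtered (2nd-order zero-lag Butterworth, 2 Hz)
before any downstream use. Displacement comes from numerical integration of
the filtered velocity; gyroscope bias makes a trial-level integral drift, so
the default path restarts the integral at every heel-strike and removes the
residual linear trend within the cycle (segment orientation is periodic over
a gait cycle, so a constant-rate drift maps exactly onto a line through the
segment endpoints). A trial-level alternative — integrate once, then 0.75 Hz
high-pass — is available through the config for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.integrate import cumulative_trapezoid

from .io_config import GaitloadError, PreprocessConfig


@dataclass
class FilterSpec:
    kind: str = "lowpass"      # lowpass | highpass
    order: int = 2
    cutoff_hz: float = 2.0
    zero_lag: bool = True


@dataclass
class DisplacementSegment:
    """Angular displacement over one gait cycle, in degrees."""

    site: str
    plane: str
    cycle: int                 # 1-based cycle number within the trial
    t: np.ndarray              # seconds, absolute trial time
    theta: np.ndarray          # degrees, theta[0] == 0
    omega: np.ndarray | None = None   # filtered angular velocity, same samples
    source: str = "per_cycle_integration"
    valid: bool = True
    reason: str = ""


def butterworth(x, fs: float, spec: FilterSpec) -> np.ndarray:
    """Zero-lag (forward-backward) Butterworth filter.

    The forward-backward pass squares the magnitude response, so the
    effective attenuation at the cutoff is -6 dB (|H|^2 = 1/2).
    """
    x = np.asarray(x, dtype=float)
    if not 0 < spec.cutoff_hz < fs / 2:
        raise GaitloadError(f"cutoff {spec.cutoff_hz} Hz outside (0, fs/2)")
    btype = {"lowpass": "low", "highpass": "high"}[spec.kind]
    b, a = signal.butter(spec.order, spec.cutoff_hz, btype=btype, fs=fs)
    if spec.zero_lag:
        padlen = 3 * max(len(a), len(b))
        if len(x) <= padlen:
            raise GaitloadError(
                f"signal too short for zero-lag filtering: need > {padlen} samples, got {len(x)}"
            )
        return signal.filtfilt(b, a, x)
    return signal.lfilter(b, a, x)


def integrate(omega, fs: float) -> np.ndarray:
    """Cumulative trapezoidal integration of angular velocity (deg/s -> deg).

    theta[0] = 0; exact for piecewise-linear signals.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.size == 0:
        return omega.copy()
    return cumulative_trapezoid(omega, dx=1.0 / fs, initial=0.0)


def _detrend_endpoints(t, theta):
    """Remove the line through the segment endpoints (theta(0)=theta(T)=0).

    A least-squares line is deliberately not used here: a sinusoid is not
    orthogonal to a linear trend over one period, so LS detrending would eat
    into the sway signal itself.
    """
    if len(theta) < 2 or t[-1] == t[0]:
        return theta - theta[0]
    slope = (theta[-1] - theta[0]) / (t[-1] - t[0])
    return theta - theta[0] - slope * (t - t[0])


def per_cycle_displacement(stream, events, plane: str, cfg: PreprocessConfig | None = None):
    """Angular displacement of one plane, one segment per gait cycle.

    Cycles are delimited by consecutive heel-strikes. The integral restarts at
    zero at each cycle start; with ``cfg.detrend_cycle`` the residual linear
    trend (constant gyro bias) is removed. Cycles with implausible duration
    (outside [min_cycle_s, max_cycle_s]) are flagged invalid.
    """
    cfg = cfg or PreprocessConfig()
    omega = butterworth(
        stream.axis(plane), stream.fs,
        FilterSpec("lowpass", cfg.order, cfg.lowpass_hz, cfg.zero_lag),
    )
    hs = np.asarray(events.heel_strikes, dtype=float)
    if len(hs) < 2:
        return []

    if cfg.remove_bias:
        # constant gyro bias: a periodic signal averages to ~0 over an integer
        # number of cycles, so the mean over the heel-strike span estimates it
        j0 = int(np.searchsorted(stream.t, hs[0]))
        j1 = int(np.searchsorted(stream.t, hs[-1]))
        if j1 - j0 > 1:
            omega = omega - float(np.mean(omega[j0:j1]))

    trial_theta = None
    if cfg.displacement_source == "trial_highpass":
        theta_full = integrate(omega, stream.fs)
        trial_theta = butterworth(
            theta_full, stream.fs,
            FilterSpec("highpass", cfg.order, cfg.highpass_hz, cfg.zero_lag),
        )

    segments = []
    idx = np.searchsorted(stream.t, hs)
    idx = np.clip(idx, 0, stream.n - 1)
    for k in range(len(hs) - 1):
        i0, i1 = idx[k], idx[k + 1]
        t_seg = stream.t[i0 : i1 + 1]
        duration = hs[k + 1] - hs[k]
        valid = cfg.min_cycle_s <= duration <= cfg.max_cycle_s
        reason = "" if valid else f"cycle duration {duration:.3f}s outside gate"
        if i1 - i0 < 3:
            valid, reason = False, "fewer than 4 samples"
            theta = np.zeros(max(i1 - i0 + 1, 1))
            source = cfg.displacement_source
        elif cfg.displacement_source == "trial_highpass":
            theta = trial_theta[i0 : i1 + 1] - trial_theta[i0]
            source = "trial_integration_highpassed"
        else:
            theta = integrate(omega[i0 : i1 + 1], stream.fs)
            if cfg.detrend_cycle:
                theta = _detrend_endpoints(t_seg, theta)
            source = "per_cycle_integration"
        segments.append(
            DisplacementSegment(
                site=stream.site, plane=plane, cycle=k + 1,
                t=t_seg, theta=theta, omega=omega[i0 : i1 + 1],
                source=source, valid=valid, reason=reason,
            )
        )
    return segments


def time_normalize(y, n_points: int = 101) -> np.ndarray:
    """Resample a cycle onto a 0-100% gait-cycle grid (linear interpolation)."""
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise GaitloadError("cannot time-normalize a segment with < 2 samples")
    x_old = np.linspace(0.0, 1.0, len(y))
    x_new = np.linspace(0.0, 1.0, n_points)
    return np.interp(x_new, x_old, y)
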