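"""Gait-event detection and spatio-temporal parameters.

Heel-strike and toe-off are located on the right shank's sagittal angular
velocity: mid-swing is a prominent positive peak; heel-strike is the first
local minimum after the peak and toe-off the last local minimum before it.
Cycles run heel-strike to heel-strike. Stride length comes from a
double-segment model: thigh and shank act as an inverted double pendulum over
the stance foot and as a double pendulum about the hip during swing; each
segment advances the body by the chord of its rotation, 2 L sin(|dtheta|/2),
with stance standing in for the contralateral step under the left/right
symmetry assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io_config import GaitloadError, EventConfig, StrideConfig, PreprocessConfig
from .preprocess import butterworth, integrate, FilterSpec

logger = logging.getLogger("gaitload")


class NoGaitError(GaitloadError):
    """Raised when no gait pattern is found in a signal."""


@dataclass
class GaitEvents:
    """Ordered gait events for one trial (times in seconds)."""

    heel_strikes: np.ndarray
    toe_offs: np.ndarray
    mid_swing_peaks: np.ndarray
    fs: float = 80.0
    dropped: list = field(default_factory=list)   # diagnostic messages

    def __post_init__(self) -> None:
        for name in ("heel_strikes", "toe_offs", "mid_swing_peaks"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if len(arr) > 1 and not np.all(np.diff(arr) > 0):
                raise GaitloadError(f"{name} not strictly increasing")

    @property
    def n_cycles(self) -> int:
        return max(len(self.heel_strikes) - 1, 0)

    def cycle_durations(self) -> np.ndarray:
        return np.diff(self.heel_strikes)


def _local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local minima (plateau-tolerant via find_peaks)."""
    idx, _ = sps.find_peaks(-x)
    return idx


def detect_events(omega_sagittal, fs: float, cfg: EventConfig | None = None,
                  prefiltered: bool = True,
                  pre_cfg: PreprocessConfig | None = None,
                  raw=None) -> GaitEvents:
    """Detect heel-strike / toe-off / mid-swing from shank sagittal velocity.

    ``omega_sagittal`` should already be low-pass filtered (2 Hz); pass
    ``prefiltered=False`` to let the detector filter a raw signal itself.
    The heavy smoothing that makes the peak structure unambiguous also skews
    or erases the narrow heel-strike/toe-off dips, so when the raw signal is
    available (``raw=...`` or ``prefiltered=False``) the minima are picked on
    a lightly filtered copy (``cfg.refine_cutoff_hz``) within the search
    windows around each mid-swing peak.
    """
    cfg = cfg or EventConfig()
    x = np.asarray(omega_sagittal, dtype=float)
    if len(x) < 2 * fs:
        raise NoGaitError("need at least 2 s of data")
    if not prefiltered:
        pre = pre_cfg or PreprocessConfig()
        raw = x if raw is None else raw
        x = butterworth(x, fs, FilterSpec("lowpass", pre.order, pre.lowpass_hz, pre.zero_lag))
    refine = None
    if raw is not None and cfg.refine_cutoff_hz and cfg.refine_cutoff_hz < fs / 2:
        refine = butterworth(
            np.asarray(raw, dtype=float), fs, FilterSpec("lowpass", 2, cfg.refine_cutoff_hz, True)
        )

    # sensor-mounting sign ambiguity: mid-swing rotation must read positive
    if cfg.auto_flip:
        hi = np.percentile(x, 97.5)
        lo = np.percentile(x, 2.5)
        if abs(lo) > abs(hi):
            x = -x
            if refine is not None:
                refine = -refine

    scale = np.percentile(np.abs(x), 95)
    prominence = max(cfg.prominence_frac * scale, 30.0)
    peaks, _ = sps.find_peaks(
        x, prominence=prominence, distance=max(int(cfg.min_separation_s * fs), 1)
    )
    if len(peaks) == 0:
        raise NoGaitError("no gait detected: no mid-swing peak above threshold")

    minima = _local_minima(x)
    win = int(round(cfg.minima_window_s * fs))
    sig = refine if refine is not None else x

    def _deepest_min(lo: int, hi: int):
        """Deepest strict interior minimum of the event signal in [lo, hi]."""
        lo, hi = max(lo, 1), min(hi, len(sig) - 2)
        if hi <= lo:
            return None
        i = lo + int(np.argmin(sig[lo : hi + 1]))
        if sig[i] <= sig[i - 1] and sig[i] <= sig[i + 1]:
            return i
        return None

    hs_idx, to_idx, ms_idx = [], [], []
    dropped = []
    for pk in peaks:
        if refine is not None:
            hs_i = _deepest_min(pk + 1, pk + win)
            to_i = _deepest_min(pk - win, pk - 1)
        else:
            after = minima[(minima > pk) & (minima <= pk + win)]
            before = minima[(minima < pk) & (minima >= pk - win)]
            hs_i = int(after[0]) if len(after) else None
            to_i = int(before[-1]) if len(before) else None
        if hs_i is None:
            dropped.append(f"peak at {pk / fs:.2f}s: no heel-strike minimum in window")
            continue
        hs_idx.append(hs_i)
        ms_idx.append(int(pk))
        to_idx.append(to_i if to_i is not None else -1)

    if not hs_idx:
        raise NoGaitError("no gait detected: peaks found but no heel-strike minima")

    t = np.arange(len(x)) / fs
    hs_t = t[np.array(hs_idx)]
    ms_t = t[np.array(ms_idx)]

    # one toe-off per cycle: the minimum preceding the mid-swing peak that
    # falls inside the cycle started by the previous heel-strike
    to_t = []
    for k in range(1, len(hs_idx)):
        ms_k, to_k = ms_idx[k], to_idx[k]
        if not hs_idx[k - 1] < ms_k < hs_idx[k]:
            dropped.append(f"cycle {k}: mid-swing outside its cycle, dropped")
            continue
        if to_k < 0 or not hs_idx[k - 1] < to_k < ms_k:
            dropped.append(f"cycle {k}: no valid toe-off, dropped")
            continue
        to_t.append(t[to_k])
    for msg in dropped:
        logger.warning(msg)
    return GaitEvents(
        heel_strikes=hs_t,
        toe_offs=np.array(to_t),
        mid_swing_peaks=ms_t,
        fs=fs,
        dropped=dropped,
    )


@dataclass
class CyclePolicy:
    """Which detected cycles enter the analysis."""

    skip_first: int = 1
    keep: int | None = 5          # None => keep all


def segment_cycles(events: GaitEvents, policy: CyclePolicy | None = None):
    """Return (start_hs_index, end_hs_index) pairs of analyzed cycles.

    The default policy skips the first cycle and keeps the next five
    (cycles 2-6), avoiding gait initiation/termination transients.
    """
    policy = policy or CyclePolicy()
    n_hs = len(events.heel_strikes)
    if policy.keep is None:
        return [(k, k + 1) for k in range(policy.skip_first, n_hs - 1)]
    needed = policy.skip_first + policy.keep + 1
    if n_hs < needed:
        raise GaitloadError(
            f"insufficient cycles: need {needed} heel-strikes "
            f"(skip {policy.skip_first}, keep {policy.keep}), found {n_hs}"
        )
    return [
        (k, k + 1)
        for k in range(policy.skip_first, policy.skip_first + policy.keep)
    ]


def _segment_rotation(omega_f, t, t0, t1, fs):
    """Integral of filtered angular velocity over [t0, t1], degrees."""
    i0 = int(np.searchsorted(t, t0))
    i1 = int(np.searchsorted(t, t1))
    if i1 - i0 < 2:
        return 0.0
    theta = integrate(omega_f[i0 : i1 + 1], fs)
    return float(theta[-1])


def stride_length(thigh_sagittal, shank_sagittal, t, events: GaitEvents,
                  thigh_length_m: float, shank_length_m: float, fs: float,
                  cfg: StrideConfig | None = None,
                  pre_cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Per-cycle stride length (m) from the double-segment gait model.

    Segment rotations are the integrals of each segment's sagittal angular
    velocity over stance (heel-strike to toe-off) and swing (toe-off to the
    next heel-strike); each contributes a chord 2 L sin(|dtheta|/2). Returns
    NaN for cycles with a missing toe-off or implausible (>120 deg) rotation.
    """
    cfg = cfg or StrideConfig()
    pre = pre_cfg or PreprocessConfig()
    if thigh_length_m <= 0 or shank_length_m <= 0:
        raise GaitloadError("segment lengths must be positive")
    from .synthetic import stride_from_rotations  # shared geometry

    spec = FilterSpec("lowpass", pre.order, cfg.lowpass_hz, pre.zero_lag)
    th_f = butterworth(np.asarray(thigh_sagittal, float), fs, spec)
    sh_f = butterworth(np.asarray(shank_sagittal, float), fs, spec)

    hs = events.heel_strikes
    out = np.full(max(len(hs) - 1, 0), np.nan)
    for k in range(len(hs) - 1):
        inside = events.toe_offs[(events.toe_offs > hs[k]) & (events.toe_offs < hs[k + 1])]
        if len(inside) != 1:
            continue
        to = float(inside[0])
        rots = [
            _segment_rotation(th_f, t, hs[k], to, fs),
            _segment_rotation(sh_f, t, hs[k], to, fs),
            _segment_rotation(th_f, t, to, hs[k + 1], fs),
            _segment_rotation(sh_f, t, to, hs[k + 1], fs),
        ]
        if any(abs(r) > cfg.max_rotation_deg for r in rots):
            logger.warning("cycle %d: implausible segment rotation, stride flagged", k + 1)
            continue
        out[k] = stride_from_rotations(
            rots[0], rots[1], rots[2], rots[3], thigh_length_m, shank_length_m
        )
    return out


def relative_speed(stride_m, duration_s, leg_length_m: float):
    """Walking speed normalized by leg length: (stride/duration)/leg."""
    if leg_length_m <= 0:
        raise GaitloadError("leg length must be positive")
    stride_m = np.asarray(stride_m, dtype=float)
    duration_s = np.asarray(duration_s, dtype=float)
    return (stride_m / duration_s) / leg_length_m


def center(values) -> np.ndarray:
    """Grand-mean centering over the analysis set (NaNs ignored in the mean)."""
    values = np.asarray(values, dtype=float)
    return values - np.nanmean(values)
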