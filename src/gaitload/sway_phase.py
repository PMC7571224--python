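"""Postural sway (ROM) and thoracic-pelvic coordination (relative phase).

Sway is the peak-to-peak range of the per-cycle angular displacement in each
anatomical plane at T6 and S1. Coordination uses the continuous-relative-phase
construction: within a cycle both the angular velocity and the integrated
displacement are amplitude-normalized to [-1, 1], the per-frame phase is the
four-quadrant arctangent of (normalized velocity / normalized displacement),
and the relative phase is the pelvic minus thoracic phase, wrapped to
(-180, 180]. By default the absolute wrapped difference is averaged over the
cycle, giving a mean relative phase in [0, 180] where 0 is in-phase
(synchronized) and 180 anti-phase movement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_config import GaitloadError, PhaseConfig
from .preprocess import DisplacementSegment, time_normalize

logger = logging.getLogger("gaitload")


def rom(segment) -> float:
    """Peak-to-peak range of motion over one cycle, degrees."""
    theta = segment.theta if isinstance(segment, DisplacementSegment) else np.asarray(segment, float)
    if len(theta) == 0:
        raise GaitloadError("empty displacement segment")
    return float(np.max(theta) - np.min(theta))


def _normalize(v: np.ndarray) -> np.ndarray:
    """Map a cycle's signal onto [-1, 1]: 2 (v - min) / (max - min) - 1."""
    vmin, vmax = float(np.min(v)), float(np.max(v))
    if vmax == vmin:
        raise GaitloadError("zero-amplitude signal: phase undefined")
    return 2.0 * (v - vmin) / (vmax - vmin) - 1.0


def phase_angle(omega_cycle, theta_cycle, unwrap: bool = True) -> np.ndarray:
    """Per-frame phase-portrait angle over one cycle, degrees.

    Displacement on the horizontal portrait axis, velocity vertical; the
    four-quadrant arctangent is used (a principal-branch arctan cannot reach
    the out-of-phase regime beyond 90 deg).
    """
    omega_cycle = np.asarray(omega_cycle, dtype=float)
    theta_cycle = np.asarray(theta_cycle, dtype=float)
    if omega_cycle.shape != theta_cycle.shape:
        raise GaitloadError("omega and theta must cover the same cycle")
    w = _normalize(omega_cycle)
    th = _normalize(theta_cycle)
    phi = np.arctan2(w, th)
    if unwrap:
        phi = np.unwrap(phi)
    return np.degrees(phi)


def relative_phase_frames(omega_t6, theta_t6, omega_s1, theta_s1,
                          cfg: PhaseConfig | None = None) -> np.ndarray:
    """Per-frame pelvic-minus-thoracic relative phase, degrees.

    Wrapped phases are differenced frame by frame and the difference wrapped
    to (-180, 180]; with ``cfg.absolute`` (default) the absolute value is
    taken, yielding values in [0, 180].
    """
    cfg = cfg or PhaseConfig()
    unwrap = cfg.unwrap_before_diff
    p_t6 = phase_angle(omega_t6, theta_t6, unwrap=unwrap)
    p_s1 = phase_angle(omega_s1, theta_s1, unwrap=unwrap)
    diff = p_s1 - p_t6
    wrapped = (diff + 180.0) % 360.0 - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return np.abs(wrapped) if cfg.absolute else wrapped


def mean_relative_phase(omega_t6, theta_t6, omega_s1, theta_s1,
                        cfg: PhaseConfig | None = None) -> float:
    """Relative phase averaged over the gait cycle (degrees)."""
    frames = relative_phase_frames(omega_t6, theta_t6, omega_s1, theta_s1, cfg)
    return float(np.mean(frames))


@dataclass
class PhaseCurve:
    """Ensemble relative-phase curve on a percent-gait-cycle grid."""

    plane: str
    condition: str
    grid: np.ndarray          # 0..100 %
    mean: np.ndarray
    se: np.ndarray | None
    n_participants: int


def ensemble_phase_curve(cycles, plane: str, condition: str,
                         n_points: int = 101,
                         cfg: PhaseConfig | None = None) -> PhaseCurve:
    """Participant-averaged ensemble relative-phase curve.

    ``cycles`` is a list of (participant_id, relative_phase_frames) pairs;
    each cycle is time-normalized, cycles are averaged within participant
    first, then across participants; SE is across participants.
    """
    if len(cycles) < 2:
        raise GaitloadError("need at least 2 cycles for an ensemble curve")
    by_participant: dict = {}
    for pid, frames in cycles:
        by_participant.setdefault(pid, []).append(time_normalize(frames, n_points))
    participant_means = np.array(
        [np.mean(np.vstack(v), axis=0) for v in by_participant.values()]
    )
    mean = participant_means.mean(axis=0)
    n_p = len(by_participant)
    if n_p < 2:
        logger.warning("ensemble curve from a single participant: SE unavailable")
        se = None
    else:
        se = participant_means.std(axis=0, ddof=1) / np.sqrt(n_p)
    return PhaseCurve(
        plane=plane,
        condition=condition,
        grid=np.linspace(0.0, 100.0, n_points),
        mean=mean,
        se=se,
        n_participants=n_p,
    )


def phase_curve_table(curve: PhaseCurve):
    """Export a PhaseCurve as a tidy DataFrame (%, mean, SE, condition)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "pct_gait_cycle": curve.grid,
            "mean_relative_phase_deg": curve.mean,
            "se_deg": curve.se if curve.se is not None else np.nan,
            "plane": curve.plane,
            "condition": curve.condition,
        }
    )
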