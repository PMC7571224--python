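"""Synthetic four-site gyroscope walk trials with exact ground truth.

The torso (T6) and pelvis (S1) are modelled as segments of an oscillating
inverted pendulum: per-plane angular displacement is sinusoidal at stride
frequency in the coronal and transverse planes and at step frequency (twice
per gait cycle) in the sagittal plane. Signals are built displacement-first —
construct theta(phi) over a warped gait-phase axis, differentiate analytically
to angular velocity — so per-cycle range of motion and thoracic-pelvic phase
lag are exact by construction. The pelvic waveform lags the thoracic one by a
configurable phase within each plane; the imposed lag in degrees of cycle
phase is the ground truth for the mean relative phase angle.

The right shank's sagittal angular velocity is a parameterized periodic
template with the canonical gait shape: a dominant positive mid-swing peak
flanked by negative minima at heel-strike and toe-off. The right thigh is a
stride-frequency sinusoid whose amplitude is solved from a two-segment
(thigh + shank) chord-length chain so that the double-pendulum stride-length
model evaluates exactly to the requested stride.

Cycle-to-cycle timing jitter is introduced by piecewise-linear warping of the
gait phase; sensor imperfections are white Gaussian noise plus a constant
bias ("drift") on every channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.integrate import solve_ivp

from .io_config import (
    GaitloadError,
    LOAD_LEVELS,
    PLANE_AXIS,
    PLANES,
    SensorStream,
    TrialRecord,
    Anthropometry,
    write_sensor_stream,
    write_manifest,
    write_anthropometry,
)

# fixed per-plane oscillation phase offsets (radians) — arbitrary but frozen
PLANE_PHI0 = {"coronal": 0.0, "transverse": 0.7, "sagittal": 1.3}
# oscillations per gait cycle: stride frequency except sagittal (step frequency)
PLANE_CYCLES = {"coronal": 1, "transverse": 1, "sagittal": 2}

_G = 9.80665  # m/s^2


# ---------------------------------------------------------------------------
# parameters and ground truth
# ---------------------------------------------------------------------------


def default_sway_amplitudes() -> dict:
    """Half peak-to-peak sway per (site, plane), degrees.

    Levels correspond to typical unloaded walking: thoracic/pelvic ROMs of
    roughly 5.6/7.5 deg (coronal), 5.6/7.4 deg (transverse), 2.9/3.8 deg
    (sagittal).
    """
    return {
        ("T6", "coronal"): 2.8,
        ("S1", "coronal"): 3.75,
        ("T6", "transverse"): 2.8,
        ("S1", "transverse"): 3.7,
        ("T6", "sagittal"): 1.45,
        ("S1", "sagittal"): 1.9,
    }


def default_phase_lags() -> dict:
    """Imposed pelvic-vs-thoracic phase lag per plane, degrees of cycle phase."""
    return {"coronal": 109.5, "transverse": 102.2, "sagittal": 81.7}


# periodic shank sagittal angular-velocity template (gait phase -> deg/s);
# heel-strike minimum at phase 0/1, toe-off minimum near 0.6, mid-swing peak
# near 0.8. Values are template knots, smoothed by a periodic cubic spline.
DEFAULT_SHANK_KNOTS = (
    (0.00, -100.0),
    (0.10, -30.0),
    (0.30, -45.0),
    (0.45, -60.0),
    (0.60, -100.0),
    (0.80, 300.0),
    (0.90, 30.0),
    (1.00, -100.0),
)


@dataclass
class GaitSimParams:
    """Study conditions for one simulated walk trial."""

    cycle_duration_s: float = 1.06       # mean gait-cycle duration
    cycle_sd_s: float = 0.02             # within-trial cycle-to-cycle SD
    stride_length_m: float = 1.09
    sway_amplitude_deg: dict = field(default_factory=default_sway_amplitudes)
    phase_lag_deg: dict = field(default_factory=default_phase_lags)
    noise_sd_dps: float = 2.0
    drift_dps: float = 0.2               # constant gyro bias on every channel
    n_cycles: int = 8
    fs: float = 80.0
    thigh_length_m: float = 0.43
    shank_length_m: float = 0.43
    leg_length_m: float = 0.94
    shank_knots: tuple = DEFAULT_SHANK_KNOTS

    def __post_init__(self) -> None:
        if self.cycle_duration_s <= 0:
            raise GaitloadError("cycle_duration_s must be positive")
        if self.n_cycles < 1:
            raise GaitloadError("n_cycles must be >= 1")
        if any(a < 0 for a in self.sway_amplitude_deg.values()):
            raise GaitloadError("sway amplitudes must be >= 0")
        for plane, lag in self.phase_lag_deg.items():
            if not 0.0 <= lag <= 180.0:
                raise GaitloadError(f"phase lag for {plane} outside [0, 180]")


@dataclass
class GroundTruth:
    """Generator-side record of the quantities the pipeline estimates."""

    heel_strikes: np.ndarray          # n_cycles + 1 times, s
    toe_offs: np.ndarray              # n_cycles times, s
    mid_swing: np.ndarray             # n_cycles times, s
    cycle_durations: np.ndarray       # n_cycles, s
    stride_length_m: np.ndarray       # per cycle
    rom_deg: dict                     # (site, plane) -> per-cycle array
    phase_lag_deg: dict               # plane -> imposed lag
    relative_speed: float
    condition: tuple                  # (mode, load_label)
    effects_applied: dict
    displacement: dict | None = None  # (site, plane) -> theta(t) arrays

    def __post_init__(self) -> None:
        n = len(self.cycle_durations)
        if len(self.heel_strikes) != n + 1 or len(self.toe_offs) != n:
            raise GaitloadError("ground-truth event counts inconsistent")
        hs = self.heel_strikes
        if not np.all((self.toe_offs > hs[:-1]) & (self.toe_offs < hs[1:])):
            raise GaitloadError("each toe-off must fall strictly within its cycle")


@dataclass
class EffectPreset:
    """Additive condition offsets: ROM (deg) and mean-relative-phase (deg).

    Keys: ``rom[(site, plane)][(mode, load_label)]`` and
    ``mrp[plane][(mode, load_label)]``. Missing keys mean no offset.
    """

    name: str = "null"
    rom: dict = field(default_factory=dict)
    mrp: dict = field(default_factory=dict)

    def rom_offset(self, site: str, plane: str, mode: str, load: str) -> float:
        return self.rom.get((site, plane), {}).get((mode, load), 0.0)

    def mrp_offset(self, plane: str, mode: str, load: str) -> float:
        return self.mrp.get(plane, {}).get((mode, load), 0.0)


def table3_preset() -> EffectPreset:
    """Condition effects matching the direction and scale of the reference
    load-carriage study: side carry drives coronal thoracic-pelvic movement
    out of phase with increasing load while anterior carry pulls it in phase;
    transverse coordination tightens under load; sagittal thoracic sway is
    larger in side carry."""
    side = "side"
    ant = "anterior"
    rom = {
        ("T6", "coronal"): {
            (side, "M"): -1.7, (side, "H"): -1.8,
            (ant, "M"): -1.7, (ant, "H"): -1.8,
        },
        ("S1", "transverse"): {
            (side, "L"): 1.7, (side, "M"): 1.7, (side, "H"): 1.7,
        },
        ("T6", "sagittal"): {
            (side, "L"): 0.5, (side, "M"): 0.5, (side, "H"): 0.6,
            (ant, "L"): -0.2, (ant, "M"): -0.5, (ant, "H"): -0.3,
        },
    }
    mrp = {
        "coronal": {
            (side, "L"): 5.0, (side, "M"): 8.4, (side, "H"): 23.6,
            (ant, "L"): -22.2, (ant, "M"): -22.9, (ant, "H"): -30.2,
        },
        "transverse": {
            (side, "L"): -30.5, (side, "M"): -30.4, (side, "H"): -33.8,
            (ant, "M"): -11.6, (ant, "H"): -18.8,
        },
        "sagittal": {
            (side, "L"): 1.8, (side, "M"): 1.8, (side, "H"): 1.8,
            (ant, "L"): -9.0, (ant, "M"): -9.0, (ant, "H"): -9.0,
        },
    }
    return EffectPreset(name="table3", rom=rom, mrp=mrp)


# ---------------------------------------------------------------------------
# shank template
# ---------------------------------------------------------------------------


class ShankTemplate:
    """Periodic shank sagittal velocity template over gait phase in [0, 1).

    The raw knot spline is adjusted to zero mean (segment orientation is
    periodic over a cycle) and re-parameterized so the heel-strike minimum
    sits exactly at phase 0.
    """

    def __init__(self, knots=DEFAULT_SHANK_KNOTS):
        phases = np.array([k[0] for k in knots])
        values = np.array([k[1] for k in knots], dtype=float)
        if phases[0] != 0.0 or phases[-1] != 1.0 or values[0] != values[-1]:
            raise GaitloadError("shank template knots must be periodic on [0, 1]")
        base = CubicSpline(phases, values, bc_type="periodic")
        anti = base.antiderivative()
        self._mean = float(anti(1.0) - anti(0.0))   # removed for periodicity
        self._base = base
        self._anti = anti
        # locate template events on a dense grid; the heel-strike minimum is
        # the deepest minimum within a quarter cycle of the nominal boundary
        grid = np.linspace(0.0, 1.0, 4001, endpoint=False)
        g = base(grid) - self._mean
        near_hs = (grid > 0.75) | (grid < 0.25)
        hs_phase = float(grid[near_hs][np.argmin(g[near_hs])])
        self._shift = hs_phase
        shifted = self(grid)
        # toe-off: deepest minimum in mid-cycle; mid-swing: global maximum
        mid = (grid > 0.3) & (grid < 0.78)
        self.phi_to = float(grid[mid][np.argmin(shifted[mid])])
        self.phi_ms = float(grid[np.argmax(shifted)])
        if not self.phi_to < self.phi_ms:
            raise GaitloadError("template toe-off must precede mid-swing peak")
        # per-unit-duration rotation over stance (deg, for T = 1 s)
        self.rot_stance_unit = self.angle_unit(self.phi_to)

    def __call__(self, phi):
        """Template angular velocity (deg/s at unit cycle duration)."""
        w = np.mod(np.asarray(phi, dtype=float) + self._shift, 1.0)
        return self._base(w) - self._mean

    def angle_unit(self, phi):
        """Integral of the template from heel-strike (phase 0), unit duration.

        Multiply by the cycle duration to get segment rotation in degrees.
        Zero-mean adjustment makes this exactly periodic (angle(1) == 0).
        """
        phi = np.asarray(phi, dtype=float)
        w = np.mod(phi + self._shift, 1.0)
        a0 = self._anti(self._shift) - self._mean * self._shift
        wrapped = self._anti(w) - self._mean * w - a0
        # account for whole cycles (integral over one cycle is 0 by design)
        return wrapped


def stride_from_rotations(rot_thigh_stance, rot_shank_stance,
                          rot_thigh_swing, rot_shank_swing,
                          thigh_length_m, shank_length_m):
    """Chord-length double-pendulum stride model.

    Stance (inverted double pendulum pivoting over the planted foot) and
    swing (double pendulum about the hip) each advance the body by the chord
    of the segment rotations, 2 L sin(|dtheta|/2) per segment; under the
    left/right symmetry assumption the stance advance stands in for the
    contralateral step, and the sum over both phases is the stride. Rotations
    in degrees, lengths in metres.
    """
    def chord(L, dtheta_deg):
        return 2.0 * L * math.sin(math.radians(min(abs(dtheta_deg), 180.0)) / 2.0)

    return (
        chord(thigh_length_m, rot_thigh_stance)
        + chord(shank_length_m, rot_shank_stance)
        + chord(thigh_length_m, rot_thigh_swing)
        + chord(shank_length_m, rot_shank_swing)
    )


def _solve_thigh_amplitude(params: GaitSimParams, template: ShankTemplate) -> float:
    """Thigh sinusoid amplitude (deg) consistent with the target stride."""
    T = params.cycle_duration_s
    rot_sh = abs(template.rot_stance_unit) * T      # stance = swing magnitude
    d_sh = 2 * (2.0 * params.shank_length_m * math.sin(math.radians(rot_sh) / 2.0))
    remainder = params.stride_length_m - d_sh
    if remainder <= 0:
        raise GaitloadError(
            f"target stride {params.stride_length_m} m shorter than the shank "
            f"contribution {d_sh:.3f} m; increase stride or soften the template"
        )
    arg = remainder / (4.0 * params.thigh_length_m)
    if arg >= 1.0:
        raise GaitloadError("target stride unreachable with these segment lengths")
    # thigh rotation magnitude per phase: |cos(2 pi phi_to) - 1| * A
    c = abs(math.cos(2 * math.pi * template.phi_to) - 1.0)
    return math.degrees(2.0 * math.asin(arg)) / c


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------


def _warped_phase(params: GaitSimParams, rng: np.random.Generator):
    """Sample times, gait phase phi(t), and its rate for one trial.

    Heel-strikes sit at integer phases 0..n_cycles; half a cycle of lead-in
    and lead-out keeps the edge events detectable.
    """
    n = params.n_cycles
    durations = params.cycle_duration_s + rng.normal(0.0, params.cycle_sd_s, size=n)
    durations = np.clip(durations, 0.5 * params.cycle_duration_s, 1.5 * params.cycle_duration_s)
    lead_in = 0.5 * durations[0]
    lead_out = 0.5 * durations[-1]
    boundaries = lead_in + np.concatenate([[0.0], np.cumsum(durations)])
    total = boundaries[-1] + lead_out
    t = np.arange(0.0, total, 1.0 / params.fs)

    phi = np.empty_like(t)
    rate = np.empty_like(t)
    # cycle index for each sample (-1 = lead-in, n = lead-out)
    k = np.searchsorted(boundaries, t, side="right") - 1
    pre = k < 0
    post = k >= n
    core = ~(pre | post)
    phi[pre] = (t[pre] - boundaries[0]) / durations[0]
    rate[pre] = 1.0 / durations[0]
    phi[post] = n + (t[post] - boundaries[-1]) / durations[-1]
    rate[post] = 1.0 / durations[-1]
    kc = k[core]
    phi[core] = kc + (t[core] - boundaries[kc]) / durations[kc]
    rate[core] = 1.0 / durations[kc]
    return t, phi, rate, boundaries, durations


def apply_effects(params: GaitSimParams, effects: EffectPreset | None,
                  condition: tuple) -> tuple[GaitSimParams, dict]:
    """Return params with condition offsets applied, plus the applied offsets."""
    mode, load = condition
    applied = {"rom": {}, "mrp": {}}
    if effects is None or mode == "none":
        return params, applied
    amps = dict(params.sway_amplitude_deg)
    lags = dict(params.phase_lag_deg)
    for key in amps:
        off = effects.rom_offset(key[0], key[1], mode, load)
        if off:
            amps[key] = max(amps[key] + off / 2.0, 0.0)
            applied["rom"][key] = off
    for plane in lags:
        off = effects.mrp_offset(plane, mode, load)
        if off:
            lags[plane] = float(np.clip(lags[plane] + off, 0.0, 180.0))
            applied["mrp"][plane] = off
    return replace(params, sway_amplitude_deg=amps, phase_lag_deg=lags), applied


def generate_trial(params: GaitSimParams, rng, condition=("none", "NL"),
                   effects: EffectPreset | None = None,
                   participant_id: str = "P01", trial_index: int = 1,
                   keep_displacement: bool = True):
    """Generate one four-site walk trial and its ground truth.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed (the PRNG
    is PCG64 throughout; the same seed reproduces the trial bit for bit).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    params, applied = apply_effects(params, effects, condition)

    template = ShankTemplate(params.shank_knots)
    t, phi, rate, boundaries, durations = _warped_phase(params, rng)
    n = params.n_cycles

    displacement = {} if keep_displacement else None
    streams = {}

    def emit(site, channels):
        gyro = np.empty((len(t), 3))
        for ax in range(3):
            clean = channels.get(ax)
            if clean is None:
                clean = np.zeros(len(t))
            gyro[:, ax] = (
                clean
                + params.drift_dps
                + rng.normal(0.0, params.noise_sd_dps, size=len(t))
            )
        streams[site] = SensorStream(site=site, fs=params.fs, t=t.copy(), gyro=gyro)

    # --- torso & pelvis: sinusoidal sway -----------------------------------
    for site in ("T6", "S1"):
        channels = {}
        for plane in PLANES:
            a = params.sway_amplitude_deg[(site, plane)]
            m = PLANE_CYCLES[plane]
            lag = math.radians(params.phase_lag_deg[plane]) if site == "S1" else 0.0
            arg = 2 * math.pi * m * phi + PLANE_PHI0[plane] - lag
            theta = a * np.sin(arg)
            omega = a * 2 * math.pi * m * np.cos(arg) * rate
            channels[PLANE_AXIS[plane]] = omega
            if keep_displacement:
                displacement[(site, plane)] = theta
        emit(site, channels)

    # --- thigh: stride-frequency sinusoid tied to the stride target --------
    A_th = _solve_thigh_amplitude(params, template)
    arg = 2 * math.pi * phi
    theta_th = A_th * np.cos(arg)
    omega_th = -A_th * 2 * math.pi * np.sin(arg) * rate
    if keep_displacement:
        displacement[("thigh_R", "sagittal")] = theta_th
    emit("thigh_R", {PLANE_AXIS["sagittal"]: omega_th})

    # --- shank: canonical gait template -------------------------------------
    # omega scaled so per-cycle rotation is cadence-independent
    omega_sh = template(phi) * (params.cycle_duration_s * rate)
    if keep_displacement:
        displacement[("shank_R", "sagittal")] = (
            params.cycle_duration_s * template.angle_unit(np.mod(phi, 1.0))
        )
    emit("shank_R", {PLANE_AXIS["sagittal"]: omega_sh})

    # --- ground truth --------------------------------------------------------
    hs = boundaries
    to = boundaries[:-1] + template.phi_to * durations
    ms = boundaries[:-1] + template.phi_ms * durations

    rot_sh = abs(template.rot_stance_unit) * params.cycle_duration_s
    c = abs(math.cos(2 * math.pi * template.phi_to) - 1.0)
    rot_th = c * A_th
    stride = stride_from_rotations(
        rot_th, rot_sh, rot_th, rot_sh,
        params.thigh_length_m, params.shank_length_m,
    )
    rom = {
        key: np.full(n, 2.0 * amp)
        for key, amp in params.sway_amplitude_deg.items()
    }
    truth = GroundTruth(
        heel_strikes=hs,
        toe_offs=to,
        mid_swing=ms,
        cycle_durations=durations,
        stride_length_m=np.full(n, stride),
        rom_deg=rom,
        phase_lag_deg=dict(params.phase_lag_deg),
        relative_speed=stride / params.cycle_duration_s / params.leg_length_m,
        condition=condition,
        effects_applied=applied,
        displacement=displacement,
    )
    mode, load = condition
    record = TrialRecord(
        participant_id=participant_id,
        carry_mode=mode,
        load_kg=LOAD_LEVELS[load],
        trial_index=trial_index,
        streams=streams,
    )
    return record, truth


# ---------------------------------------------------------------------------
# study designs
# ---------------------------------------------------------------------------


@dataclass
class DesignParams:
    """Between/within-participant variability for a simulated study."""

    n_participants: int = 9
    trials_per_cell: int = 2        # loaded (mode, load) cells
    n_noload_trials: int = 4        # no-load walks per participant
    n_cycles: int = 8
    keep_cycles: int = 5            # analysis policy: cycles 2..(1+keep)
    rel_speed_mean: float = 1.09
    rel_speed_sd: float = 0.08      # between participants
    leg_length_mean_m: float = 0.94
    leg_length_sd_m: float = 0.06
    cycle_duration_mean_s: float = 1.06
    cycle_duration_sd_s: float = 0.05   # between participants
    trial_cycle_sd_s: float = 0.01
    trial_rel_speed_sd: float = 0.02
    participant_lag_sd: float = 8.0     # deg, per plane
    trial_lag_sd: float = 6.0
    participant_amp_sd: float = 0.4     # deg
    trial_amp_sd: float = 0.2
    cov_rom_slope: float = -3.0         # deg ROM change per unit relative speed
    cov_mrp_slope: float = -15.0        # deg coronal MRP per unit relative speed
    n_dropped_cycles: int = 0           # discarded analyzed cycles (measurement issues)


EXPT1 = DesignParams()
EXPT2 = DesignParams(
    n_participants=10,
    trials_per_cell=1,
    n_noload_trials=2,
    n_cycles=12,
    keep_cycles=10,
    rel_speed_mean=1.01,
    rel_speed_sd=0.15,
    leg_length_mean_m=0.96,
    leg_length_sd_m=0.05,
    n_dropped_cycles=3,
)

DESIGNS = {"expt1": EXPT1, "expt2": EXPT2}

LOADED_CONDITIONS = [
    (mode, load) for mode in ("side", "anterior") for load in ("L", "M", "H")
]


def generate_design(design: str, base_params: GaitSimParams | None = None,
                    effects: EffectPreset | None = None, master_seed: int = 0,
                    out_dir=None, n_participants: int | None = None,
                    keep_displacement: bool = False):
    """Generate a full study: trials, ground truths, manifest, anthropometry.

    Returns a dict with keys ``trials`` (list of (TrialRecord, GroundTruth)),
    ``manifest`` (DataFrame), ``anthropometry`` (dict participant -> record),
    ``drop_list`` (DataFrame of analyzed cycles discarded), and ``design``.
    With ``out_dir`` the streams/manifest/anthropometry/ground-truth sidecar
    are also written as delimited text.
    """
    if design not in DESIGNS:
        raise GaitloadError(f"unknown design {design!r}")
    dp = DESIGNS[design]
    if n_participants is not None:
        dp = replace(dp, n_participants=n_participants)
    base = base_params or GaitSimParams()
    if design == "expt1" and base.n_cycles < 7:
        raise GaitloadError(
            "expt1 preset needs n_cycles >= 7 (cycles 2-6 are analyzed)"
        )
    base = replace(base, n_cycles=max(base.n_cycles, dp.n_cycles))
    rng = np.random.default_rng(master_seed)

    anthro = {}
    trials = []
    rows = []
    for p in range(dp.n_participants):
        pid = f"P{p + 1:02d}"
        leg = max(rng.normal(dp.leg_length_mean_m, dp.leg_length_sd_m), 0.7)
        stature = leg / 0.53
        thigh = 0.245 * stature
        shank = 0.246 * stature
        anthro[pid] = Anthropometry(pid, stature, leg, thigh, shank)
        T_i = max(rng.normal(dp.cycle_duration_mean_s, dp.cycle_duration_sd_s), 0.7)
        rel_i = max(rng.normal(dp.rel_speed_mean, dp.rel_speed_sd), 0.5)
        lag_i = {
            plane: base.phase_lag_deg[plane] + rng.normal(0.0, dp.participant_lag_sd)
            for plane in PLANES
        }
        amp_i = {
            key: max(a + rng.normal(0.0, dp.participant_amp_sd), 0.2)
            for key, a in base.sway_amplitude_deg.items()
        }

        conditions = [("none", "NL")] * dp.n_noload_trials
        for cond in LOADED_CONDITIONS:
            conditions += [cond] * dp.trials_per_cell
        trial_counter: dict = {}
        for cond in conditions:
            key = cond
            trial_counter[key] = trial_counter.get(key, 0) + 1
            tidx = trial_counter[key]
            rel_t = max(rel_i + rng.normal(0.0, dp.trial_rel_speed_sd), 0.4)
            T_t = max(T_i + rng.normal(0.0, dp.trial_cycle_sd_s), 0.6)
            lags = {
                plane: float(np.clip(lag_i[plane] + rng.normal(0.0, dp.trial_lag_sd), 0.0, 180.0))
                for plane in PLANES
            }
            amps = {
                key2: max(a + rng.normal(0.0, dp.trial_amp_sd), 0.1)
                for key2, a in amp_i.items()
            }
            # covariate dependence: faster walkers bend less and phase-lock more
            amps[("T6", "coronal")] = max(
                amps[("T6", "coronal")] + dp.cov_rom_slope * (rel_t - dp.rel_speed_mean), 0.1
            )
            lags["coronal"] = float(
                np.clip(lags["coronal"] + dp.cov_mrp_slope * (rel_t - dp.rel_speed_mean), 0.0, 180.0)
            )
            stride_t = rel_t * leg * T_t
            params_t = replace(
                base,
                cycle_duration_s=T_t,
                stride_length_m=stride_t,
                sway_amplitude_deg=amps,
                phase_lag_deg=lags,
                thigh_length_m=thigh,
                shank_length_m=shank,
                leg_length_m=leg,
            )
            record, truth = generate_trial(
                params_t, rng, condition=cond, effects=effects,
                participant_id=pid, trial_index=tidx,
                keep_displacement=keep_displacement,
            )
            trials.append((record, truth))
            rows.append(
                {
                    "participant_id": pid,
                    "carry_mode": cond[0],
                    "load_kg": LOAD_LEVELS[cond[1]],
                    "trial_index": tidx,
                }
            )
    manifest = pd.DataFrame(rows)

    # drop-list: the 6th analyzed cycle of k distinct trials (measurement issues)
    drop_rows = []
    if dp.n_dropped_cycles:
        chosen = rng.choice(len(trials), size=dp.n_dropped_cycles, replace=False)
        for i in sorted(chosen):
            r = trials[i][0]
            drop_rows.append(
                {
                    "participant_id": r.participant_id,
                    "carry_mode": r.carry_mode,
                    "load_kg": r.load_kg,
                    "trial_index": r.trial_index,
                    "cycle": 6,
                }
            )
    drop_list = pd.DataFrame(
        drop_rows, columns=["participant_id", "carry_mode", "load_kg", "trial_index", "cycle"]
    )

    result = {
        "design": design,
        "params": dp,
        "trials": trials,
        "manifest": manifest,
        "anthropometry": anthro,
        "drop_list": drop_list,
    }
    if out_dir is not None:
        _write_design(result, out_dir)
    return result


def _write_design(result, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = result["manifest"].copy()
    path_cols = {f"path_{site}": [] for site in ("T6", "S1", "thigh_R", "shank_R")}
    truth_rows = []
    for record, truth in result["trials"]:
        stem = (
            f"{record.participant_id}_{record.carry_mode}_"
            f"{record.load_label}_t{record.trial_index}"
        )
        for site, stream in record.streams.items():
            fname = f"{stem}_{site}.csv"
            write_sensor_stream(stream, out / fname)
            path_cols[f"path_{site}"].append(fname)
        for cyc in range(len(truth.cycle_durations)):
            row = {
                "participant_id": record.participant_id,
                "carry_mode": record.carry_mode,
                "load_kg": record.load_kg,
                "trial_index": record.trial_index,
                "cycle": cyc + 1,
                "hs_time_s": truth.heel_strikes[cyc],
                "to_time_s": truth.toe_offs[cyc],
                "cycle_duration_s": truth.cycle_durations[cyc],
                "stride_length_m": truth.stride_length_m[cyc],
            }
            for (site, plane), vals in truth.rom_deg.items():
                row[f"rom_{site}_{plane}_deg"] = vals[cyc]
            for plane, lag in truth.phase_lag_deg.items():
                row[f"mrp_{plane}_deg"] = lag
            truth_rows.append(row)
    for col, vals in path_cols.items():
        manifest[col] = vals
    write_manifest(manifest, out / "manifest.csv")
    write_anthropometry(result["anthropometry"], out / "anthropometry.csv")
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    result["drop_list"].to_csv(out / "drop_list.csv", index=False)


def simulate_trial_table(n_participants: int = 9, trials_per_cell: int = 2,
                         rng=None, response: str = "mrp_coronal",
                         baseline: float = 109.5,
                         participant_sd: float = 8.0, trial_sd: float = 6.0,
                         rel_speed_mean: float = 1.09, rel_speed_sd: float = 0.08,
                         trial_rel_sd: float = 0.02,
                         effects: dict | None = None):
    """Draw a trial-aggregated feature table directly at the statistical level.

    Fast path for calibrating the mixed-model stage (type-I error, power)
    without synthesizing signals: one row per (participant, mode, load,
    trial), response = baseline + participant intercept + condition effect
    + trial noise. ``effects`` maps (mode, load_label) -> additive offset;
    None simulates the null. Returns a table ready for :func:`gaitload.stats.fit_lmm`
    (carry_mode='none' on no-load rows, as in the measured designs).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    effects = effects or {}
    rows = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        intercept = rng.normal(0.0, participant_sd)
        rel_i = rng.normal(rel_speed_mean, rel_speed_sd)
        counter: dict = {}
        conditions = [("none", "NL")] * (2 * trials_per_cell)
        conditions += [c for c in LOADED_CONDITIONS for _ in range(trials_per_cell)]
        for mode, load in conditions:
            counter[(mode, load)] = counter.get((mode, load), 0) + 1
            rel_t = rel_i + rng.normal(0.0, trial_rel_sd)
            y = (
                baseline
                + intercept
                + effects.get((mode, load), 0.0)
                + rng.normal(0.0, trial_sd)
            )
            rows.append(
                {
                    "participant_id": pid,
                    "carry_mode": mode,
                    "load_kg": LOAD_LEVELS[load],
                    "trial_index": counter[(mode, load)],
                    response: y,
                    "relative_speed": rel_t,
                }
            )
    df = pd.DataFrame(rows)
    df["centered_relative_speed"] = df["relative_speed"] - df["relative_speed"].mean()
    return df


# ---------------------------------------------------------------------------
# rigid pendulum fixture
# ---------------------------------------------------------------------------


def generate_pendulum(arm_length_m: float = 0.46, initial_deg: float = 75.0,
                      duration_s: float = 30.0, fs: float = 80.0,
                      noise_sd_dps: float = 0.0, damping: float = 0.05,
                      rng=None):
    """Simulated rigid-arm pendulum released from rest.

    A uniform rod pivoted at one end: theta'' = -(3 g / 2 L) sin(theta)
    - damping * theta'. Returns a SensorStream whose sagittal (y) channel is
    the angular velocity in deg/s, plus the analytic angular displacement
    (degrees) as the oracle for the integrate-and-filter pipeline.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    omega0_sq = 3.0 * _G / (2.0 * arm_length_m)

    def rhs(_t, y):
        theta, omega = y
        return [omega, -omega0_sq * math.sin(theta) - damping * omega]

    t = np.arange(0.0, duration_s, 1.0 / fs)
    sol = solve_ivp(
        rhs, (0.0, duration_s), [math.radians(initial_deg), 0.0],
        t_eval=t, rtol=1e-10, atol=1e-12, method="DOP853",
    )
    theta_deg = np.degrees(sol.y[0])
    omega_dps = np.degrees(sol.y[1])
    gyro = np.zeros((len(t), 3))
    gyro[:, 1] = omega_dps + rng.normal(0.0, noise_sd_dps, size=len(t))
    stream = SensorStream(site="shank_R", fs=fs, t=t, gyro=gyro)
    return stream, theta_deg
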