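"""Domain types, file I/O and run configuration.

All on-disk formats are delimited text (CSV). Sensor streams are one file per
site per trial with columns ``time_s, gyro_x_dps, gyro_y_dps, gyro_z_dps``.
The axis convention is fixed: the sensor x-axis is aligned with the segment's
proximal-distal axis (pointing inferiorly), so

* x-axis -> transverse-plane rotation (axial twist),
* y-axis -> sagittal-plane rotation (flexion-extension),
* z-axis -> coronal-plane rotation (lateral bend).

Angular velocity is in degrees per second throughout; displacements and phase
angles in degrees; lengths in metres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("gaitload")

SITES = ("T6", "S1", "thigh_R", "shank_R")

#: plane -> column index of the gyro array (x, y, z)
PLANE_AXIS = {"transverse": 0, "sagittal": 1, "coronal": 2}
PLANES = ("coronal", "transverse", "sagittal")

#: load level labels -> box mass in kg
LOAD_LEVELS = {"NL": 0.0, "L": 4.5, "M": 9.1, "H": 13.6}
LOAD_BY_KG = {v: k for k, v in LOAD_LEVELS.items()}

CARRY_MODES = ("side", "anterior", "none")

STREAM_COLUMNS = ["time_s", "gyro_x_dps", "gyro_y_dps", "gyro_z_dps"]


class GaitloadError(ValueError):
    """Base class for domain validation errors."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SensorStream:
    """One sensor's tri-axial angular-velocity time series."""

    site: str
    fs: float
    t: np.ndarray          # seconds from trial start, strictly increasing
    gyro: np.ndarray       # shape (n, 3), deg/s on axes (x, y, z)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.site not in SITES:
            raise GaitloadError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.fs <= 0:
            raise GaitloadError("fs must be positive")
        if self.gyro.ndim != 2 or self.gyro.shape[1] != 3:
            raise GaitloadError("gyro must have shape (n, 3)")
        if len(self.t) != len(self.gyro):
            raise GaitloadError("time and gyro lengths differ")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise GaitloadError("non-monotonic time")

    @property
    def n(self) -> int:
        return len(self.t)

    def axis(self, plane: str) -> np.ndarray:
        """Angular velocity for an anatomical plane (deg/s)."""
        return self.gyro[:, PLANE_AXIS[plane]]


@dataclass
class TrialRecord:
    """One walk trial: identifying keys plus the per-site sensor streams."""

    participant_id: str
    carry_mode: str        # side | anterior | none
    load_kg: float         # 0, 4.5, 9.1, 13.6
    trial_index: int
    streams: dict = field(default_factory=dict)   # site -> SensorStream

    def __post_init__(self) -> None:
        if self.carry_mode not in CARRY_MODES:
            raise GaitloadError(f"unknown carry mode {self.carry_mode!r}")
        if self.load_kg not in LOAD_BY_KG:
            raise GaitloadError(f"unknown load level {self.load_kg!r}")
        if self.load_kg == 0.0 and self.carry_mode != "none":
            raise GaitloadError("no-load trials must carry carry_mode='none'")

    @property
    def load_label(self) -> str:
        return LOAD_BY_KG[self.load_kg]

    @property
    def key(self) -> tuple:
        return (self.participant_id, self.carry_mode, self.load_kg, self.trial_index)


@dataclass
class Anthropometry:
    participant_id: str
    stature_m: float
    leg_length_m: float
    thigh_length_m: float
    shank_length_m: float

    def __post_init__(self) -> None:
        for name in ("stature_m", "leg_length_m", "thigh_length_m", "shank_length_m"):
            if getattr(self, name) <= 0:
                raise GaitloadError(f"{name} must be positive")
        if self.leg_length_m >= self.stature_m:
            raise GaitloadError("leg length must be smaller than stature")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PreprocessConfig:
    lowpass_hz: float = 2.0        # sway low-pass cutoff
    highpass_hz: float = 0.75      # drift high-pass cutoff (trial-level path)
    order: int = 2
    zero_lag: bool = True
    # 'per_cycle' restarts the integral at each heel-strike (default);
    # 'trial_highpass' integrates the whole trial then high-passes.
    displacement_source: str = "per_cycle"
    remove_bias: bool = True       # subtract trial-mean velocity over whole cycles
    detrend_cycle: bool = False    # additional endpoint detrend within each cycle
    min_cycle_s: float = 0.4
    max_cycle_s: float = 2.5
    n_norm_points: int = 101


@dataclass
class EventConfig:
    prominence_frac: float = 0.40  # of the 95th percentile |omega|
    min_separation_s: float = 0.4
    minima_window_s: float = 0.35
    auto_flip: bool = True
    # coarse-to-fine: mid-swing peaks are located on the 2 Hz signal, but the
    # sharp heel-strike/toe-off minima are picked on a lightly filtered copy
    # of the raw signal (the 2 Hz smoothing skews or erases narrow dips)
    refine_cutoff_hz: float = 8.0


@dataclass
class StrideConfig:
    lowpass_hz: float = 4.0        # gentler cutoff for segment-rotation integrals
    max_rotation_deg: float = 120.0


@dataclass
class PhaseConfig:
    absolute: bool = True          # |wrapped difference| before averaging
    unwrap_before_diff: bool = False


@dataclass
class StatsConfig:
    alpha: float = 0.05
    # Bonferroni family sizes: mode-within-load contrasts are 4 families of 1,
    # load-within-mode are 2 families of 6 comparisons.
    m_mode_within_load: int = 1
    m_load_within_mode: int = 6


@dataclass
class SimulateConfig:
    # study-condition defaults live on GaitSimParams; here only the PRNG
    prng: str = "numpy-PCG64"


@dataclass
class Config:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    events: EventConfig = field(default_factory=EventConfig)
    stride: StrideConfig = field(default_factory=StrideConfig)
    phase: PhaseConfig = field(default_factory=PhaseConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "events": EventConfig,
    "stride": StrideConfig,
    "phase": PhaseConfig,
    "stats": StatsConfig,
    "simulate": SimulateConfig,
}


def load_config(path=None) -> Config:
    """Load a YAML config; missing sections/keys fall back to defaults."""
    cfg = Config()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for section, cls in _SECTIONS.items():
        vals = raw.get(section) or {}
        known = asdict(getattr(cfg, section))
        unknown = set(vals) - set(known)
        if unknown:
            raise GaitloadError(f"unknown config keys in [{section}]: {sorted(unknown)}")
        known.update(vals)
        setattr(cfg, section, cls(**known))
    return cfg


def save_config(cfg: Config, path) -> None:
    raw = {name: asdict(getattr(cfg, name)) for name in _SECTIONS}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# stream / table I/O
# ---------------------------------------------------------------------------


def read_sensor_stream(path, site: str, expected_fs: float = 80.0) -> SensorStream:
    """Read one sensor file, validate, and infer the sampling rate.

    The rate is inferred from the median time step and must agree with
    ``expected_fs`` within 1%.
    """
    df = pd.read_csv(path)
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise GaitloadError(f"{path}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise GaitloadError(f"{path}: need at least 2 samples")
    if not np.all(np.diff(t) > 0):
        raise GaitloadError(f"{path}: non-monotonic time")
    fs = 1.0 / float(np.median(np.diff(t)))
    if expected_fs and abs(fs - expected_fs) / expected_fs > 0.01:
        raise GaitloadError(
            f"{path}: fs mismatch: inferred {fs:.2f} Hz vs configured {expected_fs} Hz"
        )
    gyro = df[["gyro_x_dps", "gyro_y_dps", "gyro_z_dps"]].to_numpy(dtype=float)
    return SensorStream(site=site, fs=expected_fs or fs, t=t, gyro=gyro)


def write_sensor_stream(stream: SensorStream, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": stream.t,
            "gyro_x_dps": stream.gyro[:, 0],
            "gyro_y_dps": stream.gyro[:, 1],
            "gyro_z_dps": stream.gyro[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


MANIFEST_KEYS = ["participant_id", "carry_mode", "load_kg", "trial_index"]


def read_manifest(path):
    """Read a trial manifest into a DataFrame of trial stubs.

    One row per (participant, mode, load, trial) with per-site file path
    columns ``path_<site>``. Paths are kept relative to the manifest location.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    if df.empty:
        logger.warning("manifest %s is empty", path)
        return df
    for col in MANIFEST_KEYS:
        if col not in df.columns:
            raise GaitloadError(f"manifest missing column {col!r}")
    bad_loads = set(df["load_kg"].astype(float)) - set(LOAD_BY_KG)
    if bad_loads:
        raise GaitloadError(f"unknown load level: {sorted(bad_loads)}")
    dup = df.duplicated(subset=MANIFEST_KEYS)
    if dup.any():
        raise GaitloadError(
            f"duplicate manifest rows: {df.loc[dup, MANIFEST_KEYS].to_dict('records')}"
        )
    df["load_kg"] = df["load_kg"].astype(float)
    base = Path(path).parent
    for site in SITES:
        col = f"path_{site}"
        if col in df.columns:
            df[col] = [str(base / p) for p in df[col]]
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_anthropometry(path) -> dict:
    df = pd.read_csv(path, dtype={"participant_id": str})
    out = {}
    for _, row in df.iterrows():
        a = Anthropometry(
            participant_id=row["participant_id"],
            stature_m=float(row["stature_m"]),
            leg_length_m=float(row["leg_length_m"]),
            thigh_length_m=float(row["thigh_length_m"]),
            shank_length_m=float(row["shank_length_m"]),
        )
        out[a.participant_id] = a
    return out


def write_anthropometry(anthro: dict, path) -> None:
    pd.DataFrame([asdict(a) for a in anthro.values()]).to_csv(path, index=False)


def load_trial(row, expected_fs: float = 80.0) -> TrialRecord:
    """Materialize a TrialRecord from a manifest row (reads the stream files)."""
    streams = {}
    for site in SITES:
        col = f"path_{site}"
        if col in row and isinstance(row[col], str) and row[col]:
            streams[site] = read_sensor_stream(row[col], site, expected_fs)
    mode = row["carry_mode"]
    return TrialRecord(
        participant_id=str(row["participant_id"]),
        carry_mode=mode,
        load_kg=float(row["load_kg"]),
        trial_index=int(row["trial_index"]),
        streams=streams,
    )


def write_features(features: pd.DataFrame, path) -> None:
    """Write the tidy per-cycle feature table (one row per gait cycle)."""
    features.to_csv(path, index=False, float_format="%.10g")


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})
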