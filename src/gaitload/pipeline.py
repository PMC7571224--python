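"""End-to-end processing: raw trials -> tidy per-cycle feature table.

For each trial: detect gait events on the shank, select the analyzed cycles
(2nd-6th by default), integrate T6/S1 angular velocity per cycle and plane,
and compute the eleven per-cycle parameters (cycle duration, stride length,
six ROMs, three mean relative phase angles) plus relative speed. Centering of
relative speed happens once over the whole analysis set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_config import (
    Config, GaitloadError, PLANES, TrialRecord, load_trial,
)
from .preprocess import butterworth, per_cycle_displacement, FilterSpec
from .events import (
    CyclePolicy, NoGaitError, detect_events, segment_cycles,
    stride_length, relative_speed, center,
)
from .sway_phase import rom, relative_phase_frames, ensemble_phase_curve

logger = logging.getLogger("gaitload")

KEY_COLS = ["participant_id", "carry_mode", "load_kg", "trial_index", "cycle"]


def process_trial(record: TrialRecord, anthro, cfg: Config | None = None,
                  policy: CyclePolicy | None = None,
                  collect_phase: bool = False) -> pd.DataFrame:
    """Per-cycle features for one trial (one row per analyzed gait cycle).

    ``anthro`` is the participant's Anthropometry. Requires T6, S1 and shank
    streams; the thigh stream is optional (stride length is NaN without it).
    Set ``collect_phase`` to also return the per-frame relative-phase arrays
    (plane -> list of (cycle, frames)) for ensemble curves.
    """
    cfg = cfg or Config()
    policy = policy or CyclePolicy()
    needed = {"T6", "S1", "shank_R"}
    missing = needed - set(record.streams)
    if missing:
        raise GaitloadError(f"trial {record.key}: missing required sites {sorted(missing)}")

    shank = record.streams["shank_R"]
    sh_filt = butterworth(
        shank.axis("sagittal"), shank.fs,
        FilterSpec("lowpass", cfg.preprocess.order, cfg.preprocess.lowpass_hz,
                   cfg.preprocess.zero_lag),
    )
    events = detect_events(
        sh_filt, shank.fs, cfg.events, prefiltered=True, raw=shank.axis("sagittal")
    )
    pairs = segment_cycles(events, policy)

    segs = {
        (site, plane): per_cycle_displacement(record.streams[site], events, plane,
                                              cfg.preprocess)
        for site in ("T6", "S1") for plane in PLANES
    }
    durations = events.cycle_durations()
    if "thigh_R" in record.streams:
        strides = stride_length(
            record.streams["thigh_R"].axis("sagittal"),
            shank.axis("sagittal"),
            shank.t, events,
            anthro.thigh_length_m, anthro.shank_length_m, shank.fs,
            cfg.stride, cfg.preprocess,
        )
    else:
        strides = np.full(events.n_cycles, np.nan)

    phase_store: dict = {plane: [] for plane in PLANES} if collect_phase else None
    rows = []
    for k, _ in pairs:
        row = {
            "participant_id": record.participant_id,
            "carry_mode": record.carry_mode,
            "load_kg": record.load_kg,
            "trial_index": record.trial_index,
            "cycle": k + 1,
            "cycle_duration_s": durations[k],
            "stride_length_m": strides[k],
            "valid": True,
        }
        for plane in PLANES:
            s_t6 = segs[("T6", plane)][k]
            s_s1 = segs[("S1", plane)][k]
            if not (s_t6.valid and s_s1.valid):
                row[f"rom_T6_{plane}"] = np.nan
                row[f"rom_S1_{plane}"] = np.nan
                row[f"mrp_{plane}"] = np.nan
                row["valid"] = False
                continue
            row[f"rom_T6_{plane}"] = rom(s_t6)
            row[f"rom_S1_{plane}"] = rom(s_s1)
            try:
                frames = relative_phase_frames(
                    s_t6.omega, s_t6.theta, s_s1.omega, s_s1.theta, cfg.phase
                )
                row[f"mrp_{plane}"] = float(np.mean(frames))
                if collect_phase:
                    phase_store[plane].append((k + 1, frames))
            except GaitloadError as exc:
                logger.warning("trial %s cycle %d %s: %s", record.key, k + 1, plane, exc)
                row[f"mrp_{plane}"] = np.nan
                row["valid"] = False
        rows.append(row)
    df = pd.DataFrame(rows)
    df["relative_speed"] = relative_speed(
        df["stride_length_m"], df["cycle_duration_s"], anthro.leg_length_m
    )
    if collect_phase:
        return df, phase_store
    return df


def apply_drop_list(features: pd.DataFrame, drop_list: pd.DataFrame | None) -> pd.DataFrame:
    """Discard the analyzed cycles listed in a drop-list table."""
    if drop_list is None or drop_list.empty:
        return features
    keys = ["participant_id", "carry_mode", "load_kg", "trial_index", "cycle"]
    drop = drop_list[keys].copy()
    drop["participant_id"] = drop["participant_id"].astype(str)
    merged = features.merge(drop.assign(_drop=True), on=keys, how="left")
    kept = merged[merged["_drop"].isna()].drop(columns="_drop").reset_index(drop=True)
    n = len(features) - len(kept)
    if n != len(drop_list):
        logger.warning("drop-list matched %d rows, expected %d", n, len(drop_list))
    return kept


def process_trials(trials, anthropometry: dict, cfg: Config | None = None,
                   policy: CyclePolicy | None = None,
                   drop_list: pd.DataFrame | None = None) -> pd.DataFrame:
    """Process in-memory trials into the tidy feature table.

    ``trials`` is an iterable of TrialRecord (or (TrialRecord, GroundTruth)
    pairs, as produced by the synthetic designs). Relative speed is centered
    over all analyzed cycles at the end.
    """
    cfg = cfg or Config()
    frames = []
    for item in trials:
        record = item[0] if isinstance(item, tuple) else item
        anthro = anthropometry[record.participant_id]
        try:
            frames.append(process_trial(record, anthro, cfg, policy))
        except (NoGaitError, GaitloadError) as exc:
            logger.warning("trial %s skipped: %s", record.key, exc)
    if not frames:
        return pd.DataFrame(columns=KEY_COLS)
    features = pd.concat(frames, ignore_index=True)
    features = apply_drop_list(features, drop_list)
    features["centered_relative_speed"] = center(features["relative_speed"])
    return features


def process_manifest(manifest: pd.DataFrame, anthropometry: dict,
                     cfg: Config | None = None,
                     policy: CyclePolicy | None = None,
                     drop_list: pd.DataFrame | None = None,
                     expected_fs: float = 80.0) -> pd.DataFrame:
    """Process a manifest of on-disk trials into the feature table."""
    records = (load_trial(row, expected_fs) for _, row in manifest.iterrows())
    return process_trials(records, anthropometry, cfg, policy, drop_list)


def ensemble_curves(trials, anthropometry: dict, plane: str,
                    cfg: Config | None = None,
                    policy: CyclePolicy | None = None):
    """Condition-wise ensemble relative-phase curves from in-memory trials.

    Returns {condition_label: PhaseCurve}; conditions are 'mode-load' strings
    with the shared no-load trials labelled 'none-NL'.
    """
    cfg = cfg or Config()
    by_condition: dict = {}
    for item in trials:
        record = item[0] if isinstance(item, tuple) else item
        anthro = anthropometry[record.participant_id]
        try:
            _, phases = process_trial(record, anthro, cfg, policy, collect_phase=True)
        except (NoGaitError, GaitloadError) as exc:
            logger.warning("trial %s skipped: %s", record.key, exc)
            continue
        label = f"{record.carry_mode}-{record.load_label}"
        store = by_condition.setdefault(label, [])
        for _, frames in phases[plane]:
            store.append((record.participant_id, frames))
    return {
        label: ensemble_phase_curve(cycles, plane, label,
                                    cfg.preprocess.n_norm_points, cfg.phase)
        for label, cycles in by_condition.items()
        if len(cycles) >= 2
    }
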