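"""Synthetic kinematic cohorts with planted, recoverable ground truth.

Trajectories are analytic compositions of sinusoid/ballistic segments, not
biomechanical simulations: the point is that every quantity the feature
pipeline extracts (gait speed, stride length, swing ankle clearance,
shoulder/elbow angle peaks, chair-task durations, jump apex, calf-raise
count) is planted exactly and recorded in a ground-truth table, so parameter
recovery, null calibration and effect-faithfulness are all testable without
any recorded data.

Default group effects encode the qualitative clinical picture — FSHD with
shorter strides, elevated swing-phase foot lift (steppage compensation for
foot drop) and proximal upper-limb impairment (reduced shoulder abduction,
elbow-flexion compensation); myotonic dystrophy (DM) with slowed chair rise
and reduced plantarflexor/jump performance — with magnitudes that are
package constants chosen for plausibility, not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError
from .io import (
    GROUPS,
    KinematicsRecording,
    Participant,
    TFTRecord,
    write_mot,
    write_trc,
)

G_M_S2 = 9.80665

#: Baseline (control) performance constants. Heights in m, speeds in m/s,
#: times in s, angles in degrees. These are plausibility constants of the
#: generator, not measurements.
BASELINES = {
    "walk_speed": 1.30,
    "stride_length_frac": 0.78,  # stride length / height
    "run_speed": 2.60,
    "run_stride_frac": 1.05,
    "swing_clearance": 0.015,  # peak ankle lift above stance, m
    "sts_total_s": 9.0,
    "tug_total_s": 8.0,
    "jump_apex": 0.28,
    "calf_count": 20,
    "calf_height": 0.08,
    "calf_decay": 0.2,
    "elbow_rom": 110.0,
    "angle_baseline": 10.0,
}

#: Female fraction per group used for deterministic sex assignment.
FEMALE_FRACTION = {"FSHD": 4 / 28, "DM": 31 / 58, "CTL": 22 / 43}

AGE_MEAN_SD = {"FSHD": (48, 16), "DM": (41, 14), "CTL": (44, 17)}
BMI_MEAN_SD = {"FSHD": (25.8, 4.6), "DM": (25.4, 6.6), "CTL": (24.7, 4.4)}


class GroupEffects(BaseModel):
    """Planted group-level effects applied on top of the baselines."""

    stride_length_mult: float = Field(1.0, gt=0)
    swing_ankle_height_add: float = Field(0.0, ge=0)  # m, added peak clearance
    walk_speed_mult: float = Field(1.0, gt=0)
    shoulder_abd_max: float = Field(165.0, gt=0, le=180)  # deg
    elbow_flex_compensation: float = Field(5.0, ge=0)  # deg at peak abduction
    sts_time_mult: float = Field(1.0, gt=0)
    jump_height_mult: float = Field(1.0, gt=0)
    calf_raise_count_mult: float = Field(1.0, gt=0)
    p_unable_ankle_tasks: float = Field(0.0, ge=0, le=1)


def default_effects() -> dict[str, GroupEffects]:
    return {
        "CTL": GroupEffects(),
        "FSHD": GroupEffects(
            stride_length_mult=0.88,
            swing_ankle_height_add=0.025,
            walk_speed_mult=0.95,
            shoulder_abd_max=125.0,
            elbow_flex_compensation=30.0,
            sts_time_mult=1.30,
            jump_height_mult=0.85,
            calf_raise_count_mult=0.85,
            p_unable_ankle_tasks=0.20,
        ),
        "DM": GroupEffects(
            stride_length_mult=0.97,
            walk_speed_mult=0.93,
            shoulder_abd_max=160.0,
            elbow_flex_compensation=8.0,
            sts_time_mult=1.40,
            jump_height_mult=0.60,
            calf_raise_count_mult=0.60,
            p_unable_ankle_tasks=0.30,
        ),
    }


def null_effects() -> dict[str, GroupEffects]:
    """Identical (control) effects for every group: the calibration null."""
    return {g: GroupEffects() for g in GROUPS}


class NoiseConfig(BaseModel):
    marker_jitter_sd: float = Field(0.004, ge=0)  # m
    angle_jitter_sd: float = Field(1.0, ge=0)  # deg
    subject_sd: float = Field(0.12, ge=0)  # lognormal sigma on performance
    tft_timing_sd: float = Field(0.15, ge=0)  # stopwatch noise, s
    brooke_grader_sd: float = Field(0.25, ge=0)  # lognormal sigma on the
    # planted ratio before ordinal thresholding (grader insensitivity)


class RetestConfig(BaseModel):
    n_retest: int = Field(0, ge=0)
    day_effect_sd: float = Field(0.05, ge=0)  # fractional day-to-day variance


class SyntheticCohortConfig(BaseModel):
    n_fshd: int = Field(ge=0)
    n_dm: int = Field(ge=0)
    n_ctl: int = Field(ge=0)
    seed: int
    sampling_rate: float = Field(60.0, ge=60)
    effects: dict[str, GroupEffects] = Field(default_factory=default_effects)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    retest: RetestConfig = Field(default_factory=RetestConfig)

    @model_validator(mode="after")
    def _check_groups(self):
        unknown = set(self.effects) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups in effects: {sorted(unknown)}")
        for g in GROUPS:
            self.effects.setdefault(g, GroupEffects())
        return self


@dataclass
class SubjectParams:
    """Per-subject planted performance parameters (after group effects and
    between-subject variation)."""

    participant_id: str
    group: str
    sex: str
    age: float
    height: float
    bmi: float
    walk_speed: float
    stride_length_m: float
    run_speed: float
    run_stride_m: float
    swing_clearance: float
    shoulder_abd_max_r: float
    shoulder_abd_max_l: float
    elbow_comp_r: float
    elbow_comp_l: float
    elbow_rom: float
    sts_total_s: float
    tug_total_s: float
    jump_apex: float
    calf_count: int
    calf_height: float
    calf_decay: float
    unable_ankle: bool
    session: int = 1


def _pelvis_markers(center: np.ndarray) -> dict[str, np.ndarray]:
    offsets = {
        "r_asis": np.array([0.06, -0.02, 0.12]),
        "l_asis": np.array([0.06, -0.02, -0.12]),
        "r_psis": np.array([-0.06, 0.00, 0.08]),
        "l_psis": np.array([-0.06, 0.00, -0.08]),
    }
    return {name: center + off for name, off in offsets.items()}


def _jitter(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    return rng.normal(0.0, sd, shape) if sd > 0 else np.zeros(shape)


def _smooth_rise(u: np.ndarray) -> np.ndarray:
    """Cosine ramp 0 -> 1 over u in [0, 1], zero slope at both ends."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# gait


def generate_gait_trial(
    params: SubjectParams,
    seed: int,
    activity: str = "walk",
    fs: float = 60.0,
    duration_s: float | None = None,
    marker_jitter_sd: float = 0.0,
) -> tuple[KinematicsRecording, dict]:
    """Constant-speed gait with a parameterized periodic swing profile.

    The pelvis translates at the planted speed; each foot is stationary
    during stance (duty factor 0.6 walk / 0.55 run) and advances one stride
    length during swing with a cosine profile, with a half-sine ankle lift of
    the planted clearance. Heel strikes and toe offs are recorded as ground
    truth.
    """
    if activity == "walk":
        v, stride, duty = params.walk_speed, params.stride_length_m, 0.60
        duration_s = duration_s or 8.0
    elif activity == "run":
        v, stride, duty = params.run_speed, params.run_stride_m, 0.55
        duration_s = duration_s or 6.0
    else:
        raise ConfigurationError(f"not a gait activity: {activity!r}")
    if v <= 0 or stride <= 0:
        raise ConfigurationError("planted speed and stride length must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    T = stride / v  # stride period per side
    com_h = 0.55 * params.height + 0.012 * np.sin(2 * np.pi * (2 / T) * t)
    center = np.column_stack([v * t, com_h, np.zeros(n)])
    markers = _pelvis_markers(center)

    gt_events: dict[str, dict[str, list[float]]] = {}
    clearance = params.swing_clearance
    for side, phase, lat in (("r", 0.25, 0.10), ("l", 0.75, -0.10)):
        ts = t + phase * T  # shifted so cycles start at a heel strike
        cycle = np.floor(ts / T)
        u = ts / T - cycle
        base_x = cycle * stride - phase * stride
        swing = u >= duty
        su = (u - duty) / (1.0 - duty)
        # linear swing advance: the anterior foot-pelvis distance then peaks
        # exactly at heel strike and bottoms exactly at toe off, so the
        # planted events coincide with the coordinate-based definition
        foot_x = base_x + np.where(swing, stride * np.clip(su, 0, 1), 0.0)
        lift = np.where(swing, clearance * np.sin(np.pi * np.clip(su, 0, 1)), 0.0)
        heel = np.column_stack([foot_x, 0.03 + lift, np.full(n, lat)])
        toe = heel + np.array([0.18, -0.01, 0.0])
        ankle = heel + np.array([0.05, 0.07, 0.02 * (1 if side == "r" else -1)])
        markers[f"{side}_heel"] = heel
        markers[f"{side}_toe"] = toe
        markers[f"{side}_ankle"] = ankle
        hs = [k * T - phase * T for k in range(int(duration_s / T) + 2)]
        to = [h + duty * T for h in hs]
        gt_events[side] = {
            "heel_strikes": [x for x in hs if 0 <= x <= duration_s],
            "toe_offs": [x for x in to if 0 <= x <= duration_s],
        }

    for name in markers:
        markers[name] = markers[name] + _jitter(rng, (n, 3), marker_jitter_sd)

    rec = KinematicsRecording(
        participant_id=params.participant_id,
        activity=activity,
        time=t,
        sampling_rate=fs,
        markers=markers,
        participant_height=params.height,
        session=params.session,
    ).validate()
    gt = {
        "speed": v,
        "stride_length_m": stride,
        "stride_length": stride / params.height,
        "cadence": 1.0 / T,
        # the extractor reports the mean swing elevation; a half-sine lift of
        # peak c has mean 2c/pi over the swing phase
        "swing_ankle_height_m": clearance * 2 / math.pi,
        "swing_ankle_height": clearance * 2 / math.pi / params.height,
        "events": gt_events,
    }
    return rec, gt


# ---------------------------------------------------------------------------
# chair / jump / calf-raise tasks


def _standing_com(height: float) -> float:
    return 0.55 * height


def generate_task_trial(
    params: SubjectParams,
    seed: int,
    activity: str,
    fs: float = 60.0,
    marker_jitter_sd: float = 0.0,
    n_reps: int = 5,
    plant_jitter_peaks: bool = False,
) -> tuple[KinematicsRecording, dict]:
    """Chair-rise, jump and calf-raise trials as smooth COM-height profiles."""
    rng = np.random.default_rng(seed)
    stand = _standing_com(params.height)
    amp = 0.20 * params.height
    seated = stand - amp
    gt: dict = {}

    if activity == "sit_to_stand":
        d = params.sts_total_s / n_reps if n_reps else 1.0
        lead = 1.5
        total = params.sts_total_s
        dur = lead + total + 1.5
        n = int(round(dur * fs)) + 1
        t = np.arange(n) / fs
        h = np.full(n, seated)
        for k in range(n_reps):
            m = (t >= lead + k * d) & (t < lead + (k + 1) * d)
            u = (t[m] - lead - k * d) / d
            h[m] = seated + amp * 0.5 * (1 - np.cos(2 * np.pi * u))
        gt["boundaries"] = [lead + k * d for k in range(n_reps + 1)]
        gt["task_time"] = total if n_reps else 0.0
    elif activity == "timed_up_and_go":
        rise = 0.6
        # gross elevated span chosen so the 10%-threshold interval equals the
        # planted TUG time (crossing offset of a cosine rise at 10% amplitude)
        cross = math.acos(1 - 2 * 0.1) / math.pi * rise
        gross = params.tug_total_s + 2 * cross
        lead = 1.5
        dur = lead + gross + 1.5
        n = int(round(dur * fs)) + 1
        t = np.arange(n) / fs
        h = np.full(n, seated)
        up = (t >= lead) & (t < lead + rise)
        h[up] = seated + amp * _smooth_rise((t[up] - lead) / rise)
        mid = (t >= lead + rise) & (t < lead + gross - rise)
        h[mid] = stand + 0.01 * np.sin(2 * np.pi * 1.8 * (t[mid] - lead - rise))
        down = (t >= lead + gross - rise) & (t < lead + gross)
        h[down] = seated + amp * _smooth_rise((lead + gross - t[down]) / rise)
        gt["task_time"] = params.tug_total_s
        gt["gross_span"] = gross
    elif activity == "jump":
        apex = params.jump_apex
        v_to = math.sqrt(2 * G_M_S2 * apex)
        dip = 0.12
        t_push = 2 * dip / v_to
        t_flight = 2 * v_to / G_M_S2
        segs = [1.0, 0.35, t_push, t_flight, 0.25, 1.2]
        dur = sum(segs)
        n = int(round(dur * fs)) + 1
        t = np.arange(n) / fs
        h = np.full(n, stand)
        t0 = segs[0]
        m = (t >= t0) & (t < t0 + segs[1])  # countermovement dip
        h[m] = stand - dip * _smooth_rise((t[m] - t0) / segs[1])
        t1 = t0 + segs[1]
        m = (t >= t1) & (t < t1 + t_push)  # push: quadratic, ends at v_to
        h[m] = (stand - dip) + 0.5 * (v_to / t_push) * (t[m] - t1) ** 2
        t2 = t1 + t_push
        m = (t >= t2) & (t < t2 + t_flight)  # ballistic flight
        tau = t[m] - t2
        h[m] = stand + v_to * tau - 0.5 * G_M_S2 * tau**2
        t3 = t2 + t_flight
        m = (t >= t3) & (t < t3 + segs[4])  # landing absorption
        h[m] = stand - 0.06 * np.sin(np.pi * (t[m] - t3) / segs[4])
        gt["jump_height"] = apex
        gt["takeoff_com_velocity"] = v_to
    elif activity == "calf_raise":
        dur = 32.0
        n = int(round(dur * fs)) + 1
        t = np.arange(n) / fs
        h = np.full(n, stand)
        gt["n_raises"] = params.calf_count
    else:
        raise ConfigurationError(f"not a task activity: {activity!r}")

    center = np.column_stack([np.zeros(n), h, np.zeros(n)])
    markers = _pelvis_markers(center)
    heel_h = np.full(n, 0.02)
    if activity == "calf_raise":
        count = params.calf_count
        if count > 0:
            spacing = 27.0 / count
            width = min(0.8, 0.6 * spacing)
            peaks = []
            for k in range(count):
                t_k = 1.5 + k * spacing
                m = (t >= t_k) & (t < t_k + width)
                a_k = params.calf_height * (
                    1 - params.calf_decay * (k / max(count - 1, 1))
                )
                heel_h[m] += a_k * np.sin(np.pi * (t[m] - t_k) / width) ** 2
                peaks.append(a_k)
            gt["mean_raise_height"] = float(np.mean(peaks))
            f = params.calf_decay
            gt["raise_rate_decay"] = f / (1 - f / 2) if count > 1 else 0.0
            if plant_jitter_peaks:
                for k in range(count - 1):
                    t_k = 1.5 + (k + 0.7) * spacing
                    m = (t >= t_k) & (t < t_k + 0.3)
                    heel_h[m] += 0.08 * params.calf_height * np.sin(
                        np.pi * (t[m] - t_k) / 0.3
                    ) ** 2
        else:
            gt["mean_raise_height"] = 0.0
            gt["raise_rate_decay"] = 0.0
    elif activity == "jump":
        flight = (h - stand) > 0
        heel_h = heel_h + np.where(flight, h - stand, 0.0)
    for side, lat in (("r", 0.10), ("l", -0.10)):
        heel = np.column_stack([np.full(n, 0.1), heel_h, np.full(n, lat)])
        markers[f"{side}_heel"] = heel
        markers[f"{side}_toe"] = heel + np.array([0.18, -0.005, 0.0])
        markers[f"{side}_ankle"] = heel + np.array([0.05, 0.07, 0.0])
    for name in markers:
        markers[name] = markers[name] + _jitter(rng, (n, 3), marker_jitter_sd)
    rec = KinematicsRecording(
        participant_id=params.participant_id,
        activity=activity,
        time=t,
        sampling_rate=fs,
        markers=markers,
        participant_height=params.height,
        session=params.session,
    ).validate()
    return rec, gt


# ---------------------------------------------------------------------------
# upper limb


def generate_upper_limb_trial(
    params: SubjectParams,
    seed: int,
    activity: str,
    fs: float = 60.0,
    angle_jitter_sd: float = 0.0,
    marker_jitter_sd: float = 0.0,
    sides: tuple[str, ...] = ("r", "l"),
) -> tuple[KinematicsRecording, dict]:
    """Shoulder-abduction / elbow-flexion / arm-ROM trials.

    Shoulder abduction ramps to the planted per-side maximum with elbow
    flexion rising by the planted compensation as the shoulder saturates; the
    arm-ROM wrist path sweeps a circular sector (out from the pivot, sweep,
    retract) so its frontal-plane convex hull has the closed-form sector area.
    """
    rng = np.random.default_rng(seed)
    dur = 8.0 if activity != "elbow_flexion" else 6.0
    n = int(round(dur * fs)) + 1
    t = np.arange(n) / fs
    base = BASELINES["angle_baseline"]
    gt: dict = {"sides": {}}
    angles: dict[str, np.ndarray] = {}

    def ramp_profile(peak: float) -> np.ndarray:
        prof = np.full(n, base)
        up = (t >= 1.0) & (t < 3.5)
        prof[up] = base + (peak - base) * _smooth_rise((t[up] - 1.0) / 2.5)
        hold = (t >= 3.5) & (t < 5.0)
        prof[hold] = peak
        down = (t >= 5.0) & (t < 7.5)
        prof[down] = base + (peak - base) * _smooth_rise((7.5 - t[down]) / 2.5)
        return prof

    if activity == "shoulder_abduction":
        for side in sides:
            peak = getattr(params, f"shoulder_abd_max_{side}")
            comp = getattr(params, f"elbow_comp_{side}")
            theta_s = ramp_profile(peak)
            progress = np.clip((theta_s - base) / max(peak - base, 1e-9), 0, 1)
            theta_e = 5.0 + comp * np.clip((progress - 0.7) / 0.3, 0, 1) ** 2
            angles[f"arm_abd_{side}"] = theta_s
            angles[f"elbow_flex_{side}"] = theta_e
            gt["sides"][side] = {
                "theta_s_peak": peak,
                "theta_e_at_peak": 5.0 + comp,
                "ratio": peak / max(5.0 + comp, 1.0),
                "shoulder_rom": peak - base,
            }
        gt["brooke_ratio"] = max(v["ratio"] for v in gt["sides"].values())
    elif activity == "elbow_flexion":
        for side in sides:
            peak = base + params.elbow_rom
            angles[f"elbow_flex_{side}"] = ramp_profile(peak)
            angles[f"arm_abd_{side}"] = np.full(n, base)
            gt["sides"][side] = {"elbow_rom": params.elbow_rom}
        gt["elbow_flexion_rom"] = params.elbow_rom
    elif activity != "arm_rom":
        raise ConfigurationError(f"not an upper-limb activity: {activity!r}")

    stand = _standing_com(params.height)
    center = np.column_stack([np.zeros(n), np.full(n, stand), np.zeros(n)])
    markers = _pelvis_markers(center)

    if activity == "arm_rom":
        arm_len = 0.33 * params.height
        gt["areas"] = {}
        for side in sides:
            sgn = 1.0 if side == "r" else -1.0
            shoulder = np.array([0.0, 0.82 * params.height, sgn * 0.18])
            phi_max = math.radians(getattr(params, f"shoulder_abd_max_{side}"))
            u = t / dur
            radius = np.where(
                u < 0.2,
                arm_len * (u / 0.2),
                np.where(u < 0.8, arm_len, arm_len * (1 - u) / 0.2),
            )
            phi = np.where(
                u < 0.2, 0.0, np.where(u < 0.8, phi_max * (u - 0.2) / 0.6, phi_max)
            )
            wrist = shoulder + np.column_stack(
                [
                    np.zeros(n),
                    -radius * np.cos(phi),
                    sgn * radius * np.sin(phi),
                ]
            )
            markers[f"{side}_wrist"] = wrist
            gt["areas"][side] = 0.5 * arm_len**2 * phi_max
        gt["sector_area_total"] = sum(gt["areas"].values())

    for name in markers:
        markers[name] = markers[name] + _jitter(rng, (n, 3), marker_jitter_sd)
    for name in angles:
        angles[name] = angles[name] + _jitter(rng, n, angle_jitter_sd)
    rec = KinematicsRecording(
        participant_id=params.participant_id,
        activity=activity,
        time=t,
        sampling_rate=fs,
        markers=markers,
        joint_angles=angles,
        participant_height=params.height,
        session=params.session,
    ).validate()
    return rec, gt


# ---------------------------------------------------------------------------
# cohort


def brooke_from_ratio(ratio: float) -> int:
    """Map the planted abduction/flexion ratio to an ordinal Brooke score."""
    if ratio >= 15:
        return 6
    if ratio >= 4:
        return 5
    return 4


def draw_subject_params(
    config: SyntheticCohortConfig,
    participant_id: str,
    group: str,
    sex: str,
    rng: np.random.Generator,
    session: int = 1,
    day_factor: float = 1.0,
) -> SubjectParams:
    eff = config.effects[group]
    noise = config.noise

    def perf(base: float, mult: float = 1.0) -> float:
        return base * mult * day_factor * rng.lognormal(0.0, noise.subject_sd)

    height = rng.normal(1.77 if sex == "M" else 1.63, 0.07 if sex == "M" else 0.06)
    height = float(np.clip(height, 1.40, 2.05))
    age = float(np.clip(rng.normal(*AGE_MEAN_SD[group]), 18, 85))
    bmi = float(np.clip(rng.normal(*BMI_MEAN_SD[group]), 16, 45))
    clearance = BASELINES["swing_clearance"] + eff.swing_ankle_height_add
    clearance = max(clearance * day_factor + rng.normal(0, 0.004), 0.002)
    sh_r = float(np.clip(rng.normal(eff.shoulder_abd_max, 8.0), 40, 180))
    sh_l = float(np.clip(rng.normal(eff.shoulder_abd_max, 8.0), 40, 180))
    comp_r = float(np.clip(rng.normal(eff.elbow_flex_compensation, 5.0), 0, 90))
    comp_l = float(np.clip(rng.normal(eff.elbow_flex_compensation, 5.0), 0, 90))
    return SubjectParams(
        participant_id=participant_id,
        group=group,
        sex=sex,
        age=age,
        height=height,
        bmi=bmi,
        walk_speed=perf(BASELINES["walk_speed"], eff.walk_speed_mult),
        stride_length_m=perf(
            BASELINES["stride_length_frac"] * height, eff.stride_length_mult
        ),
        run_speed=perf(BASELINES["run_speed"], eff.walk_speed_mult),
        run_stride_m=perf(
            BASELINES["run_stride_frac"] * height, eff.stride_length_mult
        ),
        swing_clearance=clearance,
        shoulder_abd_max_r=sh_r,
        shoulder_abd_max_l=sh_l,
        elbow_comp_r=comp_r,
        elbow_comp_l=comp_l,
        elbow_rom=perf(BASELINES["elbow_rom"]),
        sts_total_s=perf(BASELINES["sts_total_s"], eff.sts_time_mult),
        tug_total_s=perf(BASELINES["tug_total_s"], eff.sts_time_mult),
        jump_apex=perf(BASELINES["jump_apex"], eff.jump_height_mult),
        calf_count=int(
            round(perf(BASELINES["calf_count"], eff.calf_raise_count_mult))
        ),
        calf_height=perf(BASELINES["calf_height"]),
        calf_decay=float(np.clip(rng.normal(BASELINES["calf_decay"], 0.05), 0, 0.6)),
        unable_ankle=bool(rng.random() < eff.p_unable_ankle_tasks),
        session=session,
    )


def perturb_for_retest(
    params: SubjectParams, config: SyntheticCohortConfig, rng: np.random.Generator
) -> SubjectParams:
    """Next-day copy of a subject: same person, performance parameters
    perturbed by independent multiplicative day effects."""
    from dataclasses import replace

    sd = config.retest.day_effect_sd

    def day(x: float) -> float:
        return x * float(rng.lognormal(0.0, sd))

    return replace(
        params,
        session=2,
        walk_speed=day(params.walk_speed),
        stride_length_m=day(params.stride_length_m),
        run_speed=day(params.run_speed),
        run_stride_m=day(params.run_stride_m),
        swing_clearance=max(day(params.swing_clearance), 0.002),
        shoulder_abd_max_r=float(np.clip(params.shoulder_abd_max_r + rng.normal(0, 2.0), 40, 180)),
        shoulder_abd_max_l=float(np.clip(params.shoulder_abd_max_l + rng.normal(0, 2.0), 40, 180)),
        elbow_comp_r=float(np.clip(params.elbow_comp_r + rng.normal(0, 2.0), 0, 90)),
        elbow_comp_l=float(np.clip(params.elbow_comp_l + rng.normal(0, 2.0), 0, 90)),
        elbow_rom=day(params.elbow_rom),
        sts_total_s=day(params.sts_total_s),
        tug_total_s=day(params.tug_total_s),
        jump_apex=day(params.jump_apex),
        calf_count=max(int(round(day(float(params.calf_count)))), 0),
        calf_height=day(params.calf_height),
        calf_decay=float(np.clip(params.calf_decay + rng.normal(0, 0.02), 0, 0.6)),
    )


ALL_ACTIVITIES = (
    "walk",
    "run",
    "timed_up_and_go",
    "sit_to_stand",
    "calf_raise",
    "jump",
    "shoulder_abduction",
    "elbow_flexion",
    "arm_rom",
)


def generate_subject_trials(
    params: SubjectParams, config: SyntheticCohortConfig, trial_seed: int
) -> tuple[list[KinematicsRecording], dict]:
    """All activity trials for one subject; ankle tasks skipped if unable."""
    fs = config.sampling_rate
    mj = config.noise.marker_jitter_sd
    aj = config.noise.angle_jitter_sd
    recs: list[KinematicsRecording] = []
    gts: dict = {}
    ss = np.random.SeedSequence(trial_seed).generate_state(len(ALL_ACTIVITIES))
    for i, activity in enumerate(ALL_ACTIVITIES):
        seed = int(ss[i] % (2**31))
        if activity in ("calf_raise", "jump") and params.unable_ankle:
            continue
        if activity in ("walk", "run"):
            rec, gt = generate_gait_trial(
                params, seed, activity, fs, marker_jitter_sd=mj
            )
        elif activity in ("sit_to_stand", "timed_up_and_go", "jump", "calf_raise"):
            rec, gt = generate_task_trial(
                params, seed, activity, fs, marker_jitter_sd=mj
            )
        else:
            rec, gt = generate_upper_limb_trial(
                params, seed, activity, fs, angle_jitter_sd=aj, marker_jitter_sd=mj
            )
        recs.append(rec)
        gts[activity] = gt
    return recs, gts


@dataclass
class CohortBundle:
    """An in-memory synthetic cohort plus its planted ground truth."""

    config: SyntheticCohortConfig
    participants: list[Participant]
    tft_records: list[TFTRecord]
    recordings: list[KinematicsRecording]
    ground_truth: pd.DataFrame
    subject_params: list[SubjectParams] = field(default_factory=list)

    def write(self, out_dir: str | Path, overwrite: bool = False) -> Path:
        """Emit TRC/MOT files, manifest.csv, trials.csv, tfts.csv and
        ground_truth.csv in the layout kinematics I/O reads back."""
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
            raise FileExistsError(f"{out_dir} exists and is not empty")
        out_dir.mkdir(parents=True, exist_ok=True)
        trial_rows = []
        for rec in self.recordings:
            stem = f"{rec.participant_id}_s{rec.session}_{rec.activity}"
            trc = mot = ""
            if rec.markers:
                trc = f"{stem}.trc"
                write_trc(rec, out_dir / trc)
            if rec.joint_angles:
                mot = f"{stem}.mot"
                write_mot(rec, out_dir / mot)
            trial_rows.append(
                {
                    "participant_id": rec.participant_id,
                    "session": rec.session,
                    "activity": rec.activity,
                    "trc_file": trc,
                    "mot_file": mot,
                }
            )
        pd.DataFrame(
            [
                {
                    "participant_id": p.participant_id,
                    "session": p.session,
                    "group": p.group,
                    "sex": p.sex,
                    "age": round(p.age, 1),
                    "height_m": round(p.height, 4),
                    "bmi": round(p.bmi, 2),
                }
                for p in self.participants
            ]
        ).to_csv(out_dir / "manifest.csv", index=False)
        pd.DataFrame(trial_rows).to_csv(out_dir / "trials.csv", index=False)
        pd.DataFrame([vars(r) for r in self.tft_records]).to_csv(
            out_dir / "tfts.csv", index=False
        )
        self.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
        return out_dir


def generate_cohort(config: SyntheticCohortConfig) -> CohortBundle:
    """Generate a full labeled cohort with planted effects and ground truth.

    The first ``retest.n_retest`` DM participants receive a second session
    with a day-to-day multiplicative perturbation of their performance
    parameters; human-measured TFT times are planted task durations plus
    stopwatch noise.
    """
    groups = (
        ["FSHD"] * config.n_fshd + ["DM"] * config.n_dm + ["CTL"] * config.n_ctl
    )
    # deterministic sex assignment reproducing the group female fractions
    sexes: list[str] = []
    for g, n_g in (("FSHD", config.n_fshd), ("DM", config.n_dm), ("CTL", config.n_ctl)):
        n_f = round(FEMALE_FRACTION[g] * n_g)
        sexes += ["F"] * n_f + ["M"] * (n_g - n_f)

    root_ss = np.random.SeedSequence(config.seed)
    subject_seeds = root_ss.generate_state(2 * len(groups) + 64)
    participants: list[Participant] = []
    tft_records: list[TFTRecord] = []
    recordings: list[KinematicsRecording] = []
    gt_rows: list[dict] = []
    all_params: list[SubjectParams] = []
    n_retest_left = config.retest.n_retest

    for i, (group, sex) in enumerate(zip(groups, sexes)):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(int(subject_seeds[2 * i] % (2**31)))
        params = draw_subject_params(config, pid, group, sex, rng)
        sessions = [(1, params)]
        if group == "DM" and n_retest_left > 0:
            n_retest_left -= 1
            rng2 = np.random.default_rng(int(subject_seeds[2 * i + 1] % (2**31)))
            sessions.append((2, perturb_for_retest(params, config, rng2)))
        for session, sp in sessions:
            participants.append(
                Participant(pid, group, sex, sp.age, sp.height, sp.bmi, session)
            )
            trial_seed = int(subject_seeds[2 * i + (session - 1)] % (2**31)) + session
            recs, gts = generate_subject_trials(sp, config, trial_seed)
            recordings.extend(recs)
            all_params.append(sp)
            ratio = gts.get("shoulder_abduction", {}).get("brooke_ratio", np.nan)
            timing = np.random.default_rng(trial_seed + 7)
            sd = config.noise.tft_timing_sd

            def stopwatch(x: float) -> float:
                return float(max(x + timing.normal(0.0, sd), 0.1))

            graded_ratio = (
                ratio * float(timing.lognormal(0.0, config.noise.brooke_grader_sd))
                if np.isfinite(ratio)
                else np.nan
            )
            tft = TFTRecord(
                participant_id=pid,
                walk10m_s=stopwatch(10.0 / sp.walk_speed),
                run10m_s=stopwatch(10.0 / sp.run_speed),
                tug_s=stopwatch(sp.tug_total_s + 0.4),
                sts5x_s=stopwatch(sp.sts_total_s + 0.3),
                brooke=brooke_from_ratio(graded_ratio) if np.isfinite(ratio) else None,
            )
            if session == 1:
                tft_records.append(tft)
            gt_rows.append(
                {
                    "participant_id": pid,
                    "session": session,
                    "group": group,
                    "sex": sex,
                    "height_m": sp.height,
                    "walk_speed": sp.walk_speed,
                    "walk_stride_length": sp.stride_length_m / sp.height,
                    "walk_swing_ankle_height": gts["walk"]["swing_ankle_height"],
                    "run_speed": sp.run_speed,
                    "run_stride_length": sp.run_stride_m / sp.height,
                    "sts5x_time": sp.sts_total_s,
                    "tug_time": sp.tug_total_s,
                    "jump_height": np.nan if sp.unable_ankle else sp.jump_apex,
                    "calf_raise_count": np.nan if sp.unable_ankle else sp.calf_count,
                    "brooke_analog": ratio,
                    "elbow_flexion_rom": sp.elbow_rom,
                    "unable_ankle": sp.unable_ankle,
                    "brooke": tft.brooke,
                    "human_walk10m_s": tft.walk10m_s,
                    "human_run10m_s": tft.run10m_s,
                    "human_tug_s": tft.tug_s,
                    "human_sts5x_s": tft.sts5x_s,
                }
            )
    return CohortBundle(
        config=config,
        participants=participants,
        tft_records=tft_records,
        recordings=recordings,
        ground_truth=pd.DataFrame(gt_rows),
        subject_params=all_params,
    )
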