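"""Activity-specific interpretable movement features.

Each feature is registered with its activity, units, body-region provenance
(upper vs lower limb) and a short clinical rationale; the registry is the
extension point for adding further features. Length features are normalized
by participant height ("m/m height") so they are dimensionless and
comparable across body sizes.

Participants who cannot complete the ankle-based activities (calf raise and
jump) receive zeros for those features, with the imputation recorded, so that
inability itself carries signal; missing trials for any other activity
exclude the participant from the feature matrix with a logged reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import ConfigurationError, ConflictError, FeatureError
from .events import (
    CUTOFF_SLOW_HZ,
    GaitEvents,
    anterior_axis,
    compute_com_height,
    count_repetitions,
    detect_gait_events,
    lowpass,
    segment_repetitions,
)
from .io import KinematicsRecording

#: Floor (degrees) applied to elbow flexion in the Brooke-analog ratio so a
#: fully straight elbow does not blow up the quotient.
ELBOW_FLOOR_DEG = 1.0

#: Activities whose absence is zero-imputed rather than excluding the subject.
ANKLE_ACTIVITIES = ("calf_raise", "jump")

#: Default semantic-angle -> column-name mapping (configurable; angle naming
#: differs between skeletal-model exports).
DEFAULT_ANGLE_MAP = {
    "shoulder_abduction_r": "arm_abd_r",
    "shoulder_abduction_l": "arm_abd_l",
    "elbow_flexion_r": "elbow_flex_r",
    "elbow_flexion_l": "elbow_flex_l",
}


def _angle(rec: KinematicsRecording, semantic: str, angle_map=None) -> np.ndarray:
    name = (angle_map or DEFAULT_ANGLE_MAP)[semantic]
    if name not in rec.joint_angles:
        raise ConfigurationError(
            f"angle column {name!r} ({semantic}) missing from {rec.activity} trial"
        )
    return rec.joint_angles[name]


def _height(rec: KinematicsRecording) -> float:
    h = rec.participant_height
    if not h > 0:
        raise FeatureError("participant height required for normalized features")
    return h


# ---------------------------------------------------------------------------
# gait


def _steady_window(events: GaitEvents) -> tuple[float, float]:
    """Steady-state gait window: drop the first and last pooled stride."""
    pooled = sorted(s for side in events.strides.values() for s in side)
    if len(pooled) < 3:
        raise FeatureError(f"{len(pooled)} strides pooled; need >= 3 for steady state")
    inner = pooled[1:-1]
    return min(s[0] for s in inner), max(s[1] for s in inner)


def walk_features(
    rec: KinematicsRecording, events: GaitEvents | None = None
) -> dict[str, float]:
    """Walking speed, stride length, swing ankle height and cadence.

    * speed (m/s): horizontal pelvis displacement over the steady-state window
    * stride_length (m/m height): mean per-stride anterior heel displacement
    * swing_ankle_height (m/m height): mean over swing phases of the ankle
      marker's elevation above its stance-phase minimum (peak variant also
      reported as ..._peak)
    * cadence (strides/s): strides per second, averaged over sides
    """
    if events is None:
        events = detect_gait_events(rec)
    height = _height(rec)
    axis = anterior_axis(rec)
    fs = rec.sampling_rate
    from .events import _pelvis_center, activity_cutoff

    cutoff = activity_cutoff(rec.activity)
    pelvis_ant = lowpass(_pelvis_center(rec) @ axis, fs, cutoff)
    t0, t1 = _steady_window(events)
    i0, i1 = np.searchsorted(rec.time, [t0, t1])
    i1 = min(i1, rec.n_frames - 1)
    if rec.time[i1] - rec.time[i0] <= 0:
        raise FeatureError("empty steady-state window")
    speed = float((pelvis_ant[i1] - pelvis_ant[i0]) / (rec.time[i1] - rec.time[i0]))

    stride_lengths: list[float] = []
    swing_heights_mean: list[float] = []
    swing_heights_peak: list[float] = []
    cadences: list[float] = []
    for side, strides in events.strides.items():
        heel_ant = lowpass(rec.markers[f"{side}_heel"] @ axis, fs, cutoff)
        ankle_name = f"{side}_ankle" if f"{side}_ankle" in rec.markers else f"{side}_heel"
        # raw signal for the swing integral (a zero-phase filter leaks area
        # and undershoots beside the swing bump); filtered copy for the peak
        ankle_raw = rec.markers[ankle_name][:, rec.vertical_axis]
        ankle_up = lowpass(ankle_raw, fs, cutoff)
        to_t = events.toe_offs[side]
        hs_t = events.heel_strikes[side]
        # stance baseline: median over stance phases (HS -> next TO); robust
        # to the undershoot a zero-phase filter leaves beside the swing bump
        stance_mask = np.zeros(rec.n_frames, dtype=bool)
        for h0 in hs_t:
            nxt = to_t[to_t > h0]
            if len(nxt):
                a0, a1 = np.searchsorted(rec.time, [h0, nxt[0]])
                mid0, mid1 = a0 + (a1 - a0) // 4, a1 - (a1 - a0) // 4
                stance_mask[mid0:mid1] = True
        stance_min = (
            float(np.median(ankle_raw[stance_mask]))
            if stance_mask.any()
            else float(np.min(ankle_up))
        )
        for s0, s1 in strides:
            j0, j1 = np.searchsorted(rec.time, [s0, s1])
            j1 = min(j1, rec.n_frames - 1)
            stride_lengths.append(float(heel_ant[j1] - heel_ant[j0]))
            to_in = to_t[(to_t > s0) & (to_t < s1)]
            if len(to_in) == 1:
                # integrate elevation over a window padded by the filter's
                # edge spread, then divide by the true swing duration: the
                # zero-phase filter conserves area, so the mean is unbiased
                pad = 2.0 / fs
                k0, k1 = np.searchsorted(rec.time, [to_in[0] - pad, s1 + pad])
                k1 = min(k1, rec.n_frames - 1)
                sw = ankle_raw[k0 : k1 + 1] - stance_min
                dur = s1 - to_in[0]
                if len(sw) > 1 and dur > 0:
                    area = float(np.trapezoid(sw, dx=1.0 / fs))
                    swing_heights_mean.append(area / dur)
                    swing_heights_peak.append(
                        float(np.max(ankle_up[k0 : k1 + 1]) - stance_min)
                    )
        span = strides[-1][1] - strides[0][0]
        if span > 0:
            cadences.append(len(strides) / span)
    return {
        "speed": speed,
        "stride_length": float(np.mean(stride_lengths)) / height,
        "swing_ankle_height": float(np.mean(swing_heights_mean)) / height,
        "swing_ankle_height_peak": float(np.mean(swing_heights_peak)) / height,
        "cadence": float(np.mean(cadences)),
    }


def run_features(
    rec: KinematicsRecording, events: GaitEvents | None = None
) -> dict[str, float]:
    """Running speed and stride length (walk extractor with run filtering)."""
    feats = walk_features(rec, events)
    return {"speed": feats["speed"], "stride_length": feats["stride_length"]}


# ---------------------------------------------------------------------------
# upper limb


def brooke_analog(rec: KinematicsRecording, angle_map=None) -> float:
    """Video analog of the Brooke Upper Extremity Scale.

    Per side: peak shoulder abduction divided by the elbow flexion at the
    frame of that peak (floored at 1 deg); the better (maximum) side is
    returned. High values mean overhead reach with straight elbows.
    """
    ratios = []
    for side in ("r", "l"):
        theta_s = _angle(rec, f"shoulder_abduction_{side}", angle_map)
        theta_e = _angle(rec, f"elbow_flexion_{side}", angle_map)
        i = int(np.argmax(theta_s))
        ratios.append(float(theta_s[i]) / max(float(theta_e[i]), ELBOW_FLOOR_DEG))
    return float(max(ratios))


def arm_rom_features(rec: KinematicsRecording, angle_map=None) -> dict[str, float]:
    """Frontal-plane reachable area and isolated joint ranges of motion.

    reachable_area: area of the 2D convex hull of all wrist-marker positions
    projected on the frontal plane, normalized by height squared.
    """
    if rec.duration < 1.0:
        raise FeatureError("arm trial shorter than 1 s")
    out: dict[str, float] = {}
    wrists = [m for m in rec.markers if m.endswith("wrist")]
    if wrists:
        height = _height(rec)
        ax = anterior_axis(rec)
        up = np.zeros(3)
        up[rec.vertical_axis] = 1.0
        lateral = np.cross(up, ax)
        pts = np.vstack([rec.markers[m] for m in wrists])
        plane = np.column_stack([pts @ lateral, pts @ up])
        spread = plane.max(axis=0) - plane.min(axis=0)
        if np.min(spread) < 1e-3:
            out["reachable_area"] = 0.0
        else:
            try:
                out["reachable_area"] = float(ConvexHull(plane).volume) / height**2
            except QhullError:
                out["reachable_area"] = 0.0
    for semantic, feat in (
        ("elbow_flexion", "elbow_flexion_rom"),
        ("shoulder_abduction", "shoulder_rom"),
    ):
        roms = []
        for side in ("r", "l"):
            key = f"{semantic}_{side}"
            name = (angle_map or DEFAULT_ANGLE_MAP)[key]
            if name in rec.joint_angles:
                a = rec.joint_angles[name]
                roms.append(float(np.max(a) - np.min(a)))
        if roms:
            out[feat] = float(max(roms))
    return out


# ---------------------------------------------------------------------------
# whole-body tasks


def jump_features(rec: KinematicsRecording) -> dict[str, float]:
    """Jump height (peak COM minus quiet standing) and takeoff COM velocity."""
    com = compute_com_height(rec)
    fs = rec.sampling_rate
    n_base = max(int(0.8 * fs), 2)
    baseline = float(np.median(com[:n_base]))
    apex_idx = int(np.argmax(com))
    height = float(com[apex_idx] - baseline)
    vel = np.gradient(com, rec.time)
    takeoff = float(np.max(vel[: apex_idx + 1])) if apex_idx > 0 else 0.0
    return {"jump_height": max(height, 0.0), "takeoff_com_velocity": max(takeoff, 0.0)}


def calf_raise_features(rec: KinematicsRecording, window_s: float = 30.0) -> dict[str, float]:
    """Raise count over the 30 s window, mean raise height, amplitude decay.

    raise_rate_decay is the fitted fractional loss of raise amplitude over
    the window (positive = fatiguing decline), dimensionless.
    """
    n = count_repetitions(rec, "heel_height", window_s)
    out = {"n_raises": float(n), "mean_raise_height": 0.0, "raise_rate_decay": 0.0}
    if n == 0:
        return out
    y = np.mean(
        [rec.markers[m][:, rec.vertical_axis] for m in ("r_heel", "l_heel")], axis=0
    )
    y = lowpass(y, rec.sampling_rate, CUTOFF_SLOW_HZ)
    mask = rec.time <= rec.time[0] + window_s
    yw, tw = y[mask], rec.time[mask]
    lo, hi = np.percentile(yw, [5, 95])
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(yw, prominence=0.3 * (hi - lo))
    base = float(np.percentile(yw, 5))
    heights = yw[peaks] - base
    out["mean_raise_height"] = float(np.mean(heights))
    if len(peaks) >= 3 and np.mean(heights) > 0:
        slope = np.polyfit(tw[peaks], heights, 1)[0]
        span = float(tw[peaks][-1] - tw[peaks][0])
        out["raise_rate_decay"] = float(-slope * span / np.mean(heights))
    return out


def chair_task_time(rec: KinematicsRecording) -> float:
    """Automated task duration (s) for sit_to_stand (5 reps) / timed_up_and_go."""
    com = compute_com_height(rec)
    if rec.activity == "sit_to_stand":
        segs = segment_repetitions(com, rec.time, n_expected=5, task="sts")
        return float(segs.repetitions[-1][1] - segs.repetitions[0][0])
    if rec.activity == "timed_up_and_go":
        segs = segment_repetitions(com, rec.time, task="tug")
        s, e = segs.repetitions[0]
        return float(e - s)
    raise ConfigurationError(f"no chair-task time for activity {rec.activity!r}")


# ---------------------------------------------------------------------------
# registry


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    activity: str
    units: str
    provenance: str  # upper_limb | lower_limb
    description: str


@dataclass
class FeatureRegistry:
    """Ordered, extensible catalogue of features; names must be unique."""

    entries: list[FeatureSpec] = field(default_factory=list)

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ConflictError("duplicate feature names in registry")
        from .io import ACTIVITIES

        for e in self.entries:
            if e.activity not in ACTIVITIES:
                raise ConfigurationError(f"{e.name}: unknown activity {e.activity!r}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def for_activity(self, activity: str) -> list[FeatureSpec]:
        return [e for e in self.entries if e.activity == activity]

    def provenance(self, name: str) -> str:
        for e in self.entries:
            if e.name == name:
                return e.provenance
        raise KeyError(name)

    def add(self, spec: FeatureSpec) -> None:
        if spec.name in self.names:
            raise ConflictError(f"feature {spec.name!r} already registered")
        self.entries.append(spec)

    def to_json(self) -> list[dict]:
        return [vars(e) for e in self.entries]


def default_registry() -> FeatureRegistry:
    L, U = "lower_limb", "upper_limb"
    mk = FeatureSpec
    return FeatureRegistry(
        entries=[
            mk("walk_speed", "walk", "m/s", L, "steady-state walking speed"),
            mk("walk_stride_length", "walk", "m/m height", L, "mean stride length, height-normalized"),
            mk("walk_swing_ankle_height", "walk", "m/m height", L, "mean swing-phase ankle elevation (foot-drop compensation)"),
            mk("walk_cadence", "walk", "strides/s", L, "stride rate per side"),
            mk("run_speed", "run", "m/s", L, "steady-state running speed"),
            mk("run_stride_length", "run", "m/m height", L, "running stride length, height-normalized"),
            mk("tug_time", "timed_up_and_go", "s", L, "automated timed up-and-go duration"),
            mk("sts5x_time", "sit_to_stand", "s", L, "automated 5x sit-to-stand duration"),
            mk("brooke_analog", "shoulder_abduction", "ratio", U, "peak shoulder abduction over elbow flexion at that peak, best side"),
            mk("reachable_area", "arm_rom", "m^2/m^2 height^2", U, "frontal-plane convex-hull area of wrist path"),
            mk("elbow_flexion_rom", "elbow_flexion", "deg", U, "isolated elbow flexion range of motion"),
            mk("shoulder_rom", "shoulder_abduction", "deg", U, "shoulder abduction range of motion"),
            mk("jump_height", "jump", "m", L, "COM flight apex above quiet standing"),
            mk("takeoff_com_velocity", "jump", "m/s", L, "peak upward COM velocity before apex"),
            mk("calf_raise_count", "calf_raise", "count/30 s", L, "prominence-qualified heel raises in 30 s"),
            mk("calf_raise_height", "calf_raise", "m", L, "mean heel elevation per raise"),
            mk("calf_raise_decay", "calf_raise", "ratio", L, "fractional amplitude decline over the window"),
        ]
    )


_EXTRACTORS: dict[str, Callable[[KinematicsRecording], dict[str, float]]] = {}


def _extract_activity(rec: KinematicsRecording) -> dict[str, float]:
    """Dispatch one trial to its extractor; returns registry-keyed values."""
    a = rec.activity
    if a == "walk":
        f = walk_features(rec)
        return {
            "walk_speed": f["speed"],
            "walk_stride_length": f["stride_length"],
            "walk_swing_ankle_height": f["swing_ankle_height"],
            "walk_cadence": f["cadence"],
        }
    if a == "run":
        f = run_features(rec)
        return {"run_speed": f["speed"], "run_stride_length": f["stride_length"]}
    if a == "timed_up_and_go":
        return {"tug_time": chair_task_time(rec)}
    if a == "sit_to_stand":
        return {"sts5x_time": chair_task_time(rec)}
    if a == "shoulder_abduction":
        out = {"brooke_analog": brooke_analog(rec)}
        out.update(
            {k: v for k, v in arm_rom_features(rec).items() if k == "shoulder_rom"}
        )
        return out
    if a == "elbow_flexion":
        f = arm_rom_features(rec)
        return {"elbow_flexion_rom": f["elbow_flexion_rom"]}
    if a == "arm_rom":
        f = arm_rom_features(rec)
        return {"reachable_area": f.get("reachable_area", 0.0)}
    if a == "jump":
        f = jump_features(rec)
        return {"jump_height": f["jump_height"], "takeoff_com_velocity": f["takeoff_com_velocity"]}
    if a == "calf_raise":
        f = calf_raise_features(rec)
        return {
            "calf_raise_count": f["n_raises"],
            "calf_raise_height": f["mean_raise_height"],
            "calf_raise_decay": f["raise_rate_decay"],
        }
    raise ConfigurationError(f"no extractor for activity {a!r}")


@dataclass
class FeatureVector:
    participant_id: str
    features: dict[str, float]
    imputed: set[str] = field(default_factory=set)
    session: int = 1


def assemble_features(
    trials: Iterable[KinematicsRecording],
    registry: FeatureRegistry | None = None,
) -> tuple[list[FeatureVector], list[dict]]:
    """Build per-participant-session feature vectors with zero imputation.

    Missing ankle-activity trials (calf raise, jump) yield zeros with the
    imputation recorded; a participant missing any other activity, or whose
    trial fails extraction, is excluded and the reason logged in the returned
    exclusion list.
    """
    registry = registry or default_registry()
    by_subject: dict[tuple[str, int], dict[str, KinematicsRecording]] = {}
    for rec in trials:
        key = (rec.participant_id, rec.session)
        acts = by_subject.setdefault(key, {})
        if rec.activity in acts:
            raise ConflictError(
                f"duplicate trial for ({rec.participant_id}, {rec.activity}, "
                f"session {rec.session})"
            )
        acts[rec.activity] = rec

    needed_activities = {e.activity for e in registry.entries}
    vectors: list[FeatureVector] = []
    exclusions: list[dict] = []
    for (pid, session), acts in sorted(by_subject.items()):
        values: dict[str, float] = {}
        imputed: set[str] = set()
        failed = None
        for activity in sorted(needed_activities):
            names = [e.name for e in registry.for_activity(activity)]
            if activity not in acts:
                if activity in ANKLE_ACTIVITIES:
                    for nm in names:
                        values[nm] = 0.0
                        imputed.add(nm)
                    continue
                failed = {"participant_id": pid, "session": session,
                          "reason": f"missing {activity} trial"}
                break
            try:
                extracted = _extract_activity(acts[activity])
            except Exception as exc:  # noqa: BLE001 - logged, participant excluded
                failed = {"participant_id": pid, "session": session,
                          "reason": f"{activity}: {exc}"}
                break
            for nm in names:
                if nm in extracted:
                    values[nm] = float(extracted[nm])
        if failed:
            exclusions.append(failed)
            continue
        ordered = {nm: values.get(nm, 0.0) for nm in registry.names}
        if not all(np.isfinite(v) for v in ordered.values()):
            exclusions.append({"participant_id": pid, "session": session,
                               "reason": "non-finite feature value"})
            continue
        vectors.append(FeatureVector(pid, ordered, imputed, session))
    return vectors, exclusions


def feature_matrix(
    vectors: Iterable[FeatureVector], registry: FeatureRegistry | None = None
) -> pd.DataFrame:
    """Feature vectors as a DataFrame in registry column order, with
    ``imputed_<name>`` boolean columns."""
    registry = registry or default_registry()
    rows = []
    for v in vectors:
        row: dict = {"participant_id": v.participant_id, "session": v.session}
        row.update({nm: v.features[nm] for nm in registry.names})
        row.update({f"imputed_{nm}": nm in v.imputed for nm in registry.names})
        rows.append(row)
    cols = (
        ["participant_id", "session"]
        + registry.names
        + [f"imputed_{nm}" for nm in registry.names]
    )
    return pd.DataFrame(rows, columns=cols)
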