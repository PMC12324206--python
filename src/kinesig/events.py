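"""Gait event detection and task-repetition segmentation.

Gait events use a coordinate-based detector: heel strike at local maxima of
the heel's anterior position relative to the pelvis, toe off at local minima
of the toe's anterior position relative to the pelvis. Chair tasks are
segmented from the vertical center-of-mass (COM) trajectory; the COM proxy is
the mean of the four pelvis markers, which tracks whole-body COM closely for
sit-to-stand, jumping and gait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .errors import (
    ConfigurationError,
    EventDetectionError,
    InsufficientGaitError,
    SegmentationError,
)
from .io import KinematicsRecording

#: Zero-phase low-pass cutoffs (Hz) per activity tempo class.
CUTOFF_SLOW_HZ = 6.0   # walk, TUG, sit-to-stand, calf raise
CUTOFF_FAST_HZ = 12.0  # run, jump

#: Default pelvis marker set used as the COM proxy.
PELVIS_MARKERS = ("r_asis", "l_asis", "r_psis", "l_psis")

#: Peak prominence threshold as a fraction of the signal's 5th-95th
#: percentile range (scale-free, robust to participant size).
PROMINENCE_FRAC = 0.30

#: Candidate events closer than this are merged, keeping the more prominent.
MIN_EVENT_SEPARATION_S = 0.1

SIDES = ("r", "l")


def lowpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """4th-order zero-phase Butterworth low-pass (order-2 sections, filtfilt)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 12 or cutoff_hz >= fs / 2:
        return x.copy()
    sos = butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def activity_cutoff(activity: str) -> float:
    return CUTOFF_FAST_HZ if activity in ("run", "jump") else CUTOFF_SLOW_HZ


@dataclass
class GaitEvents:
    """Heel strikes, toe offs and strides per side, in trial seconds."""

    heel_strikes: dict[str, np.ndarray]
    toe_offs: dict[str, np.ndarray]
    strides: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def n_strides(self, side: str) -> int:
        return len(self.strides.get(side, []))


@dataclass
class TaskSegments:
    """Non-overlapping task repetitions and the COM-height trajectory."""

    repetitions: list[tuple[float, float]]
    com_height: np.ndarray
    time: np.ndarray


def _pelvis_center(rec: KinematicsRecording, markers=PELVIS_MARKERS) -> np.ndarray:
    missing = [m for m in markers if m not in rec.markers]
    if missing:
        raise ConfigurationError(f"required pelvis markers missing: {missing}")
    return np.mean([rec.markers[m] for m in markers], axis=0)


def compute_com_height(
    rec: KinematicsRecording,
    markers=PELVIS_MARKERS,
    cutoff_hz: float | None = None,
) -> np.ndarray:
    """Vertical COM-proxy trajectory (m), low-pass filtered, one value/frame."""
    com = _pelvis_center(rec, markers)[:, rec.vertical_axis]
    if cutoff_hz is None:
        cutoff_hz = activity_cutoff(rec.activity)
    return lowpass(com, rec.sampling_rate, cutoff_hz)


def anterior_axis(rec: KinematicsRecording) -> np.ndarray:
    """Unit walking-direction vector: net horizontal pelvis displacement.

    Falls back to +X when the pelvis does not translate (standing tasks).
    """
    center = _pelvis_center(rec)
    disp = center[-1] - center[0]
    disp[rec.vertical_axis] = 0.0
    norm = np.linalg.norm(disp)
    axis = np.zeros(3)
    # require genuine travel: marker jitter alone can produce a few mm of
    # spurious net displacement whose direction is meaningless
    if norm < 0.2:
        axis[0 if rec.vertical_axis != 0 else 2] = 1.0
        return axis
    return disp / norm


def _merge_close_peaks(
    idx: np.ndarray, prominences: np.ndarray, fs: float
) -> np.ndarray:
    """Among candidates within MIN_EVENT_SEPARATION_S, keep the most prominent."""
    if len(idx) == 0:
        return idx
    keep: list[int] = []
    cluster = [0]
    min_gap = MIN_EVENT_SEPARATION_S * fs
    for j in range(1, len(idx)):
        if idx[j] - idx[cluster[-1]] <= min_gap:
            cluster.append(j)
        else:
            keep.append(cluster[int(np.argmax(prominences[cluster]))])
            cluster = [j]
    keep.append(cluster[int(np.argmax(prominences[cluster]))])
    return idx[np.array(keep)]


def _relative_peaks(signal: np.ndarray, fs: float) -> np.ndarray:
    lo, hi = np.percentile(signal, [5, 95])
    prom = PROMINENCE_FRAC * (hi - lo)
    if prom <= 0:
        return np.array([], dtype=int)
    idx, props = find_peaks(signal, prominence=prom)
    return _merge_close_peaks(idx, props["prominences"], fs)


def _subframe_times(signal: np.ndarray, idx: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Refine peak times to sub-frame precision by intersecting line fits on
    the two flanks of the peak.

    The foot-pelvis relative position is piecewise linear in time between
    events, so the event is the apex of a (filter-rounded) asymmetric
    triangle; flank-line intersection locates it without the bias a
    symmetric parabola fit has on unequal slopes.
    """
    out = []
    n = len(signal)
    dt = float(np.median(np.diff(time))) if len(time) > 1 else 1.0
    gap, width = 3, 8
    for i in idx:
        li = np.arange(max(i - width, 0), i - gap + 1)
        ri = np.arange(i + gap, min(i + width, n - 1) + 1)
        if len(li) >= 2 and len(ri) >= 2:
            al, bl = np.polyfit(time[li], signal[li], 1)
            ar, br = np.polyfit(time[ri], signal[ri], 1)
            if abs(al - ar) > 1e-12:
                t_x = (br - bl) / (al - ar)
                if abs(t_x - time[i]) <= (gap + 1) * dt:
                    out.append(float(t_x))
                    continue
        out.append(float(time[i]))
    return np.asarray(out)


def detect_gait_events(
    rec: KinematicsRecording,
    heel_markers: dict[str, str] | None = None,
    toe_markers: dict[str, str] | None = None,
) -> GaitEvents:
    """Coordinate-based gait event detection for walk/run trials.

    Raises InsufficientGaitError with < 2 heel strikes on either side and
    EventDetectionError when the HS/TO pattern violates the alternation and
    swing-shorter-than-stance sanity checks (e.g. degenerate input).
    """
    if rec.activity not in ("walk", "run"):
        raise ConfigurationError(f"gait events undefined for activity {rec.activity!r}")
    heel_markers = heel_markers or {s: f"{s}_heel" for s in SIDES}
    toe_markers = toe_markers or {s: f"{s}_toe" for s in SIDES}
    cutoff = activity_cutoff(rec.activity)
    fs = rec.sampling_rate
    axis = anterior_axis(rec)
    pelvis_ant = _pelvis_center(rec) @ axis

    heel_strikes: dict[str, np.ndarray] = {}
    toe_offs: dict[str, np.ndarray] = {}
    strides: dict[str, list[tuple[float, float]]] = {}
    for side in SIDES:
        for m in (heel_markers[side], toe_markers[side]):
            if m not in rec.markers:
                raise ConfigurationError(f"required foot marker {m!r} missing")
        heel_rel = lowpass(rec.markers[heel_markers[side]] @ axis - pelvis_ant, fs, cutoff)
        toe_rel = lowpass(rec.markers[toe_markers[side]] @ axis - pelvis_ant, fs, cutoff)
        # forward gait has the toe anterior of the heel along the direction
        # of travel; a violation means degenerate input (e.g. reversed time)
        if np.mean(toe_rel - heel_rel) <= 0:
            raise EventDetectionError(
                f"side {side}: toe is posterior of heel along the direction "
                "of travel — gait direction implausible"
            )
        hs_idx = _relative_peaks(heel_rel, fs)
        to_idx = _relative_peaks(-toe_rel, fs)
        if len(hs_idx) < 2:
            raise InsufficientGaitError(
                f"side {side}: {len(hs_idx)} heel strikes detected, need >= 2"
            )
        hs_t = _subframe_times(heel_rel, hs_idx, rec.time)
        to_t = _subframe_times(-toe_rel, to_idx, rec.time)
        side_strides: list[tuple[float, float]] = []
        swing_durs: list[float] = []
        for t0, t1 in zip(hs_t[:-1], hs_t[1:]):
            inside = to_t[(to_t > t0) & (to_t < t1)]
            if len(inside) != 1:
                raise EventDetectionError(
                    f"side {side}: stride [{t0:.2f}, {t1:.2f}] s contains "
                    f"{len(inside)} toe-offs, expected exactly 1 (alternation)"
                )
            side_strides.append((float(t0), float(t1)))
            swing_durs.append(float(t1 - inside[0]))
        stance = [t1 - t0 - sw for (t0, t1), sw in zip(side_strides, swing_durs)]
        if np.mean(swing_durs) >= np.mean(stance):
            raise EventDetectionError(
                f"side {side}: mean swing ({np.mean(swing_durs):.2f} s) not shorter "
                "than mean stance — event phasing implausible"
            )
        heel_strikes[side] = hs_t
        toe_offs[side] = to_t
        strides[side] = side_strides
    return GaitEvents(heel_strikes=heel_strikes, toe_offs=toe_offs, strides=strides)


def _edge_vertex(
    t: np.ndarray, h: np.ndarray, baseline: float, amp: float, peak_idx: int, rising: bool
) -> float:
    """Locate a repetition boundary by a sqrt-parabola vertex fit on the edge.

    Near a smooth trajectory minimum h - baseline ~ a (t - t0)^2, so
    sqrt(h - baseline) is linear in t and its zero-intercept estimates the
    boundary time without the O(0.1 s) bias of fixed-threshold crossing.
    Fits the monotone edge segment between 2% and 15% of the rise amplitude.
    """
    rel = h - baseline
    lo, hi = 0.02 * amp, 0.15 * amp
    if rising:
        sl = slice(None, peak_idx + 1)
    else:
        sl = slice(peak_idx, None)
    tt, rr = t[sl], rel[sl]
    band = np.flatnonzero((rr >= lo) & (rr <= hi))
    if rising:
        # contiguous run ending nearest the peak
        band = band[band > (np.flatnonzero(rr < lo)[-1] if (rr < lo).any() else -1)]
    else:
        band = band[band < (np.flatnonzero(rr < lo)[0] if (rr < lo).any() else len(rr))]
    if len(band) < 3:
        # too few samples on the edge: fall back to the nearest 2% crossing
        cross = np.flatnonzero(rr <= lo)
        if len(cross) == 0:
            return float(tt[0] if rising else tt[-1])
        return float(tt[cross[-1]] if rising else tt[cross[0]])
    coef = np.polyfit(tt[band], np.sqrt(rr[band]), 1)
    t0 = -coef[1] / coef[0]
    return float(np.clip(t0, t[0], t[-1]))


def segment_repetitions(
    com_height: np.ndarray,
    time: np.ndarray,
    n_expected: int | None = None,
    task: str = "sts",
    min_duration_s: float = 0.2,
) -> TaskSegments:
    """Segment chair-task repetitions from a COM-height trajectory.

    task='sts': each repetition runs from a COM minimum (seated) through the
    following maximum (standing) back to the next minimum; when ``n_expected``
    is given the n most prominent rises are kept, in time order.
    task='tug': a single repetition from the first upward crossing of
    10% above the seated baseline to the last downward crossing.
    """
    h = np.asarray(com_height, dtype=float)
    t = np.asarray(time, dtype=float)
    lo, hi = np.percentile(h, [5, 95])
    amp = hi - lo
    if amp < 1e-3:
        raise SegmentationError("flat COM trajectory: no repetitions to segment")

    if task == "tug":
        thresh = lo + 0.10 * amp
        above = h > thresh
        if not above.any():
            raise SegmentationError("COM never rises above the TUG onset threshold")
        onset = int(np.argmax(above))
        offset = int(len(h) - np.argmax(above[::-1]) - 1)
        if t[offset] - t[onset] <= min_duration_s:
            raise SegmentationError("TUG repetition shorter than minimum duration")
        return TaskSegments(
            repetitions=[(float(t[onset]), float(t[offset]))], com_height=h, time=t
        )

    peaks, props = find_peaks(h, prominence=PROMINENCE_FRAC * amp)
    if len(peaks) == 0:
        raise SegmentationError("no prominent COM rises found")
    if n_expected is not None:
        if len(peaks) < n_expected:
            raise SegmentationError(
                f"found {len(peaks)} repetitions, expected {n_expected}"
            )
        order = np.argsort(props["prominences"])[::-1][:n_expected]
        keep = np.sort(order)
        peaks = peaks[keep]

    reps: list[tuple[float, float]] = []
    bounds_left: list[float] = []
    bounds_right: list[float] = []
    for i, p in enumerate(peaks):
        left_lim = peaks[i - 1] if i > 0 else 0
        right_lim = peaks[i + 1] if i < len(peaks) - 1 else len(h) - 1
        if i > 0:
            start_idx = left_lim + int(np.argmin(h[left_lim : p + 1]))
            start = float(t[start_idx])
        else:
            base = float(np.min(h[left_lim : p + 1]))
            start = _edge_vertex(t, h, base, h[p] - base, p, rising=True)
        if i < len(peaks) - 1:
            end_idx = p + int(np.argmin(h[p : right_lim + 1]))
            end = float(t[end_idx])
        else:
            base = float(np.min(h[p : right_lim + 1]))
            end = _edge_vertex(t, h, base, h[p] - base, p, rising=False)
        bounds_left.append(start)
        bounds_right.append(end)
    for start, end in zip(bounds_left, bounds_right):
        if end - start > min_duration_s:
            reps.append((start, end))
    if n_expected is not None and len(reps) < n_expected:
        raise SegmentationError(
            f"only {len(reps)} repetitions exceed the minimum duration, "
            f"expected {n_expected}"
        )
    # enforce ordering / non-overlap (shared boundaries allowed)
    for (s0, e0), (s1, e1) in zip(reps[:-1], reps[1:]):
        if s1 < e0 - 1e-9:
            raise SegmentationError("overlapping repetitions detected")
    return TaskSegments(repetitions=reps, com_height=h, time=t)


def count_repetitions(
    rec: KinematicsRecording,
    signal: str = "heel_height",
    window_s: float = 30.0,
) -> int:
    """Count prominence-qualified repetitions (calf raises) in a time window."""
    if signal == "heel_height":
        missing = [m for m in ("r_heel", "l_heel") if m not in rec.markers]
        if missing:
            raise ConfigurationError(f"heel markers missing: {missing}")
        y = np.mean(
            [rec.markers[m][:, rec.vertical_axis] for m in ("r_heel", "l_heel")], axis=0
        )
    elif signal == "com_height":
        y = compute_com_height(rec)
    else:
        raise ConfigurationError(f"unknown counting signal {signal!r}")
    y = lowpass(y, rec.sampling_rate, CUTOFF_SLOW_HZ)
    if rec.duration < window_s:
        import warnings

        warnings.warn(
            f"trial shorter than {window_s} s window; counting over "
            f"{rec.duration:.1f} s",
            stacklevel=2,
        )
    mask = rec.time <= rec.time[0] + window_s
    yw = y[mask]
    lo, hi = np.percentile(yw, [5, 95])
    amp = hi - lo
    if amp < 5e-3:
        return 0
    peaks, _ = find_peaks(yw, prominence=PROMINENCE_FRAC * amp)
    return int(len(peaks))
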