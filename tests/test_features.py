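from dataclasses import replace

import numpy as np
import pytest

from kinesig.errors import ConflictError, KinesigError
from kinesig.features import (
    ELBOW_FLOOR_DEG,
    arm_rom_features,
    assemble_features,
    brooke_analog,
    calf_raise_features,
    default_registry,
    feature_matrix,
    jump_features,
    run_features,
    walk_features,
)
from kinesig.io import KinematicsRecording
from kinesig.synth import (
    _pelvis_markers,
    generate_gait_trial,
    generate_task_trial,
    generate_upper_limb_trial,
)


class TestGaitFeatures:
    def test_planted_walk_parameters_recovered(self, subject):
        p = replace(subject, walk_speed=1.25, stride_length_m=1.36, height=1.70)
        rec, gt = generate_gait_trial(p, 0, "walk")
        f = walk_features(rec)
        assert f["speed"] == pytest.approx(1.25, rel=0.01)
        assert f["stride_length"] == pytest.approx(0.80, abs=0.02)
        assert f["swing_ankle_height"] == pytest.approx(
            gt["swing_ankle_height"], rel=0.02
        )
        assert f["cadence"] == pytest.approx(gt["cadence"], rel=0.01)

    def test_zero_clearance_gives_zero_swing_height(self, subject):
        p = replace(subject, swing_clearance=1e-9)
        rec, _ = generate_gait_trial(p, 0, "walk")
        f = walk_features(rec)
        assert abs(f["swing_ankle_height"]) < 1e-3  # within filter ripple

    def test_planted_run_speed_recovered(self, subject):
        p = replace(subject, run_speed=2.5)
        rec, _ = generate_gait_trial(p, 0, "run")
        f = run_features(rec)
        assert f["speed"] == pytest.approx(2.5, rel=0.01)

    def test_walk_vs_run_extraction_consistent(self, subject):
        """The same trial processed with walk and run settings differs only
        by the filter cutoff; stride length must agree within 2%."""
        rec, _ = generate_gait_trial(subject, 0, "walk")
        as_run = KinematicsRecording(
            rec.participant_id, "run", rec.time, rec.sampling_rate,
            rec.markers, participant_height=rec.participant_height,
        )
        f_walk = walk_features(rec)
        f_run = run_features(as_run)
        assert f_run["stride_length"] == pytest.approx(
            f_walk["stride_length"], rel=0.02
        )

    def test_single_stride_trial_errors(self, subject):
        rec, _ = generate_gait_trial(subject, 0, "walk", duration_s=1.2)
        with pytest.raises(KinesigError):
            walk_features(rec)

    def test_geometry_scaling_invariance(self, subject):
        """Height-normalized length features are invariant to scaling the
        whole body (markers and height) together."""
        rec, _ = generate_gait_trial(subject, 0, "walk")
        f0 = walk_features(rec)
        s = 1.1
        rec2 = KinematicsRecording(
            rec.participant_id, "walk", rec.time, rec.sampling_rate,
            {k: v * s for k, v in rec.markers.items()},
            participant_height=rec.participant_height * s,
        )
        f1 = walk_features(rec2)
        assert f1["stride_length"] == pytest.approx(f0["stride_length"], rel=0.01)
        assert f1["swing_ankle_height"] == pytest.approx(
            f0["swing_ankle_height"], rel=0.01
        )


def _angles_rec(theta_s_r, theta_e_r, theta_s_l, theta_e_l, fs=60.0):
    n = len(theta_s_r)
    return KinematicsRecording(
        "P1",
        "shoulder_abduction",
        np.arange(n) / fs,
        fs,
        joint_angles={
            "arm_abd_r": np.asarray(theta_s_r, float),
            "elbow_flex_r": np.asarray(theta_e_r, float),
            "arm_abd_l": np.asarray(theta_s_l, float),
            "elbow_flex_l": np.asarray(theta_e_l, float),
        },
        participant_height=1.7,
    )


class TestBrookeAnalog:
    def test_stated_formula_arithmetic(self):
        n = 100
        s_r = np.linspace(10, 170, n)  # peak 170 with elbow 5
        e_r = np.full(n, 5.0)
        s_l = np.linspace(10, 160, n)  # peak 160 with elbow 30
        e_l = np.full(n, 30.0)
        rec = _angles_rec(s_r, e_r, s_l, e_l)
        assert brooke_analog(rec) == pytest.approx(max(170 / 5, 160 / 30))

    def test_symmetric_sides(self):
        n = 100
        s = np.linspace(10, 150, n)
        e = np.full(n, 20.0)
        rec = _angles_rec(s, e, s, e)
        assert brooke_analog(rec) == pytest.approx(150 / 20)

    def test_zero_elbow_uses_floor(self):
        n = 100
        s = np.linspace(10, 170, n)
        e = np.zeros(n)
        rec = _angles_rec(s, e, s, e)
        assert brooke_analog(rec) == pytest.approx(170 / ELBOW_FLOOR_DEG)

    def test_elbow_read_at_peak_shoulder_frame(self):
        """Elbow flexion is evaluated at the frame of peak abduction, not at
        its own maximum."""
        n = 100
        s = np.concatenate([np.linspace(10, 170, n // 2), np.linspace(170, 10, n // 2)])
        e = np.full(n, 10.0)
        e[-5:] = 80.0  # late elbow spike, shoulder already down
        rec = _angles_rec(s, e, s, e)
        assert brooke_analog(rec) == pytest.approx(170 / 10)

    def test_generator_formula_consistency(self, fshd_subject):
        rec, gt = generate_upper_limb_trial(fshd_subject, 0, "shoulder_abduction")
        assert brooke_analog(rec) == pytest.approx(gt["brooke_ratio"], rel=0.02)


class TestArmRom:
    def test_quarter_circle_sector_area(self):
        """A wrist tracing out-sweep-back over a quarter circle of radius r
        covers a convex sector of area pi r^2 / 4."""
        fs, dur, r, height = 60.0, 4.0, 0.6, 1.7
        n = int(dur * fs) + 1
        t = np.arange(n) / fs
        u = t / dur
        radius = np.where(u < 0.2, r * u / 0.2, np.where(u < 0.8, r, r * (1 - u) / 0.2))
        phi = np.where(u < 0.2, 0, np.where(u < 0.8, (np.pi / 2) * (u - 0.2) / 0.6, np.pi / 2))
        pivot = np.array([0.0, 1.4, 0.2])
        wrist = pivot + np.column_stack(
            [np.zeros(n), -radius * np.cos(phi), radius * np.sin(phi)]
        )
        center = np.column_stack([np.zeros(n), np.full(n, 0.9), np.zeros(n)])
        markers = _pelvis_markers(center)
        markers["r_wrist"] = wrist
        rec = KinematicsRecording(
            "P1", "arm_rom", t, fs, markers, participant_height=height
        )
        f = arm_rom_features(rec)
        assert f["reachable_area"] == pytest.approx(
            (np.pi * r**2 / 4) / height**2, rel=0.03
        )

    def test_stationary_arm_zero_area(self):
        fs, n = 60.0, 200
        t = np.arange(n) / fs
        center = np.column_stack([np.zeros(n), np.full(n, 0.9), np.zeros(n)])
        markers = _pelvis_markers(center)
        markers["r_wrist"] = np.tile([0.0, 1.0, 0.4], (n, 1))
        rec = KinematicsRecording(
            "P1", "arm_rom", t, fs, markers, participant_height=1.7
        )
        assert arm_rom_features(rec)["reachable_area"] == 0.0

    def test_planted_elbow_sweep_rom(self, subject):
        p = replace(subject, elbow_rom=110.0)
        rec, _ = generate_upper_limb_trial(p, 0, "elbow_flexion")
        f = arm_rom_features(rec)
        assert f["elbow_flexion_rom"] == pytest.approx(110.0, rel=0.01)

    def test_too_short_trial_errors(self):
        rec = KinematicsRecording(
            "P1", "arm_rom", np.arange(30) / 60, 60.0, participant_height=1.7
        )
        with pytest.raises(KinesigError):
            arm_rom_features(rec)


class TestWholeBody:
    def test_planted_jump_apex(self, subject):
        p = replace(subject, jump_apex=0.25)
        rec, _ = generate_task_trial(p, 0, "jump")
        f = jump_features(rec)
        assert f["jump_height"] == pytest.approx(0.25, abs=0.01)

    def test_no_flight_zero_height(self, subject):
        p = replace(subject, jump_apex=1e-6)
        rec, _ = generate_task_trial(p, 0, "jump")
        assert jump_features(rec)["jump_height"] < 0.01

    def test_planted_calf_raises(self, subject):
        p = replace(subject, calf_count=18, calf_height=0.08, calf_decay=0.0)
        rec, _ = generate_task_trial(p, 0, "calf_raise")
        f = calf_raise_features(rec)
        assert f["n_raises"] == 18
        assert f["mean_raise_height"] == pytest.approx(0.08, abs=0.005)

    def test_decaying_amplitude_positive_decay(self, subject):
        p = replace(subject, calf_count=18, calf_decay=0.3)
        rec, gt = generate_task_trial(p, 0, "calf_raise")
        f = calf_raise_features(rec)
        assert f["raise_rate_decay"] > 0
        assert f["raise_rate_decay"] == pytest.approx(gt["raise_rate_decay"], rel=0.2)


class TestAssembly:
    def _trials(self, params, config_seed=0, skip=()):
        from kinesig.synth import SyntheticCohortConfig, generate_subject_trials

        cfg = SyntheticCohortConfig(
            n_fshd=0, n_dm=0, n_ctl=1, seed=config_seed,
            noise={"marker_jitter_sd": 0, "angle_jitter_sd": 0},
        )
        recs, _ = generate_subject_trials(params, cfg, 123)
        return [r for r in recs if r.activity not in skip]

    def test_missing_jump_imputed_with_zeros(self, subject):
        recs = self._trials(subject, skip=("jump",))
        vectors, excl = assemble_features(recs)
        assert excl == []
        v = vectors[0]
        assert v.features["jump_height"] == 0.0
        assert "jump_height" in v.imputed and "takeoff_com_velocity" in v.imputed

    def test_complete_participant_no_imputation(self, subject):
        vectors, excl = assemble_features(self._trials(subject))
        assert excl == []
        assert vectors[0].imputed == set()

    def test_missing_walk_excludes_participant(self, subject):
        vectors, excl = assemble_features(self._trials(subject, skip=("walk",)))
        assert vectors == []
        assert len(excl) == 1 and "walk" in excl[0]["reason"]

    def test_duplicate_trial_conflict(self, subject):
        recs = self._trials(subject)
        with pytest.raises(ConflictError):
            assemble_features(recs + [recs[0]])

    def test_matrix_shape_and_finiteness(self, subject, fshd_subject):
        recs = self._trials(subject) + self._trials(
            replace(fshd_subject, participant_id="P002")
        )
        vectors, _ = assemble_features(recs)
        reg = default_registry()
        df = feature_matrix(vectors, reg)
        assert list(df.columns[2 : 2 + len(reg.names)]) == reg.names
        assert np.isfinite(df[reg.names].to_numpy()).all()
        assert len(df) == 2

    def test_extraction_deterministic(self, subject):
        recs = self._trials(subject)
        v1, _ = assemble_features(recs)
        v2, _ = assemble_features(recs)
        assert v1[0].features == v2[0].features


class TestRegistry:
    def test_names_unique_and_activities_valid(self):
        reg = default_registry()
        assert len(set(reg.names)) == len(reg.names)

    def test_user_extension(self):
        from kinesig.features import FeatureSpec

        reg = default_registry()
        reg.add(FeatureSpec("trunk_lean", "sit_to_stand", "deg", "lower_limb", "x"))
        assert "trunk_lean" in reg.names
        with pytest.raises(ConflictError):
            reg.add(FeatureSpec("trunk_lean", "sit_to_stand", "deg", "lower_limb", "x"))
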