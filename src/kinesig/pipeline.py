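"""End-to-end orchestration: ingest or synthesize -> events -> features ->
surrogates -> statistics -> classification -> report bundle.

All randomness flows from the single run seed through named substreams per
stage; identical config + seed produce byte-identical output files. A failed
trial excludes its participant with a logged reason; a failed stage aborts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .classify import compare_models, importance_ranking, loso_linear_svc
from .errors import KinesigError
from .features import FeatureRegistry, assemble_features, default_registry, feature_matrix
from .io import Participant, TFTRecord, read_cohort, read_mot, read_trc
from .stats import reliability_table, signature_tests
from .synth import CohortBundle, SyntheticCohortConfig, generate_cohort
from .tft import TFT_NAMES, gait_surrogate, loso_calibrate, mcid_compare

log = logging.getLogger("kinesig")

ANALYSES = ("tft_reproduction", "classification", "signatures", "importance", "reliability")


class RunConfig(BaseModel):
    mode: Literal["synthetic", "directory"] = "synthetic"
    synthetic: SyntheticCohortConfig | None = None
    input_dir: str | None = None
    analyses: list[str] = Field(default_factory=lambda: list(ANALYSES))
    seed: int = 0
    out_dir: str | None = None
    alpha: float = Field(0.05, gt=0, lt=1)

    @model_validator(mode="after")
    def _check(self):
        bad = set(self.analyses) - set(ANALYSES)
        if bad:
            raise ValueError(f"unknown analyses: {sorted(bad)}")
        if self.mode == "synthetic" and self.synthetic is None:
            self.synthetic = SyntheticCohortConfig(
                n_fshd=28, n_dm=58, n_ctl=43, seed=self.seed,
                retest={"n_retest": 13},
            )
        if self.mode == "directory" and not self.input_dir:
            raise ValueError("directory mode requires input_dir")
        return self


@dataclass
class CohortData:
    participants: list[Participant]
    tft_records: list[TFTRecord]
    features: pd.DataFrame  # one row per participant-session
    exclusions: list[dict]
    registry: FeatureRegistry
    ground_truth: pd.DataFrame | None = None


def load_directory(input_dir: str | Path, registry: FeatureRegistry | None = None) -> CohortData:
    """Read a cohort directory and extract the feature matrix."""
    registry = registry or default_registry()
    participants, tfts, trials = read_cohort(input_dir)
    heights = {(p.participant_id, p.session): p.height for p in participants}
    input_dir = Path(input_dir)
    recs = []
    for _, row in trials.iterrows():
        pid, session = str(row["participant_id"]), int(row["session"])
        height = heights.get((pid, session), float("nan"))
        rec = None
        if row["trc_file"]:
            rec = read_trc(
                input_dir / row["trc_file"], pid, row["activity"], height, session=session
            )
        if row["mot_file"]:
            mot = read_mot(
                input_dir / row["mot_file"], pid, row["activity"], height, session=session
            )
            if rec is None:
                rec = mot
            else:
                rec.joint_angles = mot.joint_angles
        if rec is not None:
            recs.append(rec)
    vectors, exclusions = assemble_features(recs, registry)
    return CohortData(
        participants=participants,
        tft_records=tfts,
        features=feature_matrix(vectors, registry),
        exclusions=exclusions,
        registry=registry,
    )


def cohort_from_bundle(bundle: CohortBundle, registry: FeatureRegistry | None = None) -> CohortData:
    registry = registry or default_registry()
    vectors, exclusions = assemble_features(bundle.recordings, registry)
    return CohortData(
        participants=bundle.participants,
        tft_records=bundle.tft_records,
        features=feature_matrix(vectors, registry),
        exclusions=exclusions,
        registry=registry,
        ground_truth=bundle.ground_truth,
    )


# ---------------------------------------------------------------------------
# analyses


def _session1(data: CohortData) -> pd.DataFrame:
    df = data.features[data.features["session"] == 1].copy()
    groups = {p.participant_id: p.group for p in data.participants if p.session == 1}
    df["group"] = df["participant_id"].map(groups)
    return df


def tft_reproduction(data: CohortData) -> dict:
    """LOSO calibration of video TFT surrogates against human times."""
    df = _session1(data)
    human = {t.participant_id: t for t in data.tft_records}
    out = {}
    surrogate_cols = {
        "walk10m": ("walk_speed", True),
        "run10m": ("run_speed", True),
        "tug": ("tug_time", False),
        "sts5x": ("sts5x_time", False),
    }
    for tft in TFT_NAMES:
        col, is_gait = surrogate_cols[tft]
        ids, surr, hum = [], [], []
        n_dropped = 0
        for _, row in df.iterrows():
            rec = human.get(row["participant_id"])
            h = getattr(rec, f"{tft}_s", None) if rec else None
            if h is None or not np.isfinite(row[col]) or row[col] <= 0:
                n_dropped += 1
                continue
            ids.append(row["participant_id"])
            surr.append(gait_surrogate(row[col]) if is_gait else float(row[col]))
            hum.append(h)
        if len(ids) < 3:
            log.warning("tft %s: only %d pairs, skipped", tft, len(ids))
            continue
        res = loso_calibrate(ids, surr, hum, tft)
        entry = {
            "tft": tft,
            "n": res.n,
            "n_dropped": n_dropped,
            "pearson_r": res.pearson_r,
            "mae_s": res.mae_s,
        }
        entry.update({k: v for k, v in mcid_compare(res.mae_s, tft).items() if k != "tft"})
        out[tft] = {**entry, "predictions": res.to_frame()}
    return out


#: Named classification presets: (positive-vs-negative groups, input set).
PRESETS = {
    "video_all_fshd_dm": (("FSHD", "DM"), "video_all"),
    "tft_only_fshd_dm": (("FSHD", "DM"), "tft_only"),
    "tft_brooke_fshd_dm": (("FSHD", "DM"), "tft_plus_brooke"),
    "video_all_fshd_ctl": (("FSHD", "CTL"), "video_all"),
    "video_all_dm_ctl": (("DM", "CTL"), "video_all"),
}


def build_design(data: CohortData, groups: tuple[str, str], input_set: str):
    """(ids, X, y, feature_names) for a classification preset; session 1 only."""
    df = _session1(data)
    df = df[df["group"].isin(groups)]
    if input_set == "video_all":
        names = data.registry.names
        X = df[names].to_numpy(float)
        ids = df["participant_id"].tolist()
        y = df["group"].to_numpy()
        return ids, X, y, names
    if input_set.startswith("video_per_activity:"):
        activity = input_set.split(":", 1)[1]
        names = [e.name for e in data.registry.for_activity(activity)]
        return (
            df["participant_id"].tolist(),
            df[names].to_numpy(float),
            df["group"].to_numpy(),
            names,
        )
    human = {t.participant_id: t for t in data.tft_records}
    names = ["walk10m_s", "run10m_s", "tug_s", "sts5x_s"]
    if input_set == "tft_plus_brooke":
        names = names + ["brooke"]
    elif input_set != "tft_only":
        raise KinesigError(f"unknown input set {input_set!r}")
    ids, rows, y = [], [], []
    for _, row in df.iterrows():
        rec = human.get(row["participant_id"])
        if rec is None:
            continue
        vals = [getattr(rec, nm) for nm in names]
        if any(v is None for v in vals):
            continue
        ids.append(row["participant_id"])
        rows.append([float(v) for v in vals])
        y.append(row["group"])
    return ids, np.array(rows, float), np.array(y), names


def classification_analysis(data: CohortData, seed: int = 0) -> dict:
    """Disease-vs-disease classification on video features vs TFT inputs,
    with McNemar comparisons against the video model."""
    out: dict = {"models": {}, "comparisons": {}}
    results = {}
    for preset in ("video_all_fshd_dm", "tft_only_fshd_dm", "tft_brooke_fshd_dm"):
        groups, input_set = PRESETS[preset]
        ids, X, y, names = build_design(data, groups, input_set)
        res = loso_linear_svc(
            X, y, ids, seed=seed, model_name=preset, input_set=input_set,
            feature_names=names,
        )
        results[preset] = res
        out["models"][preset] = {
            "input_set": input_set,
            "groups": list(groups),
            "n": len(ids),
            "balanced_accuracy": res.balanced_accuracy,
            "predictions": {
                pid: {"true": str(t), "pred": str(p), "score": float(s)}
                for pid, t, p, s in zip(ids, res.y_true, res.y_pred, res.decision_scores)
            },
            "selected_c": res.selected_c,
        }
    video = results["video_all_fshd_dm"]
    for other in ("tft_only_fshd_dm", "tft_brooke_fshd_dm"):
        # McNemar needs both models' predictions on the same subjects
        common = [p for p in video.participant_ids if p in results[other].participant_ids]
        a, b = _restrict(video, common), _restrict(results[other], common)
        out["comparisons"][f"video_vs_{other}"] = compare_models(a, b)
    out["_results"] = results
    return out


def _restrict(res, ids):
    from copy import copy

    idx = np.array([res.participant_ids.index(p) for p in ids])
    r = copy(res)
    r.participant_ids = ids
    r.y_true = res.y_true[idx]
    r.y_pred = res.y_pred[idx]
    r.decision_scores = res.decision_scores[idx]
    return r


def signatures_analysis(data: CohortData, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided KS tests FSHD vs DM on every feature, Bonferroni-corrected."""
    df = _session1(data)
    a = df[df["group"] == "FSHD"]
    b = df[df["group"] == "DM"]
    res = signature_tests(a, b, data.registry.names, alpha)
    return pd.DataFrame(
        [
            {
                "feature": r.feature_name,
                "groups": "FSHD_vs_DM",
                "ks_statistic": r.ks_statistic,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
                "significant": r.significant,
            }
            for r in res
        ]
    )


def importance_analysis(data: CohortData, seed: int = 0, top_k: int = 10) -> dict:
    """Disease-vs-control feature importance (mean |SHAP| over held-out
    subjects) for the FSHD and DM models."""
    out = {}
    for preset in ("video_all_fshd_ctl", "video_all_dm_ctl"):
        groups, input_set = PRESETS[preset]
        ids, X, y, names = build_design(data, groups, input_set)
        res = loso_linear_svc(
            X, y, ids, seed=seed, model_name=preset, input_set=input_set,
            feature_names=names,
        )
        ranking = importance_ranking(res)
        ranking["provenance"] = [data.registry.provenance(f) for f in ranking["feature"]]
        out[preset] = {
            "balanced_accuracy": res.balanced_accuracy,
            "ranking": ranking,
            "top": ranking.head(top_k),
        }
    return out


def reliability_analysis(data: CohortData) -> pd.DataFrame:
    """Per-feature test-retest ICC for subjects with two sessions."""
    s1 = data.features[data.features["session"] == 1]
    s2 = data.features[data.features["session"] == 2]
    retest_ids = set(s1["participant_id"]) & set(s2["participant_id"])
    if len(retest_ids) < 2:
        raise KinesigError("reliability analysis needs >= 2 retest participants")
    s1 = s1[s1["participant_id"].isin(retest_ids)]
    s2 = s2[s2["participant_id"].isin(retest_ids)]
    # drop features with zero variance across retest subjects (ICC undefined)
    names = [
        n
        for n in data.registry.names
        if np.std(s1[n].to_numpy()) > 0 or np.std(s2[n].to_numpy()) > 0
    ]
    table = reliability_table(s1, s2, names)
    return table


# ---------------------------------------------------------------------------
# run


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def run(config: RunConfig) -> dict:
    """Execute the enabled analyses; write the report bundle if out_dir set."""
    if config.mode == "synthetic":
        bundle = generate_cohort(config.synthetic)
        data = cohort_from_bundle(bundle)
    else:
        data = load_directory(config.input_dir)
    log.info(
        "cohort: %d participant-sessions, %d excluded",
        len(data.features),
        len(data.exclusions),
    )
    report: dict = {
        "seed": config.seed,
        "n_participant_sessions": len(data.features),
        "exclusions": data.exclusions,
    }
    outputs: dict = {"features": data.features}
    if "tft_reproduction" in config.analyses:
        tft = tft_reproduction(data)
        report["tft_reproduction"] = {
            k: {kk: vv for kk, vv in v.items() if kk != "predictions"}
            for k, v in tft.items()
        }
        outputs["tft_predictions"] = pd.concat(
            [v["predictions"] for v in tft.values()], ignore_index=True
        ) if tft else pd.DataFrame()
    if "classification" in config.analyses:
        cls = classification_analysis(data, seed=config.seed)
        report["classification"] = {
            "models": {
                k: {kk: vv for kk, vv in v.items() if kk not in ("predictions",)}
                for k, v in cls["models"].items()
            },
            "comparisons": cls["comparisons"],
        }
        outputs["classification"] = cls
    if "signatures" in config.analyses:
        sig = signatures_analysis(data, config.alpha)
        report["signatures"] = {
            "n_features": len(sig),
            "n_significant": int(sig["significant"].sum()),
        }
        outputs["signatures"] = sig
    if "importance" in config.analyses:
        imp = importance_analysis(data, seed=config.seed)
        report["importance"] = {
            k: {
                "balanced_accuracy": v["balanced_accuracy"],
                "top": v["top"][["feature", "mean_abs_shap", "provenance"]].to_dict(
                    "records"
                ),
            }
            for k, v in imp.items()
        }
        outputs["importance"] = imp
    if "reliability" in config.analyses:
        rel = reliability_analysis(data)
        moderate_plus = float(np.mean(rel["icc"] >= 0.5))
        report["reliability"] = {
            "n_features": len(rel),
            "fraction_moderate_or_better": moderate_plus,
        }
        outputs["reliability"] = rel
    report["data"] = data
    report["outputs"] = outputs

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        data.features.to_csv(out / "features.csv", index=False, float_format="%.9g")
        if "tft_reproduction" in config.analyses:
            (out / "tft_metrics.json").write_text(
                json.dumps(report["tft_reproduction"], indent=2, sort_keys=True,
                           default=_json_default)
                + "\n"
            )
            outputs["tft_predictions"].to_csv(
                out / "tft_predictions.csv", index=False, float_format="%.9g"
            )
        if "classification" in config.analyses:
            (out / "classification.json").write_text(
                json.dumps(report["classification"], indent=2, sort_keys=True,
                           default=_json_default)
                + "\n"
            )
        if "signatures" in config.analyses:
            outputs["signatures"].to_csv(
                out / "signatures.csv", index=False, float_format="%.9g"
            )
        if "importance" in config.analyses:
            pd.concat(
                [
                    v["ranking"].assign(model=k)
                    for k, v in outputs["importance"].items()
                ],
                ignore_index=True,
            ).to_csv(out / "importance.csv", index=False, float_format="%.9g")
        if "reliability" in config.analyses:
            outputs["reliability"].to_csv(
                out / "reliability.csv", index=False, float_format="%.9g"
            )
        (out / "summary.txt").write_text(_summary_text(report))
    return report


def _summary_text(report: dict) -> str:
    lines = [
        f"kinesig run (seed={report['seed']})",
        f"participant-sessions: {report['n_participant_sessions']}; "
        f"excluded: {len(report['exclusions'])}",
    ]
    if "tft_reproduction" in report:
        for tft, m in report["tft_reproduction"].items():
            lines.append(
                f"TFT {tft}: n={m['n']} r={m['pearson_r']:.3f} MAE={m['mae_s']:.2f} s"
                + (
                    f" (MCID {m['mcid_s']} s, below={m['below_mcid']})"
                    if m["mcid_s"] is not None
                    else ""
                )
            )
    if "classification" in report:
        for name, m in report["classification"]["models"].items():
            lines.append(
                f"model {name}: balanced accuracy {m['balanced_accuracy']:.3f} "
                f"(n={m['n']})"
            )
        for name, c in report["classification"]["comparisons"].items():
            lines.append(f"McNemar {name}: n01={c['n01']} n10={c['n10']} p={c['p']:.4f}")
    if "signatures" in report:
        s = report["signatures"]
        lines.append(
            f"signatures: {s['n_significant']}/{s['n_features']} features "
            "significant after Bonferroni"
        )
    if "reliability" in report:
        r = report["reliability"]
        lines.append(
            f"reliability: {100 * r['fraction_moderate_or_better']:.0f}% of "
            f"{r['n_features']} features with moderate reliability or better"
        )
    return "\n".join(lines) + "\n"
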