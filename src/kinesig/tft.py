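"""Video-based timed-function-test (TFT) surrogates and LOSO calibration.

Gait TFT surrogates divide the 10 m course length by the gait speed measured
in the camera field of view; chair-task surrogates are the automated task
durations from COM-elevation segmentation. Because surrogates differ
systematically from stopwatch times (partial course visibility, COM-based
rather than chair-contact timing), an ordinary-least-squares line per TFT is
calibrated with leave-one-subject-out cross-validation and evaluated on the
pooled held-out predictions (Pearson r, MAE), then compared against published
minimum clinically important differences (MCIDs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateFitError
from .events import TaskSegments
from .stats import mean_absolute_error, pearson_r

COURSE_LENGTH_M = 10.0

TFT_NAMES = ("walk10m", "run10m", "tug", "sts5x")

#: Published distribution-based MCIDs (s). walk10m and tug are for myotonic
#: dystrophy; run10m is the Duchenne muscular dystrophy value; no 5xSTS MCID
#: exists in the neuromuscular literature.
MCID_S: dict[str, float | None] = {
    "walk10m": 0.69,
    "tug": 0.92,
    "run10m": 2.3,
    "sts5x": None,
}


def gait_surrogate(speed_m_s: float) -> float:
    """TFT surrogate for the 10 m walk/run: course length over gait speed."""
    if not speed_m_s > 0:
        raise DataError(f"gait speed must be > 0, got {speed_m_s}")
    return COURSE_LENGTH_M / speed_m_s


def task_surrogate(segments: TaskSegments, tft_name: str) -> float:
    """Chair-task surrogate time from segmented repetitions."""
    reps = segments.repetitions
    if tft_name == "sts5x":
        if len(reps) != 5:
            raise DataError(f"5xSTS surrogate needs 5 repetitions, got {len(reps)}")
        return float(reps[-1][1] - reps[0][0])
    if tft_name == "tug":
        if len(reps) != 1:
            raise DataError(f"TUG surrogate needs 1 repetition, got {len(reps)}")
        return float(reps[0][1] - reps[0][0])
    raise DataError(f"no task surrogate for {tft_name!r}")


@dataclass
class SurrogatePrediction:
    participant_id: str
    tft_name: str
    surrogate_s: float
    predicted_s: float
    human_s: float | None = None


@dataclass
class CalibrationResult:
    tft_name: str
    predictions: list[SurrogatePrediction]
    pearson_r: float
    mae_s: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.predictions])


def loso_calibrate(
    participant_ids,
    surrogates,
    human,
    tft_name: str = "",
) -> CalibrationResult:
    """Leave-one-subject-out OLS calibration of surrogate -> human time.

    For each subject, intercept + slope are fit on all other subjects' pairs
    and applied to the held-out surrogate; r and MAE are computed over the
    pooled held-out predictions.
    """
    ids = list(participant_ids)
    s = np.asarray(surrogates, dtype=float)
    h = np.asarray(human, dtype=float)
    if not (len(ids) == len(s) == len(h)):
        raise DataError("ids, surrogates and human times must align")
    n = len(s)
    if n < 3:
        raise DataError(f"need >= 3 paired observations, got {n}")
    preds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.std(s[mask]) == 0:
            raise DegenerateFitError(
                f"{tft_name}: zero surrogate variance in fold excluding {ids[i]}"
            )
        slope, intercept = np.polyfit(s[mask], h[mask], 1)
        preds.append(
            SurrogatePrediction(
                participant_id=ids[i],
                tft_name=tft_name,
                surrogate_s=float(s[i]),
                predicted_s=float(slope * s[i] + intercept),
                human_s=float(h[i]),
            )
        )
    yhat = np.array([p.predicted_s for p in preds])
    return CalibrationResult(
        tft_name=tft_name,
        predictions=preds,
        pearson_r=pearson_r(yhat, h),
        mae_s=mean_absolute_error(yhat, h),
        n=n,
    )


def mcid_compare(mae_s: float, tft_name: str) -> dict:
    """Compare a prediction MAE against the published MCID (strict <)."""
    if tft_name not in MCID_S:
        raise DataError(f"unknown TFT {tft_name!r}")
    mcid = MCID_S[tft_name]
    return {
        "tft": tft_name,
        "mae_s": float(mae_s),
        "mcid_s": mcid,
        "below_mcid": (mae_s < mcid) if mcid is not None else None,
    }
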