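"""Statistical primitives: balanced accuracy, McNemar, KS + Bonferroni, ICC.

Bare p-values are reported for exploration, never used as pass/fail surfaces
by the package itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of per-class recalls over the classes present in y_true."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise DataError("y_true and y_pred must have equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    true_classes = set(np.unique(y_true))
    missing = [c for c in classes if c not in true_classes]
    if missing:
        raise DataError(f"classes {missing} absent from y_true")
    recalls = [np.mean(y_pred[y_true == c] == c) for c in np.unique(y_true)]
    return float(np.mean(recalls))


def mcnemar_test(n01: int, n10: int, exact_max: int = 25) -> float:
    """Two-sided McNemar test on discordant prediction counts.

    Exact binomial (p = 1/2) when n01 + n10 <= exact_max, else chi-square
    with continuity correction. (0, 0) returns 1.0 by convention.
    """
    if n01 < 0 or n10 < 0 or n01 != int(n01) or n10 != int(n10):
        raise DataError("discordant counts must be non-negative integers")
    n = n01 + n10
    if n == 0:
        return 1.0
    if n <= exact_max:
        return float(sps.binomtest(int(n01), int(n), 0.5).pvalue)
    stat = (abs(n01 - n10) - 1) ** 2 / n
    return float(sps.chi2.sf(stat, df=1))


def ks_two_sided(sample_a, sample_b, exact_max: int = 25) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (D, p).

    Exact p-value for min(n, m) <= exact_max, asymptotic otherwise; ECDF
    differences are evaluated at all pooled sample points so ties are handled.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DataError("both samples must be non-empty")
    method = "exact" if min(len(a), len(b)) <= exact_max else "asymp"
    res = sps.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p * n_tests)."""
    p = np.asarray(p_values, dtype=float)
    n = n_tests if n_tests is not None else len(p)
    return np.minimum(1.0, p * n)


@dataclass(frozen=True)
class SignatureTestResult:
    feature_name: str
    ks_statistic: float
    p_raw: float
    p_bonferroni: float
    significant: bool


def signature_tests(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    feature_names: list[str],
    alpha: float = 0.05,
) -> list[SignatureTestResult]:
    """Distribution tests on every feature between two groups, Bonferroni-
    corrected across the full feature set."""
    n = len(feature_names)
    out = []
    for name in feature_names:
        d, p = ks_two_sided(features_a[name].to_numpy(), features_b[name].to_numpy())
        p_b = float(min(1.0, p * n))
        out.append(SignatureTestResult(name, d, p, p_b, p_b < alpha))
    return out


# ---------------------------------------------------------------------------
# test-retest reliability


def _icc_category(icc: float) -> str:
    # Koo & Li cut-points
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ReliabilityReport:
    metric_name: str
    icc: float
    n_subjects: int
    n_sessions: int
    category: str


def icc_absolute_single(
    measurements: np.ndarray, metric_name: str = ""
) -> ReliabilityReport:
    """Single-measure absolute-agreement ICC from a two-way model.

    measurements: (n_subjects, k_sessions), no missing cells. Computed from
    the two-way ANOVA mean squares as
    (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)),
    which penalizes systematic between-session offsets.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2:
        raise DataError("measurements must be a subjects x sessions matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise DataError("need >= 2 subjects and >= 2 sessions")
    if np.isnan(m).any():
        raise DataError("missing cells; apply listwise deletion before calling")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    icc = float((ms_r - ms_e) / denom) if denom != 0 else 1.0
    return ReliabilityReport(metric_name, icc, n, k, _icc_category(icc))


def icc_consistency_single(measurements: np.ndarray) -> float:
    """Single-measure consistency ICC (ignores session offsets); used for
    the definitional ordering check against absolute agreement."""
    m = np.asarray(measurements, dtype=float)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = np.sum((m - grand) ** 2) - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return float((ms_r - ms_e) / (ms_r + (k - 1) * ms_e))


def reliability_table(
    session1: pd.DataFrame, session2: pd.DataFrame, feature_names: list[str]
) -> pd.DataFrame:
    """Per-feature test-retest ICC for subjects present in both sessions."""
    merged = session1.merge(
        session2, on="participant_id", suffixes=("_s1", "_s2")
    )
    rows = []
    for name in feature_names:
        m = merged[[f"{name}_s1", f"{name}_s2"]].to_numpy()
        rep = icc_absolute_single(m, name)
        rows.append(
            {
                "feature": name,
                "icc": rep.icc,
                "n_subjects": rep.n_subjects,
                "n_sessions": rep.n_sessions,
                "category": rep.category,
            }
        )
    return pd.DataFrame(rows)


def pearson_r(x, y) -> float:
    return float(sps.pearsonr(np.asarray(x, float), np.asarray(y, float)).statistic)


def mean_absolute_error(x, y) -> float:
    return float(np.mean(np.abs(np.asarray(x, float) - np.asarray(y, float))))
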