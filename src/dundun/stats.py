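"""Group-difference tests and collinearity screening on stimulus features.

Each acoustic measure is compared between the music-like and speech-like
stimulus groups with a Welch (unequal-variance) two-tailed t-test, one
stimulus = one observation, with a Bonferroni-corrected significance
threshold across the battery.  Before the perception model is fit, the
stimulus-level predictor matrix is screened for multicollinearity with
variance inflation factors (VIF), iteratively dropping the worst predictor
until all VIFs are at or below the threshold (5 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .behavior import cohens_d

__all__ = ["TTestResult", "welch_t", "corrected_threshold", "group_feature_tests", "vif_screen"]


@dataclass
class TTestResult:
    feature: str
    t: float
    df: float
    p: float
    d: float
    significant_after_correction: bool | None = None


def welch_t(group_a: np.ndarray, group_b: np.ndarray, feature: str = "") -> TTestResult:
    """Welch two-tailed t-test (A - B) with Satterthwaite df and pooled-SD d."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 finite values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance in both groups with equal means; t = 0")
            return TTestResult(feature, 0.0, float(a.size + b.size - 2), 1.0, 0.0)
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        feature=feature,
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        d=cohens_d(a, b),
    )


def corrected_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def group_feature_tests(
    stimuli: pd.DataFrame,
    features: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-tests (music - speech) for each feature, Bonferroni-corrected.

    One row per feature with t, Welch df, two-tailed p, Cohen's d and a flag
    for significance at alpha / n_tests.
    """
    if features is None:
        features = [
            "mean_intensity",
            "mean_pitch",
            "mean_timbre",
            "mean_ioi_ms",
            "mean_intensity_change",
            "mean_pitch_change",
            "mean_timbre_change",
            "mean_interval_ratio",
            "ams_peak_hz",
            "pulse_clarity",
        ]
    music = stimuli[stimuli["intended_category"] == "music"]
    speech = stimuli[stimuli["intended_category"] == "speech"]
    thr = corrected_threshold(alpha, len(features))
    rows = []
    for feat in features:
        r = welch_t(music[feat].to_numpy(), speech[feat].to_numpy(), feature=feat)
        r.significant_after_correction = r.p < thr
        rows.append(vars(r))
    out = pd.DataFrame(rows)
    out.attrs["corrected_threshold"] = thr
    return out


def _vif(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1/(1-R^2) from regressing it on the other columns."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return 1.0 / max(1.0 - r2, 1e-12)


def vif_screen(predictors: pd.DataFrame, threshold: float = 5.0) -> dict:
    """VIF screen of a stimulus-level predictor matrix.

    Exact duplicate columns are dropped first.  Then every predictor whose
    VIF in the full matrix exceeds ``threshold`` is removed in one pass
    (largest first in the report), the convention under which a correlated
    block like IOI/intensity-change is removed as a whole; if any VIF still
    exceeds the threshold afterwards, removal continues iteratively.
    Returns the retained column list, the removal order with the VIF each
    predictor had when removed, the final VIF table, and the pairwise
    Pearson correlations of the original predictors.
    """
    cols = list(predictors.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 predictors")
    if len(predictors) <= len(cols):
        raise ValueError("need more rows than predictors")
    X = predictors.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("predictor matrix contains non-finite values")

    corr = predictors.corr(method="pearson")

    removed: list[tuple[str, float]] = []
    # exact duplicates (including scaled copies) make the screen singular
    keep = cols.copy()
    i = 0
    while i < len(keep):
        j = i + 1
        while j < len(keep):
            a, b = predictors[keep[i]].to_numpy(), predictors[keep[j]].to_numpy()
            if np.allclose(np.corrcoef(a, b)[0, 1], 1.0, atol=1e-12):
                removed.append((keep[j], np.inf))
                keep.pop(j)
            else:
                j += 1
        i += 1

    first_pass = True
    while len(keep) >= 2:
        X = predictors[keep].to_numpy(dtype=np.float64)
        vifs = np.array([_vif(X, j) for j in range(len(keep))])
        if np.all(vifs <= threshold):
            break
        if first_pass:  # drop the whole offending block at once
            order = np.argsort(-vifs)
            for j in order:
                if vifs[j] > threshold:
                    removed.append((keep[j], float(vifs[j])))
            keep = [c for j, c in enumerate(keep) if vifs[j] <= threshold]
            first_pass = False
        else:
            worst = int(np.argmax(vifs))
            removed.append((keep[worst], float(vifs[worst])))
            keep.pop(worst)

    final = {
        c: float(v)
        for c, v in zip(keep, [_vif(predictors[keep].to_numpy(float), j) for j in range(len(keep))])
    } if len(keep) >= 2 else {c: 1.0 for c in keep}
    return {
        "retained": keep,
        "removed": removed,
        "vif": final,
        "correlations": corr,
    }
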