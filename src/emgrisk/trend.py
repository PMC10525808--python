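"""Fatigue trend analysis: spectral frequency versus lift progression.

Muscular fatigue compresses the EMG power spectrum: mean and median
frequency decline as a trial progresses.  For each (feature, muscle,
condition) combination the per-subject series of F_mean or F_median over
the 30 lifts is min-max normalized to [0, 1], the lift ordinal is mapped
to [0, 1], and a single ordinary-least-squares line is fitted to the
pooled (lift progression, normalized value) pairs of all subjects.  A
negative, significant slope in the RISK condition with a flat NO-RISK
slope is the fatigue signature of risky lifting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .simulate import CONDITIONS, NO_RISK, RISK

TREND_FEATURES = ("F_mean", "F_median")
MUSCLE_SUFFIXES = ("ER", "ML")


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of normalized feature value against lift progression."""

    feature: str
    muscle: str
    condition: str
    m: float  # slope, normalized units per normalized lift index
    q: float  # intercept, normalized units
    r2: float
    p_slope: float
    n: int


def normalize_series(values: np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1]; constant series is undefined."""
    values = np.asarray(values, dtype=float)
    span = np.ptp(values)
    if span == 0.0:
        raise ParameterError("cannot normalize a constant series")
    return (values - values.min()) / span


def fit_trend(x: np.ndarray, y: np.ndarray, feature: str = "",
              muscle: str = "", condition: str = "") -> TrendFit:
    """OLS slope/intercept on (x, y) pairs with the slope's t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ParameterError("need at least 3 paired observations")
    if np.ptp(x) == 0.0:
        raise ParameterError("degenerate regressor: all x values equal")
    res = stats.linregress(x, y)
    return TrendFit(feature=feature, muscle=muscle, condition=condition,
                    m=float(res.slope), q=float(res.intercept),
                    r2=float(res.rvalue ** 2), p_slope=float(res.pvalue),
                    n=len(x))


def analyze_trends(feature_table: pd.DataFrame,
                   features: tuple[str, ...] = TREND_FEATURES,
                   muscles: tuple[str, ...] = MUSCLE_SUFFIXES
                   ) -> list[TrendFit]:
    """Pooled per-condition trend fits for every (feature, muscle) pair.

    Each subject's series is min-max normalized and its lift ordinal
    mapped to [0, 1] before pooling; subjects whose series is constant
    are skipped for that combination.
    """
    table = feature_table
    if "valid" in table.columns:
        table = table[table["valid"] == True]  # noqa: E712
    fits: list[TrendFit] = []
    for feature in features:
        for muscle in muscles:
            column = f"{feature}_{muscle}"
            if column not in table.columns:
                raise ParameterError(f"missing feature column {column}")
            for condition in CONDITIONS:
                xs: list[np.ndarray] = []
                ys: list[np.ndarray] = []
                sub = table[table["label"] == condition]
                for _, group in sub.groupby("subject_id"):
                    g = group.sort_values("lift_index")
                    vals = g[column].to_numpy(dtype=float)
                    idx = g["lift_index"].to_numpy(dtype=float)
                    if len(vals) < 3 or np.ptp(vals) == 0.0 or np.ptp(idx) == 0.0:
                        continue
                    ys.append(normalize_series(vals))
                    xs.append((idx - idx.min()) / np.ptp(idx))
                if not xs:
                    continue
                fits.append(fit_trend(np.concatenate(xs), np.concatenate(ys),
                                      feature=feature, muscle=muscle,
                                      condition=condition))
    return fits


def trends_frame(fits: list[TrendFit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": f.feature, "muscle": f.muscle, "condition": f.condition,
        "m": f.m, "q": f.q, "r2": f.r2, "p": f.p_slope, "n": f.n,
    } for f in fits])


def compare_conditions(fits: list[TrendFit], alpha: float = 0.05) -> dict:
    """Summarise the RISK-vs-NO-RISK slope pattern.

    For each (feature, muscle): reports both slopes and p-values and the
    flag ``fatigue_detected`` — RISK slope negative and significant while
    the NO-RISK slope is nonnegative or non-significant.
    """
    by_key: dict[tuple[str, str], dict[str, TrendFit]] = {}
    for f in fits:
        by_key.setdefault((f.feature, f.muscle), {})[f.condition] = f
    summary: dict[str, dict] = {}
    for (feature, muscle), pair in sorted(by_key.items()):
        if NO_RISK not in pair or RISK not in pair:
            raise ParameterError(
                f"missing condition for {feature}_{muscle}")
        risk, no_risk = pair[RISK], pair[NO_RISK]
        fatigue = (risk.m < 0 and risk.p_slope < alpha
                   and (no_risk.m >= 0 or no_risk.p_slope >= alpha))
        summary[f"{feature}_{muscle}"] = {
            "m_risk": risk.m, "p_risk": risk.p_slope,
            "m_no_risk": no_risk.m, "p_no_risk": no_risk.p_slope,
            "slope_difference": risk.m - no_risk.m,
            "fatigue_detected": fatigue,
        }
    return summary
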