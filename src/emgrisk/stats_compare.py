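"""Paired NO-RISK vs RISK comparison of every spectral feature.

For each of the seven features of each muscle, lift i of the NO-RISK
trial is paired with lift i of the RISK trial of the same subject, and
the pairs are pooled across subjects.  A Shapiro-Wilk gate decides the
test: when both samples look normal (p >= alpha for each) a two-tailed
paired t-test is used, otherwise the Wilcoxon signed-rank test.  No
multiple-testing correction is applied across the 14 feature tests; the
per-feature p-values are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .simulate import NO_RISK, RISK
from .spectral import FEATURE_NAMES

ALPHA = 0.05

PARAMETRIC = "parametric"
NONPARAMETRIC = "nonparametric"


@dataclass(frozen=True)
class PairedComparisonResult:
    feature: str
    muscle: str
    mean_no_risk: float
    std_no_risk: float
    mean_risk: float
    std_risk: float
    test_used: str  # 'paired-t' or 'wilcoxon'
    p_value: float
    significant: bool
    degenerate: bool = False  # all paired differences were zero


def normality_gate(x: np.ndarray, y: np.ndarray,
                   alpha: float = ALPHA) -> str:
    """'parametric' iff Shapiro-Wilk keeps normality for BOTH samples.

    Degenerate (constant) samples, for which the Shapiro-Wilk statistic
    is undefined, fail safe to the nonparametric branch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ParameterError("need paired samples of equal length >= 3")
    for sample in (x, y):
        if np.ptp(sample) == 0.0:
            return NONPARAMETRIC
        if stats.shapiro(sample).pvalue < alpha:
            return NONPARAMETRIC
    return PARAMETRIC


def paired_compare(x: np.ndarray, y: np.ndarray, alpha: float = ALPHA,
                   feature: str = "", muscle: str = ""
                   ) -> PairedComparisonResult:
    """Gated two-tailed paired test of x (NO-RISK) vs y (RISK).

    The Wilcoxon signed-rank test is exact for n <= 25 (when scipy's
    exact method applies, i.e. no zero differences) and uses the normal
    approximation above that.  All-zero differences yield p = 1 with a
    degenerate flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gate = normality_gate(x, y, alpha)
    diffs = y - x
    degenerate = bool(np.all(diffs == 0.0))
    if degenerate:
        test_used, p = ("paired-t" if gate == PARAMETRIC else "wilcoxon"), 1.0
    elif gate == PARAMETRIC:
        test_used = "paired-t"
        p = float(stats.ttest_rel(x, y).pvalue)
    else:
        test_used = "wilcoxon"
        has_zeros = bool(np.any(diffs == 0.0))
        method = "exact" if (len(x) <= 25 and not has_zeros) else "approx"
        p = float(stats.wilcoxon(x, y, method=method).pvalue)
    return PairedComparisonResult(
        feature=feature, muscle=muscle,
        mean_no_risk=float(x.mean()), std_no_risk=float(x.std(ddof=1)),
        mean_risk=float(y.mean()), std_risk=float(y.std(ddof=1)),
        test_used=test_used, p_value=p,
        significant=bool(p < alpha), degenerate=degenerate)


def _paired_arrays(table: pd.DataFrame, column: str
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Lift-wise paired (NO-RISK, RISK) arrays pooled over subjects."""
    valid = table[table.get("valid", True) == True]  # noqa: E712
    pivot = valid.pivot_table(index=["subject_id", "lift_index"],
                              columns="label", values=column)
    pivot = pivot.dropna(subset=[NO_RISK, RISK])
    return pivot[NO_RISK].to_numpy(), pivot[RISK].to_numpy()


def summarize_tables(feature_table: pd.DataFrame, alpha: float = ALPHA
                     ) -> dict[str, pd.DataFrame]:
    """Per-muscle comparison tables (one row per feature).

    Returns ``{"ER": table, "ML": table}`` (muscles present in the input)
    with columns: feature, mean/std per condition, test used, p-value and
    the significance flag at the chosen alpha.
    """
    muscles = sorted({col.rsplit("_", 1)[1] for col in feature_table.columns
                      if col.rsplit("_", 1)[0] in FEATURE_NAMES})
    if not muscles:
        raise ParameterError("feature table contains no feature columns")
    out: dict[str, pd.DataFrame] = {}
    for muscle in muscles:
        rows = []
        for name in FEATURE_NAMES:
            column = f"{name}_{muscle}"
            if column not in feature_table.columns:
                raise ParameterError(f"missing feature column {column}")
            x, y = _paired_arrays(feature_table, column)
            res = paired_compare(x, y, alpha, feature=name, muscle=muscle)
            rows.append({
                "feature": column,
                "mean_no_risk": res.mean_no_risk,
                "std_no_risk": res.std_no_risk,
                "mean_risk": res.mean_risk,
                "std_risk": res.std_risk,
                "test_used": res.test_used,
                "p_value": res.p_value,
                "significant": res.significant,
            })
        out[muscle] = pd.DataFrame(rows)
    return out
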