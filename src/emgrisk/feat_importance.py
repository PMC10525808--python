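"""Information-gain feature ranking.

Each continuous feature is discretized with the supervised MDL method of
Fayyad and Irani — recursive binary splitting at class-boundary cut
points, accepted only while the information gain exceeds the minimum
description length cost of the split.  The information gain of the
binned feature is then

    IG = H(labels) - sum_b p(b) H(labels | bin b)      [bits]

Features are ranked by descending IG, and the share of total IG carried
by the multifidus (_ML) versus erector spinae (_ER) columns summarises
which muscle is the more informative.

When MDL accepts no cut at all (feature uninformative at the MDL bar),
the feature falls back to equal-frequency binning with 10 bins so a
small nonzero IG can still be measured; constant features stay single-
bin with IG 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .spectral import FEATURE_COLUMNS

FALLBACK_BINS = 10


def entropy_bits(labels: np.ndarray) -> float:
    """Shannon entropy of a label vector, base 2."""
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(binned: np.ndarray, labels: np.ndarray) -> float:
    """IG of a discretized feature: H(labels) - H(labels | bins), bits."""
    binned = np.asarray(binned)
    labels = np.asarray(labels)
    n = len(labels)
    cond = 0.0
    for b in np.unique(binned):
        mask = binned == b
        cond += mask.sum() / n * entropy_bits(labels[mask])
    return entropy_bits(labels) - cond


def _best_cut(values: np.ndarray, labels: np.ndarray
              ) -> tuple[float, float] | None:
    """Best binary cut (threshold, info gain); None when no cut exists.

    Candidate thresholds are midpoints between adjacent distinct values
    (boundary points suffice for optimality, but scanning all adjacent
    midpoints is cheap and equivalent here).
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = labels[order]
    n = len(v)
    classes, y_codes = np.unique(y, return_inverse=True)
    k = len(classes)
    # Cumulative class counts below each possible split position.
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y_codes] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    H = entropy_bits(y)

    def h(counts: np.ndarray) -> float:
        tot = counts.sum()
        if tot == 0:
            return 0.0
        p = counts[counts > 0] / tot
        return float(-(p * np.log2(p)).sum())

    best: tuple[float, float] | None = None
    # Split after position i (1..n-1) only where the value changes.
    change = np.flatnonzero(v[1:] != v[:-1]) + 1
    for i in change:
        left = cum[i - 1]
        right = total - left
        gain = H - (i / n) * h(left) - ((n - i) / n) * h(right)
        if best is None or gain > best[1]:
            best = ((v[i - 1] + v[i]) / 2.0, gain)
    return best


def _mdl_accepts(values: np.ndarray, labels: np.ndarray, cut: float,
                 gain: float) -> bool:
    """Fayyad-Irani MDL stopping criterion for a candidate binary cut."""
    n = len(values)
    left = labels[values <= cut]
    right = labels[values > cut]
    k = len(np.unique(labels))
    k1 = len(np.unique(left))
    k2 = len(np.unique(right))
    ent = entropy_bits(labels)
    delta = (np.log2(3 ** k - 2) - (k * ent
                                    - k1 * entropy_bits(left)
                                    - k2 * entropy_bits(right)))
    threshold = (np.log2(n - 1) + delta) / n
    return gain > threshold


def mdl_cut_points(values: np.ndarray, labels: np.ndarray) -> list[float]:
    """Recursive MDL (Fayyad-Irani) cut points, ascending."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    cuts: list[float] = []

    def recurse(mask: np.ndarray) -> None:
        v, y = values[mask], labels[mask]
        if len(v) < 2 or len(np.unique(y)) < 2:
            return
        best = _best_cut(v, y)
        if best is None:
            return
        cut, gain = best
        if not _mdl_accepts(v, y, cut, gain):
            return
        cuts.append(cut)
        recurse(mask & (values <= cut))
        recurse(mask & (values > cut))

    recurse(np.ones(len(values), dtype=bool))
    return sorted(cuts)


def discretize(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Supervised MDL discretization; returns integer bin indices.

    Falls back to equal-frequency binning (10 bins) when MDL yields a
    single bin; a constant feature stays in one bin.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(values)) < 2:
        return np.zeros(len(values), dtype=int)
    cuts = mdl_cut_points(values, labels)
    if not cuts:
        quantiles = np.quantile(values,
                                np.linspace(0, 1, FALLBACK_BINS + 1)[1:-1])
        cuts = sorted(set(quantiles))
    return np.searchsorted(cuts, values, side="left").astype(int)


@dataclass(frozen=True)
class ImportanceRanking:
    """Features ordered by descending information gain."""

    ranking: list[tuple[str, float]]  # (feature name, IG in bits)
    muscle_share: dict[str, float]  # fraction of total IG per muscle

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"feature": f, "ig_bits": g, "rank": i + 1}
             for i, (f, g) in enumerate(self.ranking)])


def rank_features(feature_table: pd.DataFrame,
                  feature_columns: tuple[str, ...] = FEATURE_COLUMNS
                  ) -> ImportanceRanking:
    """Rank features by IG and compute the per-muscle IG share."""
    missing = [c for c in feature_columns if c not in feature_table.columns]
    if missing:
        raise ParameterError(f"missing feature columns: {missing}")
    table = feature_table
    if "valid" in table.columns:
        table = table[table["valid"] == True]  # noqa: E712
    labels = table["label"].to_numpy()
    gains = {}
    for column in feature_columns:
        binned = discretize(table[column].to_numpy(dtype=float), labels)
        gains[column] = information_gain(binned, labels)
    ranking = sorted(gains.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(gains.values())
    share: dict[str, float] = {}
    for muscle in ("ER", "ML"):
        cols = [c for c in feature_columns if c.endswith(f"_{muscle}")]
        if cols:
            share[muscle] = (sum(gains[c] for c in cols) / total
                             if total > 0 else 0.0)
    return ImportanceRanking(ranking=ranking, muscle_share=share)
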