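"""Univariate characterization of the spatio-spectral features.

Spearman rank correlation quantifies the monotone relation between each
(channel, band) log-amplitude and the workload level; a two-sided Wilcoxon
rank-sum test compares the extreme levels (n = 0 vs n = 2); prevalence
aggregates per-participant significance under a Bonferroni-corrected
threshold; and the controller-bias check verifies that hand-movement
positions carry (almost) no workload information.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sst

from .features import FeatureTable
from .simulate import ControllerTrace

__all__ = [
    "spearman_feature_correlation",
    "ranksum_extremes",
    "bonferroni_threshold",
    "prevalence",
    "controller_bias_r2",
    "univariate_table",
    "prevalence_table",
]


def spearman_feature_correlation(
    features: FeatureTable,
) -> Tuple[np.ndarray, np.ndarray]:
    """Trial-wise Spearman rho of each feature with the workload label.

    Ties receive average ranks. Returns ``(rho, degenerate)`` where
    degenerate marks constant features, reported as rho = 0.
    """
    labels = features.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two distinct workload labels")
    n_feat = features.values.shape[1]
    rho = np.zeros(n_feat)
    degenerate = np.zeros(n_feat, dtype=bool)
    for j in range(n_feat):
        col = features.values[:, j]
        if np.ptp(col) == 0:
            degenerate[j] = True
            continue
        rho[j] = sst.spearmanr(col, labels).statistic
    return rho, degenerate


def ranksum_extremes(
    features: FeatureTable,
    low: int = 0,
    high: int = 2,
    method: str = "asymptotic",
) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per feature, n=low vs n=high.

    The default is the normal approximation with tie and continuity
    correction (appropriate at 76 trials per class); ``method="exact"``
    enumerates the null for small tie-free samples.
    """
    a = features.values[features.labels == low]
    b = features.values[features.labels == high]
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError(f"both extreme classes ({low}, {high}) must be non-empty")
    p = np.empty(features.values.shape[1])
    for j in range(p.size):
        res = sst.mannwhitneyu(
            a[:, j], b[:, j], alternative="two-sided", method=method
        )
        p[j] = min(float(res.pvalue), 1.0)
    return p


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Corrected per-test significance level alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def prevalence(
    per_participant_p: Sequence[pd.Series],
    threshold: float,
) -> pd.Series:
    """Fraction of participants significant per feature at ``threshold``.

    Each entry of ``per_participant_p`` is a Series of p-values indexed by
    feature name; all indexes must agree.
    """
    if len(per_participant_p) == 0:
        raise ValueError("need at least one participant")
    index = per_participant_p[0].index
    for s in per_participant_p[1:]:
        if not s.index.equals(index):
            raise ValueError("inconsistent feature sets across participants")
    stacked = np.vstack([s.to_numpy(float) for s in per_participant_p])
    return pd.Series((stacked < threshold).mean(axis=0), index=index)


def controller_bias_r2(trace: ControllerTrace) -> Tuple[float, bool]:
    """Squared Pearson correlation of controller position with workload level.

    Returns ``(r2, degenerate)``; constant positions give r2 = 0 with the
    degeneracy flag set.
    """
    if len(np.unique(trace.n_levels)) < 2:
        raise ValueError("need at least two distinct workload labels")
    if np.ptp(trace.positions) == 0:
        return 0.0, True
    r = sst.pearsonr(trace.positions, trace.n_levels.astype(float)).statistic
    return float(r**2), False


def univariate_table(
    raw: FeatureTable,
    suppressed: Optional[FeatureTable] = None,
    extremes: Tuple[int, int] = (0, 2),
) -> pd.DataFrame:
    """Tidy per-feature results: Spearman rho and rank-sum p, raw and suppressed.

    The suppressed table contributes only its low-frequency bands (an HF
    feature after suppression is undefined — HF is never itself suppressed).
    """
    frames: List[pd.DataFrame] = []
    for table, flag in ((raw, False), (suppressed, True)):
        if table is None:
            continue
        rho, _ = spearman_feature_correlation(table)
        p = ranksum_extremes(table, *extremes)
        rows = []
        k = 0
        for ch in table.channels:
            for band in table.bands:
                if not flag or band != "HF":
                    rows.append(
                        {
                            "participant": table.participant_id,
                            "channel": ch,
                            "band": band,
                            "suppressed": flag,
                            "rho": rho[k],
                            "p": p[k],
                        }
                    )
                k += 1
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


def prevalence_table(
    univariate_frames: Sequence[pd.DataFrame],
    threshold: float,
) -> pd.DataFrame:
    """Prevalence per (channel, band, suppressed) across participants."""
    series = []
    for df in univariate_frames:
        key = df.apply(
            lambda r: f"{r['channel']}:{r['band']}{'*' if r['suppressed'] else ''}",
            axis=1,
        )
        series.append(pd.Series(df["p"].to_numpy(float), index=pd.Index(key, name="feature")))
    prev = prevalence(series, threshold)
    out = prev.rename("prevalence").reset_index()
    return out
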