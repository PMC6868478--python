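"""HF suppression: regressing EMG-correlated activity out of EEG bands.

The 70-100 Hz band lies above the range of typical scalp EEG and is treated
as a proxy for scalp-muscle EMG. Because EMG is broadband and bleeds into
the lower bands, each low-frequency band feature (theta/alpha/beta/gamma) is
regressed on the same channel's HF feature (ordinary least squares across
trials), and the residual replaces the feature. The HF columns themselves
are never modified. Fitting uses no labels, so suppression may legitimately
be performed within any data partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Set, Tuple

import numpy as np

from .bands import HF_NAME, LOW_BAND_NAMES
from .features import FeatureTable

__all__ = ["SuppressionModel", "fit_suppression", "apply_suppression", "suppress"]


@dataclass
class SuppressionModel:
    """Per-(channel, band) slope/intercept of the HF regression.

    ``degenerate`` lists features whose HF regressor was constant across
    trials; for those the slope is 0 and the intercept is the feature mean.
    """

    coefficients: Dict[Tuple[str, str], Tuple[float, float]]
    fitted_on: str = "all"
    degenerate: Set[Tuple[str, str]] = field(default_factory=set)

    def to_json(self) -> str:
        payload = {
            "fitted_on": self.fitted_on,
            "entries": [
                {
                    "channel": ch,
                    "band": band,
                    "slope": slope,
                    "intercept": intercept,
                    "degenerate": (ch, band) in self.degenerate,
                }
                for (ch, band), (slope, intercept) in sorted(self.coefficients.items())
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SuppressionModel":
        payload = json.loads(text)
        coeffs = {}
        degenerate = set()
        for e in payload["entries"]:
            key = (e["channel"], e["band"])
            coeffs[key] = (float(e["slope"]), float(e["intercept"]))
            if e.get("degenerate"):
                degenerate.add(key)
        return cls(coefficients=coeffs, fitted_on=payload.get("fitted_on", "all"),
                   degenerate=degenerate)


def fit_suppression(features: FeatureTable, fitted_on: str = "all") -> SuppressionModel:
    """OLS fit of every low-band feature on the same channel's HF feature."""
    if features.n_trials < 3:
        raise ValueError("need at least 3 trials to fit the HF regression")
    if HF_NAME not in features.bands:
        raise ValueError("feature table has no HF band to use as regressor")
    low = [b for b in features.bands if b in LOW_BAND_NAMES]
    coeffs: Dict[Tuple[str, str], Tuple[float, float]] = {}
    degenerate: Set[Tuple[str, str]] = set()
    for ch in features.channels:
        x = features.column(ch, HF_NAME)
        xc = x - x.mean()
        sxx = float(xc @ xc)
        for band in low:
            y = features.column(ch, band)
            if sxx == 0.0:
                coeffs[(ch, band)] = (0.0, float(y.mean()))
                degenerate.add((ch, band))
                continue
            slope = float(xc @ (y - y.mean())) / sxx
            intercept = float(y.mean() - slope * x.mean())
            coeffs[(ch, band)] = (slope, intercept)
    return SuppressionModel(coefficients=coeffs, fitted_on=fitted_on, degenerate=degenerate)


def apply_suppression(features: FeatureTable, model: SuppressionModel) -> FeatureTable:
    """Subtract the fitted HF prediction from every covered low-band feature.

    HF features pass through unchanged; output shape equals input shape.
    """
    if HF_NAME not in features.bands:
        raise ValueError("feature table has no HF band")
    low = [b for b in features.bands if b in LOW_BAND_NAMES]
    values = features.values.copy()
    for ch in features.channels:
        hf = features.column(ch, HF_NAME)
        for band in low:
            if (ch, band) not in model.coefficients:
                raise ValueError(f"suppression model does not cover ({ch!r}, {band!r})")
            slope, intercept = model.coefficients[(ch, band)]
            j = features.column_index(ch, band)
            values[:, j] = values[:, j] - (intercept + slope * hf)
    return features.with_values(values)


def suppress(features: FeatureTable, fitted_on: str = "all") -> FeatureTable:
    """Fit and apply the HF regression on the same partition."""
    return apply_suppression(features, fit_suppression(features, fitted_on))
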