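"""Per-trial spectral features: Welch log-amplitudes averaged into bands.

Each 4-second trial and bipolar channel is reduced to the natural-log
spectral amplitude (square root of the Welch power estimate, 256-point FFT,
50 % overlap, Hamming window, 1 Hz resolution at 256 Hz), averaged over the
five analysis bands. The resulting trial x (channel, band) matrix is the
interchange object for all downstream statistics and classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import DEFAULT_BANDS, BandDefinition
from .preprocess import TrialSet

__all__ = [
    "LOG_AMPLITUDE_FLOOR",
    "FeatureTable",
    "welch_log_amplitude",
    "band_average",
    "extract_features",
]

#: Amplitudes are clipped here before the log so zero segments stay finite.
LOG_AMPLITUDE_FLOOR = 1e-12


@dataclass
class FeatureTable:
    """Trial x (channel, band) log-amplitude matrix with workload labels.

    Columns are channel-major then band: for each channel in ``channels``,
    one column per band in ``bands``, named ``"<channel>:<band>"``.
    """

    values: np.ndarray
    channels: Tuple[str, ...]
    bands: Tuple[str, ...]
    labels: np.ndarray
    participant_id: str = ""
    run_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.channels = tuple(self.channels)
        self.bands = tuple(self.bands)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (trial x feature) matrix")
        if self.values.shape[1] != len(self.channels) * len(self.bands):
            raise ValueError("feature count must equal channels x bands")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("label vector must match trial count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def feature_names(self) -> List[str]:
        return [f"{ch}:{b}" for ch in self.channels for b in self.bands]

    def column_index(self, channel: str, band: str) -> int:
        try:
            ci = self.channels.index(channel)
            bi = self.bands.index(band)
        except ValueError as e:
            raise KeyError(f"no feature ({channel!r}, {band!r})") from e
        return ci * len(self.bands) + bi

    def column(self, channel: str, band: str) -> np.ndarray:
        return self.values[:, self.column_index(channel, band)]

    def select(
        self,
        bands: Optional[Sequence[str]] = None,
        channels: Optional[Sequence[str]] = None,
    ) -> "FeatureTable":
        """Column subset by band and/or channel names (channel-major order)."""
        bands = tuple(bands) if bands is not None else self.bands
        channels = tuple(channels) if channels is not None else self.channels
        for b in bands:
            if b not in self.bands:
                raise KeyError(f"unknown band {b!r}")
        for c in channels:
            if c not in self.channels:
                raise KeyError(f"unknown channel {c!r}")
        cols = [self.column_index(c, b) for c in channels for b in bands]
        return FeatureTable(
            values=self.values[:, cols],
            channels=channels,
            bands=bands,
            labels=self.labels,
            participant_id=self.participant_id,
            run_ids=self.run_ids,
        )

    def subset_trials(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask)
        return FeatureTable(
            values=self.values[mask],
            channels=self.channels,
            bands=self.bands,
            labels=self.labels[mask],
            participant_id=self.participant_id,
            run_ids=None if self.run_ids is None else self.run_ids[mask],
        )

    def with_values(self, values: np.ndarray) -> "FeatureTable":
        return replace(self, values=values)

    def with_labels(self, labels: np.ndarray) -> "FeatureTable":
        return replace(self, labels=np.asarray(labels, dtype=int))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        if self.run_ids is not None:
            df.insert(0, "run_id", self.run_ids)
        df.insert(0, "participant", self.participant_id)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        meta = [c for c in ("participant", "run_id", "label") if c in df.columns]
        feat_cols = [c for c in df.columns if c not in meta]
        channels: List[str] = []
        bands: List[str] = []
        for name in feat_cols:
            ch, band = name.rsplit(":", 1)
            if ch not in channels:
                channels.append(ch)
            if band not in bands:
                bands.append(band)
        expected = [f"{c}:{b}" for c in channels for b in bands]
        if expected != feat_cols:
            raise ValueError("feature columns are not channel-major ordered")
        pid = str(df["participant"].iloc[0]) if "participant" in df else ""
        return cls(
            values=df[feat_cols].to_numpy(float),
            channels=tuple(channels),
            bands=tuple(bands),
            labels=df["label"].to_numpy(int),
            participant_id=pid,
            run_ids=df["run_id"].to_numpy(int) if "run_id" in df else None,
        )


def welch_log_amplitude(
    segment: np.ndarray,
    sampling_rate: float,
    fft_len: int = 256,
    overlap: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Welch log spectral amplitude of one (or many) trial segments.

    Works on any array whose last axis is time. Returns the one-sided
    frequency grid (``sampling_rate / fft_len`` resolution) and the natural
    log of the amplitude spectrum, ``log(sqrt(Pxx))``, with amplitudes
    floored at ``LOG_AMPLITUDE_FLOOR``. A 1024-sample trial at the defaults
    averages 7 overlapping Hamming-windowed periodograms.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.shape[-1] < fft_len:
        raise ValueError(
            f"segment length {segment.shape[-1]} shorter than fft_len {fft_len}"
        )
    noverlap = int(round(fft_len * overlap))
    freqs, pxx = sps.welch(
        segment,
        fs=sampling_rate,
        window="hamming",
        nperseg=fft_len,
        noverlap=noverlap,
        nfft=fft_len,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    amp = np.sqrt(pxx)
    return freqs, np.log(np.maximum(amp, LOG_AMPLITUDE_FLOOR))


def band_average(
    frequencies: np.ndarray,
    log_amplitudes: np.ndarray,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> np.ndarray:
    """Arithmetic mean of log-amplitude bins within each band (edges inclusive).

    ``log_amplitudes`` may have any leading shape with frequency on the last
    axis; the output replaces that axis with one entry per band.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    if np.any(np.diff(frequencies) <= 0):
        raise ValueError("frequencies must be strictly increasing")
    out = []
    for band in bands:
        mask = band.contains(frequencies)
        if not np.any(mask):
            raise ValueError(
                f"band {band.name!r} ({band.lo}-{band.hi} Hz) contains no "
                f"frequency bins at the current resolution"
            )
        out.append(np.mean(log_amplitudes[..., mask], axis=-1))
    return np.stack(out, axis=-1)


def extract_features(
    trials: TrialSet,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    fft_len: int = 256,
    overlap: float = 0.5,
    participant_id: str = "",
) -> FeatureTable:
    """Compute the trial x (channel, band) log-amplitude feature table.

    Row order preserves trial order; columns are channel-major then band.
    """
    freqs, logamp = welch_log_amplitude(trials.data, trials.sampling_rate, fft_len, overlap)
    per_band = band_average(freqs, logamp, bands)  # (trial, channel, band)
    n_trials = per_band.shape[0]
    values = per_band.reshape(n_trials, -1)
    return FeatureTable(
        values=values,
        channels=tuple(trials.channel_labels),
        bands=tuple(b.name for b in bands),
        labels=trials.labels,
        participant_id=participant_id,
        run_ids=trials.run_ids,
    )
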