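"""Continuous-EEG cleaning, re-referencing, and trial segmentation.

The preprocessing chain is: Hampel outlier filtering of each earlobe-
referenced channel (impulse artifacts from the wireless amplifier), bipolar
re-referencing over adjacent electrode pairs (suppresses common-mode and
far-field muscle activity), an optional zero-phase 5 Hz highpass (gross
movement), and segmentation into labeled 4-second ball-presentation trials
with the last trial of every run excluded.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from scipy import signal as sps

from .simulate import Marker, Recording

__all__ = [
    "DEFAULT_MONTAGE_PAIRS",
    "MontageSpec",
    "TrialSet",
    "hampel_filter",
    "to_bipolar",
    "highpass",
    "segment_trials",
]

# Gaussian-consistent scale factor: robust SD = 1.4826 * MAD.
MAD_SCALE = 1.4826

#: Adjacent bipolar pairs, right-to-left and anterior-to-posterior, over the
#: 8-electrode montage F3 Fz F4 / C3 C4 / P3 Pz P4.
DEFAULT_MONTAGE_PAIRS = (
    ("F3", "Fz"),
    ("Fz", "F4"),
    ("F3", "C3"),
    ("F4", "C4"),
    ("C3", "P3"),
    ("C4", "P4"),
    ("P3", "Pz"),
    ("Pz", "P4"),
)


@dataclass(frozen=True)
class MontageSpec:
    """An ordered list of (anode, cathode) bipolar derivations."""

    pairs: Tuple[Tuple[str, str], ...] = DEFAULT_MONTAGE_PAIRS

    def __post_init__(self) -> None:
        for a, c in self.pairs:
            if a == c:
                raise ValueError(f"bipolar pair with identical labels: {a!r}")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate bipolar pairs in montage")

    @property
    def channel_names(self) -> Tuple[str, ...]:
        return tuple(f"{a}-{c}" for a, c in self.pairs)


@dataclass
class TrialSet:
    """Segmented trials: (trial, channel, sample) data with labels."""

    data: np.ndarray
    labels: np.ndarray
    run_ids: np.ndarray
    trial_indices: np.ndarray
    sampling_rate: float
    channel_labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.run_ids = np.asarray(self.run_ids, dtype=int)
        self.trial_indices = np.asarray(self.trial_indices, dtype=int)
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.run_ids) == len(self.trial_indices) == n):
            raise ValueError("label/run/trial vectors must match trial count")
        if not np.all(np.isin(self.labels, (0, 1, 2))):
            raise ValueError("labels must be workload levels 0/1/2")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def hampel_filter(
    x: np.ndarray,
    window: float = 1.0,
    threshold: float = 5.0,
    sampling_rate: float = 256.0,
) -> np.ndarray:
    """Sliding-window median/MAD outlier replacement for a single channel.

    For each sample, the median and median absolute deviation (MAD) are
    computed over a window of ``window`` seconds centered on the sample
    (shrunk at the sequence boundaries). A sample deviating from the window
    median by more than ``threshold`` robust standard deviations
    (robust SD = 1.4826 x MAD) is replaced by that median. All statistics are
    computed on the original signal, so replacements never cascade. With
    MAD = 0 (locally constant signal) any deviating sample is replaced.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("hampel_filter expects a non-empty 1-D signal")
    bad = np.flatnonzero(~np.isfinite(x))
    if bad.size:
        raise ValueError(f"non-finite input sample at index {bad[0]}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    w = int(round(window * sampling_rate))
    if w < 3:
        raise ValueError("window x sampling_rate must span at least 3 samples")
    half = w // 2
    n = x.size
    y = x.copy()

    def _filter_at(i: int) -> None:
        lo, hi = max(0, i - half), min(n, i + half + 1)
        win = x[lo:hi]
        med = np.median(win)
        mad = np.median(np.abs(win - med))
        if abs(x[i] - med) > threshold * MAD_SCALE * mad:
            y[i] = med

    if n <= 2 * half:
        for i in range(n):
            _filter_at(i)
        return y

    wl = 2 * half + 1
    # Interior: rolling median via a C filter (padding cannot reach interior
    # centers), MAD exactly via chunked sliding windows.
    med_full = ndimage.median_filter(x, size=wl, mode="nearest")
    med_int = med_full[half : n - half]
    windows = sliding_window_view(x, wl)  # row i is centered on sample i+half
    chunk = max(1, int(4e6 // wl))
    for start in range(0, windows.shape[0], chunk):
        stop = min(start + chunk, windows.shape[0])
        med = med_int[start:stop]
        mad = np.median(np.abs(windows[start:stop] - med[:, None]), axis=1)
        centers = x[start + half : stop + half]
        flagged = np.abs(centers - med) > threshold * MAD_SCALE * mad
        idx = np.flatnonzero(flagged) + start + half
        y[idx] = med[flagged]
    for i in range(half):
        _filter_at(i)
    for i in range(n - half, n):
        _filter_at(i)
    return y


def to_bipolar(recording: Recording, montage: Optional[MontageSpec] = None) -> Recording:
    """Re-reference to bipolar channels: output i = anode_i - cathode_i.

    Channel names become ``"anode-cathode"``; the marker stream is preserved
    verbatim. A linear operation, so it commutes with scaling and addition.
    """
    if montage is None:
        montage = MontageSpec()
    index = {lab: i for i, lab in enumerate(recording.channel_labels)}
    for a, c in montage.pairs:
        for lab in (a, c):
            if lab not in index:
                raise ValueError(f"montage label {lab!r} not found in recording")
    rows = [
        recording.samples[index[a]] - recording.samples[index[c]]
        for a, c in montage.pairs
    ]
    return Recording(
        samples=np.vstack(rows),
        sampling_rate=recording.sampling_rate,
        channel_labels=montage.channel_names,
        markers=list(recording.markers),
    )


def highpass(recording: Recording, cutoff: float = 5.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth highpass; removes DC and sub-``cutoff`` drift."""
    nyq = recording.sampling_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff}")
    sos = sps.butter(order, cutoff, btype="highpass", fs=recording.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.samples, axis=-1)
    return Recording(
        samples=filtered,
        sampling_rate=recording.sampling_rate,
        channel_labels=recording.channel_labels,
        markers=list(recording.markers),
    )


def segment_trials(
    recording: Recording,
    duration: float = 4.0,
    drop_last_per_run: bool = True,
) -> TrialSet:
    """Cut the recording into per-marker trials of ``duration`` seconds.

    Windows are half-open, ``[onset, onset + duration * rate)``, aligned at
    marker onset. With ``drop_last_per_run`` (default) the final trial of
    every run is excluded, mirroring a recording-software issue that
    truncated the last trial: 12 runs x 20 markers yield 228 instead of 240
    trials.
    """
    n_samp = int(round(duration * recording.sampling_rate))
    by_run: dict = {}
    for m in recording.markers:
        by_run.setdefault(m.run_id, []).append(m)
    kept: List[Marker] = []
    for run_id in sorted(by_run):
        run_markers = sorted(by_run[run_id], key=lambda m: m.trial_index)
        if drop_last_per_run:
            run_markers = run_markers[:-1]
        kept.extend(run_markers)
    kept.sort(key=lambda m: m.onset)
    for m in kept:
        if m.onset < 0 or m.onset + n_samp > recording.n_samples:
            raise ValueError(f"trial window overruns recording for marker {m}")
    data = np.stack([recording.samples[:, m.onset : m.onset + n_samp] for m in kept])
    return TrialSet(
        data=data,
        labels=np.array([m.n_level for m in kept]),
        run_ids=np.array([m.run_id for m in kept]),
        trial_indices=np.array([m.trial_index for m in kept]),
        sampling_rate=recording.sampling_rate,
        channel_labels=recording.channel_labels,
    )
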