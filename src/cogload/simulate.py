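"""Synthetic VR n-back sessions: task sequences, EEG, and controller traces.

The generator emulates the structure of a seated/standing interactive n-back
study: 3 workload conditions (n = 0, 1, 2) x 4 runs x 20 four-second ball
trials, recorded from 8 scalp electrodes at 256 Hz. Each trial's EEG is a sum
of

* band-limited oscillatory components (theta/alpha/beta/gamma) whose
  log-amplitudes rise or fall linearly with the workload level according to
  per-(channel, band) slopes,
* a broadband 20-110 Hz EMG component whose log-amplitude co-varies with
  workload (scalp-muscle tension) plus spontaneous trial-to-trial jitter,
* 1/f background noise,
* impulse-like single-sample artifacts (wireless transmission glitches), and
* sub-5-Hz movement bursts at trial start and end (reach/place movements).

Hand-controller horizontal positions are drawn per trial around a per-level
mean offset. Everything is a deterministic function of the session seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

__all__ = [
    "CHANNEL_LABELS",
    "BALL_COLORS",
    "SessionSpec",
    "BallSequence",
    "Marker",
    "Recording",
    "ControllerTrace",
    "nback_target_flags",
    "generate_ball_sequence",
    "generate_session",
    "inject_impulses",
    "default_band_effects",
    "randomize_effects",
    "participant_seed",
]

#: Scalp electrode labels (10-20 system), anterior to posterior.
CHANNEL_LABELS = ("F3", "Fz", "F4", "C3", "C4", "P3", "Pz", "P4")

#: Ball colors used by the task.
BALL_COLORS = ("red", "blue", "purple", "green", "yellow")

# Oscillatory generation bands (Hz) and their baseline RMS amplitudes (uV) at
# workload level 0. Amplitudes follow a rough 1/f ordering with an alpha peak.
_OSC_BANDS: Dict[str, Tuple[float, float]] = {
    "theta": (5.0, 7.0),
    "alpha": (8.0, 14.0),
    "beta": (15.0, 30.0),
    "gamma": (31.0, 55.0),
}
_OSC_BASE_AMP: Dict[str, float] = {
    "theta": 4.0,
    "alpha": 5.0,
    "beta": 2.5,
    "gamma": 1.2,
}

# Broadband EMG component: band edges (Hz) and baseline RMS amplitude (uV).
# 20-110 Hz so that it bleeds into beta/gamma and dominates HF (70-100 Hz).
_EMG_BAND = (20.0, 110.0)
_EMG_BASE_AMP = 1.5


def default_band_effects() -> Dict[Tuple[str, str], float]:
    """Default per-(channel, band) log-amplitude slopes per workload level.

    Frontal theta increases and parietal alpha decreases with workload (the
    classical fronto-parietal pattern), with smaller beta/gamma increases.
    Magnitudes are dimensionless log-amplitude units per n-back level, chosen
    so that within-participant classification on clean synthetic sessions
    lands in a plausible 60-90 % accuracy range.
    """
    return {
        ("F3", "theta"): 0.05,
        ("Fz", "theta"): 0.05,
        ("F4", "theta"): 0.05,
        ("P3", "alpha"): -0.05,
        ("Pz", "alpha"): -0.05,
        ("P4", "alpha"): -0.05,
        ("F3", "beta"): 0.03,
        ("F4", "beta"): 0.03,
        ("F3", "gamma"): 0.03,
        ("Pz", "gamma"): 0.03,
        ("P4", "gamma"): 0.03,
    }


@dataclass(frozen=True)
class Marker:
    """Trial event marker: onset sample plus task bookkeeping."""

    onset: int
    run_id: int
    n_level: int
    trial_index: int


@dataclass
class Recording:
    """Continuous multichannel recording in microvolts.

    ``samples`` has shape (n_channels, n_samples); ``markers`` are sorted by
    onset and every marker's trial window fits inside the recording.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: Tuple[str, ...]
    markers: List[Marker] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def validate(self, trial_duration: Optional[float] = None) -> None:
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("channel count does not match labels")
        onsets = [m.onset for m in self.markers]
        if onsets != sorted(onsets):
            raise ValueError("markers must be sorted by onset")
        for m in self.markers:
            if m.n_level not in (0, 1, 2):
                raise ValueError(f"marker n_level {m.n_level} outside {{0,1,2}}")
            if trial_duration is not None:
                end = m.onset + int(round(trial_duration * self.sampling_rate))
                if m.onset < 0 or end > self.n_samples:
                    raise ValueError(f"marker window overruns recording: {m}")


@dataclass(frozen=True)
class BallSequence:
    """One run's ball colors with n-back target truth."""

    colors: Tuple[str, ...]
    target_flags: Tuple[bool, ...]
    n_level: int

    @property
    def n_targets(self) -> int:
        return sum(self.target_flags)


@dataclass
class ControllerTrace:
    """Per-trial signed normalized horizontal hand-controller position.

    Positive values are to the right of center.
    """

    positions: np.ndarray
    n_levels: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.n_levels = np.asarray(self.n_levels, dtype=int)
        if self.positions.shape != self.n_levels.shape:
            raise ValueError("positions and n_levels must align")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("controller positions must be finite")


@dataclass
class SessionSpec:
    """Full parameterization of one synthetic participant session.

    The defaults define the emulated study: 3 conditions x 4 runs x 20
    four-second trials at 256 Hz over 8 channels. ``seed`` fixes the session
    bit-exactly.
    """

    participant_id: str = "P00"
    sampling_rate: float = 256.0
    n_conditions: int = 3
    runs_per_condition: int = 4
    trials_per_run: int = 20
    trial_duration: float = 4.0
    channel_labels: Tuple[str, ...] = CHANNEL_LABELS
    band_effects: Dict[Tuple[str, str], float] = field(default_factory=default_band_effects)
    emg_effect: float = 0.06
    emg_spontaneous_sd: float = 0.10
    background_noise_scale: float = 2.0
    impulse_rate: float = 0.1
    impulse_amplitude: float = 200.0
    movement_burst_amplitude: float = 30.0
    controller_bias: Tuple[float, ...] = (0.25, 0.25, 0.25)
    controller_noise_sd: float = 0.25
    min_targets: int = 2
    run_gap: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.trials_per_run < 2:
            raise ValueError("trials_per_run must be >= 2")
        n = self.trial_duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_duration x sampling_rate must be an integer")
        if self.n_conditions < 1 or self.n_conditions > 3:
            raise ValueError("n_conditions must be in 1..3 (levels 0/1/2)")
        if len(self.controller_bias) < self.n_conditions:
            raise ValueError("controller_bias needs one entry per condition")
        for key, slope in self.band_effects.items():
            if not math.isfinite(slope):
                raise ValueError(f"non-finite band effect for {key}")
            ch, band = key
            if ch not in self.channel_labels:
                raise ValueError(f"band effect references unknown channel {ch!r}")
            if band not in _OSC_BANDS:
                raise ValueError(f"band effect references unknown band {band!r}")
        if not math.isfinite(self.emg_effect):
            raise ValueError("emg_effect must be finite")
        if self.impulse_rate < 0:
            raise ValueError("impulse_rate must be >= 0")

    @property
    def trial_samples(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate))

    @property
    def n_runs(self) -> int:
        return self.n_conditions * self.runs_per_condition

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run


def nback_target_flags(colors: Sequence[str], n_level: int) -> Tuple[bool, ...]:
    """Evaluate the n-back match rule over a color sequence.

    For n = 0 a ball is a target iff it is red; for n >= 1 iff it matches the
    color shown n trials earlier.
    """
    if n_level == 0:
        return tuple(c == "red" for c in colors)
    return tuple(
        i >= n_level and colors[i] == colors[i - n_level] for i in range(len(colors))
    )


def generate_ball_sequence(
    n_level: int,
    length: int = 20,
    min_targets: int = 2,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 10000,
) -> BallSequence:
    """Draw a uniform-random color sequence with at least ``min_targets`` targets.

    Sequences are resampled (rejection sampling) until the n-back rule yields
    the required number of target trials. Raises ``ValueError`` if the
    constraint is impossible for the given length and ``RuntimeError`` if the
    attempt cap is exhausted.
    """
    if n_level not in (0, 1, 2):
        raise ValueError(f"n_level must be 0, 1 or 2, got {n_level}")
    if min_targets < 0 or length < min_targets:
        raise ValueError("need length >= min_targets >= 0")
    achievable = length if n_level == 0 else max(0, length - n_level)
    if min_targets > achievable:
        raise ValueError(
            f"min_targets={min_targets} impossible for length={length}, n={n_level} "
            f"(at most {achievable} targets)"
        )
    if rng is None:
        rng = np.random.default_rng()
    for _ in range(max_attempts):
        idx = rng.integers(0, len(BALL_COLORS), size=length)
        colors = tuple(BALL_COLORS[i] for i in idx)
        flags = nback_target_flags(colors, n_level)
        if sum(flags) >= min_targets:
            return BallSequence(colors=colors, target_flags=flags, n_level=n_level)
    raise RuntimeError(
        f"rejection sampling failed after {max_attempts} attempts "
        f"(n={n_level}, length={length}, min_targets={min_targets})"
    )


def _pink_noise(rng: np.random.Generator, shape: Tuple[int, int], scale: float) -> np.ndarray:
    """1/f-amplitude background noise, per-channel std ``scale`` uV."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0)  # normalized; only the shape matters
    shape_f = np.zeros_like(f)
    nz = f > 0
    shape_f[nz] = 1.0 / np.sqrt(f[nz])
    x = np.fft.irfft(spec * shape_f, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * scale


def _band_sos(lo: float, hi: float, fs: float):
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    return sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def generate_session(
    spec: SessionSpec,
) -> Tuple[Recording, ControllerTrace, List[BallSequence]]:
    """Generate one participant's full session.

    Returns the continuous recording (with trial markers), the per-trial
    controller trace, and the per-run ball sequences. Condition blocks are
    presented in seeded-random order (a single-participant stand-in for the
    study-level counterbalancing); the ``runs_per_condition`` runs of a block
    are contiguous, separated by ``run_gap`` seconds of marker-free signal.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    trial_len = spec.trial_samples
    run_len = spec.trials_per_run * trial_len
    gap = int(round(spec.run_gap * fs))
    n_ch = len(spec.channel_labels)

    levels = list(range(spec.n_conditions))
    block_order = [int(v) for v in rng.permutation(levels)]
    run_levels: List[int] = []
    for lvl in block_order:
        run_levels.extend([lvl] * spec.runs_per_condition)

    sequences = [
        generate_ball_sequence(lvl, spec.trials_per_run, spec.min_targets, rng)
        for lvl in run_levels
    ]

    total = gap + spec.n_runs * (run_len + gap)
    markers: List[Marker] = []
    trial_onsets = np.empty(spec.n_trials, dtype=int)
    trial_levels = np.empty(spec.n_trials, dtype=int)
    k = 0
    for r, lvl in enumerate(run_levels):
        run_start = gap + r * (run_len + gap)
        for t in range(spec.trials_per_run):
            onset = run_start + t * trial_len
            markers.append(Marker(onset=onset, run_id=r, n_level=lvl, trial_index=t))
            trial_onsets[k] = onset
            trial_levels[k] = lvl
            k += 1

    x = _pink_noise(rng, (n_ch, total), spec.background_noise_scale)

    # Oscillatory components: per band, independent unit-variance band-limited
    # noise per (trial, channel), scaled by exp(log base + slope * level).
    slopes = np.zeros((len(_OSC_BANDS), n_ch))
    for bi, band in enumerate(_OSC_BANDS):
        for ci, ch in enumerate(spec.channel_labels):
            slopes[bi, ci] = spec.band_effects.get((ch, band), 0.0)
    for bi, (band, (lo, hi)) in enumerate(_OSC_BANDS.items()):
        noise = rng.standard_normal((spec.n_trials, n_ch, trial_len))
        sos = _band_sos(lo, hi, fs)
        filt = sps.sosfiltfilt(sos, noise, axis=-1)
        filt = filt / filt.std(axis=-1, keepdims=True)
        amp = np.exp(
            math.log(_OSC_BASE_AMP[band])
            + slopes[bi][None, :] * trial_levels[:, None]
        )
        filt *= amp[:, :, None]
        for ti in range(spec.n_trials):
            o = trial_onsets[ti]
            x[:, o : o + trial_len] += filt[ti]

    # Broadband EMG: shared per-trial log-amplitude jitter across channels.
    emg_noise = rng.standard_normal((spec.n_trials, n_ch, trial_len))
    sos = _band_sos(*_EMG_BAND, fs)
    emg = sps.sosfiltfilt(sos, emg_noise, axis=-1)
    emg = emg / emg.std(axis=-1, keepdims=True)
    jitter = rng.normal(0.0, spec.emg_spontaneous_sd, size=spec.n_trials)
    emg_amp = np.exp(math.log(_EMG_BASE_AMP) + spec.emg_effect * trial_levels + jitter)
    emg *= emg_amp[:, None, None]
    for ti in range(spec.n_trials):
        o = trial_onsets[ti]
        x[:, o : o + trial_len] += emg[ti]

    # Sub-5-Hz movement bursts at trial start and end (reach / place).
    burst_len = int(round(0.5 * fs))
    if spec.movement_burst_amplitude > 0 and burst_len >= 2:
        t_axis = np.arange(burst_len) / fs
        win = np.hanning(burst_len)
        for ti in range(spec.n_trials):
            o = trial_onsets[ti]
            for start in (o, o + trial_len - burst_len):
                phase = rng.uniform(0, 2 * np.pi)
                burst = (
                    spec.movement_burst_amplitude
                    * np.sin(2 * np.pi * 2.0 * t_axis + phase)
                    * win
                )
                x[:, start : start + burst_len] += burst

    rec = Recording(
        samples=x,
        sampling_rate=fs,
        channel_labels=tuple(spec.channel_labels),
        markers=markers,
    )
    rec, _ = inject_impulses(rec, spec.impulse_rate, spec.impulse_amplitude, rng)

    bias = np.asarray(spec.controller_bias, dtype=float)[trial_levels]
    positions = bias + rng.normal(0.0, spec.controller_noise_sd, size=spec.n_trials)
    trace = ControllerTrace(positions=positions, n_levels=trial_levels)

    rec.validate(trial_duration=spec.trial_duration)
    return rec, trace, sequences


def inject_impulses(
    recording: Recording,
    rate: float,
    amplitude: float,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Recording, List[int]]:
    """Add single-sample spikes at Poisson-distributed times.

    Each impulse hits every channel at the same sample (a wireless
    transmission glitch affects the whole frame) with a random sign. The
    injected sample positions are returned so artifact-filter tests can
    validate against ground truth.
    """
    if rate < 0:
        raise ValueError("impulse rate must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    samples = recording.samples.copy()
    out = Recording(
        samples=samples,
        sampling_rate=recording.sampling_rate,
        channel_labels=recording.channel_labels,
        markers=list(recording.markers),
    )
    if rate == 0:
        return out, []
    duration = recording.n_samples / recording.sampling_rate
    n = int(rng.poisson(rate * duration))
    positions = np.sort(rng.integers(0, recording.n_samples, size=n))
    signs = rng.choice([-1.0, 1.0], size=n)
    for pos, s in zip(positions, signs):
        samples[:, pos] += s * amplitude
    return out, [int(p) for p in positions]


def randomize_effects(
    effects: Dict[Tuple[str, str], float],
    rng: np.random.Generator,
    mode: str = "per-feature",
) -> Dict[Tuple[str, str], float]:
    """Randomly sign-flip effect slopes to emulate individual differences.

    ``mode="global"`` flips all slopes together with probability 1/2;
    ``mode="per-feature"`` flips each (channel, band) slope independently.
    """
    if mode == "global":
        s = -1.0 if rng.random() < 0.5 else 1.0
        return {k: s * v for k, v in effects.items()}
    if mode == "per-feature":
        return {
            k: (-v if rng.random() < 0.5 else v) for k, v in effects.items()
        }
    raise ValueError(f"unknown mode {mode!r}")


def participant_seed(base_seed: int, participant_index: int, stage: int = 0) -> int:
    """Deterministic child seed for one participant (and optional stage)."""
    ss = np.random.SeedSequence([int(base_seed), int(participant_index), int(stage)])
    return int(ss.generate_state(1)[0] % (2**31))
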