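"""End-to-end orchestration: simulate -> preprocess -> features -> analysis.

A :class:`PipelineConfig` fully determines a run; the config is serialized
verbatim into every output, so any report can be regenerated from its
embedded config alone. A single master seed fans out deterministically to
per-participant, per-stage child seeds, so individual participants can be
regenerated independently of the rest of the study.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .bands import DEFAULT_BANDS, BandDefinition
from .classify import (
    chance_level,
    crossval_classify,
    parse_comparison,
    permutation_null,
)
from .features import FeatureTable, extract_features
from .preprocess import (
    DEFAULT_MONTAGE_PAIRS,
    MontageSpec,
    TrialSet,
    hampel_filter,
    highpass,
    segment_trials,
    to_bipolar,
)
from .simulate import (
    Recording,
    SessionSpec,
    default_band_effects,
    generate_session,
    participant_seed,
    randomize_effects,
)
from .stats import bonferroni_threshold, controller_bias_r2, prevalence_table, univariate_table

__all__ = ["PipelineConfig", "run_pipeline", "process_recording", "summarize"]

log = logging.getLogger("cogload")

#: Band subsets evaluated by default: each band alone, the classic low-band
#: range theta..beta, and the cumulative theta..HF set.
DEFAULT_BAND_SETS = (
    ("theta",),
    ("alpha",),
    ("beta",),
    ("gamma",),
    ("HF",),
    ("theta", "alpha", "beta"),
    ("theta", "alpha", "beta", "gamma"),
    ("theta", "alpha", "beta", "gamma", "HF"),
)


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs.

    ``session`` holds keyword overrides forwarded to :class:`SessionSpec`
    (effect slopes, noise levels, trial counts, ...). ``heterogeneous``
    randomly sign-flips the per-(channel, band) effect template per
    participant, emulating individual differences in workload physiology.
    """

    seed: int = 0
    n_participants: int = 15
    out_dir: str = "cogload_out"
    heterogeneous: bool = True
    comparisons: Tuple[str, ...] = ("0v2", "0v1v2")
    band_sets: Tuple[Tuple[str, ...], ...] = DEFAULT_BAND_SETS
    suppression_modes: Tuple[str, ...] = ("off", "per-partition")
    folds: int = 4
    n_perm: int = 0
    hampel_enabled: bool = True
    hampel_window: float = 1.0
    hampel_threshold: float = 5.0
    highpass_enabled: bool = False
    highpass_cutoff: float = 5.0
    welch_fft_len: int = 256
    welch_overlap: float = 0.5
    drop_last_per_run: bool = True
    montage: Tuple[Tuple[str, str], ...] = DEFAULT_MONTAGE_PAIRS
    alpha: float = 0.05
    bonferroni_tests: int = 72  # 9 bands (5 raw + 4 suppressed) x 8 channels
    session: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_sets"] = [list(b) for b in self.band_sets]
        d["montage"] = [list(p) for p in self.montage]
        d["comparisons"] = list(self.comparisons)
        d["suppression_modes"] = list(self.suppression_modes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "band_sets" in d:
            d["band_sets"] = tuple(tuple(b) for b in d["band_sets"])
        if "montage" in d:
            d["montage"] = tuple(tuple(p) for p in d["montage"])
        if "comparisons" in d:
            d["comparisons"] = tuple(d["comparisons"])
        if "suppression_modes" in d:
            d["suppression_modes"] = tuple(d["suppression_modes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def build_session_spec(config: PipelineConfig, participant_index: int) -> SessionSpec:
    """SessionSpec for one participant, seeded from the master seed."""
    overrides = dict(config.session)
    effects = overrides.pop("band_effects", None)
    if effects is None:
        effects = default_band_effects()
    else:
        effects = {tuple(k.split(":")) if isinstance(k, str) else tuple(k): v
                   for k, v in effects.items()}
    seed = participant_seed(config.seed, participant_index, stage=0)
    if config.heterogeneous:
        flip_rng = np.random.default_rng(
            participant_seed(config.seed, participant_index, stage=1)
        )
        effects = randomize_effects(effects, flip_rng, mode="per-feature")
    return SessionSpec(
        participant_id=f"P{participant_index:02d}",
        band_effects=effects,
        seed=seed,
        **overrides,
    )


def process_recording(recording: Recording, config: PipelineConfig) -> TrialSet:
    """Hampel -> bipolar -> optional highpass -> segmentation."""
    rec = recording
    if config.hampel_enabled:
        cleaned = np.stack(
            [
                hampel_filter(
                    ch,
                    window=config.hampel_window,
                    threshold=config.hampel_threshold,
                    sampling_rate=rec.sampling_rate,
                )
                for ch in rec.samples
            ]
        )
        rec = Recording(cleaned, rec.sampling_rate, rec.channel_labels, rec.markers)
    rec = to_bipolar(rec, MontageSpec(config.montage))
    if config.highpass_enabled:
        rec = highpass(rec, config.highpass_cutoff)
    duration = float(config.session.get("trial_duration", 4.0))
    trials = segment_trials(rec, duration=duration,
                            drop_last_per_run=config.drop_last_per_run)
    log.info(
        "segmented %d trials (%d markers) from %.1f s recording",
        trials.n_trials, len(recording.markers), recording.duration,
    )
    return trials


def run_participant(config: PipelineConfig, participant_index: int) -> dict:
    """Simulate and analyze one participant; returns a result dict."""
    spec = build_session_spec(config, participant_index)
    recording, trace, sequences = generate_session(spec)
    trials = process_recording(recording, config)
    features = extract_features(
        trials,
        fft_len=config.welch_fft_len,
        overlap=config.welch_overlap,
        participant_id=spec.participant_id,
    )
    from .suppression import suppress

    suppressed = suppress(features) if "per-partition" in config.suppression_modes else None
    uni = univariate_table(features, suppressed)
    r2, _ = controller_bias_r2(trace)

    cls_rng = np.random.default_rng(
        participant_seed(config.seed, participant_index, stage=2)
    )
    classification = []
    for comparison in config.comparisons:
        for band_set in config.band_sets:
            for mode in config.suppression_modes:
                res = crossval_classify(
                    features,
                    comparison,
                    bands=band_set,
                    suppression=mode,
                    folds=config.folds,
                    rng=cls_rng,
                )
                entry = res.to_dict()
                if config.n_perm > 0:
                    null = permutation_null(
                        features,
                        comparison,
                        n_perm=config.n_perm,
                        rng=cls_rng,
                        bands=band_set,
                        suppression=mode,
                        folds=config.folds,
                    )
                    entry["null_quantiles"] = {
                        "q05": float(np.quantile(null, 0.05)),
                        "q50": float(np.quantile(null, 0.50)),
                        "q95": float(np.quantile(null, 0.95)),
                    }
                classification.append(entry)
    return {
        "participant": spec.participant_id,
        "n_markers": len(recording.markers),
        "n_trials": trials.n_trials,
        "controller_r2": r2,
        "min_targets": min(s.n_targets for s in sequences),
        "features": features,
        "univariate": uni,
        "classification": classification,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full simulated study and write the report tree.

    Output layout: ``participants/<id>/{features.tsv, univariate.tsv,
    classification.json}``, a study-level ``prevalence.tsv``, and
    ``report.json`` embedding the config and all per-participant summaries.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    uni_frames: List[pd.DataFrame] = []
    participants = []
    for i in range(config.n_participants):
        res = run_participant(config, i)
        pdir = out / "participants" / res["participant"]
        pdir.mkdir(parents=True, exist_ok=True)
        res["features"].to_tsv(pdir / "features.tsv")
        res["univariate"].to_csv(pdir / "univariate.tsv", sep="\t", index=False)
        (pdir / "classification.json").write_text(
            json.dumps(res["classification"], indent=2)
        )
        uni_frames.append(res["univariate"])
        participants.append(
            {k: res[k] for k in
             ("participant", "n_markers", "n_trials", "controller_r2",
              "min_targets", "classification")}
        )
        log.info("participant %s done (%d trials)", res["participant"], res["n_trials"])

    threshold = bonferroni_threshold(config.alpha, config.bonferroni_tests)
    prev = prevalence_table(uni_frames, threshold)
    prev.to_csv(out / "prevalence.tsv", sep="\t", index=False)
    report = {
        "config": config.to_dict(),
        "bonferroni_threshold": threshold,
        "participants": participants,
        "prevalence": prev.to_dict(orient="records"),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def summarize(reports: Sequence) -> pd.DataFrame:
    """Across-participant accuracy grid from one or more run reports.

    Accepts report dicts or paths to ``report.json`` files. Returns one row
    per (comparison, band set, suppression mode) with the mean and SD of the
    per-participant mean accuracies and the chance level.
    """
    loaded = []
    for r in reports:
        if isinstance(r, (str, Path)):
            loaded.append(json.loads(Path(r).read_text()))
        else:
            loaded.append(r)
    if not loaded:
        raise ValueError("need at least one report")
    rows: Dict[Tuple[str, str, str], List[float]] = {}
    chance: Dict[Tuple[str, str, str], float] = {}
    for rep in loaded:
        for part in rep["participants"]:
            for entry in part["classification"]:
                key = (
                    entry["comparison"],
                    ":".join(entry["bands"]),
                    entry["suppression"],
                )
                rows.setdefault(key, []).append(entry["mean_accuracy"])
                chance[key] = entry["chance"]
    records = [
        {
            "comparison": comp,
            "bands": bands,
            "suppression": mode,
            "n_participants": len(accs),
            "mean_accuracy": float(np.mean(accs)),
            "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            "chance": chance[(comp, bands, mode)],
        }
        for (comp, bands, mode), accs in sorted(rows.items())
    ]
    return pd.DataFrame(records)
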