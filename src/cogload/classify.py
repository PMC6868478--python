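"""Regularized LDA classification of workload levels.

The classifier is linear discriminant analysis with a shrunk pooled
covariance, Sigma(gamma) = (1 - gamma) * Sigma + gamma * diag(Sigma): the
off-diagonal entries are attenuated toward zero while per-feature variances
are kept. gamma = 0 recovers classical LDA, gamma = 1 a naive
diagonal-covariance discriminant. The shrinkage level is chosen on the
training partition only, by inner cross-validation over a fixed grid with
ties broken toward smaller gamma.

Evaluation follows the study protocol: stratified 4-fold cross-validation
within participant (228 trials divide evenly into 4 folds), HF suppression
applied fold-wise, permutation tests for chance calibration, and a
leave-one-participant-out transfer protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import linalg as sla

from .features import FeatureTable
from .suppression import apply_suppression, fit_suppression

__all__ = [
    "DEFAULT_SHRINKAGE_GRID",
    "RldaModel",
    "ClassificationResult",
    "rlda_fit",
    "rlda_scores",
    "rlda_predict",
    "optimize_shrinkage",
    "crossval_classify",
    "permutation_null",
    "transfer_learning",
    "chance_level",
    "majority_class_rate",
    "parse_comparison",
]

#: gamma in {0, 0.05, ..., 1.0}; ascending so argmax tie-breaks to smaller.
DEFAULT_SHRINKAGE_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))

SUPPRESSION_MODES = ("off", "per-partition", "fit-on-train")


@dataclass
class RldaModel:
    """Fitted regularized linear discriminant.

    ``coef`` (features x classes) and ``intercept`` (classes,) give linear
    scores; prediction is the argmax class.
    """

    classes: np.ndarray
    means: np.ndarray
    priors: np.ndarray
    shrinkage: float
    coef: np.ndarray
    intercept: np.ndarray


@dataclass
class ClassificationResult:
    """Cross-validated accuracy for one comparison and feature subset."""

    comparison: str
    bands: Tuple[str, ...]
    channels: Tuple[str, ...]
    suppression: str
    fold_accuracies: List[float]
    mean_accuracy: float
    chance: float
    shrinkages: List[float]

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "bands": list(self.bands),
            "channels": list(self.channels),
            "suppression": self.suppression,
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "chance": self.chance,
            "shrinkages": self.shrinkages,
        }


def parse_comparison(comparison: Union[str, Sequence[int]]) -> Tuple[int, ...]:
    """``"0v2"`` -> (0, 2); sequences pass through."""
    if isinstance(comparison, str):
        return tuple(int(tok) for tok in comparison.split("v"))
    return tuple(int(c) for c in comparison)


def _class_stats(X: np.ndarray, y: np.ndarray):
    classes = np.unique(y)
    n, p = X.shape
    k = len(classes)
    means = np.empty((k, p))
    priors = np.empty(k)
    scatter = np.zeros((p, p))
    for i, c in enumerate(classes):
        Xi = X[y == c]
        means[i] = Xi.mean(axis=0)
        priors[i] = Xi.shape[0] / n
        d = Xi - means[i]
        scatter += d.T @ d
    cov = scatter / max(n - k, 1)
    return classes, means, priors, cov


def _discriminant(means, priors, cov, gamma):
    """Linear scores from pooled stats; raises LinAlgError if singular."""
    reg = (1.0 - gamma) * cov + gamma * np.diag(np.diag(cov))
    coef = sla.solve(reg, means.T, assume_a="pos")  # (features, classes)
    intercept = -0.5 * np.einsum("kf,fk->k", means, coef) + np.log(priors)
    if not (np.all(np.isfinite(coef)) and np.all(np.isfinite(intercept))):
        raise sla.LinAlgError("non-finite discriminant coefficients")
    return coef, intercept


def rlda_fit(X: np.ndarray, y: np.ndarray, shrinkage: float = 0.0) -> RldaModel:
    """Fit the shrunk-covariance linear discriminant.

    Requires at least two classes with two trials each and finite features.
    With ``shrinkage = 0`` a singular pooled covariance is an error (the
    message suggests gamma > 0).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if np.any(counts < 2):
        raise ValueError("every class needs at least two trials")
    classes, means, priors, cov = _class_stats(X, y)
    try:
        coef, intercept = _discriminant(means, priors, cov, shrinkage)
    except (sla.LinAlgError, ValueError) as e:
        if shrinkage == 0.0:
            raise ValueError(
                "pooled covariance is singular at shrinkage 0; use shrinkage > 0"
            ) from e
        raise
    return RldaModel(
        classes=classes,
        means=means,
        priors=priors,
        shrinkage=shrinkage,
        coef=coef,
        intercept=intercept,
    )


def rlda_scores(model: RldaModel, X: np.ndarray) -> np.ndarray:
    """Per-class discriminant scores delta_k(x)."""
    return np.asarray(X, dtype=float) @ model.coef + model.intercept


def rlda_predict(model: RldaModel, X: np.ndarray) -> np.ndarray:
    return model.classes[np.argmax(rlda_scores(model, X), axis=1)]


def _stratified_folds(
    y: np.ndarray,
    n_folds: int,
    rng: np.random.Generator,
    trim: bool = False,
) -> List[np.ndarray]:
    """Seeded stratified fold index lists; optionally trim per-class remainders."""
    per_fold: List[List[int]] = [[] for _ in range(n_folds)]
    trimmed = 0
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(len(idx))]
        if trim and len(idx) % n_folds:
            trimmed += len(idx) % n_folds
            idx = idx[: len(idx) - (len(idx) % n_folds)]
        for f, part in enumerate(np.array_split(idx, n_folds)):
            per_fold[f].extend(part.tolist())
    if trimmed:
        warnings.warn(
            f"trial count not divisible by {n_folds} folds; "
            f"trimmed {trimmed} trials (per-class remainders)"
        )
    return [np.sort(np.array(f, dtype=int)) for f in per_fold]


def optimize_shrinkage(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[float] = DEFAULT_SHRINKAGE_GRID,
    inner_folds: int = 4,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Pick gamma maximizing inner-CV accuracy on the training partition.

    The grid is scanned in ascending order and ties go to the smallest
    gamma. Grid values whose fit fails (singular covariance at gamma = 0)
    score minus infinity. If no value yields a valid fit, gamma = 1 is
    returned with a warning.
    """
    if len(grid) == 0:
        raise ValueError("shrinkage grid must be non-empty")
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = _stratified_folds(y, inner_folds, rng)
    grid = sorted(float(g) for g in grid)
    scores = np.zeros(len(grid))
    valid = np.ones(len(grid), dtype=bool)
    for fold_idx in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[fold_idx] = False
        Xtr, ytr = X[mask], y[mask]
        Xva, yva = X[fold_idx], y[fold_idx]
        if len(np.unique(ytr)) < 2 or len(yva) == 0:
            continue
        classes, means, priors, cov = _class_stats(Xtr, ytr)
        for gi, g in enumerate(grid):
            if not valid[gi]:
                continue
            try:
                coef, intercept = _discriminant(means, priors, cov, g)
            except (sla.LinAlgError, ValueError):
                valid[gi] = False
                continue
            pred = classes[np.argmax(Xva @ coef + intercept, axis=1)]
            scores[gi] += float(np.mean(pred == yva))
    scores[~valid] = -np.inf
    if not np.any(valid):
        warnings.warn("no shrinkage value produced a valid fit; falling back to 1.0")
        return 1.0
    return grid[int(np.argmax(scores))]


def _fold_suppress(
    train: FeatureTable, test: FeatureTable, mode: str
) -> Tuple[FeatureTable, FeatureTable]:
    if mode == "off":
        return train, test
    if mode == "per-partition":
        return (
            apply_suppression(train, fit_suppression(train, "train")),
            apply_suppression(test, fit_suppression(test, "test")),
        )
    if mode == "fit-on-train":
        model = fit_suppression(train, "train")
        return apply_suppression(train, model), apply_suppression(test, model)
    raise ValueError(f"unknown suppression mode {mode!r}; choose from {SUPPRESSION_MODES}")


def crossval_classify(
    features: FeatureTable,
    comparison: Union[str, Sequence[int]] = "0v1v2",
    bands: Optional[Sequence[str]] = None,
    channels: Optional[Sequence[str]] = None,
    suppression: str = "off",
    folds: int = 4,
    rng: Optional[np.random.Generator] = None,
    grid: Sequence[float] = DEFAULT_SHRINKAGE_GRID,
    shrinkage: Optional[float] = None,
) -> ClassificationResult:
    """Stratified k-fold rLDA accuracy for one comparison and feature subset.

    Per fold: HF suppression is applied in the configured mode (fit on the
    partitions independently by default — fitting uses no labels), the
    feature subset is selected, shrinkage is optimized on the training
    partition (unless fixed via ``shrinkage``), and accuracy is measured on
    the held-out fold.
    """
    if rng is None:
        rng = np.random.default_rng()
    classes = parse_comparison(comparison)
    present = set(np.unique(features.labels).tolist())
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"requested classes absent from data: {missing}")
    sub = features.subset_trials(np.isin(features.labels, classes))
    fold_idx = _stratified_folds(sub.labels, folds, rng, trim=True)
    kept = np.concatenate(fold_idx)
    accs: List[float] = []
    gammas: List[float] = []
    for f in range(folds):
        test_ids = fold_idx[f]
        train_ids = np.setdiff1d(kept, test_ids)
        train_t = sub.subset_trials(train_ids)
        test_t = sub.subset_trials(test_ids)
        train_t, test_t = _fold_suppress(train_t, test_t, suppression)
        Xtr = train_t.select(bands, channels).values
        Xte = test_t.select(bands, channels).values
        ytr, yte = train_t.labels, test_t.labels
        g = shrinkage if shrinkage is not None else optimize_shrinkage(
            Xtr, ytr, grid=grid, inner_folds=folds, rng=rng
        )
        model = rlda_fit(Xtr, ytr, shrinkage=g)
        accs.append(float(np.mean(rlda_predict(model, Xte) == yte)))
        gammas.append(float(g))
    comp_str = comparison if isinstance(comparison, str) else "v".join(map(str, classes))
    return ClassificationResult(
        comparison=comp_str,
        bands=tuple(bands) if bands is not None else features.bands,
        channels=tuple(channels) if channels is not None else features.channels,
        suppression=suppression,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        chance=1.0 / len(classes),
        shrinkages=gammas,
    )


def permutation_null(
    features: FeatureTable,
    comparison: Union[str, Sequence[int]] = "0v1v2",
    n_perm: int = 100,
    rng: Optional[np.random.Generator] = None,
    **cv_kwargs,
) -> np.ndarray:
    """Null distribution of mean CV accuracy under label permutation.

    Each replicate uniformly shuffles the label vector and reruns the full
    cross-validated procedure (fold-wise suppression and shrinkage
    optimization included). Returns the replicate mean accuracies.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    out = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(features.n_trials)
        shuffled = features.with_labels(features.labels[perm])
        res = crossval_classify(shuffled, comparison, rng=rng, **cv_kwargs)
        out[i] = res.mean_accuracy
    return out


def transfer_learning(
    participants: Sequence[FeatureTable],
    comparison: Union[str, Sequence[int]] = "0v1v2",
    bands: Optional[Sequence[str]] = None,
    channels: Optional[Sequence[str]] = None,
    suppression: str = "per-partition",
    grid: Sequence[float] = DEFAULT_SHRINKAGE_GRID,
    rng: Optional[np.random.Generator] = None,
    shrinkage: Optional[float] = None,
) -> Dict[str, float]:
    """Leave-one-participant-out accuracy.

    For each participant, one rLDA (shrinkage optimized on the pooled
    training trials) is trained on all other participants and tested on the
    held-out one. With per-partition suppression the HF regression is fitted
    within each participant (it uses no labels); ``fit-on-train`` fits a
    single model on the pooled training participants instead.
    """
    if len(participants) < 2:
        raise ValueError("transfer learning needs at least two participants")
    names = participants[0].feature_names
    for t in participants[1:]:
        if t.feature_names != names:
            raise ValueError("participants have inconsistent feature sets")
    if rng is None:
        rng = np.random.default_rng()
    classes = parse_comparison(comparison)

    subs = [t.subset_trials(np.isin(t.labels, classes)) for t in participants]
    results: Dict[str, float] = {}
    for i, held in enumerate(subs):
        train_tables = [t for j, t in enumerate(subs) if j != i]
        if suppression == "per-partition":
            train_tables = [
                apply_suppression(t, fit_suppression(t, t.participant_id))
                for t in train_tables
            ]
            held_t = apply_suppression(held, fit_suppression(held, held.participant_id))
        elif suppression == "fit-on-train":
            pooled = FeatureTable(
                values=np.vstack([t.values for t in train_tables]),
                channels=held.channels,
                bands=held.bands,
                labels=np.concatenate([t.labels for t in train_tables]),
            )
            model = fit_suppression(pooled, "pooled-train")
            train_tables = [apply_suppression(t, model) for t in train_tables]
            held_t = apply_suppression(held, model)
        elif suppression == "off":
            held_t = held
        else:
            raise ValueError(f"unknown suppression mode {suppression!r}")
        Xtr = np.vstack([t.select(bands, channels).values for t in train_tables])
        ytr = np.concatenate([t.labels for t in train_tables])
        Xte = held_t.select(bands, channels).values
        yte = held_t.labels
        g = shrinkage if shrinkage is not None else optimize_shrinkage(
            Xtr, ytr, grid=grid, rng=rng
        )
        model = rlda_fit(Xtr, ytr, shrinkage=g)
        key = held.participant_id or f"participant_{i}"
        results[key] = float(np.mean(rlda_predict(model, Xte) == yte))
    return results


def chance_level(labels: Sequence[int]) -> float:
    """1 / number of distinct classes (balanced-design chance)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    return 1.0 / len(np.unique(labels))


def majority_class_rate(labels: Sequence[int]) -> float:
    """Empirical majority-class rate (chance under class imbalance)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    _, counts = np.unique(labels, return_counts=True)
    return float(counts.max() / labels.size)
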