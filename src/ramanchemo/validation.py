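"""Leave-one-out validation of DAPC models and classification metrics.

For each spectrum in turn, PCA *and* DAPC are refit from scratch on the
remaining spectra (same retained-PC count) and the held-out spectrum is
projected and classified — so the held-out scan never contributes to
centering, the PC basis, or the discriminant axes.  Predictions are
tallied into a confusion matrix from which overall accuracy and
one-vs-rest sensitivity (true-positive %) and specificity
(true-negative %) per class are computed, alongside the analytic
uniform-random-classifier baselines (``100/C`` % sensitivity and
``100·(1 − 1/C)`` % specificity for ``C`` classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemometrics import classify, fit_dapc, fit_pca
from .errors import FoldError, InputError, ParameterError, UndefinedMetricError
from .spectra import SpectraSet


@dataclass
class ConfusionMatrix:
    """Square count matrix: rows = true class, columns = predicted."""

    counts: np.ndarray
    classes: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        C = len(self.classes)
        if self.counts.shape != (C, C):
            raise InputError("confusion matrix must be square over the classes")
        if (self.counts < 0).any():
            raise InputError("confusion matrix entries must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * float(np.trace(self.counts)) / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics (in percent) for a designated positive class."""

    positive: object
    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float


@dataclass(frozen=True)
class RandomChanceBaseline:
    """Expected metrics of a uniform random classifier over C classes."""

    n_classes: int
    sensitivity_pct: float
    specificity_pct: float


def random_chance(n_classes: int) -> RandomChanceBaseline:
    """Analytic chance baselines: ``100/C`` sensitivity, ``100(1−1/C)``
    specificity."""
    if n_classes < 2:
        raise ParameterError("random chance needs at least 2 classes")
    return RandomChanceBaseline(
        n_classes=int(n_classes),
        sensitivity_pct=100.0 / n_classes,
        specificity_pct=100.0 * (1.0 - 1.0 / n_classes),
    )


def confusion_from_predictions(true_labels, pred_labels, classes=None) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.size != pred_labels.size:
        raise InputError("prediction/truth length mismatch")
    if classes is None:
        classes = sorted(set(true_labels.tolist()) | set(pred_labels.tolist()))
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=list(classes))


def metrics_from_confusion(cm: ConfusionMatrix, positive) -> ClassMetrics:
    """Sensitivity/specificity for ``positive`` (one-vs-rest) plus accuracy."""
    if positive not in cm.classes:
        raise InputError(f"{positive!r} is not a class of this matrix")
    i = cm.classes.index(positive)
    tp = cm.counts[i, i]
    fn = cm.counts[i].sum() - tp
    fp = cm.counts[:, i].sum() - tp
    tn = cm.total - tp - fn - fp
    if tp + fn == 0:
        raise UndefinedMetricError(f"class {positive!r} has no true members")
    return ClassMetrics(
        positive=positive,
        sensitivity_pct=100.0 * tp / (tp + fn),
        specificity_pct=100.0 * tn / (tn + fp),
        accuracy_pct=cm.accuracy_pct,
    )


def all_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class metrics table with the analytic chance baselines."""
    chance = random_chance(len(cm.classes))
    rows = []
    for c in cm.classes:
        m = metrics_from_confusion(cm, c)
        rows.append(
            {
                "class": c,
                "sensitivity_pct": m.sensitivity_pct,
                "specificity_pct": m.specificity_pct,
                "accuracy_pct": m.accuracy_pct,
                "chance_sensitivity_pct": chance.sensitivity_pct,
                "chance_specificity_pct": chance.specificity_pct,
            }
        )
    return pd.DataFrame(rows)


def loo_dapc(X: SpectraSet, n_pcs: int, labels=None) -> ConfusionMatrix:
    """Leave-one-out validation with full per-fold refit of PCA + DAPC.

    Every class must have ≥ 3 members so each training fold retains ≥ 2.
    """
    labels = np.asarray(labels if labels is not None else X.labels)
    if labels.size != len(X):
        raise InputError("one label per spectrum required")
    classes = sorted(set(labels.tolist()))
    for c in classes:
        if np.sum(labels == c) < 3:
            raise FoldError(
                f"class {c!r} has fewer than 3 members; a fold would leave < 2"
            )
    n = len(X)
    preds = []
    for i in range(n):
        mask = np.arange(n) != i
        pca_i = fit_pca(X.select(mask))
        dapc_i = fit_dapc(pca_i, labels[mask], n_pcs=min(n_pcs, _rank_cap(pca_i)))
        s = pca_i.transform(X.intensities[i])
        label, _ = classify(dapc_i, s)
        preds.append(label)
    return confusion_from_predictions(labels, preds, classes=classes)


def _rank_cap(pca) -> int:
    var = pca.scores.var(axis=0, ddof=1)
    return int(np.sum(var > 1e-12 * max(float(var.max()), 1.0)))


def monte_carlo_random_classifier(
    n_classes: int,
    n_draws: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Empirical chance metrics: uniform predictions on balanced truths.

    Returns mean per-class sensitivity/specificity (percent) plus their
    binomial Monte-Carlo standard deviations.
    """
    if n_classes < 2:
        raise ParameterError("need at least 2 classes")
    rng = rng if rng is not None else np.random.default_rng()
    per_class = n_draws // n_classes
    truths = np.repeat(np.arange(n_classes), per_class)
    preds = rng.integers(0, n_classes, size=truths.size)
    cm = confusion_from_predictions(truths, preds, classes=list(range(n_classes)))
    sens = np.mean([metrics_from_confusion(cm, c).sensitivity_pct for c in cm.classes])
    spec = np.mean([metrics_from_confusion(cm, c).specificity_pct for c in cm.classes])
    p = 1.0 / n_classes
    n_neg = truths.size - per_class
    return {
        "sensitivity_pct": float(sens),
        "specificity_pct": float(spec),
        # SD of a mean of C per-class binomial proportions
        "sd_sensitivity_pct": 100.0 * np.sqrt(p * (1 - p) / per_class / n_classes),
        "sd_specificity_pct": 100.0 * np.sqrt(p * (1 - p) / n_neg / n_classes),
    }


def permutation_baseline(
    X: SpectraSet,
    n_pcs: int,
    n_shuffles: int = 200,
    rng: np.random.Generator | None = None,
) -> dict:
    """Label-permutation control for the leave-one-out analysis.

    The per-fold PCA does not depend on labels, so the fold bases and
    held-out projections are computed once and only the DAPC refit and
    classification are repeated for each shuffled label vector.  Returns
    the mean per-class LOO sensitivity over shuffles, its Monte-Carlo
    standard error, and the per-shuffle values.
    """
    rng = rng if rng is not None else np.random.default_rng()
    labels = X.labels
    n = len(X)
    folds = []
    for i in range(n):
        mask = np.arange(n) != i
        pca_i = fit_pca(X.select(mask))
        folds.append((mask, pca_i, pca_i.transform(X.intensities[i])))

    means = []
    for _ in range(n_shuffles):
        perm = rng.permutation(labels)
        classes = sorted(set(perm.tolist()))
        preds = []
        ok = all(np.sum(perm == c) >= 3 for c in classes)
        if not ok:  # permutation preserves class sizes, so this cannot trip
            continue
        for (mask, pca_i, s) in folds:
            dapc_i = fit_dapc(pca_i, perm[mask], n_pcs=min(n_pcs, _rank_cap(pca_i)))
            label, _ = classify(dapc_i, s)
            preds.append(label)
        cm = confusion_from_predictions(perm, preds, classes=classes)
        sens = [metrics_from_confusion(cm, c).sensitivity_pct for c in cm.classes]
        means.append(float(np.mean(sens)))
    means = np.asarray(means)
    return {
        "mean_sensitivity_pct": float(means.mean()),
        "se_pct": float(means.std(ddof=1) / np.sqrt(means.size)),
        "per_shuffle_pct": means,
    }
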