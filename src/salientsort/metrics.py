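"""Evaluation metrics and validation classifiers.

Per-class classification accuracy (CA) is the recall of the class;
``Chance`` is the class's empirical relative frequency in the test set (the
expected recall of proportional random guessing), and the chance-level-
independent accuracy

    CA_CLI = (CA - Chance) / (1 - Chance)

rescales CA so that 0 means "no better than guessing" and 1 means perfect,
regardless of class balance.  A Gaussian naive Bayes classifier serves as
the validation classifier for feature-set comparisons, alongside simplified
reconstructions of the static geometric feature sets used by earlier
on-implant sorters (SDE, FSDE, DDsE, ZCF).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as _scipy_stats

from .datatypes import SpikeMatrix
from .errors import EstimationError, ParameterError


@dataclass
class EvalReport:
    """Per-class and aggregate accuracy of one evaluated channel."""

    per_class: dict[str, dict]
    overall_ca: float            # weighted by class test counts
    overall_ca_class_mean: float  # unweighted mean over classes
    overall_ca_cli: float        # mean of per-class CA_CLI

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "overall_ca": self.overall_ca,
            "overall_ca_class_mean": self.overall_ca_class_mean,
            "overall_ca_cli": self.overall_ca_cli,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r: float
    n: int


def chance_level(test_labels: np.ndarray) -> dict[str, float]:
    """Empirical relative frequency of each class in the test set."""
    labels = np.asarray(test_labels, dtype=str)
    if labels.size == 0:
        raise ParameterError("test labels must be nonempty")
    uniq, counts = np.unique(labels, return_counts=True)
    return {lab: float(c) / labels.size for lab, c in zip(uniq, counts)}


def ca_cli(ca: float, chance: float) -> float:
    """Chance-level-independent accuracy (CA - Chance) / (1 - Chance)."""
    if chance >= 1.0:
        raise ParameterError("chance level must be < 1")
    return (ca - chance) / (1.0 - chance)


def classification_accuracy(
    true_labels: np.ndarray, predicted_labels: np.ndarray
) -> EvalReport:
    """Per-class recall, chance, and CA_CLI, plus channel aggregates.

    ``UNCLASSIFIED`` predictions count as errors.  ``overall_ca`` weights
    classes by their test counts (equals total correct / total spikes);
    ``overall_ca_class_mean`` is the unweighted class mean.
    """
    true = np.asarray(true_labels, dtype=str)
    pred = np.asarray(predicted_labels, dtype=str)
    if true.shape != pred.shape:
        raise ParameterError("true and predicted label vectors differ in length")
    if true.size == 0:
        raise ParameterError("empty label vectors")
    chances = chance_level(true)
    per_class: dict[str, dict] = {}
    for lab in sorted(chances):
        mask = true == lab
        ca = float((pred[mask] == lab).mean())
        ch = chances[lab]
        per_class[lab] = {
            "ca": ca,
            "chance": ch,
            "ca_cli": ca_cli(ca, ch),
            "n_test": int(mask.sum()),
        }
    total = sum(v["n_test"] for v in per_class.values())
    overall = sum(v["ca"] * v["n_test"] for v in per_class.values()) / total
    class_mean = float(np.mean([v["ca"] for v in per_class.values()]))
    cli_mean = float(np.mean([v["ca_cli"] for v in per_class.values()]))
    return EvalReport(
        per_class=per_class,
        overall_ca=float(overall),
        overall_ca_class_mean=class_mean,
        overall_ca_cli=cli_mean,
    )


def bayes_classify(
    train: SpikeMatrix,
    test: SpikeMatrix,
    feature_indices: list[int] | None = None,
) -> np.ndarray:
    """Gaussian naive Bayes prediction over the given feature subset.

    Class-conditional per-feature Gaussian likelihoods with a variance
    floor of 1e-9 times the mean feature variance (quantized integer data
    can have zero within-class variance); priors are training frequencies;
    ties resolve to the smallest label.
    """
    if not train.is_labeled:
        raise EstimationError("training matrix must be labeled")
    labels = train.class_labels()
    Xtr = train.waveforms.astype(float)
    Xte = np.atleast_2d(test.waveforms.astype(float))
    if feature_indices is not None:
        Xtr = Xtr[:, feature_indices]
        Xte = Xte[:, feature_indices]
    floor = 1e-9 * max(float(Xtr.var(axis=0).mean()), np.finfo(float).tiny)
    log_post = np.zeros((Xte.shape[0], len(labels)))
    for c, lab in enumerate(labels):
        rows = Xtr[train.labels == lab]
        if rows.shape[0] < 2:
            raise EstimationError(f"class {lab!r} needs at least 2 training spikes")
        mu = rows.mean(axis=0)
        var = np.maximum(rows.var(axis=0, ddof=1), floor)
        prior = rows.shape[0] / Xtr.shape[0]
        ll = -0.5 * (np.log(2 * np.pi * var) + (Xte - mu) ** 2 / var).sum(axis=1)
        log_post[:, c] = np.log(prior) + ll
    # argmax returns the first (smallest) label on exact ties
    return np.asarray([labels[c] for c in np.argmax(log_post, axis=1)], dtype=str)


STATIC_METHODS = ("SDE", "FSDE", "DDsE", "ZCF")


def static_features(matrix: SpikeMatrix, method: str) -> np.ndarray:
    """Simplified reconstructions of static geometric feature sets.

    * ``SDE``  — spike peak-to-peak and the extrema of the first derivative;
    * ``FSDE`` — extrema of the first and second derivatives;
    * ``DDsE`` — extrema of discrete differences at lags 1, 3 and 7;
    * ``ZCF``  — indices of the first two zero crossings after the trough
      plus the trough amplitude.

    These follow the one-line descriptions of the originals, not the cited
    hardware implementations.
    """
    X = matrix.waveforms.astype(float)
    if X.shape[1] < 4:
        raise ParameterError("waveforms must have at least 4 samples")
    if method == "SDE":
        d1 = np.diff(X, axis=1)
        return np.column_stack([X.max(1) - X.min(1), d1.max(1), d1.min(1)])
    if method == "FSDE":
        d1 = np.diff(X, axis=1)
        d2 = np.diff(d1, axis=1)
        return np.column_stack([d1.max(1), d1.min(1), d2.max(1), d2.min(1)])
    if method == "DDsE":
        cols = []
        for lag in (1, 3, 7):
            dd = X[:, lag:] - X[:, :-lag]
            cols += [dd.max(1), dd.min(1)]
        return np.column_stack(cols)
    if method == "ZCF":
        trough_idx = X.argmin(axis=1)
        trough_amp = X.min(axis=1)
        zc1 = np.zeros(X.shape[0])
        zc2 = np.zeros(X.shape[0])
        for n in range(X.shape[0]):
            after = X[n, trough_idx[n]:]
            crossings = np.flatnonzero((after[:-1] < 0) & (after[1:] >= 0))
            if crossings.size > 0:
                zc1[n] = trough_idx[n] + crossings[0] + 1
            if crossings.size > 1:
                zc2[n] = trough_idx[n] + crossings[1] + 1
        return np.column_stack([zc1, zc2, trough_amp])
    raise ParameterError(f"unknown static feature method {method!r}; "
                         f"choose from {STATIC_METHODS}")


def ca_ca_regression(pairs: list[tuple[float, float]]) -> RegressionSummary:
    """OLS of method CA on reference CA (the CA-CA diagnostic)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ParameterError("need at least 2 (reference, method) CA pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.all(x == x[0]):
        raise ParameterError("reference CA values are all equal; slope undefined")
    res = _scipy_stats.linregress(x, y)
    return RegressionSummary(slope=float(res.slope), intercept=float(res.intercept),
                             r=float(res.rvalue), n=len(x))


def saliency_ca_correlation(log_saliencies: np.ndarray,
                            ca_cli_values: np.ndarray) -> float:
    """Pearson r between per-class log saliency and achieved CA_CLI."""
    x = np.asarray(log_saliencies, dtype=float)
    y = np.asarray(ca_cli_values, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ParameterError("need >= 3 matched (log-saliency, CA_CLI) pairs")
    if x.std() == 0 or y.std() == 0:
        raise ParameterError("zero variance in correlation input")
    return float(np.corrcoef(x, y)[0, 1])
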