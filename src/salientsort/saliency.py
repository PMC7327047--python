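"""Salient feature selection (SFS).

The central statistic is the exponential class discrimination index between
classes *i* and *j* on feature *k*,

    d_ij[k] = exp( |mu_i[k] - mu_j[k]| / sqrt(P_i sigma_i[k]^2 + P_j sigma_j[k]^2) ),

a prior-weighted standardized mean difference mapped through exp so that
d >= 1 always.  The saliency of class *i* on feature *k* combines the
weighted geometric mean of its discrimination indices against every other
class with a homogeneity factor (geometric over arithmetic mean), rewarding
features on which the class is both far from and *evenly* separated from all
other classes:

    sigma_i[k] = ( prod_{j != i} d_ij[k]^{P_j} )^2  /  sum_{j != i} P_j d_ij[k].

Two weightings of the saliency are provided.  With the other-class priors
renormalized to sum to 1 (``normalize_weights=True``), the saliency equals
exactly G x H — the weighted geometric mean of the discrimination indices
times the homogeneity (geometric over arithmetic mean) — which is the
product form that motivates the statistic.  The unnormalized ("literal")
weighting above is also available; note that it degenerates to the constant
2 for two classes with balanced priors (the exponent 2 P_j - 1 vanishes),
so feature *selection* always uses the normalized G x H form.

Features are selected greedily: the first pick maximizes saliency; each
subsequent pick maximizes saliency discounted by (1 - rho) against every
feature already selected, where rho is the absolute class-conditional
Pearson correlation — so later features add non-redundant information.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datatypes import SpikeMatrix
from .errors import EstimationError, ParameterError

#: Exponent clip used when a between-class mean gap has zero pooled variance:
#: e^30 ~ 1.07e13 dominates any finite competitor without double overflow.
E_MAX = 30.0


class DegenerateVarianceWarning(UserWarning):
    """Raised when d_ij is computed with zero pooled variance and a nonzero gap."""


@dataclass(frozen=True)
class ClassStatistics:
    """Per-feature first and second moments of one spike class."""

    label: str
    mean: np.ndarray   # length K
    std: np.ndarray    # length K, ddof=1
    prior: float
    count: int


@dataclass
class SaliencyProfile:
    """Per-feature discrimination structure of one class against all others.

    ``discrimination`` is (N_c - 1) x K (rows follow ``other_labels``);
    ``geo_mean`` and ``homogeneity`` are the weighted-geometric-mean /
    AM-GM-ratio decomposition of the saliency vector.
    """

    class_label: str
    other_labels: list[str]
    discrimination: np.ndarray
    geo_mean: np.ndarray
    homogeneity: np.ndarray
    saliency: np.ndarray


@dataclass
class SalientFeatureSet:
    """Ordered salient feature indices for one class.

    ``saliencies`` holds the greedy criterion value at each selection step;
    ``correlations`` is the L x L matrix of absolute within-class Pearson
    correlations among the selected features.
    """

    class_label: str
    indices: list[int]
    saliencies: list[float]
    correlations: np.ndarray
    K: int

    def to_dict(self) -> dict:
        return {
            "class": self.class_label,
            "indices": list(map(int, self.indices)),
            "saliencies": list(map(float, self.saliencies)),
            "correlations": np.asarray(self.correlations).tolist(),
            "K": int(self.K),
            "L": len(self.indices),
        }


def estimate_class_stats(matrix: SpikeMatrix) -> list[ClassStatistics]:
    """Per-class, per-feature sample mean/std (ddof=1) and empirical prior."""
    if not matrix.is_labeled:
        raise EstimationError("matrix must be labeled")
    labels = matrix.class_labels()
    if len(labels) < 2:
        raise EstimationError("at least two distinct classes are required")
    N = matrix.n_spikes
    out = []
    W = matrix.waveforms.astype(float)
    for lab in labels:
        rows = W[matrix.labels == lab]
        if rows.shape[0] < 2:
            raise EstimationError(
                f"class {lab!r} has {rows.shape[0]} spikes; need at least 2"
            )
        out.append(ClassStatistics(
            label=lab,
            mean=rows.mean(axis=0),
            std=rows.std(axis=0, ddof=1),
            prior=rows.shape[0] / N,
            count=rows.shape[0],
        ))
    return out


def discrimination_vector(stats_i: ClassStatistics, stats_j: ClassStatistics) -> np.ndarray:
    """d_ij over all K features at once (symmetric in i and j)."""
    gap = np.abs(stats_i.mean - stats_j.mean)
    pooled = stats_i.prior * stats_i.std ** 2 + stats_j.prior * stats_j.std ** 2
    denom = np.sqrt(pooled)
    with np.errstate(divide="ignore", invalid="ignore"):
        expo = np.where(denom > 0, gap / np.where(denom > 0, denom, 1.0), 0.0)
    degenerate = (denom == 0) & (gap > 0)
    if np.any(degenerate):
        warnings.warn(
            f"zero pooled variance with nonzero mean gap between classes "
            f"{stats_i.label!r} and {stats_j.label!r}; exponent clipped at {E_MAX}",
            DegenerateVarianceWarning,
            stacklevel=2,
        )
        expo = np.where(degenerate, E_MAX, expo)
    expo = np.minimum(expo, E_MAX)
    return np.exp(expo)


def discrimination_index(stats_i: ClassStatistics, stats_j: ClassStatistics, k: int) -> float:
    """Exponential class discrimination index d_ij[k] for one feature."""
    K = stats_i.mean.size
    if not 0 <= k < K:
        raise ParameterError(f"feature index {k} out of range [0, {K})")
    return float(discrimination_vector(stats_i, stats_j)[k])


def _saliency_components(
    d: np.ndarray, weights: np.ndarray, normalize_weights: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Saliency, weighted geometric mean G and homogeneity H from a
    (N_c - 1) x K discrimination matrix and the other-class priors."""
    w = weights[:, None]
    S = float(weights.sum())
    log_d = np.log(d)
    G = np.exp((w * log_d).sum(axis=0) / S)              # normalized geo mean
    A = (w * d).sum(axis=0) / S                           # normalized arith mean
    H = G / A
    if normalize_weights:
        sal = G ** 2 / A
    else:
        sal = np.exp((w * log_d).sum(axis=0)) ** 2 / (w * d).sum(axis=0)
    return sal, G, H


def class_saliency(
    all_stats: list[ClassStatistics],
    i: str,
    k: int,
    normalize_weights: bool = False,
) -> tuple[float, float, float]:
    """Saliency of class ``i`` on feature ``k``.

    Returns ``(saliency, geo_mean, homogeneity)``.  With
    ``normalize_weights=True`` the other-class priors are renormalized to
    sum to 1, in which case saliency equals geo_mean x homogeneity exactly.
    """
    if len(all_stats) < 2:
        raise EstimationError("need at least two classes")
    stats_i = _find(all_stats, i)
    others = [s for s in all_stats if s.label != i]
    d = np.vstack([discrimination_vector(stats_i, s) for s in others])
    weights = np.array([s.prior for s in others])
    sal, G, H = _saliency_components(d, weights, normalize_weights)
    K = stats_i.mean.size
    if not 0 <= k < K:
        raise ParameterError(f"feature index {k} out of range [0, {K})")
    return float(sal[k]), float(G[k]), float(H[k])


def _find(all_stats: list[ClassStatistics], label: str) -> ClassStatistics:
    for s in all_stats:
        if s.label == label:
            return s
    raise ParameterError(f"no class labeled {label!r}")


def build_profiles(
    matrix: SpikeMatrix, normalize_weights: bool = True
) -> dict[str, SaliencyProfile]:
    """Full K-length discrimination / geo-mean / homogeneity / saliency
    vectors for every class in the matrix."""
    all_stats = estimate_class_stats(matrix)
    profiles: dict[str, SaliencyProfile] = {}
    for stats_i in all_stats:
        others = [s for s in all_stats if s.label != stats_i.label]
        d = np.vstack([discrimination_vector(stats_i, s) for s in others])
        weights = np.array([s.prior for s in others])
        sal, G, H = _saliency_components(d, weights, normalize_weights)
        profiles[stats_i.label] = SaliencyProfile(
            class_label=stats_i.label,
            other_labels=[s.label for s in others],
            discrimination=d,
            geo_mean=G,
            homogeneity=H,
            saliency=sal,
        )
    return profiles


def feature_correlation(
    matrix: SpikeMatrix,
    i: str,
    kappa: int,
    h_feature: int,
    population: str = "class",
) -> float:
    """Absolute Pearson correlation between two feature columns.

    Computed over the spikes of class ``i`` only by default
    (``population="class"``); ``population="pooled"`` uses all spikes.
    Returns 0 when either column is constant.
    """
    if population == "class":
        rows = matrix.waveforms[matrix.labels == i].astype(float)
    elif population == "pooled":
        rows = matrix.waveforms.astype(float)
    else:
        raise ParameterError("population must be 'class' or 'pooled'")
    if rows.shape[0] < 3:
        raise EstimationError(f"class {i!r} needs at least 3 spikes for correlation")
    x, y = rows[:, kappa], rows[:, h_feature]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


def select_salient_features(
    matrix: SpikeMatrix,
    i: str,
    L: int,
    max_index: int | None = None,
    population: str = "class",
) -> SalientFeatureSet:
    """Greedy decorrelated selection of the L most salient features of class i.

    Step 1 takes the feature of maximum saliency; step l maximizes
    saliency * prod_{h<l} (1 - rho(candidate, selected_h)) over the features
    not yet selected.  Ties break toward the smaller feature index.
    ``max_index`` (exclusive) restricts the search range — used for
    hardware-compatible configurations whose feature-index registers are
    narrower than the spike length.
    """
    K = matrix.n_samples
    search_K = K if max_index is None else min(K, max_index)
    if not 1 <= L <= search_K:
        raise ParameterError(f"L must be in [1, {search_K}]")
    all_stats = estimate_class_stats(matrix)
    stats_i = _find(all_stats, i)
    others = [s for s in all_stats if s.label != i]
    d = np.vstack([discrimination_vector(stats_i, s) for s in others])
    weights = np.array([s.prior for s in others])
    # G x H saliency: the literal weighting is constant for two balanced
    # classes, so selection always uses the renormalized form
    sal, _, _ = _saliency_components(d, weights, normalize_weights=True)
    sal = sal[:search_K]

    rows = matrix.waveforms[matrix.labels == i].astype(float) \
        if population == "class" else matrix.waveforms.astype(float)
    cols = rows[:, :search_K]
    col_std = cols.std(axis=0, ddof=1)

    selected: list[int] = []
    criterion_values: list[float] = []
    penalty = np.ones(search_K)
    for _ in range(L):
        crit = sal * penalty
        crit[selected] = -np.inf
        best = int(np.argmax(crit))  # argmax takes the first (smallest) index on ties
        selected.append(best)
        criterion_values.append(float(crit[best]))
        # update the redundancy penalty with the newly selected feature
        rho = _abs_corr_against(cols, col_std, best)
        penalty *= (1.0 - rho)
    corr = np.ones((L, L))
    for a in range(L):
        ra = _abs_corr_against(cols, col_std, selected[a])
        for b in range(L):
            corr[a, b] = 1.0 if a == b else ra[selected[b]]
    return SalientFeatureSet(
        class_label=i,
        indices=selected,
        saliencies=criterion_values,
        correlations=corr,
        K=K,
    )


def _abs_corr_against(cols: np.ndarray, col_std: np.ndarray, idx: int) -> np.ndarray:
    """|Pearson r| of every column against column ``idx``; 0 where degenerate."""
    x = cols[:, idx]
    sx = col_std[idx]
    if sx == 0:
        return np.zeros(cols.shape[1])
    xc = x - x.mean()
    cov = (cols - cols.mean(axis=0)).T @ xc / (len(x) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(col_std > 0, np.abs(cov) / (col_std * sx), 0.0)
    return np.clip(rho, 0.0, 1.0)


def select_all_classes(
    matrix: SpikeMatrix, L: int, max_index: int | None = None
) -> dict[str, SalientFeatureSet]:
    """Salient feature sets for every class in a labeled matrix."""
    return {
        lab: select_salient_features(matrix, lab, L, max_index=max_index)
        for lab in matrix.class_labels()
    }


def save_feature_sets(sets: dict[str, SalientFeatureSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({lab: s.to_dict() for lab, s in sets.items()}, fh, indent=1)
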