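"""Multi-label window discrimination (WD).

Each class gets one axis-aligned rectangular window in its own salient
feature space (default two features, i.e. four borders per class).  A spike
matches a class iff every salient-feature value lies inside the closed
interval of that class's window — so a spike can match several classes
(multi-label), exactly one, or none.  Conflicts are resolved by normalized
window depth; no match yields the explicit ``UNCLASSIFIED`` label, which
evaluation counts as an error.

Window bounds are fit per class from training data: percentile
initialization (default 1st/99th) optionally refined by a coordinate-wise
grid search over the class's order statistics, maximizing one-vs-rest
balanced accuracy.  Axis-aligned closed intervals are what a pair of
hardware comparators can evaluate, which is the point of the method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datatypes import SpikeMatrix
from .errors import ParameterError, TrainingError
from .saliency import SalientFeatureSet

#: Output label for spikes matching no discrimination window.
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class DiscriminationWindow:
    """Axis-aligned box for one class over its salient features."""

    class_label: str
    feature_indices: list[int]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if len(set(self.feature_indices)) != len(self.feature_indices):
            raise ParameterError("feature indices must be distinct")
        if self.lower.shape != self.upper.shape or \
                self.lower.shape != (len(self.feature_indices),):
            raise ParameterError("lower/upper must match feature_indices length")
        if np.any(self.lower > self.upper):
            raise ParameterError("window requires lower <= upper on every axis")

    def contains(self, waveform: np.ndarray) -> bool:
        x = np.asarray(waveform, dtype=float)[self.feature_indices]
        return bool(np.all(x >= self.lower) & np.all(x <= self.upper))

    def depth(self, waveform: np.ndarray) -> float:
        """Normalized depth in [0, 1]: 1 at the center, 0 at a border.

        Zero-width axes contribute depth 1 when the value sits exactly on
        the (collapsed) bound.
        """
        x = np.asarray(waveform, dtype=float)[self.feature_indices]
        center = 0.5 * (self.lower + self.upper)
        half = 0.5 * (self.upper - self.lower)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(half > 0, 1.0 - np.abs(x - center) / np.where(half > 0, half, 1.0), 1.0)
        return float(np.min(d))


@dataclass
class SorterConfig:
    """The full WD parameter payload sent to the online sorter."""

    channel_id: str
    windows: list[DiscriminationWindow]
    L: int
    K: int

    def to_dict(self) -> dict:
        return {
            "channel_id": self.channel_id,
            "L": self.L,
            "K": self.K,
            "windows": [
                {
                    "class": w.class_label,
                    "indices": list(map(int, w.feature_indices)),
                    "lower": w.lower.tolist(),
                    "upper": w.upper.tolist(),
                }
                for w in self.windows
            ],
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, payload: dict) -> "SorterConfig":
        windows = [
            DiscriminationWindow(
                class_label=w["class"],
                feature_indices=list(w["indices"]),
                lower=np.asarray(w["lower"]),
                upper=np.asarray(w["upper"]),
            )
            for w in payload["windows"]
        ]
        return cls(channel_id=payload["channel_id"], windows=windows,
                   L=int(payload["L"]), K=int(payload["K"]))

    @classmethod
    def load(cls, path: str | Path) -> "SorterConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SortResult:
    matched_labels: list[str]
    resolved_label: str
    depth_scores: dict[str, float]


def fit_windows(
    matrix: SpikeMatrix,
    feature_sets: dict[str, SalientFeatureSet],
    p_lo: float = 1.0,
    p_hi: float = 99.0,
    refine: bool = True,
    max_sweeps: int = 10,
    margin: bool = True,
    margin_cap_sigmas: float = 2.0,
) -> SorterConfig:
    """Fit one discrimination window per class.

    Bounds start at the (``p_lo``, ``p_hi``) percentiles of the class's own
    training values on each salient feature.  With ``refine`` on, each bound
    is then greedily moved over the class's order statistics to maximize the
    one-vs-rest balanced accuracy J = (in-window rate of the class +
    out-of-window rate of the rest) / 2, sweeping coordinates until no bound
    changes (at most ``max_sweeps`` sweeps).  Ties prefer the wider window.

    With ``margin`` on, each bound is finally pushed outward halfway toward
    the nearest competitor point that the move could admit (capped at
    ``margin_cap_sigmas`` within-class standard deviations).  This is the
    continuum limit of the prefer-wider tie rule: training J is unchanged,
    but held-out spikes in the class tails — beyond the training extremes —
    stay inside the window.
    """
    if not 0 <= p_lo < p_hi <= 100:
        raise ParameterError("require 0 <= p_lo < p_hi <= 100")
    if not matrix.is_labeled:
        raise TrainingError("window fitting requires a labeled matrix")
    labels = matrix.class_labels()
    missing = [lab for lab in labels if lab not in feature_sets]
    if missing:
        raise TrainingError(f"no salient feature set for classes {missing}")
    W = matrix.waveforms.astype(float)
    windows = []
    for lab in labels:
        fs = feature_sets[lab]
        own = W[matrix.labels == lab][:, fs.indices]
        if own.shape[0] < 2:
            raise TrainingError(f"class {lab!r} has fewer than 2 training spikes")
        others = W[matrix.labels != lab][:, fs.indices]
        lower = np.percentile(own, p_lo, axis=0)
        upper = np.percentile(own, p_hi, axis=0)
        if refine:
            lower, upper = _refine_bounds(own, others, lower, upper, max_sweeps)
        if margin:
            lower, upper = _expand_margins(own, others, lower, upper,
                                           margin_cap_sigmas)
        windows.append(DiscriminationWindow(
            class_label=lab,
            feature_indices=list(fs.indices),
            lower=lower,
            upper=upper,
        ))
    L = len(windows[0].feature_indices)
    return SorterConfig(channel_id=matrix.channel_id, windows=windows,
                        L=L, K=matrix.n_samples)


def balanced_accuracy(own: np.ndarray, others: np.ndarray,
                      lower: np.ndarray, upper: np.ndarray) -> float:
    """One-vs-rest J = (own in-window rate + others out-of-window rate) / 2."""
    in_own = np.all((own >= lower) & (own <= upper), axis=1)
    if others.shape[0] == 0:
        return 0.5 * (float(in_own.mean()) + 1.0)
    in_oth = np.all((others >= lower) & (others <= upper), axis=1)
    return 0.5 * (float(in_own.mean()) + float(1.0 - in_oth.mean()))


def _refine_bounds(own, others, lower, upper, max_sweeps):
    """Coordinate-wise greedy search of window bounds over order statistics."""
    L = own.shape[1]
    lower, upper = lower.copy(), upper.copy()
    for _ in range(max_sweeps):
        changed = False
        for axis in range(L):
            grid = np.unique(own[:, axis])
            # mask of points already inside on the *other* axes
            keep = [a for a in range(L) if a != axis]
            own_ok = np.all((own[:, keep] >= lower[keep]) & (own[:, keep] <= upper[keep]), axis=1)
            oth_ok = (np.all((others[:, keep] >= lower[keep]) & (others[:, keep] <= upper[keep]), axis=1)
                      if others.shape[0] else np.zeros(0, dtype=bool))
            for bound, candidates in (
                ("lower", grid[grid <= upper[axis]]),
                ("upper", grid[grid >= lower[axis]]),
            ):
                best_val, best_j, best_width = None, -np.inf, -np.inf
                for c in candidates:
                    lo = c if bound == "lower" else lower[axis]
                    hi = c if bound == "upper" else upper[axis]
                    j = _axis_balanced_accuracy(own[:, axis], own_ok,
                                                others[:, axis] if others.shape[0] else np.zeros(0),
                                                oth_ok, lo, hi)
                    width = hi - lo
                    if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and width > best_width):
                        best_val, best_j, best_width = c, j, width
                current = lower[axis] if bound == "lower" else upper[axis]
                if best_val is not None and best_val != current:
                    cur_j = _axis_balanced_accuracy(
                        own[:, axis], own_ok,
                        others[:, axis] if others.shape[0] else np.zeros(0),
                        oth_ok, lower[axis], upper[axis])
                    cur_width = upper[axis] - lower[axis]
                    if best_j > cur_j + 1e-12 or (abs(best_j - cur_j) <= 1e-12
                                                  and best_width > cur_width):
                        if bound == "lower":
                            lower[axis] = best_val
                        else:
                            upper[axis] = best_val
                        changed = True
        if not changed:
            break
    return lower, upper


def _expand_margins(own, others, lower, upper, cap_sigmas):
    """Widen each bound halfway toward the nearest admissible competitor.

    A competitor is admissible on an axis if it lies inside the window on
    every other axis (only such points can be admitted by moving this
    bound).  The expansion never exceeds ``cap_sigmas`` within-class
    standard deviations, so windows stay compact when competitors are far
    or absent, keeping the depth-based conflict resolution meaningful.
    """
    L = own.shape[1]
    lower, upper = lower.copy(), upper.copy()
    sigma = own.std(axis=0, ddof=1) if own.shape[0] > 1 else np.zeros(L)
    for axis in range(L):
        keep = [a for a in range(L) if a != axis]
        if others.shape[0]:
            oth_ok = np.all((others[:, keep] >= lower[keep])
                            & (others[:, keep] <= upper[keep]), axis=1)
            vals = others[oth_ok, axis]
        else:
            vals = np.empty(0)
        cap = cap_sigmas * sigma[axis]
        below = vals[vals < lower[axis]]
        gap_lo = (lower[axis] - below.max()) / 2.0 if below.size else np.inf
        lower[axis] -= min(gap_lo, cap)
        above = vals[vals > upper[axis]]
        gap_hi = (above.min() - upper[axis]) / 2.0 if above.size else np.inf
        upper[axis] += min(gap_hi, cap)
    return lower, upper


def _axis_balanced_accuracy(own_x, own_ok, oth_x, oth_ok, lo, hi):
    in_own = own_ok & (own_x >= lo) & (own_x <= hi)
    if oth_x.shape[0] == 0:
        return 0.5 * (float(in_own.mean()) + 1.0)
    in_oth = oth_ok & (oth_x >= lo) & (oth_x <= hi)
    return 0.5 * (float(in_own.mean()) + float(1.0 - in_oth.mean()))


def classify_spike(waveform: np.ndarray, config: SorterConfig) -> SortResult:
    """Match a single spike against every class window (closed intervals)."""
    waveform = np.asarray(waveform, dtype=float)
    if waveform.shape != (config.K,):
        raise ParameterError(f"waveform must have length {config.K}")
    matched = [w.class_label for w in config.windows if w.contains(waveform)]
    depths = {w.class_label: w.depth(waveform)
              for w in config.windows if w.class_label in matched}
    return SortResult(
        matched_labels=matched,
        resolved_label=resolve_label(matched, waveform, config),
        depth_scores=depths,
    )


def resolve_label(matches: list[str], waveform: np.ndarray,
                  config: SorterConfig) -> str:
    """Collapse a multi-label match set to one label.

    No match -> ``UNCLASSIFIED``; one match -> that label; several -> the
    label whose window holds the spike at maximum normalized depth, ties
    broken toward the smallest label.
    """
    if not matches:
        return UNCLASSIFIED
    if len(matches) == 1:
        return matches[0]
    by_label = {w.class_label: w for w in config.windows}
    best = sorted(matches)[0]
    best_depth = by_label[best].depth(waveform)
    for lab in sorted(matches)[1:]:
        d = by_label[lab].depth(waveform)
        if d > best_depth + 1e-15:
            best, best_depth = lab, d
    return best


def sort_stream(matrix: SpikeMatrix, config: SorterConfig) -> np.ndarray:
    """Row-wise classification of a spike matrix; order-preserving, stateless."""
    if matrix.n_spikes and matrix.n_samples != config.K:
        raise ParameterError(
            f"matrix has {matrix.n_samples} samples per spike, config expects {config.K}"
        )
    return np.asarray(
        [classify_spike(row, config).resolved_label for row in matrix.waveforms],
        dtype=str,
    ) if matrix.n_spikes else np.empty(0, dtype=str)
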