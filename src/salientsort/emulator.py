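"""Behavioral model of the on-implant online spike sorter (OSS).

The implant-side sorter is nothing but register banks plus comparators: per
class it stores the salient feature indices (5-bit unsigned), the window
bounds (7-bit signed), and a class identifier (3-bit).  Classification of a
spike is, per configured feature, one index comparison selecting the sample
and two bound comparisons testing lower <= value <= upper — all integer.

This module provides the fixed-point quantization of a float
:class:`~salientsort.windows.SorterConfig` into register words, an
integer-only emulation of the comparator datapath, and the register-bank
memory-budget arithmetic for the shared multi-channel banks.

Quantization is *outward* (lower bound rounds down to the grid, upper bound
rounds up), so a quantized window always contains the float window: the
fixed-point sorter can only gain matches relative to the float path, never
lose the correct one.  Samples wider than the bound registers are compared
after an arithmetic right shift by the width difference (dropping sample
LSBs), which composes with outward rounding to preserve containment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np

from .datatypes import SpikeMatrix
from .errors import ConfigurationError, ParameterError
from .windows import UNCLASSIFIED, SorterConfig


@dataclass(frozen=True)
class BitWidths:
    """Register widths of the OSS datapath."""

    index_bits: int = 5
    bound_bits: int = 7
    classid_bits: int = 3
    sample_bits: int = 8

    def __post_init__(self) -> None:
        for name in ("index_bits", "bound_bits", "classid_bits", "sample_bits"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")


@dataclass(frozen=True)
class RegisterBanks:
    """Geometry of the register banks shared among all channels."""

    n_classes: int = 512
    features_per_class: int = 2

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.features_per_class < 1:
            raise ParameterError("bank dimensions must be >= 1")


@dataclass
class QuantizedConfig:
    """Fixed-point register image of one channel's sorter configuration."""

    channel_id: str
    class_labels: list[str]
    class_ids: np.ndarray           # unsigned, classid_bits wide
    feature_indices: np.ndarray     # (n_classes, L), unsigned, index_bits wide
    lower: np.ndarray               # (n_classes, L), signed, bound_bits wide (grid units)
    upper: np.ndarray               # (n_classes, L), signed, bound_bits wide (grid units)
    shift: int                      # sample right-shift before bound comparison
    K: int

    @property
    def L(self) -> int:
        return int(self.feature_indices.shape[1])

    def dequantized_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Sample-unit interval actually accepted by the integer datapath."""
        step = 1 << self.shift
        return self.lower * step, self.upper * step + (step - 1)

    def to_dict(self) -> dict:
        return {
            "channel_id": self.channel_id,
            "K": int(self.K),
            "L": self.L,
            "shift": int(self.shift),
            "classes": [
                {
                    "label": lab,
                    "class_id": int(cid),
                    "indices": idx.tolist(),
                    "lower": lo.tolist(),
                    "upper": hi.tolist(),
                }
                for lab, cid, idx, lo, hi in zip(
                    self.class_labels, self.class_ids,
                    self.feature_indices, self.lower, self.upper)
            ],
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def register_image(self, widths: BitWidths) -> str:
        """Flat hexadecimal register image: for each class, per feature, the
        concatenated (index, lower, upper, class-id) words."""
        bits = ""
        for cid, idx, lo, hi in zip(self.class_ids, self.feature_indices,
                                    self.lower, self.upper):
            for l in range(self.L):
                bits += format(int(idx[l]), f"0{widths.index_bits}b")
                bits += _to_twos_complement(int(lo[l]), widths.bound_bits)
                bits += _to_twos_complement(int(hi[l]), widths.bound_bits)
                bits += format(int(cid), f"0{widths.classid_bits}b")
        bits += "0" * (-len(bits) % 4)
        return format(int(bits, 2), f"0{len(bits) // 4}x") if bits else ""


def _to_twos_complement(value: int, bits: int) -> str:
    return format(value & ((1 << bits) - 1), f"0{bits}b")


def quantize_config(
    config: SorterConfig,
    widths: BitWidths = BitWidths(),
    full_scale: float | None = None,
) -> QuantizedConfig:
    """Map a float sorter configuration onto fixed-point registers.

    Bounds land on the uniform ``2**bound_bits``-point grid over
    ``[-full_scale, +full_scale)`` (default full scale: the sample range,
    ``2**(sample_bits - 1)``): lower bounds round down, upper bounds round
    up, then saturate to the representable range — the stored window never
    shrinks.  Feature indices are stored verbatim and must fit in
    ``index_bits``.
    """
    if full_scale is None:
        full_scale = float(1 << (widths.sample_bits - 1))
    step = 2.0 * full_scale / (1 << widths.bound_bits)
    if step < 1 or 2 ** round(math.log2(step)) != step:
        raise ConfigurationError(
            f"full scale {full_scale} with {widths.bound_bits} bound bits gives "
            f"grid step {step}; an integer power-of-two step is required for "
            "the integer comparator datapath"
        )
    shift = int(round(math.log2(step)))
    n = len(config.windows)
    L = config.L
    max_index = 1 << widths.index_bits
    qlo = np.zeros((n, L), dtype=np.int64)
    qhi = np.zeros((n, L), dtype=np.int64)
    indices = np.zeros((n, L), dtype=np.int64)
    class_ids = np.arange(n, dtype=np.int64)
    if n > (1 << widths.classid_bits):
        raise ConfigurationError(
            f"{n} classes exceed the {widths.classid_bits}-bit class-id range"
        )
    lo_rep, hi_rep = -(1 << (widths.bound_bits - 1)), (1 << (widths.bound_bits - 1)) - 1
    for c, w in enumerate(config.windows):
        for l, feat in enumerate(w.feature_indices):
            if feat >= max_index:
                raise ConfigurationError(
                    f"class {w.class_label!r} uses feature index {feat}, which "
                    f"does not fit in {widths.index_bits} bits; restrict the "
                    f"salient-feature search range to the first {max_index} samples"
                )
            indices[c, l] = feat
            qlo[c, l] = max(lo_rep, math.floor(w.lower[l] / step))
            qhi[c, l] = min(hi_rep, math.ceil(w.upper[l] / step))
    return QuantizedConfig(
        channel_id=config.channel_id,
        class_labels=[w.class_label for w in config.windows],
        class_ids=class_ids,
        feature_indices=indices,
        lower=qlo,
        upper=qhi,
        shift=shift,
        K=config.K,
    )


def emulate_sort(
    matrix: SpikeMatrix,
    qconfig: QuantizedConfig,
    widths: BitWidths = BitWidths(),
) -> np.ndarray:
    """Integer-only emulation of the OSS comparator datapath.

    Per spike and configured feature: the stored index selects the sample,
    the sample is arithmetic-right-shifted onto the bound grid, and two
    bound comparators test the closed interval.  Multi-label conflicts are
    resolved by the same normalized-depth rule as the float path, computed
    in exact integer (rational) arithmetic.
    """
    W = matrix.waveforms
    if not np.issubdtype(W.dtype, np.integer):
        raise ParameterError("emulate_sort requires integer sample data")
    lo_s, hi_s = -(1 << (widths.sample_bits - 1)), (1 << (widths.sample_bits - 1)) - 1
    if W.size and (W.min() < lo_s or W.max() > hi_s):
        raise ConfigurationError(
            f"samples exceed the signed {widths.sample_bits}-bit range"
        )
    if matrix.n_spikes == 0:
        return np.empty(0, dtype=str)
    if matrix.n_samples != qconfig.K:
        raise ParameterError("sample count does not match configuration")
    # arithmetic right shift == floor division by 2**shift for signed ints
    shifted = W.astype(np.int64) >> qconfig.shift
    selected = shifted[:, qconfig.feature_indices]       # (n_spikes, n_classes, L)
    inside = np.all(
        (selected >= qconfig.lower[None]) & (selected <= qconfig.upper[None]),
        axis=2,
    )                                                     # (n_spikes, n_classes)
    labels_out = np.empty(matrix.n_spikes, dtype=object)
    order = np.argsort(np.asarray(qconfig.class_labels))
    for n in range(matrix.n_spikes):
        matched = np.flatnonzero(inside[n])
        if matched.size == 0:
            labels_out[n] = UNCLASSIFIED
        elif matched.size == 1:
            labels_out[n] = qconfig.class_labels[matched[0]]
        else:
            labels_out[n] = _resolve_integer_depth(
                matched, order, selected[n], qconfig)
    return labels_out.astype(str)


def _resolve_integer_depth(matched, order, selected_n, qconfig) -> str:
    """Max normalized depth among matched classes, ties to smallest label.

    Depth per axis is 1 - |x - center| / half_width; doubling numerator and
    denominator keeps everything integral: depth = (width - |2x - (lo+hi)|)
    / width with width = hi - lo in grid units.  Zero-width axes (matched
    means x sits exactly on the bound) have depth 1.
    """
    best_label, best_depth = None, Fraction(-1)
    matched_set = set(matched.tolist())
    for c in order:
        if c not in matched_set:
            continue
        depth = Fraction(1)
        for l in range(qconfig.L):
            width = int(qconfig.upper[c, l] - qconfig.lower[c, l])
            if width == 0:
                continue
            dist2 = abs(2 * int(selected_n[c, l])
                        - int(qconfig.lower[c, l] + qconfig.upper[c, l]))
            depth = min(depth, Fraction(width - dist2, width))
        if depth > best_depth:
            best_label, best_depth = qconfig.class_labels[c], depth
    return best_label


def memory_report(
    banks: RegisterBanks = RegisterBanks(),
    widths: BitWidths = BitWidths(),
) -> dict:
    """Exact register-bank bit budget of the shared OSS parameter memory.

    Index bank: one index word per class per feature; bound bank: two bound
    words per class per feature; class-id bank: one id word per class per
    feature.  Kibit values divide by 1024.
    """
    entries = banks.n_classes * banks.features_per_class
    index_bits = entries * widths.index_bits
    bound_bits = entries * 2 * widths.bound_bits
    classid_bits = entries * widths.classid_bits
    total = index_bits + bound_bits + classid_bits
    return {
        "index_bank_bits": index_bits,
        "bound_bank_bits": bound_bits,
        "classid_bank_bits": classid_bits,
        "total_bits": total,
        "per_bank_kibit": {
            "index": index_bits / 1024,
            "bound": bound_bits / 1024,
            "classid": classid_bits / 1024,
            "total": total / 1024,
        },
    }
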