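"""Reading and writing spike waveform matrices.

Two interchange formats:

* delimited text — comma-separated, one spike per row, optional header,
  optional trailing ``label`` column;
* flat binary — raw C-order matrix plus a JSON sidecar carrying dtype,
  shape, labels and sampling rate.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .datatypes import DEFAULT_SAMPLE_RATE_HZ, SpikeMatrix
from .errors import FormatError, ParameterError

SIDECAR_SUFFIX = ".json"


def write_spike_matrix(matrix: SpikeMatrix, path: str | Path, format: str = "csv") -> None:
    """Write a spike matrix to ``path`` in ``csv`` or ``binary`` format."""
    path = Path(path)
    if format == "csv":
        _write_csv(matrix, path)
    elif format == "binary":
        _write_binary(matrix, path)
    else:
        raise ParameterError(f"unknown format {format!r}")


def read_spike_matrix(path: str | Path, format: str = "csv") -> SpikeMatrix:
    """Read a spike matrix written by :func:`write_spike_matrix`."""
    path = Path(path)
    if format == "csv":
        return _read_csv(path)
    if format == "binary":
        return _read_binary(path)
    raise ParameterError(f"unknown format {format!r}")


def _write_csv(matrix: SpikeMatrix, path: Path) -> None:
    K = matrix.n_samples
    header = ",".join(f"s{k}" for k in range(K))
    with open(path, "w") as fh:
        if matrix.is_labeled:
            fh.write(header + ",label\n")
            for row, lab in zip(matrix.waveforms, matrix.labels):
                fh.write(",".join(str(int(v)) for v in row) + f",{lab}\n")
        else:
            fh.write(header + "\n")
            for row in matrix.waveforms:
                fh.write(",".join(str(int(v)) for v in row) + "\n")


def _read_csv(path: Path) -> SpikeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    first = lines[0].split(",")
    has_header = not _is_number(first[0])
    has_labels = has_header and first[-1].strip().lower() == "label"
    data_lines = lines[1:] if has_header else lines
    if not has_header and data_lines:
        # headerless: a non-numeric last field means a label column
        has_labels = not _is_number(data_lines[0].split(",")[-1])
    rows, labels = [], []
    width = None
    for ln_no, ln in enumerate(data_lines, start=2 if has_header else 1):
        fields = ln.split(",")
        if has_labels:
            *vals, lab = fields
            labels.append(lab.strip())
        else:
            vals = fields
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise FormatError(
                f"{path}: row {ln_no} has {len(vals)} samples, expected {width}"
            )
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise FormatError(f"{path}: row {ln_no}: {exc}") from exc
    if not rows:
        raise FormatError(f"{path}: no data rows")
    waveforms = np.asarray(rows)
    if np.allclose(waveforms, np.rint(waveforms)):
        waveforms = waveforms.astype(np.int32)
    return SpikeMatrix(
        waveforms=waveforms,
        labels=np.asarray(labels, dtype=str) if has_labels else None,
    )


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _write_binary(matrix: SpikeMatrix, path: Path) -> None:
    arr = np.ascontiguousarray(matrix.waveforms)
    arr.tofile(path)
    sidecar = {
        "dtype": str(arr.dtype),
        "n_spikes": matrix.n_spikes,
        "n_samples": matrix.n_samples,
        "labels": matrix.labels.tolist() if matrix.is_labeled else None,
        "sample_rate_hz": matrix.sample_rate_hz,
        "channel_id": matrix.channel_id,
    }
    with open(path.with_suffix(path.suffix + SIDECAR_SUFFIX), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def _read_binary(path: Path) -> SpikeMatrix:
    sidecar_path = path.with_suffix(path.suffix + SIDECAR_SUFFIX)
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    try:
        dtype = np.dtype(meta["dtype"])
        n_spikes, n_samples = int(meta["n_spikes"]), int(meta["n_samples"])
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{sidecar_path}: invalid sidecar: {exc}") from exc
    expected = n_spikes * n_samples * dtype.itemsize
    actual = path.stat().st_size
    if expected != actual:
        raise FormatError(
            f"{path}: sidecar declares {expected} bytes "
            f"({n_spikes}x{n_samples} {dtype}), file holds {actual}"
        )
    waveforms = np.fromfile(path, dtype=dtype).reshape(n_spikes, n_samples)
    labels = meta.get("labels")
    return SpikeMatrix(
        waveforms=waveforms,
        labels=np.asarray(labels, dtype=str) if labels is not None else None,
        channel_id=meta.get("channel_id", "ch0"),
        sample_rate_hz=meta.get("sample_rate_hz", DEFAULT_SAMPLE_RATE_HZ),
    )
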