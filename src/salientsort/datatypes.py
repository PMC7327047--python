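"""Core containers for spike waveform data.

A *spike* is a short, temporally aligned snippet of an extracellular
recording (default 48 samples at 30 kS/s, i.e. 1.6 ms).  Each sample index
doubles as a feature index for the saliency machinery, so the waveform matrix
(rows = spikes, columns = samples) is the package's canonical data container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: Default number of samples (= features) per aligned spike.
DEFAULT_K = 48

#: Default sampling rate of the emulated recordings, in samples per second.
DEFAULT_SAMPLE_RATE_HZ = 30_000.0


@dataclass(frozen=True)
class SpikeTemplate:
    """Noise-free waveform of one unit (neuron).

    Parameters
    ----------
    samples
        Real-valued amplitudes, length ``K``.
    label
        Class identifier for spikes generated from this template.
    """

    samples: np.ndarray
    label: str

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ParameterError("template samples must be a non-empty 1-D vector")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def peak_to_peak(self) -> float:
        """Trough-to-peak amplitude, ``max(samples) - min(samples)``."""
        return float(np.max(self.samples) - np.min(self.samples))


@dataclass(frozen=True)
class ChannelSpec:
    """Full recipe for synthesizing one recording channel.

    ``snr_per_unit`` uses the convention SNR = peak-to-peak amplitude of the
    template divided by twice the noise standard deviation.
    """

    templates: tuple[SpikeTemplate, ...]
    priors: np.ndarray
    snr_per_unit: np.ndarray
    n_spikes: int
    jitter_samples: int = 0
    quantization_bits: int = 8
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    seed: int = 0
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        templates = tuple(self.templates)
        priors = np.asarray(self.priors, dtype=float)
        snr = np.asarray(self.snr_per_unit, dtype=float)
        n_units = len(templates)
        if n_units < 1:
            raise ParameterError("at least one template is required")
        if priors.shape != (n_units,) or snr.shape != (n_units,):
            raise ParameterError(
                "templates, priors and snr_per_unit must have equal length"
            )
        if abs(priors.sum() - 1.0) > 1e-9 or np.any(priors < 0):
            raise ParameterError("priors must be nonnegative and sum to 1")
        if np.any(snr <= 0):
            raise ParameterError("every per-unit SNR must be positive")
        if self.n_spikes <= 0:
            raise ParameterError("n_spikes must be positive")
        if self.jitter_samples < 0:
            raise ParameterError("jitter_samples must be nonnegative")
        if self.quantization_bits < 2:
            raise ParameterError("quantization_bits must be at least 2")
        lengths = {t.n_samples for t in templates}
        if len(lengths) != 1:
            raise ParameterError("all templates must have the same length")
        object.__setattr__(self, "templates", templates)
        object.__setattr__(self, "priors", priors)
        object.__setattr__(self, "snr_per_unit", snr)

    @property
    def n_units(self) -> int:
        return len(self.templates)

    @property
    def n_samples(self) -> int:
        return self.templates[0].n_samples


@dataclass
class SpikeMatrix:
    """Aligned spike waveforms with optional labels.

    ``waveforms`` holds quantized integer amplitudes, one spike per row;
    ``labels`` (if present) has one class identifier per row.
    """

    waveforms: np.ndarray
    labels: np.ndarray | None = None
    channel_id: str = "ch0"
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms))
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=str)
            if self.labels.shape != (self.waveforms.shape[0],):
                raise ParameterError(
                    f"labels length {self.labels.shape} does not match "
                    f"{self.waveforms.shape[0]} spikes"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.waveforms.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.waveforms.shape[1])

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    def class_labels(self) -> list[str]:
        """Sorted distinct labels present in the matrix."""
        if self.labels is None:
            raise ParameterError("matrix is unlabeled")
        return sorted(set(self.labels.tolist()))

    def with_labels(self, labels: np.ndarray) -> "SpikeMatrix":
        return SpikeMatrix(
            waveforms=self.waveforms,
            labels=np.asarray(labels, dtype=str),
            channel_id=self.channel_id,
            sample_rate_hz=self.sample_rate_hz,
        )


@dataclass
class ContinuousTrace:
    """Single-channel continuous signal with ground-truth spike insertions."""

    signal: np.ndarray
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    spike_labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=str))
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
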