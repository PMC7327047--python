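"""Synthetic extracellular spike generator.

Emulates the statistics of single-channel Utah-array recordings: 2-4 units
per channel, 48-sample spikes at 30 kS/s quantized to 8 bits, per-unit SNR
anywhere from well below 1 up to ~22 (SNR = template peak-to-peak divided by
twice the noise standard deviation).  Templates are biphasic — a sharp
negative trough followed by a slower positive rebound — which is the typical
extracellular action-potential shape near the soma.
"""

from __future__ import annotations

import numpy as np

from .datatypes import ChannelSpec, ContinuousTrace, SpikeMatrix, SpikeTemplate
from .errors import GenerationError, ParameterError

#: Relative head-room of the quantizer full scale over the largest template
#: amplitude on the channel (leaves room for noise excursions).
FULL_SCALE_HEADROOM = 1.2

DEFAULT_MORPHOLOGY = {
    "trough_depth": (45.0, 90.0),     # amplitude units (ADC-ish)
    "trough_latency": (10.0, 24.0),   # samples after window start
    "trough_width": (1.2, 3.2),       # Gaussian sigma, samples
    "rebound_fraction": (0.25, 0.6),  # rebound amplitude / trough depth
    "rebound_lag": (5.0, 11.0),       # samples from trough to rebound peak
    "rebound_width": (3.5, 8.0),      # Gaussian sigma, samples
}


def _biphasic(k: np.ndarray, depth: float, t0: float, w0: float,
              rebound: float, t1: float, w1: float) -> np.ndarray:
    trough = -depth * np.exp(-0.5 * ((k - t0) / w0) ** 2)
    peak = rebound * np.exp(-0.5 * ((k - t1) / w1) ** 2)
    return trough + peak


def generate_templates(
    n_units: int,
    K: int = 48,
    morphology_params: dict | None = None,
    seed: int = 0,
) -> list[SpikeTemplate]:
    """Draw ``n_units`` distinct biphasic spike templates of length ``K``.

    Trough latencies are stratified across units (each unit draws from its
    own slice of the latency range) so that units on the same channel are
    morphologically distinguishable, as real co-recorded neurons are.
    """
    if n_units < 1:
        raise ParameterError("n_units must be >= 1")
    if K < 8:
        raise ParameterError("K must be >= 8")
    params = dict(DEFAULT_MORPHOLOGY)
    if morphology_params:
        params.update(morphology_params)
    rng = np.random.default_rng(seed)
    k = np.arange(K, dtype=float)
    lat_lo, lat_hi = params["trough_latency"]
    lat_edges = np.linspace(lat_lo, lat_hi, n_units + 1)
    templates: list[SpikeTemplate] = []
    for u in range(n_units):
        depth = rng.uniform(*params["trough_depth"])
        t0 = rng.uniform(lat_edges[u], lat_edges[u + 1])
        w0 = rng.uniform(*params["trough_width"])
        rebound = depth * rng.uniform(*params["rebound_fraction"])
        t1 = t0 + rng.uniform(*params["rebound_lag"])
        w1 = rng.uniform(*params["rebound_width"])
        samples = _biphasic(k, depth, t0, w0, rebound, t1, w1)
        templates.append(SpikeTemplate(samples=samples, label=f"u{u}"))
    return templates


def quantization_step(spec: ChannelSpec) -> float:
    """Width of one quantizer LSB for the channel.

    Mid-tread quantizer: full scale is ``FULL_SCALE_HEADROOM`` times the
    largest absolute template amplitude on the channel, mapped onto the
    signed ``quantization_bits`` range.
    """
    max_amp = max(float(np.max(np.abs(t.samples))) for t in spec.templates)
    full_scale = FULL_SCALE_HEADROOM * max_amp
    return full_scale / 2 ** (spec.quantization_bits - 1)


def quantize(values: np.ndarray, step: float, bits: int) -> np.ndarray:
    """Mid-tread quantization with saturation (never wrap-around)."""
    lo, hi = -(2 ** (bits - 1)), 2 ** (bits - 1) - 1
    q = np.rint(np.asarray(values, dtype=float) / step)
    return np.clip(q, lo, hi).astype(np.int32)


def _shift_waveform(w: np.ndarray, shift: int) -> np.ndarray:
    """Shift right by `shift` samples (may be negative), edge-replicating."""
    if shift == 0:
        return w
    out = np.empty_like(w)
    if shift > 0:
        out[shift:] = w[:-shift]
        out[:shift] = w[0]
    else:
        out[:shift] = w[-shift:]
        out[shift:] = w[-1]
    return out


def synthesize_channel(spec: ChannelSpec) -> SpikeMatrix:
    """Generate a labeled spike matrix for one channel.

    Each spike's class is drawn from ``spec.priors``; i.i.d. Gaussian noise
    is added with standard deviation ``peak_to_peak / (2 * SNR)``; an
    optional uniform integer jitter in ``[-jitter_samples, +jitter_samples]``
    emulates alignment error; the result is quantized with saturation.
    """
    rng = np.random.default_rng(spec.seed)
    K = spec.n_samples
    step = quantization_step(spec)
    classes = rng.choice(spec.n_units, size=spec.n_spikes, p=spec.priors)
    waveforms = np.empty((spec.n_spikes, K), dtype=np.int32)
    labels = np.empty(spec.n_spikes, dtype=object)
    noise_std = np.array([
        t.peak_to_peak / (2.0 * snr)
        for t, snr in zip(spec.templates, spec.snr_per_unit)
    ])
    for n, u in enumerate(classes):
        tmpl = spec.templates[u].samples
        if spec.jitter_samples:
            shift = int(rng.integers(-spec.jitter_samples, spec.jitter_samples + 1))
            tmpl = _shift_waveform(tmpl, shift)
        analog = tmpl + rng.normal(0.0, noise_std[u], size=K)
        waveforms[n] = quantize(analog, step, spec.quantization_bits)
        labels[n] = spec.templates[u].label
    return SpikeMatrix(
        waveforms=waveforms,
        labels=labels.astype(str),
        channel_id=spec.channel_id,
        sample_rate_hz=spec.sample_rate_hz,
    )


def planted_feature_channel(
    planted: tuple[int, ...] = (20, 21, 22, 23),
    delta_fraction: float = 0.3,
    snr: float = 4.0,
    n_spikes: int = 400,
    K: int = 48,
    seed: int = 0,
) -> tuple[SpikeMatrix, tuple[int, ...]]:
    """Two-class channel whose classes differ *only* at ``planted`` samples.

    Class ``u1`` equals class ``u0`` plus a mean offset of
    ``delta_fraction * peak_to_peak`` at each planted sample index.  Used
    for feature-recovery experiments: a correct selector must place its
    first salient features inside the planted set.
    """
    base = generate_templates(1, K, seed=seed)[0]
    shifted = base.samples.copy()
    shifted[list(planted)] += delta_fraction * base.peak_to_peak
    templates = (
        SpikeTemplate(samples=base.samples, label="u0"),
        SpikeTemplate(samples=shifted, label="u1"),
    )
    spec = ChannelSpec(
        templates=templates,
        priors=np.array([0.5, 0.5]),
        snr_per_unit=np.array([snr, snr]),
        n_spikes=n_spikes,
        jitter_samples=0,
        seed=seed,
    )
    return synthesize_channel(spec), tuple(planted)


def synthesize_continuous(
    spec: ChannelSpec,
    duration_s: float,
    rate_hz_per_unit: np.ndarray,
) -> ContinuousTrace:
    """Poisson-placed template insertions on Gaussian background noise.

    Insertions are guarded against overlap: any event starting within one
    spike length of an accepted predecessor is dropped.  Raises
    :class:`GenerationError` when the requested rates make non-overlapping
    placement infeasible (expected occupancy above half the trace).
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    rates = np.asarray(rate_hz_per_unit, dtype=float)
    if rates.shape != (spec.n_units,):
        raise ParameterError("one firing rate per unit is required")
    if np.any(rates < 0):
        raise ParameterError("firing rates must be nonnegative")
    K = spec.n_samples
    n_total = int(round(duration_s * spec.sample_rate_hz))
    expected = rates.sum() * duration_s
    if expected * K > 0.5 * n_total:
        raise GenerationError(
            "requested firing rates are too high for non-overlapping spikes"
        )
    rng = np.random.default_rng(spec.seed)
    step = quantization_step(spec)
    # mean noise std across units sets the background level
    noise_std = float(np.mean([
        t.peak_to_peak / (2.0 * snr)
        for t, snr in zip(spec.templates, spec.snr_per_unit)
    ]))
    signal = rng.normal(0.0, noise_std, size=n_total)
    events: list[tuple[int, int]] = []  # (start sample, unit)
    for u, rate in enumerate(rates):
        n_ev = rng.poisson(rate * duration_s)
        starts = rng.integers(0, max(1, n_total - K), size=n_ev)
        events.extend((int(s), u) for s in starts)
    events.sort()
    kept_times, kept_units = [], []
    last_end = -1
    for start, u in events:
        if start <= last_end or start + K > n_total:
            continue
        signal[start:start + K] += spec.templates[u].samples
        kept_times.append(start)
        kept_units.append(u)
        last_end = start + K
    return ContinuousTrace(
        signal=quantize(signal, step, spec.quantization_bits).astype(float),
        spike_times=np.asarray(kept_times, dtype=int),
        spike_labels=np.asarray(
            [spec.templates[u].label for u in kept_units], dtype=str
        ),
        sample_rate_hz=spec.sample_rate_hz,
    )


def detect_and_align(
    trace: np.ndarray,
    threshold: float,
    pre_samples: int = 8,
    K: int = 48,
    polarity: str = "negative",
) -> SpikeMatrix:
    """Threshold-crossing spike detection with fixed-window extraction.

    A crossing is the first sample at or beyond ``threshold`` whose
    predecessor is not (negative-going by default).  A ``K``-sample window is
    cut starting ``pre_samples`` before the crossing, so the crossing sample
    sits at index ``pre_samples`` of every extracted waveform.  A dead time
    of ``K`` samples after each detection suppresses re-triggering; windows
    truncated by the trace boundaries are discarded.
    """
    if not 0 <= pre_samples < K:
        raise ParameterError("require K > pre_samples >= 0")
    if polarity not in ("negative", "positive"):
        raise ParameterError("polarity must be 'negative' or 'positive'")
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        return SpikeMatrix(waveforms=np.empty((0, K), dtype=np.int32))
    if polarity == "negative":
        below = x <= threshold
    else:
        below = x >= threshold
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    windows = []
    next_allowed = 0
    for c in crossings:
        if c < next_allowed:
            continue
        start = c - pre_samples
        if start < 0 or start + K > x.size:
            continue
        windows.append(x[start:start + K])
        next_allowed = c + K
    if not windows:
        return SpikeMatrix(waveforms=np.empty((0, K), dtype=np.int32))
    return SpikeMatrix(waveforms=np.asarray(windows).astype(np.int32))
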