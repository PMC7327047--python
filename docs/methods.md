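# Methods

## Model and procedure

The package implements a two-sided spike-sorting architecture.  The
*online* side is deliberately minimal: per channel, each trained unit owns
an axis-aligned window over `L` salient samples of the aligned waveform
(default `L = 2`, i.e. four stored borders per unit), and a spike belongs
to a unit iff every salient sample lies inside the closed interval of that
unit's window.  Because windows of different units may overlap, matching
is multi-label; conflicts are resolved by normalized window depth (below),
and a spike matching no window is returned as `UNCLASSIFIED` and counted
as an error in every accuracy figure.

The *offline* side trains that classifier: (1) if the training spikes are
unlabeled, k-means clustering on the raw K-dimensional waveforms with the
cluster count chosen by mean silhouette over k = 2…4; (2) a stratified
50–50 train/test split per class; (3) greedy salient feature selection per
class; (4) window fitting per class; (5) fixed-point quantization of the
resulting configuration into register words for the implant; (6)
evaluation on the held-out half.

### Discrimination, saliency, homogeneity

All statistics operate on per-class, per-sample moments (sample mean,
standard deviation with the n−1 denominator, and empirical prior
P_i = n_i/N).  The discrimination index between classes i and j at sample
k is `exp(|μ_i−μ_j| / sqrt(P_i σ_i² + P_j σ_j²))`, a prior-weighted
standardized mean gap mapped through exp so the index is ≥ 1 and products
across classes accumulate separation multiplicatively.

The saliency of class i at sample k aggregates the indices against all
other classes.  Writing S = Σ_{j≠i} P_j, G for the weighted geometric
mean of the d_ij (weights P_j/S) and A for the weighted arithmetic mean,
saliency is computed in two conventions:

* **Product form** ς = G × H with homogeneity H = G/A.  This is the form
  used for feature selection and the profile vectors.  H ∈ (0, 1] by the
  weighted AM–GM inequality, with H = 1 iff the class is equally far from
  every other class.
* **Unnormalized form** ς = (∏ d^{P_j})² / (Σ P_j d), the formula with
  raw priors as weights.  The two coincide exactly when S = 1.  For two
  classes with balanced priors the unnormalized exponent 2P_j − 1
  vanishes and ς ≡ 2 regardless of the data — a degenerate objective —
  which is why selection always uses the product form.  The evaluator
  `class_saliency` exposes both via `normalize_weights`.

Degenerate variances (possible on quantized integer data): a zero pooled
variance with a zero mean gap yields d = 1; with a nonzero gap the
exponent is clipped at 30 (e³⁰ ≈ 1.07 × 10¹³ dominates any finite
competitor without overflowing doubles) and a `DegenerateVarianceWarning`
is raised.

### Greedy selection

Step 1 takes the sample of maximal saliency; step l maximizes
ς[κ] · ∏_{h<l}(1 − ρ(κ, h)) over the remaining samples, where ρ is the
absolute Pearson correlation between sample columns computed over the
spikes of the class being isolated (class-conditional; a pooled variant is
available).  The absolute value treats anti-correlated features as equally
redundant.  Constant columns get ρ = 0.  Argmax ties break toward the
smaller sample index, making selection fully deterministic.  An optional
`max_index` restricts the search to the first 2^5 = 32 samples so that
selected indices always fit the implant's 5-bit index registers; the
training pipeline enables this by default (spike troughs and rebounds sit
well inside the first 32 samples under the alignment convention used).

### Window fitting

The fitting objective is a package design choice (only the window shape is
dictated by the hardware).  Per class and salient feature: bounds start at
the 1st/99th percentiles of the class's training values; a coordinate-wise
greedy search over the class's order statistics then maximizes the
one-vs-rest balanced accuracy J = ½(in-window rate of the class +
out-of-window rate of the rest), sweeping axes until no bound moves (≤ 10
sweeps), ties preferring the wider window.  Finally each bound is pushed
outward halfway toward the nearest competitor point that the move could
admit, capped at 2 within-class standard deviations.  The margin step is
the continuum limit of the prefer-wider tie rule: it cannot change
training J, but it covers the class tails beyond the training extremes —
without it, roughly 2/n of held-out spikes per axis fall just outside the
fitted window and are lost to `UNCLASSIFIED`.

### Conflict resolution

A spike matching several windows resolves to the window holding it at
maximal normalized depth, depth = min over axes of 1 − |x − center| /
half-width (1 at the center, 0 on a border; zero-width axes contribute
depth 1).  Ties resolve to the smallest class label.  The fixed-point path
computes the same rule in exact rational arithmetic on the quantized grid.

### Fixed-point emulation and memory budget

Configuration registers: 5-bit unsigned feature indices, 7-bit signed
window bounds, 3-bit class ids; samples are 8-bit signed.  Bounds are
quantized *outward* (lower floors, upper ceils) onto the 2⁷-point grid
over [−full-scale, +full-scale), full scale defaulting to the sample
range; samples are compared after an arithmetic right shift by
(sample bits − bound bits).  Outward rounding composes with the shift so
the quantized window always contains the float window: the integer path
can only add borderline matches, never drop a correct one.  Exact
float/integer equality therefore cannot hold for spikes within one grid
step of a border; on separable channels (spike mass away from borders)
resolved-label agreement is ≥ 99%, which is the guarantee tested.  For the
512-class shared banks with two features per class this gives exactly
512×2×5 = 5120 bits of indices, 512×2×2×7 = 14336 bits of bounds and
512×2×3 = 3072 bits of class ids (5 / 14 / 3 kibit).

### Evaluation

Per-class CA is recall; Chance is the class's empirical test-set
frequency (the expected recall of proportional random guessing);
CA_CLI = (CA − Chance)/(1 − Chance) and may be negative.  The overall CA
is reported both spike-weighted (total correct / total spikes) and as the
unweighted class mean.  The validation classifier is a Gaussian naive
Bayes with training-frequency priors and a per-feature variance floor of
1e-9 × the mean feature variance (quantized data can have zero
within-class variance); prediction ties resolve to the smallest label.
The static baselines SDE, FSDE, DDsE (lags 1, 3, 7) and ZCF are faithful
to their one-line geometric definitions, not to the cited hardware
implementations.

## Synthetic data

The generator emulates single-channel cortical microelectrode-array
recordings: 48-sample spikes at 30 kS/s quantized to 8 bits with
saturation (mid-tread, full scale = 1.2 × the largest template amplitude
on the channel), 2–4 biphasic units per channel with trough latencies
stratified across units, i.i.d. Gaussian noise with SNR defined as
template peak-to-peak over twice the noise standard deviation (per-unit
SNR configurable anywhere in the ~0.3–22 range of real recordings),
optional ±1-sample alignment jitter, and Poisson-timed insertions with a
refractory guard for continuous traces.  Default study sizes: 250 spikes
per unit ("hundreds" per class), 50-channel campaigns at SNR 8 for
end-to-end evaluation, 200 channels across the full SNR range for the
saliency–accuracy correlation.

What it does *not* emulate — and hence what passing tests do not show
about real data: overlapping spikes (collisions), electrode drift and
waveform nonstationarity, correlated or non-Gaussian noise, bursting
cells with amplitude decrement, and multi-electrode geometry.  Real
recordings also contain unit counts and SNRs outside the configured
range on some channels.  Synthetic channels at SNR 8 separate almost
perfectly (held-out CA ≈ 99.8%), which exercises the machinery end to end
but is easier than typical in vivo data.

## Numerical conventions and degenerate inputs

* Seeds: every random operation takes an explicit integer seed
  (`numpy.random.default_rng`); identical inputs give bitwise identical
  outputs, including the CLI's written files.
* Silhouette: s = (b − a)/max(a, b); 0/0 → 0; singleton clusters → 0;
  model selection ties go to the smaller k.
* k-means: scikit-learn, k-means++ init, best of 10 restarts, tolerance
  1e-6, ≤ 300 Lloyd iterations.
* Detection: negative-going first threshold crossing (configurable
  polarity); the crossing sample sits at index 8 of the extracted window;
  K-sample dead time; truncated windows discarded.
* Quantization never wraps: all paths saturate at the signed range.
* Window intervals are closed on both sides (a value equal to a border is
  inside), matching ≤ comparator semantics and stable under quantization.

## Known limitations

* The window-fitting search is axis-wise greedy and can stop at local
  optima of J; the margin heuristic assumes roughly unimodal class
  marginals.
* Saliency is a first/second-moment statistic: units distinguishable only
  by higher moments or by temporal correlations are invisible to it.
* The emulator models the comparator datapath and register contents, not
  timing, power, or the telemetry protocol.
* With fewer than ~10 spikes per class, percentile initialization and the
  order-statistic grid collapse; training requires at least 2 spikes per
  class and realistically needs dozens.
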