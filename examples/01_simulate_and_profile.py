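"""Generate a synthetic 3-unit channel and inspect its saliency profiles.

Builds 750 labeled spikes (48 samples, 8-bit, SNR 8), then computes each
class's per-feature saliency — the weighted geometric mean of its
discrimination indices against the other classes times the homogeneity of
that separation.  The argmax of a class's saliency vector is its most
salient feature (MSF): the single sample that best isolates the class.
"""

import numpy as np

import salientsort as ss

matrix, spec = ss.simulate_channel(
    {"n_units": 3, "n_spikes": 750, "snr": 8.0, "seed": 42})
print(f"channel: {matrix.n_spikes} spikes x {matrix.n_samples} samples, "
      f"classes {matrix.class_labels()}")

profiles = ss.build_profiles(matrix)
for label, prof in profiles.items():
    msf = int(np.argmax(prof.saliency))
    print(f"class {label}: MSF = sample {msf:2d}  "
          f"saliency {prof.saliency[msf]:9.1f}  "
          f"geo-mean {prof.geo_mean[msf]:9.1f}  "
          f"homogeneity {prof.homogeneity[msf]:.3f}")

# The MSF sits where this class's waveform departs most reliably from the
# others (usually near a trough or rebound peak); homogeneity near 1 means
# the class is about equally far from every other class at that sample.
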